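# ddgkit

Feature-rich prediction of protein thermostability change (ΔΔG) from point
mutations, for structural bioinformaticians who want a fully inspectable,
download-free pipeline: featurization from structure, antisymmetric dataset
construction, recursive feature elimination with a gradient-boosted tree
regressor, and an evaluation suite that takes the reverse-mutation theory
seriously.

## The science in brief

A point mutation A→B changes the folding free energy by
ΔΔG = ΔG(mutant) − ΔG(wild type), in kcal/mol. Because ΔG is a state
function, the hypothetical reverse mutation must satisfy

    ΔΔG(A→B) = −ΔΔG(B→A)

ddgkit builds this antisymmetry into every stage:

* **Datasets** — raw mutation tables (PDB id, substitution like `K6Q`,
  chain, pH, temperature, ΔΔG) are validated, merged (duplicates collapse;
  conflicting measurements resolve to the value nearest 0), and augmented
  with reverse twins carrying negated labels. Splits and cross-validation
  folds treat each direct/reverse pair as one unit, so augmentation can
  never leak across a fold boundary.
* **Features** — four groups totalling 597 registry-ordered columns:
  wild-type structure/environment over 7/10/13 Å shells and the whole
  protein (residue categories, secondary structure, burial, interactions,
  pharmacophores, hydrophobic clusters, disorder, RSA, Gaussian-network
  fluctuations, energy terms, conditions); mutant−wild-type differences;
  mutation-type encodings (one-hots, category flags, BLOSUM62, SIFT);
  evolutionary PSSM scores around the site (26 features). External-tool
  outputs (FoldX, DSSP, SIFT, disorder, B-factor) are ingested from saved
  reports via parsers; internal geometric baselines cover every step so the
  pipeline runs with zero external binaries.
* **Modelling** — XGBoost regression, pair-level k-fold cross-validation
  scored by R² = 1 − SSE/SST, recursive feature elimination that removes
  the single least-important feature (total gain) per round and selects the
  round with the highest mean R².
* **Evaluation** — γ (Pearson), σ (RMSE) and R² over all/direct/reverse
  records; antisymmetry metrics γ_dir,rev (ideal −1) and δ, the mean
  per-pair prediction sum (ideal 0); biased MMD² under an RBF kernel for
  distribution comparison; Steiger's Z for dependent correlations;
  equal-count-bin calibration.

See `docs/methods.md` for the full model description, all geometric
constants, and known limitations.

## Worked example

Train and evaluate on a synthetic planted-signal benchmark (200
direct/reverse pairs, 4 informative of 20 features, noise σ = 0.2):

```python
from ddgkit.synthetic import make_ddg_benchmark
from ddgkit.pipeline import crossval_pairlevel
from ddgkit.evaluation import evaluate_predictions

bench = make_ddg_benchmark(n_pairs=200, n_features=20, n_informative=4,
                           noise_sd=0.2, seed=11)
scores, mean_r2, std_r2, oof = crossval_pairlevel(bench.table, k=5, seed=0,
                                                  return_predictions=True)
print(f"5-fold pair-level CV: mean R^2 = {mean_r2:.3f} (sd {std_r2:.3f})")

direct = bench.table.origins == "direct"
report = evaluate_predictions(
    oof[direct], bench.table.labels[direct],
    oof[~direct], bench.table.labels[~direct],
)
print(f"gamma_all = {report.gamma_all:.3f}   sigma_all = {report.sigma_all:.3f} kcal/mol")
print(f"gamma_dir_rev = {report.gamma_dir_rev:.3f}   delta = {report.delta:.4f} kcal/mol")
```

prints

```
5-fold pair-level CV: mean R^2 = 0.890 (sd 0.037)
gamma_all = 0.954   sigma_all = 1.086 kcal/mol
gamma_dir_rev = -0.987   delta = 0.0650 kcal/mol
```

The out-of-fold correlation (γ_all) and error (σ_all) describe held-out
prediction quality; γ_dir,rev near −1 and δ near 0 show the model has
learnt the antisymmetric response, i.e. it predicts a reverse mutation as
the near-exact negation of its direct twin.

Real data flows through the CLI:

```bash
ddgkit featurize --input raw.csv --pdb-dir structures/ --pssm-dir profiles/ \
                 --out features.csv
ddgkit select   --features features.csv --k 20 --seed 42 --out trace.json
ddgkit train    --features features.csv --subset trace.json --out model
ddgkit predict  --model model --features features.csv --out pred.csv
ddgkit evaluate --pred pred.csv --truth features.csv --paired --out report.json
ddgkit saturate --pdb structures/1ABC.pdb --chain A --out saturation.csv
```

or in one shot from a config file: `ddgkit pipeline --config run.json`.

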
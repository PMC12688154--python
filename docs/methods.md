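# Methods

## Problem and model

A point mutation changes a protein's folding free energy by ΔΔG (kcal/mol);
predicting ΔΔG from structure is the core task of computational
thermostability engineering. ddgkit implements a feature-based approach: each
mutation record (structure, chain, site, substitution, pH, temperature,
measured ΔΔG) is expanded into a wide numeric feature vector, and a
gradient-boosted tree regressor is trained on the labelled vectors after
recursive feature elimination.

Because ΔΔG is a thermodynamic state function, the hypothetical reverse
mutation B→A must satisfy ΔΔG(B→A) = −ΔΔG(A→B). This antisymmetry drives
three design choices that run through the whole package:

1. **Augmentation.** Every direct record gains a reverse twin with negated
   label, swapped amino acids and identical conditions; the two share a
   `pair_id`.
2. **Pair-level splitting.** Train/test splits and cross-validation folds
   operate on pairs, never on individual records, so an augmented twin can
   never leak information about its sibling across a fold boundary. A guard
   assertion inside the CV loop verifies the invariant on every fold.
3. **Role swap in featurization.** For a reverse record the mutant structure
   plays the wild-type role and vice versa. Every internally computed
   difference feature is then an exact negation of its direct twin, which is
   what lets a tree model learn the antisymmetric response.

## Feature groups

The default registry carries 597 named columns in four groups (counts are the
registry's own manifest; the registry, not any external tabulation, is the
source of truth for composition and order):

* **Group 1 — wild-type structure and environment (252).** Over each of four
  spatial regions (residues within 7, 10 and 13 Å of the mutation site, and
  the whole structure): 20 amino-acid proportions, 8 category proportions,
  8-class secondary-structure distribution, buried/exposed fractions,
  6 interaction-type counts, 8 pharmacophore counts, hydrophobic-cluster
  count/largest/fraction, and disorder proportion. Site-level: RSA, GNM
  fluctuation, B-factor (experimental column or adapter), three
  physicochemical scales of the wild-type residue. Adapter-level: the 20
  wild-type FoldX-style energy terms (masked when no report is supplied).
  Conditions: pH and temperature as plain numeric features.
* **Group 2 — mutant − wild-type differences (238).** The same quantities
  recomputed on the mutant structure and differenced, except disorder and
  buried/exposed proportions, which barely move under a single point
  mutation and are excluded.
* **Group 3 — mutation type (81).** One-hot wild-type and mutant residues
  (20 + 20), category-membership flags for both (8 + 8), site secondary
  structure before/after (8 + 8), per-type interaction-count deltas at the
  site (6), BLOSUM62 lookup (1), SIFT score and tolerated flag (2, masked
  without a report).
* **Group 4 — evolutionary (26).** Profile log-odds at the site and the ±5
  surrounding positions for the wild-type and mutant residues (11 + 11), the
  two surrounding-window averages, and the two differences
  (`diff_PSSM_score`, `diff_PSSM_score_aver`). The half-width 5 is the value
  at which 2·(2w+1) + 4 equals the printed group size of 26, and is
  configurable. Mutant scores reuse the wild-type profile matrix (the mutant
  residue's column at the mutated position) — standard practice that avoids
  re-running a profile search per mutant; a provider hook accepts genuine
  mutant profiles.

Missing values are masked (NaN), never zero-imputed; the tree learner handles
them natively. A strict mode in prediction aborts on missing model features.

## Geometric baselines and their constants

The package is runnable with zero external binaries. Where a published
pipeline would call an external tool, ddgkit substitutes a documented
internal baseline and exposes a parser/adapter for the tool's saved output:

* **SASA** — Shrake–Rupley sphere-point quadrature, probe 1.4 Å, 960
  deterministic golden-spiral points per atom, element vdW radii
  C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 / P 1.80 (default 1.70).
  RSA divides by the theoretical maximum ASA per residue (Tien et al. 2013)
  and is clipped to [0, 1.2]; burial threshold RSA < 0.25.
* **Secondary structure** — (φ, ψ) Ramachandran-region table mapped to the
  eight DSSP-style classes (3₁₀-, α-, π-helix, turn, extended β, β-bridge,
  bend, other/loop). The region table is an explicit, overridable constant;
  termini and chain breaks (C–N > 2.0 Å) are other/loop. A DSSP-file adapter
  overrides the baseline when real assignments are supplied.
* **Flexibility** — Cα Gaussian network model, contact cutoff 7.3 Å;
  fluctuations are the diagonal of the Moore–Penrose pseudo-inverse of the
  Kirchhoff matrix, normalised to unit mean. This is a *baseline* stand-in
  for normal-mode analysis, not a numeric replication of any package.
* **Interactions** — geometric criteria: donor/acceptor N/O ≤ 3.5 Å
  (hydrogen bond), SG–SG ≤ 2.5 Å (disulfide), charged-group atoms ≤ 4.0 Å
  (ionic), heavy atoms within vdW-radii sum + 0.5 Å for non-adjacent
  residues (van der Waals), cation-to-ring-centroid ≤ 5.0 Å (π–cation),
  ring-centroid distance ≤ 6.5 Å (π–π). A pair may satisfy several criteria
  and contributes one edge per satisfied type.
* **Pharmacophores** — a (residue, atom-name) → class-set table in the
  mCSM style; classes are not mutually exclusive, so an atom increments
  every class it belongs to (e.g. ring atoms are aromatic *and*
  hydrophobic). Untyped carbons are hydrophobic, other untyped atoms
  neutral.
* **Hydrophobic clusters** — nodes {A, V, L, I, M, F, W, C}, edge when
  side-chain heavy atoms come within 4.5 Å, clusters are connected
  components of size ≥ 2.
* **Disorder** — provider-backed only; the baseline labels everything
  ordered (proportion 0) and flags the value, since re-implementing a
  neural disorder predictor is out of scope.
* **Mutant structures** — baseline truncation to Cβ (renamed residue,
  backbone + Cβ kept, Cβ dropped for glycine), flagged
  `sidechain_incomplete`; full side-chain modelling plugs in through the
  same `ProteinStructure` interface.
* **Amino-acid categories** — the four charge/polarity categories partition
  the 20 residues (uncharged polar STNQCY, positive KRH, negative DE,
  nonpolar AVLIMFWPG); aromatic FWYH, aliphatic AVLI, heterocyclic PHW and
  sulfur-containing CM overlap them. The membership table is shipped
  explicitly because category names alone do not determine memberships.

The shell-membership metric is the minimum heavy-atom distance between
residues (Cα-only mode behind a flag). The distance convention for the
7/10/13 Å regions is this package's documented choice, not an inference
about any other implementation.

## Dataset mechanics

Merging groups records by (mutation key, pH, temperature): identical ΔΔG
duplicates collapse to one; conflicting ΔΔG values resolve to the record
with the smallest |ΔΔG| (values nearer zero are treated as the more reliable
measurement), ties to the first encountered. Records differing in pH or
temperature are distinct. Output preserves first-occurrence order so that
downstream seeded shuffles are reproducible.

The train/test split shuffles pairs with a seed (default 42) and takes the
first ⌈0.9·n⌉ pairs for training — the ceiling rule reproduces the
7,089/787 pair split from 7,876 pairs (0.9 · 7,876 = 7,088.4). Fold
assignment shuffles pairs and deals them into k blocks whose sizes differ by
at most one; the default k is 20, configurable down to 3 for desk-scale
runs.

## Learning stack

The regressor is XGBoost (gradient-boosted trees with L1/L2 regularisation
and native missing-value support), `tree_method="hist"`, single-threaded for
determinism, seeded explicitly. Defaults: 200 trees, depth 6, learning rate
0.1, subsample/colsample 0.9, α 0.1, λ 1.0. Feature importance is total
gain; features the booster never splits on score 0.

RFE removes exactly one feature per round. Each round records the pair-level
cross-validated mean and standard deviation of R² for the current set, then
drops the least-important feature, ties broken by removing the later
registry column (a deterministic convention). The optimal subset is the
remaining set at the round with the highest mean R². A zero-variance
validation fold makes R² undefined and raises a descriptive error rather
than returning a sentinel; folds with fewer than two pairs are rejected.

Hyperparameter search is a hook: the default is seeded random search over
listed candidate values; any strategy (e.g. Bayesian optimisation) can be
plugged in as a generator of parameter dicts. The best score always equals
the maximum over the trial log.

## Evaluation

R² is 1 − SSE/SST over the held-out fold (it can be negative and is not a
squared correlation). γ is the textbook Pearson
coefficient and σ the root mean square error, each reported over all
records, the direct subset and the reverse subset. Antisymmetry is
summarised by γ_dir,rev (Pearson between paired direct and reverse
predictions; ideal −1) and δ (mean of per-pair prediction sums; ideal 0).

MMD² uses the biased V-statistic with all diagonal terms included — the
estimator as printed, not the unbiased U-statistic — under an RBF kernel
with bandwidth parameter defaulting to 1/dimension (recorded in the result).
Steiger's Z compares two dependent correlations sharing one variable
(Fisher-z difference scaled by the dependent covariance term); the p-value
is one-tailed upper, the convention consistent with published (z, p) pairs
such as (1.83, 0.03) and (0.92, 0.17), which appear truncated to two
decimals. Calibration sorts by the true values into equal-count bins
(remainder spread over the leading bins) and reports per-bin mean
prediction, mean truth and the standard error of the residuals.

## Synthetic data

The generators emulate formats and statistical structure, not protein
physics:

* Helical peptides are built from ideal internal coordinates at exact
  (φ, ψ); they exercise the PDB round-trip, shells, SASA, secondary
  structure and GNM code paths, but have no packing, no sidechains beyond
  Cβ, and no tertiary contacts.
* Profile/property files are seeded random values wrapped in the exact
  flat-file dialects, with ground truth returned for round-trip assertions.
* The ΔΔG benchmark plants a linear signal: direct labels are
  w·x over 5 informative of 40 standard-normal features plus
  Normal(0, 0.2) noise, with 500 pairs; the reverse row negates the
  informative block, the noise term and the label, so pair antisymmetry is
  exact by construction. Weights are drawn from ±U(0.5, 2). The noise level
  and sizes are chosen so that signal recovery is decisive but not trivial
  (signal-to-noise ≈ 40:1 in variance); passing shows the selection and
  modelling machinery is correct, not that real ΔΔG data are this easy.
* The raw mutation-table generator enumerates unique keys deterministically
  and draws ΔΔG ~ Normal(0, 1.5), the rough spread of curated
  thermostability measurements, at pH 7 and 25 °C.

Desk-scale problem sizes used by the shipped checks: dataset mechanics run
at the published scale (7,876 records); the recovery benchmark runs the full
RFE (40 → 1 features) with 3-fold pair-level CV, a size chosen so the whole
stack executes end to end on one CPU in a few minutes.

## Known limitations

* The internal baselines (SASA radii, Ramachandran regions, interaction
  cutoffs, GNM) are documented conventions, not replications of DSSP,
  RING, FoldX or NMA numerics; parity with those tools is explicitly not
  claimed. Adapters exist precisely so real tool outputs can replace the
  baselines.
* The baseline mutant (Cβ truncation) under-represents side-chain
  rearrangement; difference features computed from it are conservative.
* Published feature-group totals for this family of pipelines are not
  internally consistent; the registry manifest (252/238/81/26, total 597)
  is this package's own bookkeeping and the only composition it asserts.
* Disorder and SIFT features are masked without reports, so models trained
  purely on internal baselines see slightly fewer effective features.
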
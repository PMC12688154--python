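"""Assembly of the four ΔΔG feature groups into a stable-ordered table.

Group 1 describes the wild-type protein's structure and environment: residue
and category proportions, secondary-structure distribution, buried/exposed
fractions, interaction-type counts, pharmacophore counts, hydrophobic-cluster
summaries and disorder proportion over four spatial regions (7/10/13 Å shells
around the mutation site and the whole structure), plus site-level properties
(RSA, GNM fluctuation, B-factor, physicochemical scales), optional wild-type
energy terms from a saved FoldX report, and the measurement conditions
(pH, temperature).

Group 2 is the mutant-minus-wild-type difference of every shared group-1
feature except the documented exclusions (disorder proportion and the
buried/exposed fractions, which barely move under a point mutation).

Group 3 encodes the mutation type: one-hot wild-type and mutant residues,
category-membership flags on both sides, site secondary structure before and
after, per-type interaction-count deltas at the site, substitution-matrix
lookups, and the optional SIFT score/verdict.

Group 4 is evolutionary: profile log-odds at the mutation site and the ±5
surrounding positions for both wild-type and mutant residues, the two window
averages, and their differences (26 features at the default window).

For a reverse mutation record the mutant structure plays the wild-type role
and vice versa, which makes every internally computed group-2 difference an
exact negation of its direct twin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AA_ALPHABET, DDGDataset, MutationKey, MutationRecord
from .profiles import FOLDX_TERMS, PSSM_ALPHABET, EnergyTermBundle, PSSMProfile
from .structure import (
    ProteinStructure,
    SS_CLASSES,
    assign_secondary_structure,
    build_mutant_baseline,
    gnm_fluctuations,
    relative_accessibility,
    residues_within_radius,
    shrake_rupley_sasa,
)
from .struct_features import (
    AA_CATEGORIES,
    INTERACTION_TYPES,
    PHARMACOPHORE_CLASSES,
    aa_category_proportions,
    hydrophobic_clusters,
    interaction_network,
    pharmacophore_counts,
)

GROUPS = ("G1_wt_struct_env", "G2_diff", "G3_mutation_type", "G4_evolutionary")
SHELLS = ("7", "10", "13", "global")
SHELL_RADII = {"7": 7.0, "10": 10.0, "13": 13.0, "global": math.inf}

# In-code physicochemical scales for the default registry (values indexed by
# 1-letter code).  Kyte–Doolittle hydropathy; residue molecular weight (Da);
# net side-chain charge at pH 7 (His counted as +0.1).
DEFAULT_AA_PROPERTIES: dict[str, dict[str, float]] = {
    "hydropathy_kd": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    "molecular_weight": {
        "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
        "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.15, "I": 131.17,
        "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
        "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
    },
    "net_charge_ph7": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0,
        "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
}

# Group-2 exclusion list: shell-feature stems that are not differenced.
DIFF_EXCLUDED_STEMS = ("disorder", "prop_buried", "prop_exposed")

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    group: str
    shell: str  # one of SHELLS, "site", or "none"
    source: str  # internal | adapter | condition

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _shell_feature_stems() -> list[str]:
    stems = [f"prop_aa_{aa}" for aa in AA_ALPHABET]
    stems += [f"prop_cat_{cat}" for cat in AA_CATEGORIES]
    stems += [f"ss_{cls}" for cls in SS_CLASSES]
    stems += ["prop_buried", "prop_exposed"]
    stems += [f"int_{t}" for t in INTERACTION_TYPES]
    stems += [f"pharm_{c}" for c in PHARMACOPHORE_CLASSES]
    stems += ["hclust_count", "hclust_largest", "hclust_fraction"]
    stems += ["disorder"]
    return stems


@dataclass
class FeatureRegistry:
    """Ordered feature specification; the single source of column order."""

    specs: list[FeatureSpec]
    aaindex_properties: tuple[str, ...]
    matrices: tuple[str, ...]
    window: int
    version: str = "ddgkit-registry-1"

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def manifest(self) -> dict:
        counts = {g: 0 for g in GROUPS}
        for s in self.specs:
            counts[s.group] += 1
        return {
            "version": self.version,
            "group_counts": counts,
            "total": len(self.specs),
            "window": self.window,
            "aaindex_properties": list(self.aaindex_properties),
            "matrices": list(self.matrices),
        }


def default_registry(
    aaindex_properties: tuple[str, ...] = tuple(DEFAULT_AA_PROPERTIES),
    matrices: tuple[str, ...] = ("BLOSUM62",),
    window: int = DEFAULT_WINDOW,
) -> FeatureRegistry:
    specs: list[FeatureSpec] = []

    def add(name, group, shell, source="internal"):
        specs.append(FeatureSpec(name, group, shell, source))

    stems = _shell_feature_stems()
    # group 1: shells
    for shell in SHELLS:
        for stem in stems:
            add(f"wt_shell{shell}_{stem}", "G1_wt_struct_env", shell)
    # group 1: site properties
    add("wt_site_rsa", "G1_wt_struct_env", "site")
    add("wt_site_gnm_fluct", "G1_wt_struct_env", "site")
    add("wt_site_bfactor", "G1_wt_struct_env", "site")
    for prop in aaindex_properties:
        add(f"wt_site_aaindex_{prop}", "G1_wt_struct_env", "site")
    # group 1: wild-type energy terms (adapter-backed)
    for term in FOLDX_TERMS:
        add(f"wt_foldx_{term}", "G1_wt_struct_env", "none", "adapter")
    # group 1: measurement conditions
    add("cond_ph", "G1_wt_struct_env", "none", "condition")
    add("cond_temperature", "G1_wt_struct_env", "none", "condition")

    # group 2: diffs of shell features minus exclusions, site props, energies
    for shell in SHELLS:
        for stem in stems:
            if any(stem.startswith(x) for x in DIFF_EXCLUDED_STEMS):
                continue
            add(f"diff_shell{shell}_{stem}", "G2_diff", shell)
    add("diff_site_rsa", "G2_diff", "site")
    add("diff_site_gnm_fluct", "G2_diff", "site")
    add("diff_site_bfactor", "G2_diff", "site")
    for prop in aaindex_properties:
        add(f"diff_site_aaindex_{prop}", "G2_diff", "site")
    for term in FOLDX_TERMS:
        add(f"diff_foldx_{term}", "G2_diff", "none", "adapter")

    # group 3: mutation-type encodings
    for aa in AA_ALPHABET:
        add(f"mut3_wt_is_{aa}", "G3_mutation_type", "none")
    for aa in AA_ALPHABET:
        add(f"mut3_mut_is_{aa}", "G3_mutation_type", "none")
    for cat in AA_CATEGORIES:
        add(f"mut3_wt_cat_{cat}", "G3_mutation_type", "none")
    for cat in AA_CATEGORIES:
        add(f"mut3_mut_cat_{cat}", "G3_mutation_type", "none")
    for cls in SS_CLASSES:
        add(f"mut3_ss_before_{cls}", "G3_mutation_type", "site")
    for cls in SS_CLASSES:
        add(f"mut3_ss_after_{cls}", "G3_mutation_type", "site")
    for t in INTERACTION_TYPES:
        add(f"mut3_site_int_delta_{t}", "G3_mutation_type", "site")
    for m in matrices:
        add(f"mut3_matrix_{m}", "G3_mutation_type", "none")
    add("mut3_sift_score", "G3_mutation_type", "none", "adapter")
    add("mut3_sift_tolerated", "G3_mutation_type", "none", "adapter")

    # group 4: evolutionary profile features
    for off in range(-window, window + 1):
        add(_pssm_name("wt", off), "G4_evolutionary", "site")
    for off in range(-window, window + 1):
        add(_pssm_name("mut", off), "G4_evolutionary", "site")
    add("wt_PSSM_score_aver", "G4_evolutionary", "site")
    add("mut_PSSM_score_aver", "G4_evolutionary", "site")
    add("diff_PSSM_score", "G4_evolutionary", "site")
    add("diff_PSSM_score_aver", "G4_evolutionary", "site")

    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in registry")
    return FeatureRegistry(
        specs=specs,
        aaindex_properties=tuple(aaindex_properties),
        matrices=tuple(matrices),
        window=window,
    )


def _pssm_name(side: str, offset: int) -> str:
    if offset == 0:
        return f"{side}_PSSM_score"
    sign = "m" if offset < 0 else "p"
    return f"{side}_PSSM_{sign}{abs(offset)}"


#: Per-group counts of the shipped default registry (its own manifest, frozen
#: here so bookkeeping drift is caught by tests).
DEFAULT_MANIFEST_COUNTS = {
    "G1_wt_struct_env": 252,
    "G2_diff": 238,
    "G3_mutation_type": 81,
    "G4_evolutionary": 26,
}


class StructureContext:
    """Caches the per-structure computations shared by all feature groups."""

    def __init__(
        self,
        structure: ProteinStructure,
        dssp: dict | None = None,
        bfactor: dict | None = None,
        disorder: dict | None = None,
        foldx: EnergyTermBundle | None = None,
    ):
        self.structure = structure
        self.dssp = dssp
        self.bfactor = bfactor
        self.disorder = disorder
        self.foldx = foldx
        self._sasa = None
        self._ss = None
        self._gnm = None
        self._edges = None
        self._shells: dict = {}

    @property
    def sasa(self):
        if self._sasa is None:
            self._sasa = shrake_rupley_sasa(self.structure)
        return self._sasa

    @property
    def ss(self):
        if self._ss is None:
            if self.dssp is not None:
                self._ss = {
                    r.rid: self.dssp.get(r.rid, ("other_loop", 0.0))[0]
                    for r in self.structure.residues
                }
            else:
                self._ss = assign_secondary_structure(self.structure)
        return self._ss

    @property
    def gnm(self):
        if self._gnm is None:
            self._gnm = gnm_fluctuations(self.structure)
        return self._gnm

    @property
    def edges(self):
        if self._edges is None:
            self._edges, _ = interaction_network(self.structure)
        return self._edges

    def shell(self, site_rid, shell_key: str):
        ck = (site_rid, shell_key)
        if ck not in self._shells:
            self._shells[ck] = residues_within_radius(
                self.structure, site_rid, SHELL_RADII[shell_key]
            )
        return self._shells[ck]

    def site_bfactor(self, rid) -> float:
        if self.bfactor is not None:
            chain, num, _ = rid
            val = self.bfactor.get((chain, num, ""))
            return float(val) if val is not None else np.nan
        res = self.structure.get_residue(*rid)
        bs = [a.b_factor for a in res.atoms if a.is_heavy]
        return float(np.mean(bs)) if bs else np.nan

    def site_interaction_counts(self, rid) -> dict[str, int]:
        counts = {t: 0 for t in INTERACTION_TYPES}
        for e in self.edges:
            if rid in (e.res_a, e.res_b):
                counts[e.type] += 1
        return counts


def _shell_values(ctx: StructureContext, members: frozenset) -> dict[str, float]:
    structure = ctx.structure
    residues = [r for r in structure.residues if r.rid in members]
    out = dict(aa_category_proportions(residues))
    # secondary-structure distribution
    n = len(residues)
    for cls in SS_CLASSES:
        out[f"ss_{cls}"] = (
            sum(ctx.ss[r.rid] == cls for r in residues) / n if n else 0.0
        )
    # buried/exposed
    if n:
        buried = 0
        for r in residues:
            _, label = relative_accessibility(ctx.sasa[r.rid], r.aa1)
            buried += label == "buried"
        out["prop_buried"] = buried / n
        out["prop_exposed"] = 1.0 - buried / n
    else:
        out["prop_buried"] = out["prop_exposed"] = 0.0
    # interactions restricted to the shell
    _, counts = interaction_network(structure, scope=set(members))
    for t in INTERACTION_TYPES:
        out[f"int_{t}"] = float(counts[t])
    # pharmacophores
    for c, v in pharmacophore_counts(structure, set(members)).items():
        out[f"pharm_{c}"] = float(v)
    # hydrophobic clusters
    _, summary = hydrophobic_clusters(structure, scope=set(members))
    out["hclust_count"] = summary["cluster_count"]
    out["hclust_largest"] = summary["largest_cluster_size"]
    out["hclust_fraction"] = summary["fraction_clustered"]
    # disorder
    if ctx.disorder is not None:
        labels = [bool(ctx.disorder.get((r.chain_id, r.author_number, ""), False))
                  for r in residues]
        out["disorder"] = sum(labels) / n if n else 0.0
    else:
        out["disorder"] = 0.0
    return out


def compute_group1(
    ctx: StructureContext,
    site_rid,
    ph: float,
    temperature_c: float,
    registry: FeatureRegistry,
) -> dict[str, float]:
    """Wild-type structural/environmental feature values (named wt_*/cond_*)."""
    out: dict[str, float] = {}
    for shell in SHELLS:
        members = ctx.shell(site_rid, shell).members
        for stem, v in _shell_values(ctx, members).items():
            out[f"wt_shell{shell}_{stem}"] = v
    res = ctx.structure.get_residue(*site_rid)
    rsa, _ = relative_accessibility(ctx.sasa[site_rid], res.aa1)
    out["wt_site_rsa"] = rsa
    out["wt_site_gnm_fluct"] = float(ctx.gnm.get(site_rid, np.nan))
    out["wt_site_bfactor"] = ctx.site_bfactor(site_rid)
    for prop in registry.aaindex_properties:
        out[f"wt_site_aaindex_{prop}"] = DEFAULT_AA_PROPERTIES[prop][res.aa1]
    for term in FOLDX_TERMS:
        out[f"wt_foldx_{term}"] = (
            ctx.foldx.terms[term] if ctx.foldx is not None else np.nan
        )
    out["cond_ph"] = ph
    out["cond_temperature"] = temperature_c
    return out


def compute_group2_diff(
    wt_values: dict[str, float], mut_values: dict[str, float]
) -> dict[str, float]:
    """Mutant − wild-type differences for every shared feature.

    Inputs are the group-1 dictionaries of the two sides; the exclusion list
    (disorder, buried/exposed) and the condition features are dropped; names
    gain the ``diff_`` prefix.
    """
    if set(wt_values) != set(mut_values):
        raise ValueError("wild-type and mutant feature sets differ")
    out: dict[str, float] = {}
    for name, wt_v in wt_values.items():
        if name.startswith("cond_"):
            continue
        if name.startswith("wt_shell"):
            shell_part, stem = name[len("wt_"):].split("_", 1)
            if any(stem.startswith(x) for x in DIFF_EXCLUDED_STEMS):
                continue
            out[f"diff_{shell_part}_{stem}"] = mut_values[name] - wt_v
        elif name.startswith("wt_site_") or name.startswith("wt_foldx_"):
            out["diff_" + name[len("wt_"):]] = mut_values[name] - wt_v
        else:
            raise ValueError(f"unrecognised group-1 feature name {name!r}")
    return out


def compute_group3_mutation_type(
    key: MutationKey,
    wt_ctx: StructureContext,
    mut_ctx: StructureContext,
    site_rid,
    matrices: dict[str, object],
    sift_entry: tuple[float, bool] | None,
    registry: FeatureRegistry,
) -> dict[str, float]:
    """Mutation-type encodings (one-hots, category flags, SS change, deltas)."""
    out: dict[str, float] = {}
    for aa in AA_ALPHABET:
        out[f"mut3_wt_is_{aa}"] = float(aa == key.wt_aa)
        out[f"mut3_mut_is_{aa}"] = float(aa == key.mut_aa)
    for cat, members in AA_CATEGORIES.items():
        out[f"mut3_wt_cat_{cat}"] = float(key.wt_aa in members)
        out[f"mut3_mut_cat_{cat}"] = float(key.mut_aa in members)
    ss_before = wt_ctx.ss[site_rid]
    ss_after = mut_ctx.ss[site_rid]
    for cls in SS_CLASSES:
        out[f"mut3_ss_before_{cls}"] = float(cls == ss_before)
        out[f"mut3_ss_after_{cls}"] = float(cls == ss_after)
    wt_counts = wt_ctx.site_interaction_counts(site_rid)
    mut_counts = mut_ctx.site_interaction_counts(site_rid)
    for t in INTERACTION_TYPES:
        out[f"mut3_site_int_delta_{t}"] = float(mut_counts[t] - wt_counts[t])
    for mname in registry.matrices:
        mat = matrices.get(mname)
        out[f"mut3_matrix_{mname}"] = (
            float(_matrix_lookup(mat, key.wt_aa, key.mut_aa)) if mat is not None else np.nan
        )
    if sift_entry is not None:
        out["mut3_sift_score"] = float(sift_entry[0])
        out["mut3_sift_tolerated"] = float(bool(sift_entry[1]))
    else:
        out["mut3_sift_score"] = np.nan
        out["mut3_sift_tolerated"] = np.nan
    return out


def _matrix_lookup(mat, a: str, b: str) -> float:
    if hasattr(mat, "lookup"):
        return mat.lookup(a, b)
    return mat[a, b]  # Bio.Align.substitution_matrices Array


def compute_group4_evolutionary(
    pssm: PSSMProfile | None,
    site_position: int,
    wt_aa: str,
    mut_aa: str,
    window: int = DEFAULT_WINDOW,
) -> dict[str, float]:
    """Evolutionary profile features around the mutation site.

    The wild-type values are the profile's log-odds for the sequence residue
    at the site and its ±window neighbours; the mutant values reuse the same
    profile with the mutant residue's column at the site (off-site positions
    are unchanged).  Window averages exclude the site itself and positions
    beyond the sequence ends; out-of-range positions are masked (NaN).
    """
    out: dict[str, float] = {}
    names = (
        [_pssm_name("wt", off) for off in range(-window, window + 1)]
        + [_pssm_name("mut", off) for off in range(-window, window + 1)]
        + ["wt_PSSM_score_aver", "mut_PSSM_score_aver",
           "diff_PSSM_score", "diff_PSSM_score_aver"]
    )
    if pssm is None:
        return {n: np.nan for n in names}
    if not 1 <= site_position <= len(pssm):
        raise IndexError(
            f"site {site_position} outside profile of length {len(pssm)}"
        )
    wt_window, mut_window = [], []
    for off in range(-window, window + 1):
        pos = site_position + off
        if 1 <= pos <= len(pssm):
            seq_aa = pssm.sequence[pos - 1]
            wt_v = pssm.score(pos, seq_aa if off != 0 else wt_aa)
            mut_v = pssm.score(pos, seq_aa if off != 0 else mut_aa)
        else:
            wt_v = mut_v = np.nan
        out[_pssm_name("wt", off)] = wt_v
        out[_pssm_name("mut", off)] = mut_v
        if off != 0 and not np.isnan(wt_v):
            wt_window.append(wt_v)
            mut_window.append(mut_v)
    wt_aver = float(np.mean(wt_window)) if wt_window else np.nan
    mut_aver = float(np.mean(mut_window)) if mut_window else np.nan
    out["wt_PSSM_score_aver"] = wt_aver
    out["mut_PSSM_score_aver"] = mut_aver
    out["diff_PSSM_score"] = out[_pssm_name("mut", 0)] - out[_pssm_name("wt", 0)]
    out["diff_PSSM_score_aver"] = mut_aver - wt_aver
    return out


@dataclass
class FeatureTable:
    """Stable-ordered named feature matrix with ΔΔG labels.

    Missing values are NaN (the mask); rows align 1:1 with records.
    """

    values: pd.DataFrame  # rows = record ids, columns = registry order
    labels: pd.Series  # ddg per row
    registry: FeatureRegistry
    pair_ids: pd.Series | None = None
    origins: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.registry.names:
            raise ValueError("column order does not match the registry")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must align with rows")

    def __len__(self) -> int:
        return len(self.values)

    def write_csv(self, path, manifest_path=None) -> None:
        df = self.values.copy()
        df.insert(0, "ddg", self.labels)
        if self.pair_ids is not None:
            df.insert(0, "pair_id", self.pair_ids)
        if self.origins is not None:
            df.insert(0, "origin", self.origins)
        df.to_csv(path, index_label="record_id")
        if manifest_path is not None:
            manifest = self.registry.manifest()
            manifest["n_rows"] = len(df)
            manifest["mask_fraction"] = float(self.values.isna().mean().mean())
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=2)

    @classmethod
    def read_csv(cls, path, registry: FeatureRegistry | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="record_id")
        meta_cols = [c for c in ("origin", "pair_id", "ddg") if c in df.columns]
        labels = df["ddg"]
        pair_ids = df["pair_id"] if "pair_id" in df.columns else None
        origins = df["origin"] if "origin" in df.columns else None
        values = df.drop(columns=meta_cols)
        if registry is None:
            specs = [FeatureSpec(c, "G1_wt_struct_env", "none", "internal") for c in values.columns]
            registry = FeatureRegistry(
                specs=specs, aaindex_properties=(), matrices=(), window=0,
                version="external",
            )
        return cls(values=values, labels=labels, registry=registry,
                   pair_ids=pair_ids, origins=origins)


@dataclass
class RecordFailure:
    record_index: int
    key: MutationKey
    error: str


def assemble_table(
    dataset: DDGDataset,
    structures: dict[str, ProteinStructure],
    profiles: dict[str, PSSMProfile] | None = None,
    adapters: dict[str, dict] | None = None,
    registry: FeatureRegistry | None = None,
    matrices: dict[str, object] | None = None,
) -> tuple[FeatureTable, list[RecordFailure]]:
    """Featurize every record of a (possibly augmented) dataset.

    ``structures`` maps PDB id → wild-type structure; ``profiles`` maps PDB
    id → wild-type profile; ``adapters`` maps PDB id → a dict with optional
    keys ``foldx`` (wild-type energy bundle), ``foldx_mut`` (substitution →
    bundle), ``sift`` (substitution → (score, tolerated)), ``dssp``,
    ``bfactor``, ``disorder``.  Per-record failures are collected and
    reported; the failing record is simply absent from the table.

    Reverse records swap structure roles: their "wild type" is the mutant
    baseline of the direct mutation and their "mutant" is the original
    structure, which realises the antisymmetry construction exactly.
    """
    registry = registry or default_registry()
    profiles = profiles or {}
    adapters = adapters or {}
    if matrices is None:
        matrices = _default_matrices(registry)
    wt_ctx_cache: dict[str, StructureContext] = {}
    mut_ctx_cache: dict[tuple[str, str], StructureContext] = {}
    rows: list[dict[str, float]] = []
    index: list[str] = []
    labels: list[float] = []
    pair_ids: list[str | None] = []
    origins: list[str] = []
    failures: list[RecordFailure] = []
    for i, rec in enumerate(dataset.records):
        try:
            row = _featurize_record(
                rec, structures, profiles, adapters, registry, matrices,
                wt_ctx_cache, mut_ctx_cache,
            )
        except Exception as exc:  # noqa: BLE001 — atomic per-record failure
            failures.append(RecordFailure(i, rec.key, f"{type(exc).__name__}: {exc}"))
            continue
        rows.append(row)
        index.append(f"r{i:06d}")
        labels.append(rec.ddg)
        pair_ids.append(rec.pair_id)
        origins.append(rec.origin)
    values = pd.DataFrame(rows, index=index, columns=registry.names)
    table = FeatureTable(
        values=values,
        labels=pd.Series(labels, index=index, name="ddg"),
        registry=registry,
        pair_ids=pd.Series(pair_ids, index=index, name="pair_id"),
        origins=pd.Series(origins, index=index, name="origin"),
    )
    return table, failures


def _default_matrices(registry: FeatureRegistry) -> dict[str, object]:
    out: dict[str, object] = {}
    for name in registry.matrices:
        if name == "BLOSUM62":
            from Bio.Align import substitution_matrices

            out[name] = substitution_matrices.load("BLOSUM62")
    return out


def _featurize_record(
    rec: MutationRecord,
    structures,
    profiles,
    adapters,
    registry,
    matrices,
    wt_ctx_cache,
    mut_ctx_cache,
) -> dict[str, float]:
    pdb_id = rec.key.pdb_id
    if pdb_id not in structures:
        raise KeyError(f"no structure supplied for {pdb_id}")
    ad = adapters.get(pdb_id, {})
    direct_key = rec.key if rec.origin == "direct" else rec.key.reversed()
    sub = direct_key.substitution

    if pdb_id not in wt_ctx_cache:
        wt_ctx_cache[pdb_id] = StructureContext(
            structures[pdb_id],
            dssp=ad.get("dssp"),
            bfactor=ad.get("bfactor"),
            disorder=ad.get("disorder"),
            foldx=ad.get("foldx"),
        )
    base_ctx = wt_ctx_cache[pdb_id]
    mkey = (pdb_id, sub)
    if mkey not in mut_ctx_cache:
        mut_struct = build_mutant_baseline(structures[pdb_id], direct_key)
        mut_ctx_cache[mkey] = StructureContext(
            mut_struct,
            dssp=ad.get("dssp"),
            bfactor=ad.get("bfactor"),
            disorder=ad.get("disorder"),
            foldx=ad.get("foldx_mut", {}).get(sub),
        )
    mutant_ctx = mut_ctx_cache[mkey]

    # role assignment: the reverse record's "wild type" is the mutant structure
    if rec.origin == "direct":
        wt_ctx, mut_ctx = base_ctx, mutant_ctx
    else:
        wt_ctx, mut_ctx = mutant_ctx, base_ctx

    site_rid = (rec.key.chain_id, rec.key.position, rec.key.icode)
    row: dict[str, float] = {}
    g1 = compute_group1(wt_ctx, site_rid, rec.ph, rec.temperature_c, registry)
    g1_mut = compute_group1(mut_ctx, site_rid, rec.ph, rec.temperature_c, registry)
    row.update(g1)
    row.update(compute_group2_diff(g1, g1_mut))
    sift = ad.get("sift", {}).get(rec.key.substitution) if ad.get("sift") else None
    row.update(
        compute_group3_mutation_type(
            rec.key, wt_ctx, mut_ctx, site_rid, matrices, sift, registry
        )
    )
    pssm = profiles.get(pdb_id)
    seq_pos = _author_to_seq_position(structures[pdb_id], site_rid) if pssm else 1
    row.update(
        compute_group4_evolutionary(
            pssm, seq_pos, rec.key.wt_aa, rec.key.mut_aa, registry.window
        )
    )
    return row


def _author_to_seq_position(structure: ProteinStructure, site_rid) -> int:
    """1-based index of the site within its chain's residue order."""
    chain_id = site_rid[0]
    for i, res in enumerate(structure.chain_residues(chain_id), start=1):
        if res.rid == site_rid:
            return i
    raise KeyError(f"site {site_rid} not found in chain {chain_id}")
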
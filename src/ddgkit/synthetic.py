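"""Synthetic inputs for building and testing the pipeline without downloads.

Three generator families live here, all pure functions of their arguments
(seed included):

* ideal α-helical peptide structures built from internal coordinates, valid
  fixed-width PDB text that round-trips through the structure parser;
* syntactically valid profile/property files (ASCII PSSM, AAindex1/2) with
  the ground-truth matrices returned alongside the text for round-trip
  assertions;
* ΔΔG benchmarks with planted linear signal and exact direct/reverse
  antisymmetry (reverse rows negate the informative feature block and the
  label), sized for parameter-recovery tests of the RFE/model stack; plus a
  raw mutation-table generator for dataset-mechanics checks at the scale of
  the curated thermostability corpora (thousands of unique records).

These fixtures emulate formats and statistical structure, not protein
physics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AA_ALPHABET, DDGDataset, MutationKey, MutationRecord
from .features import FeatureRegistry, FeatureSpec, FeatureTable
from .profiles import PSSM_ALPHABET
from .structure import ONE_TO_THREE, Atom, ProteinStructure, Residue, write_pdb

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom from three reference atoms (natural extension)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-length * math.cos(angle),
         length * math.sin(angle) * math.cos(dihedral),
         length * math.sin(angle) * math.sin(dihedral)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_helix_structure(
    sequence: str, phi: float = -57.0, psi: float = -47.0, chain_id: str = "A"
) -> str:
    """Build an ideal helical peptide (N, CA, C, O, CB atoms) as PDB text.

    The default (φ, ψ) = (−57°, −47°) is the canonical α-helix, giving the
    usual ~1.5 Å rise and ~100° twist per residue.  Glycine residues carry no
    Cβ.  Sequences shorter than four residues are rejected (no interior
    residue would have both dihedrals defined).
    """
    seq = sequence.strip().upper()
    if len(seq) < 4:
        raise ValueError("helix fixture needs at least 4 residues")
    bad = [aa for aa in seq if aa not in AA_ALPHABET]
    if bad:
        raise ValueError(f"invalid residue letters {bad}")
    omega = 180.0
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    c_pos = [ca_pos[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, len(seq)):
        n_i = _place(n_pos[-1], ca_pos[-1], c_pos[-1], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_pos[-1], c_pos[-1], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(c_pos[-1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)
    residues = []
    for i, aa in enumerate(seq):
        atoms = [
            Atom("N", "N", n_pos[i]),
            Atom("CA", "C", ca_pos[i]),
            Atom("C", "C", c_pos[i]),
        ]
        # carbonyl O anti to the next amide nitrogen
        psi_i = psi if i < len(seq) - 1 else -47.0
        atoms.append(
            Atom("O", "O", _place(n_pos[i], ca_pos[i], c_pos[i],
                                  _B_C_O, _A_CA_C_O, psi_i + 180.0))
        )
        if aa != "G":
            # tetrahedral Cβ from the local N/C frame
            u = n_pos[i] - ca_pos[i]
            v = c_pos[i] - ca_pos[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            bis = -(u + v)
            bis /= np.linalg.norm(bis)
            perp = np.cross(v, u)
            perp /= np.linalg.norm(perp)
            direction = bis * math.cos(math.radians(54.7)) + perp * math.sin(
                math.radians(54.7)
            )
            atoms.append(Atom("CB", "C", ca_pos[i] + _B_CA_CB * direction))
        residues.append(
            Residue(name3=ONE_TO_THREE[aa], chain_id=chain_id,
                    author_number=i + 1, atoms=atoms)
        )
    return write_pdb(ProteinStructure(residues=residues, source="helix-fixture"))


@dataclass
class ProfileFixtures:
    pssm_text: str
    pssm_scores: np.ndarray  # (L, 20)
    aaindex1_text: str
    aaindex1_values: dict[str, np.ndarray]
    aaindex2_text: str
    aaindex2_matrix: np.ndarray  # (20, 20) symmetric


def make_profile_fixtures(sequence: str, seed: int = 0, n_entries: int = 3) -> ProfileFixtures:
    """Seeded PSSM and AAindex fixture files plus their ground-truth values."""
    rng = np.random.RandomState(seed)
    seq = sequence.strip().upper()
    scores = rng.randint(-8, 11, size=(len(seq), 20))
    pssm_lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSSM_ALPHABET) + "   " + "  ".join(PSSM_ALPHABET),
    ]
    percents = rng.randint(0, 100, size=(len(seq), 20))
    for i, aa in enumerate(seq):
        row = " ".join(f"{v:3d}" for v in scores[i])
        prow = " ".join(f"{v:3d}" for v in percents[i])
        pssm_lines.append(f"{i + 1:5d} {aa}  {row}  {prow}  {rng.rand():4.2f} {rng.rand():4.2f}")
    pssm_lines += ["", "                      K         Lambda", ""]

    aaindex1_lines = []
    aaindex1_values = {}
    for e in range(n_entries):
        acc = f"SYNT{e:02d}01"
        vals = np.round(rng.uniform(-5, 5, size=20), 3)
        aaindex1_values[acc] = vals
        aaindex1_lines += [
            f"H {acc}",
            f"D Synthetic property scale {e} (fixture)",
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V",
        ]
        aaindex1_lines.append("  " + "  ".join(f"{v:7.3f}" for v in vals[:10]))
        aaindex1_lines.append("  " + "  ".join(f"{v:7.3f}" for v in vals[10:]))
        aaindex1_lines.append("//")

    tri = np.round(rng.uniform(-4, 4, size=(20, 20)), 2)
    sym = np.tril(tri) + np.tril(tri, -1).T
    aaindex2_lines = [
        "H SYNTM901",
        "D Synthetic substitution matrix (fixture)",
        f"M rows = {PSSM_ALPHABET}, cols = {PSSM_ALPHABET}",
    ]
    for i in range(20):
        aaindex2_lines.append("  " + " ".join(f"{sym[i, j]:6.2f}" for j in range(i + 1)))
    aaindex2_lines.append("//")

    return ProfileFixtures(
        pssm_text="\n".join(pssm_lines) + "\n",
        pssm_scores=scores.astype(float),
        aaindex1_text="\n".join(aaindex1_lines) + "\n",
        aaindex1_values=aaindex1_values,
        aaindex2_text="\n".join(aaindex2_lines) + "\n",
        aaindex2_matrix=sym,
    )


@dataclass
class SyntheticBenchmark:
    """Planted-signal ΔΔG benchmark with exact pair antisymmetry."""

    table: FeatureTable
    informative: list[str]
    weights: np.ndarray
    noise_sd: float
    seed: int


def make_ddg_benchmark(
    n_pairs: int = 500,
    n_features: int = 40,
    n_informative: int = 5,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Generate an augmented feature table with planted linear signal.

    Direct labels are ``w · x_informative + ε`` with ε ~ Normal(0, noise_sd);
    each reverse row negates the informative feature block, the noise term
    and hence the label exactly, mirroring the antisymmetric augmentation
    (non-informative columns are carried over unchanged).
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if n_pairs < 1 or n_features < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.RandomState(seed)
    names = [f"f{i:03d}" for i in range(n_features)]
    inf_idx = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    weights = rng.uniform(0.5, 2.0, size=n_informative) * rng.choice(
        [-1.0, 1.0], size=n_informative
    )
    x_dir = rng.normal(size=(n_pairs, n_features))
    eps = rng.normal(scale=noise_sd, size=n_pairs) if noise_sd > 0 else np.zeros(n_pairs)
    y_dir = x_dir[:, inf_idx] @ weights + eps
    x_rev = x_dir.copy()
    x_rev[:, inf_idx] *= -1.0
    y_rev = -y_dir
    rows, labels, index, pair_ids, origins = [], [], [], [], []
    for i in range(n_pairs):
        pid = f"p{i:06d}"
        for tag, x, y in (("d", x_dir[i], y_dir[i]), ("r", x_rev[i], y_rev[i])):
            rows.append(x)
            labels.append(y)
            index.append(f"b{i:06d}{tag}")
            pair_ids.append(pid)
            origins.append("direct" if tag == "d" else "reverse")
    values = pd.DataFrame(np.array(rows), index=index, columns=names)
    registry = FeatureRegistry(
        specs=[FeatureSpec(n, "G1_wt_struct_env", "none", "internal") for n in names],
        aaindex_properties=(),
        matrices=(),
        window=0,
        version="synthetic-benchmark",
    )
    table = FeatureTable(
        values=values,
        labels=pd.Series(labels, index=index, name="ddg"),
        registry=registry,
        pair_ids=pd.Series(pair_ids, index=index, name="pair_id"),
        origins=pd.Series(origins, index=index, name="origin"),
    )
    return SyntheticBenchmark(
        table=table,
        informative=[names[i] for i in inf_idx],
        weights=weights,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_raw_ddg_table(n_records: int, seed: int = 0) -> DDGDataset:
    """A raw direct-mutation table with ``n_records`` unique keys.

    Keys cycle deterministically over synthetic 4-character structure ids,
    positions and substitutions; ΔΔG values are drawn Normal(0, 1.5) — the
    rough spread of curated thermostability measurements — at pH 7, 25 °C.
    """
    rng = np.random.RandomState(seed)
    records = []
    combos = itertools.product(
        range(10_000),  # pseudo-structure index
        range(1, 51),  # positions
        itertools.permutations(AA_ALPHABET, 2),
    )
    # regroup so consecutive records vary in substitution first
    flat = (
        (f"S{sidx:03d}", pos, wt, mut)
        for sidx, pos, (wt, mut) in combos
    )
    for pdb_id, pos, wt, mut in itertools.islice(flat, n_records):
        key = MutationKey(pdb_id=pdb_id, chain_id="A", position=pos, wt_aa=wt, mut_aa=mut)
        records.append(
            MutationRecord(
                key=key,
                ph=7.0,
                temperature_c=25.0,
                ddg=float(np.round(rng.normal(scale=1.5), 3)),
            )
        )
    return DDGDataset(records=records, provenance=[f"synthetic(seed={seed})"])
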
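"""Point-mutation ΔΔG datasets: parsing, merging, antisymmetric augmentation,
and pair-level splitting.

A ΔΔG observation is a single point mutation on a protein chain, measured at
some pH and temperature, with the change in folding free energy (kcal/mol) as
the label.  Because ΔΔG is a state function, the hypothetical reverse
mutation B→A at the same site must carry exactly the negated free-energy
change of the direct mutation A→B.  This module materialises that theory:
every direct record can be augmented with its reverse twin, and all
splitting/fold-assignment operations treat a direct/reverse pair as an
indivisible unit so that augmentation can never leak across a train/validation
boundary.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard residues
AA_SET = frozenset(AA_ALPHABET)

_SUBSTITUTION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)([A-Za-z])$")

CSV_COLUMNS = ["pdb_id", "substitution", "chain_id", "ph", "temperature_c", "ddg"]
CSV_COLUMNS_AUGMENTED = CSV_COLUMNS + ["origin", "pair_id"]


class SubstitutionParseError(ValueError):
    """Raised for malformed or chemically invalid substitution strings."""


class DatasetIntegrityError(ValueError):
    """Raised when pairing/origin invariants of a dataset are violated."""


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Parse a substitution string like ``"K6Q"`` into ``(wt, position, mut)``.

    The convention is 1-letter wild-type residue, author sequence position
    (1-based, optional insertion code letter), 1-letter mutant residue.
    Letters are canonicalised to uppercase.

    Returns
    -------
    (wt_aa, position, mut_aa) — the insertion code, when present, is appended
    to the returned position as part of a ``MutationKey`` by callers that need
    it; this function returns the integer position only and raises if an
    insertion code is present (use :func:`parse_substitution_full`).
    """
    wt, pos, icode, mut = parse_substitution_full(text)
    if icode:
        raise SubstitutionParseError(
            f"substitution {text!r} carries insertion code {icode!r}; "
            "use parse_substitution_full"
        )
    return wt, pos, mut


def parse_substitution_full(text: str) -> tuple[str, int, str, str]:
    """Like :func:`parse_substitution` but returns ``(wt, pos, icode, mut)``."""
    token = text.strip()
    if not token:
        raise SubstitutionParseError("empty substitution string")
    m = _SUBSTITUTION_RE.match(token)
    if not m:
        raise SubstitutionParseError(f"malformed substitution string {token!r}")
    wt, pos_s, icode, mut = m.groups()
    wt, mut, icode = wt.upper(), mut.upper(), icode.upper()
    for aa in (wt, mut):
        if aa not in AA_SET:
            raise SubstitutionParseError(
                f"non-standard amino acid {aa!r} in substitution {token!r}"
            )
    if wt == mut:
        raise SubstitutionParseError(
            f"self-substitution {token!r}: wild-type equals mutant"
        )
    pos = int(pos_s)
    if pos < 1:
        raise SubstitutionParseError(f"position must be >= 1 in {token!r}")
    return wt, pos, icode, mut


@dataclass(frozen=True, order=True)
class MutationKey:
    """Identity of a point mutation: structure, chain, site, and substitution."""

    pdb_id: str
    chain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    icode: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_SET or self.mut_aa not in AA_SET:
            raise ValueError(f"non-standard amino acid in {self}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"self-substitution in {self}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def substitution(self) -> str:
        return f"{self.wt_aa}{self.position}{self.icode}{self.mut_aa}"

    def reversed(self) -> "MutationKey":
        """The hypothetical reverse mutation's key (wt and mut swapped)."""
        return replace(self, wt_aa=self.mut_aa, mut_aa=self.wt_aa)

    @classmethod
    def from_strings(cls, pdb_id: str, substitution: str, chain_id: str) -> "MutationKey":
        wt, pos, icode, mut = parse_substitution_full(substitution)
        return cls(pdb_id.strip().upper(), chain_id.strip(), pos, wt, mut, icode)


@dataclass(frozen=True)
class MutationRecord:
    """One ΔΔG observation (direct) or its antisymmetric twin (reverse)."""

    key: MutationKey
    ph: float
    temperature_c: float
    ddg: float
    origin: str = "direct"  # {"direct", "reverse"}
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("direct", "reverse"):
            raise ValueError(f"origin must be 'direct' or 'reverse', got {self.origin!r}")
        if not (np.isfinite(self.ph) and np.isfinite(self.temperature_c)):
            raise ValueError("pH and temperature must be finite")


@dataclass(frozen=True)
class MutationPair:
    """A direct record and its reverse twin, sharing conditions and pair_id."""

    direct: MutationRecord
    reverse: MutationRecord

    def __post_init__(self) -> None:
        d, r = self.direct, self.reverse
        if d.origin != "direct" or r.origin != "reverse":
            raise DatasetIntegrityError("pair members have wrong origins")
        if d.pair_id is None or d.pair_id != r.pair_id:
            raise DatasetIntegrityError("pair members must share a pair_id")
        if r.key != d.key.reversed():
            raise DatasetIntegrityError("reverse key must swap wt/mut at same site")
        if r.ddg != -d.ddg:
            raise DatasetIntegrityError("reverse ddg must equal the negated direct ddg")
        if (d.ph, d.temperature_c) != (r.ph, r.temperature_c):
            raise DatasetIntegrityError("pair members must share pH and temperature")


@dataclass
class DDGDataset:
    """An ordered collection of mutation records with provenance notes."""

    records: list[MutationRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def is_augmented(self) -> bool:
        return any(r.origin == "reverse" for r in self.records)

    def pairs(self) -> list[MutationPair]:
        """Group an augmented dataset into validated direct/reverse pairs.

        Order follows the first occurrence of each pair_id.
        """
        by_id: dict[str, dict[str, MutationRecord]] = {}
        order: list[str] = []
        for rec in self.records:
            if rec.pair_id is None:
                raise DatasetIntegrityError(f"record {rec.key} has no pair_id")
            slot = by_id.setdefault(rec.pair_id, {})
            if rec.origin in slot:
                raise DatasetIntegrityError(
                    f"duplicate {rec.origin} record for pair {rec.pair_id}"
                )
            slot[rec.origin] = rec
            if rec.pair_id not in order:
                order.append(rec.pair_id)
        out = []
        for pid in order:
            slot = by_id[pid]
            if set(slot) != {"direct", "reverse"}:
                raise DatasetIntegrityError(f"pair {pid} is incomplete")
            out.append(MutationPair(slot["direct"], slot["reverse"]))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "pdb_id": r.key.pdb_id,
                    "substitution": r.key.substitution,
                    "chain_id": r.key.chain_id,
                    "ph": r.ph,
                    "temperature_c": r.temperature_c,
                    "ddg": r.ddg,
                    "origin": r.origin,
                    "pair_id": r.pair_id if r.pair_id is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS_AUGMENTED)


def read_ddg_csv(source, name: str | None = None) -> DDGDataset:
    """Read a raw ΔΔG mutation table.

    The schema is a header line of ``pdb_id, substitution, chain_id, ph,
    temperature_c, ddg`` (UTF-8, comma separated, ``.`` decimal).  The
    ``origin``/``pair_id`` columns written by :func:`write_ddg_csv` are
    accepted on re-read.
    """
    df = pd.read_csv(source, dtype={"pdb_id": str, "substitution": str, "chain_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    has_origin = "origin" in df.columns and "pair_id" in df.columns
    records = []
    for row in df.itertuples(index=False):
        key = MutationKey.from_strings(row.pdb_id, row.substitution, row.chain_id)
        origin = getattr(row, "origin", "direct") if has_origin else "direct"
        pair_id = getattr(row, "pair_id", None) if has_origin else None
        if isinstance(pair_id, float) and np.isnan(pair_id):
            pair_id = None
        if pair_id == "":
            pair_id = None
        records.append(
            MutationRecord(
                key=key,
                ph=float(row.ph),
                temperature_c=float(row.temperature_c),
                ddg=float(row.ddg),
                origin=origin,
                pair_id=pair_id,
            )
        )
    prov = [name] if name else [getattr(source, "name", str(source))]
    return DDGDataset(records=records, provenance=prov)


def write_ddg_csv(ds: DDGDataset, target) -> None:
    ds.to_frame().to_csv(target, index=False)


def merge_records(sources: Sequence[DDGDataset]) -> DDGDataset:
    """Merge datasets, deduplicating per (mutation key, pH, temperature).

    Within a duplicate group, identical ΔΔG values collapse to one record;
    differing ΔΔG values are resolved by keeping the record whose |ΔΔG| is
    smallest (values nearer zero are considered the more reliable
    measurement).  Ties on |ΔΔG| keep the first record encountered.  Output
    preserves first-occurrence order so downstream seeding is deterministic.
    """
    best: dict[tuple, MutationRecord] = {}
    order: list[tuple] = []
    for ds in sources:
        for rec in ds.records:
            if rec.origin != "direct":
                raise DatasetIntegrityError("merge_records expects direct records only")
            gkey = (rec.key, rec.ph, rec.temperature_c)
            if gkey not in best:
                best[gkey] = rec
                order.append(gkey)
            elif abs(rec.ddg) < abs(best[gkey].ddg):
                best[gkey] = rec
    prov = list(itertools.chain.from_iterable(ds.provenance for ds in sources))
    return DDGDataset(records=[best[g] for g in order], provenance=prov)


def augment_reverse(ds: DDGDataset) -> DDGDataset:
    """Add the hypothetical reverse mutation for every direct record.

    Each direct record A→B with value ΔΔG gains a sibling B→A with value
    −ΔΔG at the same site and conditions; the two share a pair_id.  The
    output interleaves direct/reverse so pairs are adjacent, and has exactly
    twice the input's length.
    """
    if ds.is_augmented:
        raise DatasetIntegrityError(
            "dataset already contains reverse records; double augmentation forbidden"
        )
    out: list[MutationRecord] = []
    for i, rec in enumerate(ds.records):
        pair_id = f"p{i:06d}"
        direct = replace(rec, pair_id=pair_id)
        reverse = MutationRecord(
            key=rec.key.reversed(),
            ph=rec.ph,
            temperature_c=rec.temperature_c,
            ddg=-rec.ddg,
            origin="reverse",
            pair_id=pair_id,
        )
        out.extend([direct, reverse])
    return DDGDataset(records=out, provenance=list(ds.provenance) + ["augment_reverse"])


def pair_split(
    ds: DDGDataset, train_fraction: float = 0.9, seed: int = 42
) -> tuple[DDGDataset, DDGDataset]:
    """Shuffle pairs with the given seed and split at ⌈fraction·n_pairs⌉.

    Direct/reverse pairs are the shuffling unit so neither partition ever
    holds only half of a pair.  With 7,876 pairs and fraction 0.9 the split
    is 7,089 / 787 pairs (the ceiling rule).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    pairs = ds.pairs()
    rng = np.random.RandomState(seed)
    idx = np.arange(len(pairs))
    rng.shuffle(idx)
    n_train = int(np.ceil(train_fraction * len(pairs)))
    train_idx, test_idx = idx[:n_train], idx[n_train:]

    def subset(indices: np.ndarray, tag: str) -> DDGDataset:
        recs: list[MutationRecord] = []
        for i in indices:
            recs.extend([pairs[i].direct, pairs[i].reverse])
        return DDGDataset(records=recs, provenance=list(ds.provenance) + [tag])

    return subset(train_idx, f"train(seed={seed})"), subset(test_idx, f"test(seed={seed})")


def make_pair_folds(ds: DDGDataset, k: int = 20, seed: int = 0) -> dict[str, int]:
    """Assign every pair to one of ``k`` folds (sizes differing by ≤ 1).

    Returns a mapping pair_id → fold index.  Pairs are shuffled with the
    seed, then dealt into k contiguous blocks whose sizes differ by at most
    one, so direct and reverse members always share a fold.
    """
    pairs = ds.pairs()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds number of pairs ({len(pairs)})")
    rng = np.random.RandomState(seed)
    idx = np.arange(len(pairs))
    rng.shuffle(idx)
    assignment: dict[str, int] = {}
    for fold, block in enumerate(np.array_split(idx, k)):
        for i in block:
            assignment[pairs[i].direct.pair_id] = fold
    return assignment
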
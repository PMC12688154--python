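"""Readers for the flat-file dialects the featurization pipeline consumes.

Covers the AAindex database dialects (AAindex1 single-property entries,
AAindex2/3 substitution/contact matrices), the ASCII position-specific scoring
matrix written by iterated profile search, and the saved outputs of external
per-structure tools (FoldX energy tables, classic DSSP listings, SIFT
substitution reports, per-residue B-factor and disorder predictions).

External binaries are never executed here: users supply saved reports, or the
pipeline falls back to internal baselines.  NA cells in AAindex entries are
masked, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Single shared column order for every 20-wide profile and property vector.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: The 20 named energy terms of the FoldX-style energy bundle; the total
#: energy is the first term.
FOLDX_TERMS = (
    "total_energy", "backbone_hbond", "sidechain_hbond", "van_der_waals",
    "electrostatics", "solvation_polar", "solvation_hydrophobic", "vdw_clashes",
    "entropy_sidechain", "entropy_mainchain", "sloop_entropy", "mloop_entropy",
    "cis_bond", "torsional_clash", "backbone_clash", "helix_dipole",
    "water_bridge", "disulfide", "electrostatic_kon", "partial_covalent_bonds",
)

#: DSSP secondary-structure letters mapped onto the eight classes.
DSSP_CLASS_MAP = {
    "G": "310_helix", "H": "alpha_helix", "I": "pi_helix", "T": "helix_turn",
    "E": "extended_beta", "B": "beta_bridge", "S": "bend",
}

REPORT_KINDS = ("foldx", "dssp", "sift", "bfactor", "disorder")


class ProfileParseError(ValueError):
    pass


@dataclass
class AAIndexEntry:
    """One AAindex1 property: 20 values in A R N D C Q E G H I L K M F P S T W Y V order."""

    accession: str
    description: str
    values: np.ndarray  # shape (20,), NaN where masked
    na_mask: np.ndarray  # shape (20,), True where the entry printed NA

    def value(self, aa1: str) -> float:
        i = PSSM_ALPHABET.index(aa1)
        if self.na_mask[i]:
            raise KeyError(f"{self.accession}: value for {aa1!r} is NA")
        return float(self.values[i])


@dataclass
class SubstitutionMatrix:
    accession: str
    description: str
    values: np.ndarray  # shape (20, 20)
    symmetric_completed: bool

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[PSSM_ALPHABET.index(a), PSSM_ALPHABET.index(b)])


@dataclass
class PSSMProfile:
    """Per-position log-odds profile; positions are 1-based."""

    sequence: str
    scores: np.ndarray  # shape (L, 20), PSSM_ALPHABET column order

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError("score matrix shape must be (len(sequence), 20)")

    def __len__(self) -> int:
        return len(self.sequence)

    def score(self, position: int, aa1: str) -> float:
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside profile of length {len(self)}")
        return float(self.scores[position - 1, PSSM_ALPHABET.index(aa1)])


@dataclass
class EnergyTermBundle:
    terms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.terms) != FOLDX_TERMS:
            raise ValueError("energy bundle must carry exactly the 20 schema terms in order")

    @property
    def total_energy(self) -> float:
        return self.terms["total_energy"]


def parse_aaindex1(text: str) -> list[AAIndexEntry]:
    """Parse AAindex1 flat-file text into property entries.

    The dialect is record lines keyed by a leading letter (H accession,
    D description, I index header) with the 20 values on the two lines
    following the I line (ten per line, first row A R N D C Q E G H I, second
    row L K M F P S T W Y V).  ``NA`` cells are masked.
    """
    entries: list[AAIndexEntry] = []
    accession = description = None
    values: list[float] = []
    mask: list[bool] = []
    expect_values = 0
    for raw in text.splitlines():
        if raw.startswith("H "):
            accession = raw[2:].strip()
            description, values, mask, expect_values = "", [], [], 0
        elif raw.startswith("D "):
            description = raw[2:].strip()
        elif raw.startswith("I "):
            expect_values = 2
        elif expect_values > 0 and raw.strip():
            for tok in raw.split():
                if tok.upper() == "NA":
                    values.append(np.nan)
                    mask.append(True)
                else:
                    try:
                        values.append(float(tok))
                    except ValueError as exc:
                        raise ProfileParseError(
                            f"{accession}: bad value token {tok!r}"
                        ) from exc
                    mask.append(False)
            expect_values -= 1
        elif raw.startswith("//"):
            if accession is None:
                continue
            if len(values) != 20:
                raise ProfileParseError(
                    f"{accession}: expected 20 values, got {len(values)}"
                )
            entries.append(
                AAIndexEntry(
                    accession=accession,
                    description=description or "",
                    values=np.array(values, dtype=float),
                    na_mask=np.array(mask, dtype=bool),
                )
            )
            accession = None
    return entries


def parse_aaindex_matrix(text: str) -> SubstitutionMatrix:
    """Parse an AAindex2/3 matrix entry (lower-triangular or square body).

    Lower-triangular bodies are symmetric-completed so ``lookup(a, b) ==
    lookup(b, a)``; square bodies are accepted verbatim.
    """
    accession = description = None
    rows_alpha = cols_alpha = None
    body: list[list[float]] = []
    in_body = False
    for raw in text.splitlines():
        if raw.startswith("H "):
            accession = raw[2:].strip()
        elif raw.startswith("D "):
            description = raw[2:].strip()
        elif raw.startswith("M "):
            decl = raw[2:]
            parts = {}
            for p in decl.replace(",", ";").split(";"):
                if "=" in p:
                    k, v = p.split("=", 1)
                    parts[k.strip()] = v.strip()
            rows_alpha = parts.get("rows", "")
            cols_alpha = parts.get("cols", "")
            if rows_alpha != PSSM_ALPHABET or cols_alpha != PSSM_ALPHABET:
                raise ProfileParseError(
                    f"{accession}: row/col alphabet mismatch "
                    f"(rows={rows_alpha!r}, cols={cols_alpha!r})"
                )
            in_body = True
        elif raw.startswith("//"):
            in_body = False
        elif in_body and raw.strip():
            body.append([float(t) if t.upper() != "NA" else np.nan for t in raw.split()])
    if accession is None or not body:
        raise ProfileParseError("no matrix entry found")
    n = 20
    mat = np.full((n, n), np.nan)
    lower_triangular = all(len(row) == i + 1 for i, row in enumerate(body))
    if lower_triangular and len(body) == n:
        for i, row in enumerate(body):
            for j, v in enumerate(row):
                mat[i, j] = v
                mat[j, i] = v
        completed = True
    elif all(len(row) == n for row in body) and len(body) == n:
        mat = np.array(body)
        completed = False
    else:
        raise ProfileParseError(
            f"{accession}: body is neither lower-triangular nor square 20x20"
        )
    return SubstitutionMatrix(
        accession=accession,
        description=description or "",
        values=mat,
        symmetric_completed=completed,
    )


def parse_pssm_ascii(text: str) -> PSSMProfile:
    """Parse the ASCII PSSM dialect of iterated profile search.

    Per-position rows carry the position index, the query residue, 20
    log-odds integers, 20 weighted-percentage columns, and information
    columns; only the residue letter and the first 20 numeric columns are
    captured.
    """
    seq_letters: list[str] = []
    rows: list[list[float]] = []
    for raw in text.splitlines():
        parts = raw.split()
        if len(parts) < 22:
            continue
        if not parts[0].isdigit():
            continue
        aa = parts[1]
        if len(aa) != 1 or not aa.isalpha():
            continue
        try:
            scores = [float(t) for t in parts[2:22]]
        except ValueError:
            continue
        idx = int(parts[0])
        if idx != len(seq_letters) + 1:
            raise ProfileParseError(
                f"position index {idx} does not follow row {len(seq_letters)}"
            )
        seq_letters.append(aa.upper())
        rows.append(scores)
    if not rows:
        raise ProfileParseError("no PSSM rows found in input")
    return PSSMProfile(sequence="".join(seq_letters), scores=np.array(rows, dtype=float))


def parse_tool_report(kind: str, text: str):
    """Parse a saved external-tool report into a typed bundle.

    ``kind`` selects the dialect: ``foldx`` (tab-separated header + one row
    of the 20 energy terms), ``dssp`` (classic fixed-column listing; SS
    letters mapped to the eight classes), ``sift`` (substitution / score /
    TOLERATED-or-DELETERIOUS rows), ``bfactor`` and ``disorder``
    (chain / position / value rows).
    """
    if kind not in REPORT_KINDS:
        raise ValueError(f"unknown report kind {kind!r}; expected one of {REPORT_KINDS}")
    parser = {
        "foldx": _parse_foldx,
        "dssp": _parse_dssp,
        "sift": _parse_sift,
        "bfactor": _parse_per_residue_floats,
        "disorder": _parse_per_residue_bools,
    }[kind]
    return parser(text)


def _data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line and not line.startswith("#"):
            yield lineno, line


def _parse_foldx(text: str) -> EnergyTermBundle:
    lines = list(_data_lines(text))
    if len(lines) < 2:
        raise ProfileParseError("FoldX table needs a header line and a value row")
    header = lines[0][1].split("\t")
    if tuple(h.strip() for h in header) != FOLDX_TERMS:
        raise ProfileParseError(
            f"FoldX header does not match the 20-term schema (line {lines[0][0]})"
        )
    values = lines[1][1].split("\t")
    if len(values) != 20:
        raise ProfileParseError(
            f"FoldX row has {len(values)} values, expected 20 (line {lines[1][0]})"
        )
    return EnergyTermBundle(
        terms={name: float(v) for name, v in zip(FOLDX_TERMS, values)}
    )


def _parse_dssp(text: str):
    """Classic DSSP listing → {residue id: (ss_class, acc)}."""
    out: dict[tuple[str, int, str], tuple[str, float]] = {}
    in_table = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(raw) < 38:
            continue
        if raw[13] == "!":  # chain break marker
            continue
        try:
            number = int(raw[5:10])
        except ValueError as exc:
            raise ProfileParseError(f"bad residue number at line {lineno}") from exc
        icode = raw[10].strip()
        chain = raw[11].strip()
        ss_letter = raw[16].strip()
        try:
            acc = float(raw[34:38])
        except ValueError as exc:
            raise ProfileParseError(f"bad ACC field at line {lineno}") from exc
        out[(chain, number, icode)] = (DSSP_CLASS_MAP.get(ss_letter, "other_loop"), acc)
    if not out:
        raise ProfileParseError("no residue rows found in DSSP input")
    return out


def _parse_sift(text: str):
    """SIFT report → {substitution string: (score, tolerated flag)}."""
    out: dict[str, tuple[float, bool]] = {}
    for lineno, line in _data_lines(text):
        parts = line.split()
        if len(parts) < 3:
            raise ProfileParseError(f"SIFT row too short at line {lineno}")
        sub, score_s, verdict = parts[0], parts[1], parts[2].upper()
        if verdict not in ("TOLERATED", "DELETERIOUS"):
            raise ProfileParseError(f"bad SIFT verdict {verdict!r} at line {lineno}")
        out[sub.upper()] = (float(score_s), verdict == "TOLERATED")
    if not out:
        raise ProfileParseError("no rows in SIFT input")
    return out


def _parse_per_residue_floats(text: str):
    out: dict[tuple[str, int, str], float] = {}
    for lineno, line in _data_lines(text):
        parts = line.split()
        if len(parts) < 3:
            raise ProfileParseError(f"row too short at line {lineno}")
        out[(parts[0], int(parts[1]), "")] = float(parts[2])
    if not out:
        raise ProfileParseError("no rows in per-residue input")
    return out


def _parse_per_residue_bools(text: str):
    out: dict[tuple[str, int, str], bool] = {}
    for lineno, line in _data_lines(text):
        parts = line.split()
        if len(parts) < 3:
            raise ProfileParseError(f"row too short at line {lineno}")
        out[(parts[0], int(parts[1]), "")] = bool(int(parts[2]))
    if not out:
        raise ProfileParseError("no rows in per-residue input")
    return out
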
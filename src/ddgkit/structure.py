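"""Protein structures and the geometric primitives behind featurization.

Structures are parsed from PDB-format text (first model only, highest-occupancy
alternate locations, no heteroatoms or waters) into light dataclasses keyed by
author numbering, which is how mutation sites are printed in substitution
strings.  On top of that sit the geometric operations the feature groups
consume: spatial shells around a mutation site (7/10/13 Å and whole-protein),
Shrake–Rupley solvent accessibility and its residue-normalised RSA, a
Ramachandran-region secondary-structure baseline in the eight DSSP-style
classes, and a Cα Gaussian-network-model estimate of residue fluctuations.

The mutant-structure builder is deliberately a *baseline*: it renames the
residue and truncates the side chain at Cβ, leaving full side-chain modelling
to an external provider hook.  Structures built this way are flagged
``sidechain_incomplete`` so downstream features can tell the two apart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Van der Waals radii per element (Å); fallback 1.70 for uncommon elements.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

# Theoretical maximum accessible surface areas (Å²) used to normalise SASA
# into relative solvent accessibility (Tien et al. 2013, theoretical column).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

RSA_BURIED_THRESHOLD = 0.25

SS_CLASSES = (
    "310_helix", "alpha_helix", "pi_helix", "helix_turn",
    "extended_beta", "beta_bridge", "bend", "other_loop",
)

# Ramachandran-region table for the eight-class baseline classifier.
# Checked in order; first region containing (phi, psi) wins.  Each entry is
# (class, phi_lo, phi_hi, psi_lo, psi_hi) in degrees.  The regions are a
# documented convention for this package, not a claim about any external
# assignment program; a DSSP-file adapter overrides this baseline when real
# assignments are available.
RAMACHANDRAN_REGIONS: list[tuple[str, float, float, float, float]] = [
    ("alpha_helix",  -80.0, -40.0, -60.0, -35.0),
    ("310_helix",    -80.0, -40.0, -35.0, -10.0),
    ("pi_helix",    -105.0, -80.0, -60.0, -20.0),
    ("extended_beta", -180.0, -45.0,  90.0, 180.0),
    ("extended_beta", -180.0, -45.0, -180.0, -160.0),
    ("beta_bridge",  -180.0, -45.0,  45.0,  90.0),
    ("helix_turn",     30.0,  90.0, -30.0,  60.0),
    ("bend",         -100.0, -45.0, -10.0,  45.0),
]


class PDBParseError(ValueError):
    pass


class MutationSiteError(KeyError):
    """Mutation site cannot be resolved in the structure."""


class WildTypeMismatchError(ValueError):
    """Residue at the mutation site does not match the stated wild type."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW)


@dataclass
class Residue:
    name3: str
    chain_id: str
    author_number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa1(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def rid(self) -> tuple[str, int, str]:
        """(chain_id, author_number, icode) — unique within a structure."""
        return (self.chain_id, self.author_number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class ProteinStructure:
    residues: list[Residue]
    source: str = ""
    sidechain_incomplete: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            if r.rid in seen:
                raise PDBParseError(f"duplicate residue id {r.rid}")
            seen.add(r.rid)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def get_residue(self, chain_id: str, author_number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.rid == (chain_id, author_number, icode):
                return r
        raise MutationSiteError(
            f"residue {chain_id}/{author_number}{icode or ''} not found in {self.source!r}"
        )

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa1 for r in self.chain_residues(chain_id))


def read_pdb(text: str, source: str = "<string>") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only the first model is used.  Alternate locations are resolved per atom
    name to the highest-occupancy conformer (ties go to altloc 'A', then
    alphabetically).  HETATM records, waters, and non-amino-acid residues are
    excluded; hydrogens are kept but ignored by heavy-atom operations.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise PDBParseError(f"{source}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{source}: no models in input")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.name == "HOH":
                continue
            if res.name not in THREE_TO_ONE:
                continue
            # resolve altlocs: per atom name keep highest occupancy, tie -> 'A'
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    continue
                key_new = (atom.occ, -(ord(atom.altloc or "~")))
                key_old = (prev.occ, -(ord(prev.altloc or "~")))
                if key_new > key_old:
                    by_name[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                    altloc=a.altloc or "",
                )
                for a in by_name.values()
            ]
            if not all(np.all(np.isfinite(a.coords)) for a in atoms):
                raise PDBParseError(f"{source}: non-finite coordinates in {res.name}")
            residues.append(
                Residue(
                    name3=res.name,
                    chain_id=chain.name,
                    author_number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
    if not residues:
        raise PDBParseError(f"{source}: no standard amino-acid ATOM records found")
    return ProteinStructure(residues=residues, source=source)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialise a structure to fixed-width PDB text (ATOM/TER/END records)."""
    lines: list[str] = []
    serial = 1
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.name3:>3s} {res.chain_id:1s}"
                f"{res.author_number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element.upper():>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def build_mutant_baseline(structure: ProteinStructure, key) -> ProteinStructure:
    """Build a baseline mutant: rename the residue and truncate past Cβ.

    The mutated residue keeps its backbone (N, CA, C, O, OXT) plus Cβ when
    both the wild-type and mutant residues have one; mutation to glycine drops
    Cβ.  All other residues are carried over untouched.  The result is
    flagged ``sidechain_incomplete`` so features can distinguish the baseline
    from a fully modelled mutant supplied by a provider.
    """
    site = structure.get_residue(key.chain_id, key.position, key.icode)
    if site.aa1 != key.wt_aa:
        raise WildTypeMismatchError(
            f"residue {key.chain_id}/{key.position}{key.icode} is {site.aa1}, "
            f"expected wild-type {key.wt_aa}"
        )
    keep = set(_BACKBONE)
    if key.mut_aa != "G":
        keep.add("CB")
    new_atoms = [a for a in site.atoms if a.name in keep]
    mutated = Residue(
        name3=ONE_TO_THREE[key.mut_aa],
        chain_id=site.chain_id,
        author_number=site.author_number,
        icode=site.icode,
        atoms=new_atoms,
    )
    new_residues = [mutated if r.rid == site.rid else r for r in structure.residues]
    return ProteinStructure(
        residues=new_residues,
        source=f"{structure.source}|{key.substitution}",
        sidechain_incomplete=True,
    )


@dataclass
class SpatialShell:
    radius: float  # Å; math.inf means the whole structure
    members: frozenset  # residue ids (chain, number, icode)


def residues_within_radius(
    structure: ProteinStructure,
    site: tuple[str, int, str],
    radius: float,
    ca_only: bool = False,
) -> SpatialShell:
    """Residues whose minimum heavy-atom distance to the site is ≤ radius.

    With ``ca_only`` the distance is Cα–Cα instead.  ``radius=inf`` returns
    every residue.  The site residue is always a member.
    """
    site_res = structure.get_residue(*site)
    if math.isinf(radius):
        return SpatialShell(radius=radius, members=frozenset(r.rid for r in structure.residues))

    def coords_of(res: Residue) -> np.ndarray:
        if ca_only:
            ca = res.atom("CA")
            return np.array([ca.coords]) if ca is not None else np.empty((0, 3))
        return res.heavy_coords()

    site_pts = coords_of(site_res)
    members = {site_res.rid}
    for res in structure.residues:
        if res.rid == site_res.rid:
            continue
        pts = coords_of(res)
        if len(pts) == 0 or len(site_pts) == 0:
            continue
        d2 = np.sum((pts[:, None, :] - site_pts[None, :, :]) ** 2, axis=-1)
        if d2.min() <= radius * radius:
            members.add(res.rid)
    return SpatialShell(radius=radius, members=frozenset(members))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int, str], float]:
    """Per-residue solvent-accessible surface area (Å²) by sphere quadrature.

    Each heavy atom is expanded by the probe radius and sampled with a fixed
    golden-spiral point set; a point counts as accessible when it lies outside
    every neighbouring expanded sphere.  Deterministic for a fixed point count.
    """
    atoms: list[Atom] = []
    owner: list[tuple[str, int, str]] = []
    for res in structure.residues:
        for a in res.atoms:
            if a.is_heavy:
                atoms.append(a)
                owner.append(res.rid)
    if not atoms:
        return {res.rid: 0.0 for res in structure.residues}
    centers = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius + probe_radius for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(centers)
    max_r = radii.max()
    sasa: dict[tuple[str, int, str], float] = {res.rid: 0.0 for res in structure.residues}
    for i in range(len(atoms)):
        r_i = radii[i]
        pts = centers[i] + r_i * unit
        neighbours = [j for j in tree.query_ball_point(centers[i], r_i + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * math.pi * r_i * r_i * accessible.sum() / n_points
        sasa[owner[i]] += area
    return sasa


def relative_accessibility(sasa: float, aa1: str) -> tuple[float, str]:
    """RSA = SASA / max-ASA(residue), clipped to [0, 1.2]; buried iff RSA < 0.25."""
    if aa1 not in MAX_ASA:
        raise KeyError(f"unknown residue {aa1!r} for RSA normalisation")
    rsa = float(np.clip(sasa / MAX_ASA[aa1], 0.0, 1.2))
    label = "buried" if rsa < RSA_BURIED_THRESHOLD else "exposed"
    return rsa, label


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees for four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(
    structure: ProteinStructure,
) -> dict[tuple[str, int, str], tuple[float | None, float | None]]:
    """(φ, ψ) per residue; None at chain termini or across chain breaks.

    Consecutive residues in a chain are treated as bonded only when the
    C(i-1)–N(i) distance is below 2.0 Å.
    """
    out: dict[tuple[str, int, str], tuple[float | None, float | None]] = {}
    for chain_id in structure.chains:
        chain = structure.chain_residues(chain_id)
        for i, res in enumerate(chain):
            phi = psi = None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if None not in (n, ca, c):
                if i > 0:
                    prev_c = chain[i - 1].atom("C")
                    if prev_c is not None and np.linalg.norm(prev_c.coords - n.coords) < 2.0:
                        phi = _dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
                if i < len(chain) - 1:
                    next_n = chain[i + 1].atom("N")
                    if next_n is not None and np.linalg.norm(c.coords - next_n.coords) < 2.0:
                        psi = _dihedral(n.coords, ca.coords, c.coords, next_n.coords)
            out[res.rid] = (phi, psi)
    return out


def classify_phi_psi(phi: float | None, psi: float | None,
                     regions=None) -> str:
    """Map a (φ, ψ) pair onto the eight-class table; undefined → other/loop."""
    if phi is None or psi is None:
        return "other_loop"
    for name, plo, phi_hi, slo, shi in (regions or RAMACHANDRAN_REGIONS):
        if plo <= phi <= phi_hi and slo <= psi <= shi:
            return name
    return "other_loop"


def assign_secondary_structure(
    structure: ProteinStructure, regions=None
) -> dict[tuple[str, int, str], str]:
    """Baseline 8-class secondary structure from backbone dihedrals.

    Residues with missing backbone atoms or undefined dihedrals (termini,
    chain breaks) are labelled other/loop with a warning rather than raising.
    """
    dihedrals = backbone_dihedrals(structure)
    labels: dict[tuple[str, int, str], str] = {}
    for res in structure.residues:
        if res.atom("N") is None or res.atom("CA") is None or res.atom("C") is None:
            warnings.warn(f"missing backbone atoms in {res.rid}; labelling other_loop")
            labels[res.rid] = "other_loop"
            continue
        phi, psi = dihedrals[res.rid]
        labels[res.rid] = classify_phi_psi(phi, psi, regions)
    return labels


def gnm_kirchhoff(structure: ProteinStructure, cutoff: float = 7.3) -> tuple[np.ndarray, list]:
    """Cα-contact Kirchhoff (connectivity) matrix and the residue-id order."""
    ca_ids, coords = [], []
    for res in structure.residues:
        ca = res.atom("CA")
        if ca is not None:
            ca_ids.append(res.rid)
            coords.append(ca.coords)
    if len(coords) < 2:
        raise ValueError("Gaussian network model needs at least two C-alpha atoms")
    xyz = np.array(coords)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    contact = (d2 <= cutoff * cutoff) & ~np.eye(len(xyz), dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1).astype(float))
    return gamma, ca_ids


def gnm_fluctuations(
    structure: ProteinStructure, cutoff: float = 7.3
) -> dict[tuple[str, int, str], float]:
    """Relative mean-square fluctuations from the GNM pseudo-inverse diagonal.

    Fluctuations are the diagonal of the Moore–Penrose pseudo-inverse of the
    Kirchhoff matrix, normalised to unit mean (relative units).  A
    disconnected contact graph is computed as-is with a warning; the
    pseudo-inverse handles each component's zero mode.
    """
    gamma, ca_ids = gnm_kirchhoff(structure, cutoff)
    n_components = _count_components(gamma)
    if n_components > 1:
        warnings.warn(
            f"GNM contact graph has {n_components} components; "
            "fluctuations computed per component"
        )
    diag = np.diag(np.linalg.pinv(gamma, rcond=1e-10))
    diag = np.maximum(diag, 0.0)
    mean = diag.mean()
    if mean > 0:
        diag = diag / mean
    return dict(zip(ca_ids, diag))


def _count_components(gamma: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    adj = (gamma < 0).astype(int)
    return int(connected_components(adj, directed=False)[0])
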
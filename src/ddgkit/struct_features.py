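"""Self-contained structural/environmental descriptors over residue sets.

These are the internal counterparts of the descriptor families a ΔΔG
featurization pipeline usually delegates to external tools: amino-acid and
category proportions, a geometric residue-interaction network (hydrogen bonds,
disulfides, salt bridges, van der Waals contacts, π–cation, π–π stacking),
per-atom pharmacophore class counts, hydrophobic-cluster analysis, and a
provider-backed disorder proportion.  All cutoffs and membership tables are
explicit module-level constants — they are this package's documented
convention, configurable by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dataset import AA_ALPHABET
from .structure import ProteinStructure, Residue

# ---------------------------------------------------------------------------
# Amino-acid category table.  The first four categories (uncharged polar,
# positively charged polar, negatively charged polar, nonpolar) partition the
# 20 standard residues; the remaining four overlap them.
AA_CATEGORIES: dict[str, frozenset[str]] = {
    "uncharged_polar": frozenset("STNQCY"),
    "positively_charged_polar": frozenset("KRH"),
    "negatively_charged_polar": frozenset("DE"),
    "nonpolar": frozenset("AVLIMFWPG"),
    "aromatic": frozenset("FWYH"),
    "aliphatic": frozenset("AVLI"),
    "heterocyclic": frozenset("PHW"),
    "sulfur_containing": frozenset("CM"),
}
PARTITION_CATEGORIES = (
    "uncharged_polar",
    "positively_charged_polar",
    "negatively_charged_polar",
    "nonpolar",
)

INTERACTION_TYPES = ("hydrogen_bond", "disulfide", "ionic", "vdw", "pi_cation", "pi_pi")

# Geometric criteria (Å).  RING-style defaults; every value is configurable
# through the keyword arguments of interaction_network.
HBOND_CUTOFF = 3.5
DISULFIDE_CUTOFF = 2.5
IONIC_CUTOFF = 4.0
VDW_SLACK = 0.5
PI_CATION_CUTOFF = 5.0
PI_PI_CUTOFF = 6.5

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Hydrogen-bond capable atoms: donors are nitrogens plus hydroxyl/thiol
# oxygens; acceptors are oxygens plus carbonyl-like side-chain oxygens.
_DONOR_EXTRA = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}
_POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                   ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CATION_ATOMS = {("LYS", "NZ"), ("ARG", "CZ")}

AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}

HYDROPHOBIC_SET = frozenset("AVLIMFWC")
HYDROPHOBIC_CONTACT_CUTOFF = 4.5

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "positive", "negative", "acceptor",
    "donor", "aromatic", "sulphur", "neutral",
)


def aa_category_proportions(residues: list[Residue]) -> dict[str, float]:
    """Per-amino-acid (20) and per-category (8) proportions of a residue set.

    Categories may overlap, so a residue contributes to every category it
    belongs to; the empty set yields all zeros.
    """
    out = {f"prop_aa_{aa}": 0.0 for aa in AA_ALPHABET}
    out.update({f"prop_cat_{cat}": 0.0 for cat in AA_CATEGORIES})
    n = len(residues)
    if n == 0:
        return out
    for res in residues:
        aa = res.aa1
        if f"prop_aa_{aa}" in out:
            out[f"prop_aa_{aa}"] += 1.0
        for cat, members in AA_CATEGORIES.items():
            if aa in members:
                out[f"prop_cat_{cat}"] += 1.0
    return {k: v / n for k, v in out.items()}


@dataclass(frozen=True)
class InteractionEdge:
    res_a: tuple[str, int, str]
    res_b: tuple[str, int, str]
    type: str
    distance: float

    def __post_init__(self) -> None:
        if self.type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.type!r}")


def _ring_centroids(res: Residue) -> list[np.ndarray]:
    cents = []
    for ring in AROMATIC_RINGS.get(res.name3, ()):
        pts = [res.atom(n).coords for n in ring if res.atom(n) is not None]
        if len(pts) >= 3:
            cents.append(np.mean(pts, axis=0))
    return cents


def _min_dist(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    if len(pts_a) == 0 or len(pts_b) == 0:
        return np.inf
    d2 = np.sum((pts_a[:, None, :] - pts_b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def interaction_network(
    structure: ProteinStructure,
    scope: set | None = None,
    hbond_cutoff: float = HBOND_CUTOFF,
    disulfide_cutoff: float = DISULFIDE_CUTOFF,
    ionic_cutoff: float = IONIC_CUTOFF,
    vdw_slack: float = VDW_SLACK,
    pi_cation_cutoff: float = PI_CATION_CUTOFF,
    pi_pi_cutoff: float = PI_PI_CUTOFF,
) -> tuple[list[InteractionEdge], dict[str, int]]:
    """Detect residue–residue interactions by geometric criteria.

    A pair may satisfy several criteria and then yields one edge per type
    (e.g. a lysine–aspartate contact at 3 Å is both ionic and a hydrogen
    bond).  Sequence-adjacent residues are excluded from the van der Waals
    type only.  ``scope`` restricts detection to residues whose id is in the
    set (both endpoints must be in scope).
    """
    residues = [r for r in structure.residues if scope is None or r.rid in scope]
    edges: list[InteractionEdge] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            a, b = residues[i], residues[j]
            # cheap prefilter on heavy-atom bounding distance
            pa, pb = a.heavy_coords(), b.heavy_coords()
            if _min_dist(pa, pb) > max(pi_pi_cutoff, pi_cation_cutoff, 8.0):
                continue
            edges.extend(_pair_edges(a, b, hbond_cutoff, disulfide_cutoff,
                                     ionic_cutoff, vdw_slack,
                                     pi_cation_cutoff, pi_pi_cutoff))
    counts = {t: 0 for t in INTERACTION_TYPES}
    for e in edges:
        counts[e.type] += 1
    return edges, counts


def _pair_edges(a, b, hbond_cutoff, disulfide_cutoff, ionic_cutoff,
                vdw_slack, pi_cation_cutoff, pi_pi_cutoff) -> list[InteractionEdge]:
    out: list[InteractionEdge] = []

    def donors(res):
        for at in res.atoms:
            if not at.is_heavy:
                continue
            if at.element.upper() == "N" or (res.name3, at.name) in _DONOR_EXTRA:
                yield at

    def acceptors(res):
        for at in res.atoms:
            if at.is_heavy and at.element.upper() == "O":
                yield at

    # hydrogen bond (either direction)
    best = np.inf
    for da, ab in ((a, b), (b, a)):
        for d in donors(da):
            for ac in acceptors(ab):
                dist = float(np.linalg.norm(d.coords - ac.coords))
                best = min(best, dist)
    if best <= hbond_cutoff:
        out.append(InteractionEdge(a.rid, b.rid, "hydrogen_bond", best))

    # disulfide
    if a.name3 == "CYS" and b.name3 == "CYS":
        sa, sb = a.atom("SG"), b.atom("SG")
        if sa is not None and sb is not None:
            dist = float(np.linalg.norm(sa.coords - sb.coords))
            if dist <= disulfide_cutoff:
                out.append(InteractionEdge(a.rid, b.rid, "disulfide", dist))

    # ionic: min distance between a positive-group atom and a negative-group atom
    best = np.inf
    for pa, na in ((a, b), (b, a)):
        pos = [at.coords for at in pa.atoms if (pa.name3, at.name) in _POSITIVE_ATOMS]
        neg = [at.coords for at in na.atoms if (na.name3, at.name) in _NEGATIVE_ATOMS]
        if pos and neg:
            best = min(best, _min_dist(np.array(pos), np.array(neg)))
    if best <= ionic_cutoff:
        out.append(InteractionEdge(a.rid, b.rid, "ionic", best))

    # van der Waals: non-adjacent residues, heavy atoms within sum of radii + slack
    adjacent = a.chain_id == b.chain_id and abs(a.author_number - b.author_number) == 1
    if not adjacent:
        best = np.inf
        for at_a in a.atoms:
            if not at_a.is_heavy:
                continue
            for at_b in b.atoms:
                if not at_b.is_heavy:
                    continue
                dist = float(np.linalg.norm(at_a.coords - at_b.coords))
                if dist <= at_a.vdw_radius + at_b.vdw_radius + vdw_slack:
                    best = min(best, dist)
        if np.isfinite(best):
            out.append(InteractionEdge(a.rid, b.rid, "vdw", best))

    # pi-cation
    best = np.inf
    for cat_res, ring_res in ((a, b), (b, a)):
        cats = [at.coords for at in cat_res.atoms
                if (cat_res.name3, at.name) in _CATION_ATOMS]
        for cent in _ring_centroids(ring_res):
            for c in cats:
                best = min(best, float(np.linalg.norm(c - cent)))
    if best <= pi_cation_cutoff:
        out.append(InteractionEdge(a.rid, b.rid, "pi_cation", best))

    # pi-pi stacking
    best = np.inf
    for ca_ in _ring_centroids(a):
        for cb_ in _ring_centroids(b):
            best = min(best, float(np.linalg.norm(ca_ - cb_)))
    if best <= pi_pi_cutoff:
        out.append(InteractionEdge(a.rid, b.rid, "pi_pi", best))
    return out


# ---------------------------------------------------------------------------
# Pharmacophore typing: (residue name, atom name) -> set of classes.  Untyped
# carbons default to hydrophobic, anything else untyped to neutral; an atom
# increments every class it belongs to.
_PHARM_TABLE: dict[tuple[str, str], frozenset[str]] = {}


def _pt(entries, classes):
    for res, name in entries:
        _PHARM_TABLE[(res, name)] = frozenset(classes)


_pt([("ARG", n) for n in ("NE", "NH1", "NH2")], {"positive", "donor"})
_pt([("LYS", "NZ")], {"positive", "donor"})
_pt([("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")],
    {"negative", "acceptor"})
_pt([("ASN", "OD1"), ("GLN", "OE1")], {"acceptor"})
_pt([("ASN", "ND2"), ("GLN", "NE2")], {"donor"})
_pt([("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")], {"donor", "acceptor"})
_pt([("CYS", "SG"), ("MET", "SD")], {"sulphur"})
_pt([("TRP", "NE1")], {"donor", "aromatic"})
for _res, _rings in AROMATIC_RINGS.items():
    for _ring in _rings:
        for _name in _ring:
            key = (_res, _name)
            base = _PHARM_TABLE.get(key, frozenset())
            _PHARM_TABLE[key] = base | {"aromatic", "hydrophobic"}


def pharmacophore_counts(
    structure: ProteinStructure, scope: set | None = None
) -> dict[str, int]:
    """Count atoms per pharmacophore class over the scoped residues.

    Backbone N is a donor and backbone O (and OXT) an acceptor for every
    residue; side-chain atoms follow the typing table; untyped carbons count
    as hydrophobic and any other untyped atom as neutral.  Classes are not
    exclusive, so one atom may increment several counts.
    """
    counts = {c: 0 for c in PHARMACOPHORE_CLASSES}
    for res in structure.residues:
        if scope is not None and res.rid not in scope:
            continue
        for at in res.atoms:
            if not at.is_heavy:
                continue
            if at.name == "N":
                classes = frozenset({"donor"})
            elif at.name in ("O", "OXT"):
                classes = frozenset({"acceptor"})
            else:
                classes = _PHARM_TABLE.get((res.name3, at.name))
                if classes is None:
                    if at.element.upper() == "C":
                        classes = frozenset({"hydrophobic"})
                    else:
                        classes = frozenset({"neutral"})
            for c in classes:
                counts[c] += 1
    return counts


@dataclass(frozen=True)
class HydrophobicCluster:
    members: frozenset
    size: int


def hydrophobic_clusters(
    structure: ProteinStructure,
    scope: set | None = None,
    cutoff: float = HYDROPHOBIC_CONTACT_CUTOFF,
) -> tuple[list[HydrophobicCluster], dict[str, float]]:
    """Connected components of hydrophobic side-chain contacts.

    Nodes are residues in the hydrophobic set {A, V, L, I, M, F, W, C};
    an edge joins two residues whose side-chain heavy atoms come within the
    contact cutoff; clusters are components of size ≥ 2.  The summary reports
    cluster count, largest size, and the fraction of scoped residues that are
    clustered.
    """
    residues = [r for r in structure.residues if scope is None or r.rid in scope]
    nodes = [r for r in residues if r.aa1 in HYDROPHOBIC_SET]
    g = nx.Graph()
    g.add_nodes_from(r.rid for r in nodes)

    def side_chain(res: Residue) -> np.ndarray:
        pts = [a.coords for a in res.atoms
               if a.is_heavy and a.name not in _BACKBONE_NAMES]
        return np.array(pts) if pts else np.empty((0, 3))

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if _min_dist(side_chain(nodes[i]), side_chain(nodes[j])) <= cutoff:
                g.add_edge(nodes[i].rid, nodes[j].rid)
    clusters = [
        HydrophobicCluster(frozenset(comp), len(comp))
        for comp in nx.connected_components(g)
        if len(comp) >= 2
    ]
    clusters.sort(key=lambda c: (-c.size, sorted(c.members)[0]))
    n_clustered = sum(c.size for c in clusters)
    summary = {
        "cluster_count": float(len(clusters)),
        "largest_cluster_size": float(max((c.size for c in clusters), default=0)),
        "fraction_clustered": n_clustered / len(residues) if residues else 0.0,
    }
    return clusters, summary


def disorder_proportion(
    structure: ProteinStructure,
    report: dict[tuple[str, int, str], bool] | None = None,
) -> tuple[float, bool]:
    """Fraction of residues labelled disordered.

    With an external disorder report (residue id → disordered flag) the
    proportion comes from its labels; the baseline fallback labels every
    residue ordered and flags the value as a baseline.  Returns
    ``(proportion, is_baseline)``.
    """
    if report is None:
        return 0.0, True
    known = {r.rid for r in structure.residues}
    unknown = [rid for rid in report if rid not in known]
    if unknown:
        raise ValueError(f"disorder report names residues absent from structure: {unknown[:3]}")
    if not report:
        return 0.0, False
    n_dis = sum(bool(v) for v in report.values())
    return n_dis / len(structure.residues), False
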
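"""Hydrogen-bond detection, G-quartet identification and stability scoring.

A G-quartet is a square-planar cycle of four guanines in which each base
donates two Hoogsteen hydrogen bonds (N1->O6 and N2->N7) to its clockwise
neighbour, for a total of 8 bonds per quartet and 24 in a three-layer stem.
Quartets are found as directed 4-cycles in the guanine donor->acceptor graph;
integrity over a trajectory is scored by re-counting the within-layer Hoogsteen
bonds of the frame-0 assignment in every frame, so bond loss registers as
instability rather than as re-assignment.  A complex whose mean within-quartet
bond count falls to 15 or below (of 24) is labelled unstable.

The H-bond criterion is geometric: donor--acceptor heavy-atom distance at or
below 3.5 A, plus an H-donor-acceptor angle at or below 30 degrees whenever
hydrogens are present on the donor.  Structures without hydrogens (all in-repo
fixtures) use the distance-only heavy-atom fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
from scipy.spatial import cKDTree

from . import config as cfg
from .errors import GQKitError
from .structures import (
    Atom,
    Ensemble,
    ResidueRole,
    StructureModel,
    classify_residues,
    molecule_class,
)

__all__ = [
    "HBondCriterion",
    "HBond",
    "QuartetAssignment",
    "StabilitySeries",
    "detect_hbonds",
    "detect_quartets",
    "quartet_hbond_series",
    "classify_stability",
    "stability_scatter",
]

HOOGSTEEN_DONORS = frozenset({"N1", "N2"})
HOOGSTEEN_ACCEPTORS = frozenset({"O6", "N7"})


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (heavy-atom distances in Angstrom)."""

    donor_acceptor_max: float = 3.5
    h_angle_max: float = 30.0
    heavy_atom_fallback: bool = True

    def __post_init__(self):
        if self.donor_acceptor_max <= 0:
            raise ValueError("donor_acceptor_max must be positive")
        if not (0 < self.h_angle_max <= 90):
            raise ValueError("h_angle_max must lie in (0, 90]")


@dataclass(frozen=True)
class HBond:
    donor: int        # atom index into the frame
    acceptor: int
    donor_atom: Atom
    acceptor_atom: Atom
    distance: float
    kind: str         # "hoogsteen_GG" | "intermolecular" | "other"


@dataclass
class QuartetAssignment:
    """Detected quartet layers, ordered bottom-to-top along the channel axis."""

    quartets: list[list[tuple[str, int]]]   # each: 4 guanine (chain, resid)
    axis: np.ndarray                        # unit 3-vector
    layer_of: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def n_quartets(self) -> int:
        return len(self.quartets)

    def __bool__(self) -> bool:
        return self.n_quartets > 0


@dataclass
class StabilitySeries:
    per_frame_quartet_hbonds: np.ndarray
    per_frame_intermolecular_hbonds: np.ndarray
    n_quartets: int
    label: str = ""
    cutoff: int = 15

    @property
    def mean_quartet(self) -> float:
        return float(np.mean(self.per_frame_quartet_hbonds))

    @property
    def mean_intermolecular(self) -> float:
        return float(np.mean(self.per_frame_intermolecular_hbonds))


# ---------------------------------------------------------------------------
# donor / acceptor assignment
# ---------------------------------------------------------------------------

def _donor_acceptor_indices(frame, roles):
    """Return (donor indices, acceptor indices) from the residue-type tables."""
    donors: list[int] = []
    acceptors: list[int] = []
    for i, a in enumerate(frame.atoms):
        if a.is_hydrogen():
            continue
        role = roles[(a.chain, a.resid)]
        name = a.name
        if role == ResidueRole.PROTEIN:
            resname = a.resname.strip().upper()
            if name == "N":
                donors.append(i)
            if name == "O":
                acceptors.append(i)
            if name in cfg.PROTEIN_SIDECHAIN_DONORS.get(resname, ()):
                donors.append(i)
            if name in cfg.PROTEIN_SIDECHAIN_ACCEPTORS.get(resname, ()):
                acceptors.append(i)
        elif role in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE):
            letter = cfg.base_letter(a.resname)
            if letter is not None:
                if name in cfg.NUCLEIC_BASE_DONORS.get(letter, ()):
                    donors.append(i)
                if name in cfg.NUCLEIC_BASE_ACCEPTORS.get(letter, ()):
                    acceptors.append(i)
            if name in cfg.NUCLEIC_BACKBONE_ACCEPTORS:
                acceptors.append(i)
    return donors, acceptors


def _hydrogens_on(frame: StructureModel) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of hydrogens covalently attached (< 1.25 A)."""
    h_idx = [i for i, a in enumerate(frame.atoms) if a.is_hydrogen()]
    if not h_idx:
        return {}
    heavy_idx = [i for i, a in enumerate(frame.atoms) if not a.is_hydrogen()]
    tree = cKDTree(frame.coords[heavy_idx])
    out: dict[int, list[int]] = {}
    for h in h_idx:
        d, j = tree.query(frame.coords[h])
        if d < 1.25:
            out.setdefault(heavy_idx[j], []).append(h)
    return out


def _bond_kind(frame, roles, d_idx: int, a_idx: int) -> str:
    da, aa = frame.atoms[d_idx], frame.atoms[a_idx]
    d_role = roles[(da.chain, da.resid)]
    a_role = roles[(aa.chain, aa.resid)]
    if (
        d_role == ResidueRole.GUANINE
        and a_role == ResidueRole.GUANINE
        and da.name in HOOGSTEEN_DONORS
        and aa.name in HOOGSTEEN_ACCEPTORS
        and (da.chain, da.resid) != (aa.chain, aa.resid)
    ):
        return "hoogsteen_GG"
    dc, ac = molecule_class(d_role), molecule_class(a_role)
    if {dc, ac} == {"protein", "nucleic"}:
        return "intermolecular"
    return "other"


def detect_hbonds(
    frame: StructureModel,
    criterion: HBondCriterion | None = None,
    config: cfg.PipelineConfig | None = None,
) -> list[HBond]:
    """All hydrogen bonds of one frame under the geometric criterion.

    Each unordered atom pair is reported at most once (donor->acceptor
    direction chosen by the tables; when both directions qualify the
    lower-index atom donates).  Same-residue pairs are excluded.  The result
    is independent of atom input order.
    """
    criterion = criterion or HBondCriterion()
    roles = classify_residues(frame, config)
    donors, acceptors = _donor_acceptor_indices(frame, roles)
    if not donors or not acceptors:
        return []
    coords = frame.coords
    h_on = _hydrogens_on(frame)

    acc_tree = cKDTree(coords[acceptors])
    pairs: dict[tuple[int, int], tuple[int, int, float]] = {}
    for d in donors:
        for j in acc_tree.query_ball_point(coords[d], criterion.donor_acceptor_max):
            a = acceptors[j]
            if a == d:
                continue
            da, aa = frame.atoms[d], frame.atoms[a]
            if (da.chain, da.resid) == (aa.chain, aa.resid):
                continue
            dist = float(np.linalg.norm(coords[d] - coords[a]))
            if dist > criterion.donor_acceptor_max:
                continue
            # angle criterion only when the donor carries hydrogens
            hs = h_on.get(d, [])
            if hs:
                v_a = coords[a] - coords[d]
                ok = False
                for h in hs:
                    v_h = coords[h] - coords[d]
                    cosang = np.dot(v_h, v_a) / (
                        np.linalg.norm(v_h) * np.linalg.norm(v_a) + 1e-12
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang <= criterion.h_angle_max:
                        ok = True
                        break
                if not ok:
                    continue
            key = (min(d, a), max(d, a))
            prev = pairs.get(key)
            if prev is None or d < prev[0]:
                pairs[key] = (d, a, dist)

    bonds = [
        HBond(d, a, frame.atoms[d], frame.atoms[a], dist, _bond_kind(frame, roles, d, a))
        for d, a, dist in pairs.values()
    ]
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


# ---------------------------------------------------------------------------
# quartet detection
# ---------------------------------------------------------------------------

def detect_quartets(
    frame: StructureModel,
    criterion: HBondCriterion | None = None,
    config: cfg.PipelineConfig | None = None,
) -> QuartetAssignment:
    """Identify G-quartet layers from the Hoogsteen donor->acceptor graph.

    An edge G -> G' exists when a hoogsteen_GG bond runs from G's donor face
    (N1/N2) to G''s acceptor face (O6/N7).  Quartets are directed 4-cycles,
    extracted greedily by descending total incident Hoogsteen-bond count (ties
    broken lexicographically by (chain, resid)), each guanine used at most
    once.  Layers are ordered along the channel axis (principal axis of the
    quartet centroids; best-fit plane normal when fewer than two layers).
    Returns an empty assignment (not an error) when no 4-cycle exists.
    """
    bonds = detect_hbonds(frame, criterion, config)
    gg = [b for b in bonds if b.kind == "hoogsteen_GG"]
    graph = nx.DiGraph()
    bond_count: dict[tuple, int] = {}
    for b in gg:
        u = (b.donor_atom.chain, b.donor_atom.resid)
        v = (b.acceptor_atom.chain, b.acceptor_atom.resid)
        graph.add_edge(u, v)
        bond_count[(u, v)] = bond_count.get((u, v), 0) + 1

    cycles = []
    for cyc in nx.simple_cycles(graph, length_bound=4):
        if len(cyc) != 4:
            continue
        n_bonds = sum(
            bond_count.get((cyc[i], cyc[(i + 1) % 4]), 0) for i in range(4)
        )
        canon = min(
            tuple(cyc[i:] + cyc[:i]) for i in range(4)
        )  # rotation-canonical form for determinism
        cycles.append((n_bonds, canon))
    cycles.sort(key=lambda t: (-t[0], t[1]))

    used: set[tuple[str, int]] = set()
    quartets: list[list[tuple[str, int]]] = []
    for _, cyc in cycles:
        if any(g in used for g in cyc):
            continue
        quartets.append(list(cyc))
        used.update(cyc)

    if not quartets:
        return QuartetAssignment([], np.array([0.0, 0.0, 1.0]))

    by_res = frame.atom_indices_by_residue()
    coords = frame.coords

    def centroid(group):
        idx = [i for g in group for i in by_res[g]]
        return coords[idx].mean(axis=0)

    cents = np.array([centroid(q) for q in quartets])
    if len(quartets) >= 2:
        c0 = cents - cents.mean(axis=0)
        _, _, vt = np.linalg.svd(c0)
        axis = vt[0]
        # orient from first- to last-listed centroid for a deterministic sign
        if np.dot(axis, cents[-1] - cents[0]) < 0:
            axis = -axis
    else:
        idx = [i for g in quartets[0] for i in by_res[g]]
        pts = coords[idx] - coords[idx].mean(axis=0)
        _, _, vt = np.linalg.svd(pts)
        axis = vt[2]  # best-fit plane normal
        if axis[2] < 0:
            axis = -axis
    axis = axis / np.linalg.norm(axis)

    order = np.argsort(cents @ axis, kind="stable")
    quartets = [quartets[i] for i in order]
    layer_of = {g: layer for layer, q in enumerate(quartets) for g in q}
    return QuartetAssignment(quartets, axis, layer_of)


# ---------------------------------------------------------------------------
# stability scoring
# ---------------------------------------------------------------------------

def quartet_hbond_series(
    ens: Ensemble,
    assign: QuartetAssignment,
    criterion: HBondCriterion | None = None,
    config: cfg.PipelineConfig | None = None,
    cutoff: int | None = None,
) -> StabilitySeries:
    """Per-frame within-layer Hoogsteen bond counts plus intermolecular counts.

    Quartet membership is frozen at the frame-0 assignment: only hoogsteen_GG
    bonds between guanines of the same assigned layer are counted, so a bond
    lost to strand displacement lowers the count instead of re-assigning the
    quartet.  A donor atom engaged with a neighbouring guanine counts once
    even when transiently bifurcated across its O6 and N7 acceptors, keeping
    the per-quartet maximum at 8 (two donors per adjacent pair).
    """
    if not assign:
        raise GQKitError("empty quartet assignment: nothing to score")
    conf = config or cfg.DEFAULT_CONFIG
    cutoff = conf.instability_cutoff if cutoff is None else cutoff
    q_counts = np.zeros(ens.frame_count, dtype=int)
    im_counts = np.zeros(ens.frame_count, dtype=int)
    for f in range(ens.frame_count):
        frame = ens.frame(f)
        engaged: set[tuple[int, tuple[str, int]]] = set()
        for b in detect_hbonds(frame, criterion, config):
            if b.kind == "hoogsteen_GG":
                u = (b.donor_atom.chain, b.donor_atom.resid)
                v = (b.acceptor_atom.chain, b.acceptor_atom.resid)
                lu, lv = assign.layer_of.get(u), assign.layer_of.get(v)
                if lu is not None and lu == lv:
                    engaged.add((b.donor, v))
            elif b.kind == "intermolecular":
                im_counts[f] += 1
        q_counts[f] = len(engaged)
    series = StabilitySeries(q_counts, im_counts, assign.n_quartets, cutoff=cutoff)
    series.label = classify_stability(series, cutoff)
    return series


def classify_stability(series: StabilitySeries, cutoff: int = 15) -> str:
    """A complex is unstable iff its mean within-quartet bond count is <= cutoff."""
    if series.per_frame_quartet_hbonds.size == 0:
        raise GQKitError("empty stability series")
    return "unstable" if series.mean_quartet <= cutoff else "stable"


def stability_scatter(
    complex_results: list[StabilitySeries],
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """One row per complex: mean intermolecular vs mean quartet H-bonds + label.

    This is the tabular form of the stability scatter (intermolecular
    peptide-GQ bonds against intramolecular quartet bonds).
    """
    if not complex_results:
        raise GQKitError("no stability results")
    ids = ids or [f"complex_{i}" for i in range(len(complex_results))]
    rows = [
        {
            "complex": cid,
            "mean_intermolecular": s.mean_intermolecular,
            "mean_quartet": s.mean_quartet,
            "label": s.label or classify_stability(s, s.cutoff),
        }
        for cid, s in zip(ids, complex_results)
    ]
    return pd.DataFrame(rows, columns=["complex", "mean_intermolecular", "mean_quartet", "label"])
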
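"""Synthetic structure generators: idealized G-quadruplexes, disordered-peptide
conformers, planted binding poses and stable/unstable pseudo-trajectories.

These generators define the study conditions for the whole test suite, in
place of downloaded PDB entries or MD trajectories.  The quadruplex builder
places a standard planar guanine template in C4 symmetry so that each base
donates its two Hoogsteen bonds (N1->O6 and N2->N7, both near 2.9 A) to its
clockwise neighbour; layers stack at a 3.4 A rise with a 30 degree helical
twist, and K+ ions sit on the channel axis midway between adjacent quartet
planes.  Loop and overhang nucleotides are geometric placeholders with correct
residue naming (only contact/role logic, never loop conformation, is analyzed
downstream).  Hydrogens are omitted throughout, so the heavy-atom H-bond
fallback criterion is the tested default.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import config as cfg
from .errors import BuildError, PlacementError
from .structures import Atom, Ensemble, ResidueRole, StructureModel, classify_residues

__all__ = [
    "GQSpec",
    "PoseSpec",
    "build_gq",
    "make_peptide_conformers",
    "place_peptide",
    "make_unfolding_trajectory",
    "DEFAULT_PEPTIDE_SEQUENCE",
]

# standard planar guanine geometry (base reference frame, z = 0), Angstrom
_GUANINE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "C1'": (-2.477, 5.399, 0.000),
    "N9": (-1.289, 4.551, 0.000),
    "C8": (0.023, 4.962, 0.000),
    "N7": (0.870, 3.969, 0.000),
    "C5": (0.071, 2.833, 0.000),
    "C6": (0.424, 1.460, 0.000),
    "O6": (1.554, 0.955, 0.000),
    "N1": (-0.700, 0.641, 0.000),
    "C2": (-1.999, 1.087, 0.000),
    "N2": (-2.949, 0.139, 0.000),
    "N3": (-2.342, 2.364, 0.000),
    "C4": (-1.265, 3.177, 0.000),
}
_G_NAMES = list(_GUANINE_TEMPLATE)
_G_XYZ = np.array([_GUANINE_TEMPLATE[n] for n in _G_NAMES])
_G_IDX = {n: i for i, n in enumerate(_G_NAMES)}

# Arg/Gly-repeat-rich 53-mer with interspersed Phe/Tyr/Asn, emulating the
# composition of an RGG-box low-complexity region (synthetic sequence).
DEFAULT_PEPTIDE_SEQUENCE = "GSRGGFGGNDFGRGGNFGGRGGYGGSGGGRGGFGGNRGGYGNQSSNFGRGGYG"

_ELEMENT_OVERRIDES = {"K": "K", "NA": "NA"}


def _element_of(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    return stripped[0].upper() if stripped else "X"


@dataclass(frozen=True)
class GQSpec:
    """Parameters of an idealized G-quadruplex stem."""

    n_quartets: int = 3
    n_strands: int = 4            # molecularity: 1, 2 or 4
    nucleic_kind: str = "DNA"     # "DNA" | "RNA"
    sequence_repeat: str = ""     # default TTAGGG (DNA) / UUAGGG (RNA)
    rise: float = 3.4
    twist: float = 30.0
    hoogsteen_NO_dist: float = 2.9

    def __post_init__(self):
        if self.n_quartets < 1:
            raise ValueError("n_quartets must be >= 1")
        if self.n_strands not in (1, 2, 4):
            raise ValueError("n_strands must be one of 1, 2, 4")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.nucleic_kind not in ("DNA", "RNA"):
            raise ValueError("nucleic_kind must be 'DNA' or 'RNA'")

    @property
    def repeat(self) -> str:
        if self.sequence_repeat:
            return self.sequence_repeat
        base = "TTA" if self.nucleic_kind == "DNA" else "UUA"
        return base + "G" * self.n_quartets

    @property
    def loop_prefix(self) -> str:
        """Non-guanine connector bases of the repeat (e.g. TTA)."""
        return "".join(c for c in self.repeat if c != "G")


@dataclass(frozen=True)
class PoseSpec:
    """A planted peptide binding pose: end-stacking, groove, loop, or far."""

    mode: str = "end_stack"       # end_stack | groove | loop | far
    target_distance: float = 0.0  # 0 -> mode default (3.5, or 8.0 for far)
    peptide_residue_index: int = 0

    def __post_init__(self):
        if self.mode not in ("end_stack", "groove", "loop", "far"):
            raise ValueError(f"unknown pose mode {self.mode!r}")
        if self.target_distance < 0:
            raise ValueError("target_distance must be positive")

    @property
    def distance(self) -> float:
        if self.target_distance > 0:
            return self.target_distance
        return 8.0 if self.mode == "far" else 3.5


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _solve_quartet_placement(target: float) -> np.ndarray:
    """In-plane rigid transform (theta, x, y) of the guanine template so that
    each base Hoogsteen-bonds its +90-degree neighbour at the target distance,
    cross donor-acceptor pairs stay beyond the 3.5 A criterion and no cross
    pair clashes."""
    n1, n2, o6, n7 = (_G_IDX[k] for k in ("N1", "N2", "O6", "N7"))

    def place(params):
        th, x, y = params
        g0 = _G_XYZ @ _rz(th).T + np.array([x, y, 0.0])
        return g0, g0 @ _rz(90).T

    def resid(params):
        g0, g1 = place(params)
        d = np.linalg.norm(g0[:, None, :] - g1[None, :, :], axis=-1)
        return [
            d[n1, o6] - target,
            d[n2, n7] - target,
            0.3 * (np.linalg.norm(g0[o6][:2]) - 2.2),
            2.0 * max(0.0, 3.65 - d[n1, n7]),
            2.0 * max(0.0, 3.65 - d[n2, o6]),
            5.0 * np.maximum(0.0, 2.7 - d).sum(),
        ]

    sol = least_squares(resid, [263.3, 1.40, 2.34], xtol=1e-14, ftol=1e-14)
    return sol.x


def build_gq(spec: GQSpec | None = None, seed: int = 0) -> StructureModel:
    """Build an idealized G-quadruplex with loops/overhangs and channel ions.

    The stem holds ``n_quartets`` C4-symmetric layers of four guanines each;
    (n_quartets - 1) K+ ions sit on the channel axis midway between adjacent
    planes.  Connector/overhang T/U/A residues from the sequence repeat are
    placed at large radius with approximate, non-clashing geometry; the
    backbone is represented by C1' and P pseudo-positions.  A geometric
    self-check verifies every intra-quartet N1...O6 distance lies in
    [2.6, 3.2] A.
    """
    spec = spec or GQSpec()
    params = _solve_quartet_placement(spec.hoogsteen_NO_dist)
    th, x, y = params
    g_base = _G_XYZ @ _rz(th).T + np.array([x, y, 0.0])

    is_dna = spec.nucleic_kind == "DNA"
    g_resname = "DG" if is_dna else "G"
    loop_resname = {"T": "DT" if is_dna else "T", "U": "U", "A": "DA" if is_dna else "A"}

    # guanine coordinates per (layer, strand-position)
    def guanine_coords(layer: int, pos: int) -> np.ndarray:
        rot = _rz(pos * 90.0 + layer * spec.twist)
        return g_base @ rot.T + np.array([0.0, 0.0, layer * spec.rise])

    def guanine_atoms(layer: int, pos: int, chain: str, resid: int) -> list[Atom]:
        xyz = guanine_coords(layer, pos)
        atoms = []
        for name in _G_NAMES:
            atoms.append(Atom(0, name, _element_of(name), g_resname, resid, chain,
                              xyz[_G_IDX[name]].copy()))
        # P pseudo-position: radially beyond C1', slightly out of plane
        c1 = xyz[_G_IDX["C1'"]]
        n9 = xyz[_G_IDX["N9"]]
        u = c1 - n9
        u = u / np.linalg.norm(u)
        p = c1 + 1.6 * u + np.array([0.0, 0.0, 1.0])
        atoms.append(Atom(0, "P", "P", g_resname, resid, chain, p))
        return atoms

    top_z = (spec.n_quartets - 1) * spec.rise

    def loop_atoms(letter: str, chain: str, resid: int, angle_deg: float, z: float) -> list[Atom]:
        resname = loop_resname[letter]
        base_name = "N9" if letter == "A" else "N1"
        ang = np.deg2rad(angle_deg)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        return [
            Atom(0, base_name, "N", resname, resid, chain, 10.5 * u + np.array([0, 0, z])),
            Atom(0, "C1'", "C", resname, resid, chain, 11.8 * u + np.array([0, 0, z + 0.4])),
            Atom(0, "P", "P", resname, resid, chain, 13.1 * u + np.array([0, 0, z + 0.9])),
        ]

    atoms: list[Atom] = []
    chains = "ABCD"
    prefix = spec.loop_prefix
    columns_per_strand = 4 // spec.n_strands

    for strand in range(spec.n_strands):
        chain = chains[strand]
        resid = 0
        for col_in_strand in range(columns_per_strand):
            pos = strand * columns_per_strand + col_in_strand
            strand_angle = pos * 90.0 + 45.0
            if col_in_strand == 0:
                # 5' overhang below the stem
                for m, letter in enumerate(prefix):
                    resid += 1
                    z = -(m + 1) * 2.8 - 1.5
                    atoms.extend(loop_atoms(letter, chain, resid, strand_angle - 15 * m, z))
            else:
                # connector loop above the stem, between adjacent columns
                for m, letter in enumerate(prefix):
                    resid += 1
                    frac = (m + 1) / (len(prefix) + 1)
                    ang = strand_angle - 90.0 + 90.0 * frac
                    z = top_z + 3.0 + 1.2 * np.sin(np.pi * frac)
                    atoms.extend(loop_atoms(letter, chain, resid, ang, z))
            for layer in range(spec.n_quartets):
                resid += 1
                atoms.extend(guanine_atoms(layer, pos, chain, resid))

    # channel ions between adjacent quartet planes
    for j in range(spec.n_quartets - 1):
        z = (j + 0.5) * spec.rise
        atoms.append(
            Atom(0, "K", "K", "K", j + 1, "I", np.array([0.0, 0.0, z]), hetero=True)
        )

    for i, a in enumerate(atoms):
        a.serial = i + 1
    model = StructureModel(atoms)
    model.validate()
    _self_check_quartets(model, spec)
    return model


def _self_check_quartets(model: StructureModel, spec: GQSpec) -> None:
    """Verify every intra-quartet N1...O6 distance lies in [2.6, 3.2] A."""
    by_key: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    guanines = [a for a in model.atoms if a.resname in ("DG", "G")]
    for a in guanines:
        by_key.setdefault((a.chain, a.resid), {})[a.name] = a.xyz
    # group guanines by z of their base centroid into layers
    items = sorted(by_key.items(), key=lambda kv: kv[1]["N9"][2])
    for layer in range(spec.n_quartets):
        group = items[layer * 4:(layer + 1) * 4]
        if len(group) != 4:
            raise BuildError("self-check: could not group guanines into layers")
        for _, gi in group:
            dmin = min(
                float(np.linalg.norm(gi["N1"] - gj["O6"]))
                for _, gj in group
                if gj is not gi
            )
            if not (2.6 <= dmin <= 3.2):
                raise BuildError(
                    f"self-check: intra-quartet N1...O6 distance {dmin:.2f} A outside [2.6, 3.2]"
                )


# ---------------------------------------------------------------------------
# peptide conformers
# ---------------------------------------------------------------------------

def make_peptide_conformers(
    sequence: str = DEFAULT_PEPTIDE_SEQUENCE,
    n: int = 50,
    seed: int = 0,
    backbone: str = "full",
) -> Ensemble:
    """Self-avoiding random-walk peptide conformers.

    Each conformer is a Calpha trace with 3.8 A virtual bonds and a
    self-avoidance threshold of 4.0 A between non-adjacent Calpha atoms.
    ``backbone="full"`` adds pseudo N, C, O backbone atoms (so the peptide has
    hydrogen-bond donors/acceptors) plus a sidechain-centroid CB pseudo-atom
    for every non-Gly residue; ``backbone="trace"`` emits Calpha + CB only.
    Bitwise reproducible for a fixed seed.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if backbone not in ("full", "trace"):
        raise ValueError("backbone must be 'full' or 'trace'")
    rng = np.random.default_rng(seed)
    frames = [_one_conformer(sequence, rng, backbone) for _ in range(n)]
    return Ensemble.from_frames(frames)


def _random_walk_ca(nres: int, rng: np.random.Generator) -> np.ndarray:
    step, min_sep = 3.8, 4.0
    for _ in range(200):  # full restarts
        pts = [np.zeros(3)]
        direction = _random_unit(rng)
        ok = True
        for _ in range(nres - 1):
            placed = False
            for _ in range(80):
                cand_dir = 0.55 * direction + _random_unit(rng)
                cand_dir = cand_dir / np.linalg.norm(cand_dir)
                cand = pts[-1] + step * cand_dir
                prior = np.array(pts[:-1]) if len(pts) > 1 else None
                if prior is None or np.min(np.linalg.norm(prior - cand, axis=1)) >= min_sep:
                    pts.append(cand)
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise PlacementError("self-avoiding walk failed to complete")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _one_conformer(sequence: str, rng: np.random.Generator, backbone: str) -> StructureModel:
    ca = _random_walk_ca(len(sequence), rng)
    atoms: list[Atom] = []
    for i, letter in enumerate(sequence):
        resname = cfg.AA1_TO_3.get(letter.upper())
        if resname is None:
            raise ValueError(f"unknown amino-acid letter {letter!r}")
        resid = i + 1
        u_prev = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[min(i + 1, len(ca) - 1)] - ca[i])
        u_next = _unit(ca[i + 1] - ca[i]) if i < len(ca) - 1 else u_prev
        perp = _unit(np.cross(u_next, _random_unit(rng)))
        if backbone == "full":
            atoms.append(Atom(0, "N", "N", resname, resid, "P", ca[i] - 1.33 * u_prev))
            atoms.append(Atom(0, "CA", "C", resname, resid, "P", ca[i].copy()))
            atoms.append(Atom(0, "C", "C", resname, resid, "P", ca[i] + 1.33 * u_next))
            atoms.append(Atom(0, "O", "O", resname, resid, "P",
                              ca[i] + 1.33 * u_next + 1.23 * perp))
        else:
            atoms.append(Atom(0, "CA", "C", resname, resid, "P", ca[i].copy()))
        if letter.upper() != "G":
            side = _unit(np.cross(u_prev + u_next, perp) + 0.3 * _random_unit(rng))
            atoms.append(Atom(0, "CB", "C", resname, resid, "P", ca[i] + 1.8 * side))
    for k, a in enumerate(atoms):
        a.serial = k + 1
    return StructureModel(atoms)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# pose planting
# ---------------------------------------------------------------------------

def place_peptide(
    gq: StructureModel,
    peptide: StructureModel,
    pose: PoseSpec | None = None,
    seed: int = 0,
    config: cfg.PipelineConfig | None = None,
    max_tries: int = 600,
) -> StructureModel:
    """Rigidly place a peptide against a G-quadruplex in a designated pose.

    The designated peptide residue's Calpha is anchored near a mode-specific
    target atom: an outer-quartet O6 (end_stack), a groove-exposed guanine
    atom (groove), any loop-nucleotide atom (loop); for "far" every peptide
    atom ends at least ``target_distance`` from every GQ atom.  Random rigid
    orientations about the anchor are tried until no peptide-GQ atom pair is
    closer than 2.0 A; failure after bounded retries raises PlacementError.
    """
    from .hbonds import detect_quartets  # local import to avoid cycle

    pose = pose or PoseSpec()
    conf = config or cfg.DEFAULT_CONFIG
    if len(peptide) == 0:
        raise ValueError("peptide is empty")
    assign = detect_quartets(gq, config=conf)
    if not assign:
        raise PlacementError("GQ contains no detectable quartet")
    rng = np.random.default_rng(seed)

    roles = classify_residues(gq, conf)
    by_res = gq.atom_indices_by_residue()
    gq_coords = gq.coords
    gq_heavy = np.array([i for i, a in enumerate(gq.atoms) if not a.is_hydrogen()])
    tree = cKDTree(gq_coords[gq_heavy])

    pep_res = peptide.residues()
    if not (0 <= pose.peptide_residue_index < len(pep_res)):
        raise ValueError("peptide_residue_index out of range")
    anchor_idx = next(
        i for i in peptide.atom_indices_by_residue()[pep_res[pose.peptide_residue_index]]
        if peptide.atoms[i].name == "CA"
    )
    pep0 = peptide.coords - peptide.coords[anchor_idx]

    center = gq_coords[gq_heavy].mean(axis=0)
    axis = assign.axis

    if pose.mode == "far":
        radius = np.max(np.linalg.norm(gq_coords[gq_heavy] - center, axis=1))
        pep_radius = np.max(np.linalg.norm(pep0, axis=1))
        direction = _unit(np.array([1.0, 0.3, 0.2]))
        offset = radius + pep_radius + pose.distance + 2.0
        for _ in range(max_tries):
            rot = Rotation.random(random_state=rng).as_matrix()
            coords = pep0 @ rot.T + center + offset * direction
            dmin, _ = tree.query(coords)
            if np.min(dmin) >= pose.distance:
                return _merge(gq, peptide, coords)
            offset += 1.0
        raise PlacementError("could not satisfy the far-pose separation")

    d_anchor = min(pose.distance - 0.3, 0.92 * pose.distance)
    candidates = _pose_candidates(pose.mode, gq, assign, roles, by_res, conf, center, axis)
    # rank candidate anchor points by clearance from the GQ: an anchor buried
    # against a backbone atom can never be made clash-free by rotation
    scored = []
    for target_xyz, approach in candidates:
        anchor_pos = target_xyz + d_anchor * approach
        clearance, _ = tree.query(anchor_pos)
        scored.append((float(clearance), target_xyz, approach, anchor_pos))
    scored.sort(key=lambda t: -t[0])
    top = [s for s in scored if s[0] >= 2.0][:8]
    if not top:
        raise PlacementError(
            f"every candidate {pose.mode} anchor point is buried (best clearance "
            f"{scored[0][0]:.2f} A)"
        )
    tries_each = max(1, max_tries // len(top))
    for clearance, target_xyz, approach, anchor_pos in top:
        # bias the search: point the peptide's bulk outward along the approach
        # direction, then scan spins about it with a progressively wider tilt
        u_pep = pep0.mean(axis=0)
        if np.linalg.norm(u_pep) < 1e-6:
            u_pep = _random_unit(rng)
        u_pep = _unit(u_pep)
        align, _ = Rotation.align_vectors(approach[None, :], u_pep[None, :])
        for t in range(tries_each):
            spin = Rotation.from_rotvec(approach * rng.uniform(0.0, 2 * np.pi))
            tilt_max = min(np.pi, 0.25 + 3.0 * t / tries_each)
            tilt = Rotation.from_rotvec(_random_unit(rng) * rng.uniform(0.0, tilt_max))
            rot = (spin * tilt * align).as_matrix()
            coords = pep0 @ rot.T + anchor_pos
            dmin, _ = tree.query(coords)
            if np.min(dmin) >= 2.0:
                # anchor satisfied by construction; re-check against drift
                if float(np.linalg.norm(coords[anchor_idx] - target_xyz)) <= pose.distance:
                    return _merge(gq, peptide, coords)
    raise PlacementError(
        f"no clash-free {pose.mode} placement found after {max_tries} orientations "
        f"(target distance {pose.distance} A)"
    )


def _pose_candidates(mode, gq, assign, roles, by_res, conf, center, axis):
    """All (target atom position, outward approach direction) pairs for a mode."""
    gq_coords = gq.coords

    def radial(i):
        v = gq_coords[i] - center
        return _unit(v - (v @ axis) * axis)

    out: list[tuple[np.ndarray, np.ndarray]] = []
    if mode == "end_stack":
        for g in assign.quartets[-1]:
            for i in by_res[g]:
                if gq.atoms[i].name == "O6":
                    out.append((gq_coords[i], _unit(axis)))
    elif mode == "groove":
        groove_names = conf.groove_atoms()
        for q in assign.quartets:
            for g in q:
                for i in by_res[g]:
                    if gq.atoms[i].name in groove_names:
                        out.append((gq_coords[i], radial(i)))
    elif mode == "loop":
        loops = [k for k, r in roles.items() if r == ResidueRole.LOOP_NUCLEOTIDE]
        if not loops:
            raise PlacementError("GQ has no loop nucleotides for a loop pose")
        for k in loops:
            for i in by_res[k]:
                if not gq.atoms[i].is_hydrogen():
                    out.append((gq_coords[i], radial(i)))
    else:
        raise ValueError(mode)
    return out


def _merge(gq: StructureModel, peptide: StructureModel, pep_coords: np.ndarray) -> StructureModel:
    atoms = [
        Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain, a.xyz.copy(), a.hetero)
        for a in gq.atoms
    ]
    for i, a in enumerate(peptide.atoms):
        atoms.append(Atom(0, a.name, a.element, a.resname, a.resid, "P", pep_coords[i].copy()))
    for k, a in enumerate(atoms):
        a.serial = k + 1
    model = StructureModel(atoms)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# pseudo-trajectories
# ---------------------------------------------------------------------------

def make_unfolding_trajectory(
    complex: StructureModel,
    n_frames: int = 20,
    strand_displacement_per_frame: float = 0.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
    strand_chain: str = "A",
    config: cfg.PipelineConfig | None = None,
) -> Ensemble:
    """Pseudo-trajectory: Gaussian coordinate noise everywhere plus a rigid
    per-frame translation of one designated strand along its groove normal.

    Frame f (0-based) = base coordinates + N(0, noise_sigma) + f *
    strand_displacement_per_frame applied to the designated chain.  The groove
    normal is the unit vector from the channel axis through the displaced
    strand's guanine centroid, perpendicular to the axis.  With zero
    displacement this yields a stable trajectory; a few tenths of an Angstrom
    per frame progressively severs the displaced strand's Hoogsteen bonds.
    """
    from .hbonds import detect_quartets

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    chains = {a.chain for a in complex.atoms}
    if strand_chain not in chains:
        raise ValueError(f"designated strand chain {strand_chain!r} absent from complex")

    conf = config or cfg.DEFAULT_CONFIG
    coords0 = complex.coords
    mask = np.array([a.chain == strand_chain for a in complex.atoms])

    if strand_displacement_per_frame != 0.0:
        assign = detect_quartets(complex, config=conf)
        if not assign:
            raise ValueError("no quartet detected: cannot define a groove normal")
        axis = assign.axis
        roles = classify_residues(complex, conf)
        g_idx = [
            i for i, a in enumerate(complex.atoms)
            if a.chain == strand_chain and roles[(a.chain, a.resid)] == ResidueRole.GUANINE
        ]
        if not g_idx:
            raise ValueError(f"designated strand {strand_chain!r} carries no guanines")
        stem_res = set(assign.layer_of)
        stem = coords0[[
            i for i, a in enumerate(complex.atoms)
            if (a.chain, a.resid) in stem_res and not a.is_hydrogen()
        ]]
        center = stem.mean(axis=0)
        v = coords0[g_idx].mean(axis=0) - center
        normal = v - (v @ axis) * axis
        normal = normal / np.linalg.norm(normal)
    else:
        normal = np.zeros(3)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, len(complex), 3))
    for f in range(n_frames):
        noisy = coords0 + rng.normal(scale=noise_sigma, size=coords0.shape)
        noisy[mask] += f * strand_displacement_per_frame * normal
        frames[f] = noisy
    return Ensemble(complex, frames)
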
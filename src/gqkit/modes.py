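"""Binding-mode classification and composition-normalized interaction matrices.

A peptide residue explores the end-stacking mode when any of its heavy atoms
lies within the contact cutoff (default 4 A) of a quartet guanine O6 (the
carbonyl oxygens lining the central channel); the groove mode when it contacts
a groove-exposed guanine atom from {N2, C2, N3, C4, C8, N9}; and the loop mode
when it contacts any atom of a connector/overhang nucleotide, irrespective of
backbone, sugar or base.  The three modes are not exclusive: one residue can
carry all three flags simultaneously.

Interaction matrices count, per amino-acid type and per GQ base, the number of
residue-base-frame contacts satisfying the mode's atom rule, normalized by the
number of residues of that type in the peptide sequence (so each entry is
"contacts per residue of that type").  A residue-base contact in a frame
counts once regardless of how many atom pairs are within the cutoff
(switchable to atom-pair counting via config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import config as cfg
from .errors import GQKitError
from .hbonds import QuartetAssignment
from .structures import Ensemble, ResidueRole, StructureModel, classify_residues

__all__ = ["ModeFlags", "ModeMatrix", "classify_residue_modes", "interaction_matrix", "MODES"]

MODES = ("end_stack", "groove", "loop")


@dataclass(frozen=True)
class ModeFlags:
    end_stack: bool = False
    groove: bool = False
    loop: bool = False

    def any(self) -> bool:
        return self.end_stack or self.groove or self.loop


@dataclass
class ModeMatrix:
    """Amino-acid-type x GQ-base normalized interaction counts for one mode."""

    table: pd.DataFrame   # rows: one-letter aa types present; cols: base labels
    mode: str

    def __post_init__(self):
        if (self.table.values < 0).any():
            raise GQKitError("interaction matrix entries must be non-negative")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def _mode_target_atoms(
    frame: StructureModel,
    assign: QuartetAssignment,
    roles,
    conf: cfg.PipelineConfig,
) -> dict[str, list[int]]:
    """Atom indices that define each mode's contact target set."""
    by_res = frame.atom_indices_by_residue()
    quartet_res = set(assign.layer_of)
    if conf.end_stack_outer_only and assign.n_quartets >= 2:
        outer = set(assign.quartets[0]) | set(assign.quartets[-1])
    else:
        outer = quartet_res
    groove_names = conf.groove_atoms()
    targets: dict[str, list[int]] = {m: [] for m in MODES}
    for key, idx in by_res.items():
        role = roles[key]
        if role == ResidueRole.GUANINE and key in quartet_res:
            for i in idx:
                name = frame.atoms[i].name
                if name == "O6" and key in outer:
                    targets["end_stack"].append(i)
                if name in groove_names:
                    targets["groove"].append(i)
        elif role == ResidueRole.LOOP_NUCLEOTIDE and conf.overhangs_are_loops:
            targets["loop"].extend(i for i in idx if not frame.atoms[i].is_hydrogen())
        elif role == ResidueRole.LOOP_NUCLEOTIDE:
            # even with overhangs excluded, connector loops would be listed by
            # the caller; the flag simply empties the loop target set here
            pass
    return targets


def classify_residue_modes(
    frame: StructureModel,
    assign: QuartetAssignment,
    cutoff: float = 4.0,
    config: cfg.PipelineConfig | None = None,
) -> dict[tuple[str, int], ModeFlags]:
    """Per-residue binding-mode flags for one frame (heavy atoms only)."""
    if not assign:
        raise GQKitError("empty quartet assignment")
    conf = config or cfg.DEFAULT_CONFIG
    roles = classify_residues(frame, conf)
    prot_res = [k for k, r in roles.items() if r == ResidueRole.PROTEIN]
    if not prot_res:
        raise GQKitError("no protein chain in frame")
    by_res = frame.atom_indices_by_residue()
    coords = frame.coords
    targets = _mode_target_atoms(frame, assign, roles, conf)
    trees = {
        m: cKDTree(coords[idx]) if idx else None for m, idx in targets.items()
    }
    out: dict[tuple[str, int], ModeFlags] = {}
    for key in prot_res:
        heavy = [i for i in by_res[key] if not frame.atoms[i].is_hydrogen()]
        pts = coords[heavy]
        flags = {}
        for m in MODES:
            tree = trees[m]
            if tree is None:
                flags[m] = False
                continue
            d, _ = tree.query(pts)
            flags[m] = bool(np.min(d) <= cutoff)
        out[key] = ModeFlags(**flags)
    return out


def interaction_matrix(
    ens: Ensemble,
    assign: QuartetAssignment,
    mode: str,
    cutoff: float = 4.0,
    config: cfg.PipelineConfig | None = None,
) -> ModeMatrix:
    """Normalized amino-acid-type x base interaction matrix for one mode.

    Columns are all GQ bases in sequence order, labelled ``chain.resname+resid``;
    rows are the one-letter amino-acid types present in the peptide.  Entry
    (t, b) = number of (residue-of-type-t, base b) frame-contacts under the
    mode's atom rule, divided by the count of type t in the sequence.
    """
    if mode not in MODES:
        raise ValueError(f"invalid mode {mode!r}; expected one of {MODES}")
    conf = config or cfg.DEFAULT_CONFIG
    topo = ens.topology
    roles = classify_residues(topo, conf)
    by_res = topo.atom_indices_by_residue()
    prot_res = [k for k, r in roles.items() if r == ResidueRole.PROTEIN]
    base_res = [
        k for k, r in roles.items()
        if r in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE)
    ]
    if not prot_res or not base_res:
        raise GQKitError("ensemble must contain both protein and GQ bases")

    resname = topo.resname_of()
    aa_of = {k: cfg.AA3_TO_1.get(resname[k].strip().upper(), resname[k].strip()) for k in prot_res}
    composition: dict[str, int] = {}
    for k in prot_res:
        composition[aa_of[k]] = composition.get(aa_of[k], 0) + 1

    # per-base target atom indices under this mode's rule
    quartet_res = set(assign.layer_of)
    groove_names = conf.groove_atoms()
    if conf.end_stack_outer_only and assign.n_quartets >= 2:
        outer = set(assign.quartets[0]) | set(assign.quartets[-1])
    else:
        outer = quartet_res
    base_targets: dict[tuple[str, int], list[int]] = {}
    for k in base_res:
        role = roles[k]
        idx: list[int] = []
        if mode == "end_stack" and role == ResidueRole.GUANINE and k in quartet_res and k in outer:
            idx = [i for i in by_res[k] if topo.atoms[i].name == "O6"]
        elif mode == "groove" and role == ResidueRole.GUANINE and k in quartet_res:
            idx = [i for i in by_res[k] if topo.atoms[i].name in groove_names]
        elif mode == "loop" and role == ResidueRole.LOOP_NUCLEOTIDE and conf.overhangs_are_loops:
            idx = [i for i in by_res[k] if not topo.atoms[i].is_hydrogen()]
        base_targets[k] = idx

    prot_heavy = {k: [i for i in by_res[k] if not topo.atoms[i].is_hydrogen()] for k in prot_res}
    labels = [f"{c}.{resname[(c, r)]}{r}" for c, r in base_res]
    types = sorted(composition)
    counts = pd.DataFrame(0.0, index=types, columns=labels)

    for f in range(ens.frame_count):
        coords = ens.coords[f]
        for b_i, b in enumerate(base_res):
            t_idx = base_targets[b]
            if not t_idx:
                continue
            tree = cKDTree(coords[t_idx])
            for p in prot_res:
                d, _ = tree.query(coords[prot_heavy[p]])
                if conf.count_atom_pairs:
                    n = int(np.sum(d <= cutoff))
                else:
                    n = int(np.min(d) <= cutoff)
                if n:
                    counts.iloc[counts.index.get_loc(aa_of[p]), b_i] += n

    for t in types:
        counts.loc[t] /= composition[t]
    return ModeMatrix(counts, mode)
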
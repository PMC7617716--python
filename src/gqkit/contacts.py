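"""Residue-wise protein x nucleotide contact lifetime maps.

A contact exists in a frame when any heavy-atom pair between a peptide residue
and a GQ base lies at or below the cutoff (default 4 A; closed interval).  The
lifetime is the fraction of frames with a contact; entries persisting for less
than the minimum lifetime (default 1% of the trajectory) are reported as zero.
Maps over several runs are pooled by total contact frames over total frames
(integer counting, so merging is exact, associative and order-independent),
with the persistence filter re-applied after pooling — a contact sparse in
each run but persistent overall survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import config as cfg
from .errors import GQKitError
from .structures import Ensemble, ResidueRole, classify_residues

__all__ = ["ContactMap", "contact_map", "merge_maps"]


@dataclass
class ContactMap:
    row_labels: list[str]          # peptide residues, sequence order
    col_labels: list[str]          # GQ bases, sequence order
    counts: np.ndarray             # integer contact-frame counts
    n_frames: int
    cutoff: float = 4.0
    min_lifetime: float = 0.01

    @property
    def values(self) -> np.ndarray:
        """Lifetime fractions in [0, 1], zeroed below the persistence filter."""
        v = self.counts / self.n_frames
        v[v < self.min_lifetime] = 0.0
        return v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def contact_map(
    ens: Ensemble,
    cutoff: float = 4.0,
    min_lifetime: float = 0.01,
    config: cfg.PipelineConfig | None = None,
    residue_offset: int = 0,
) -> ContactMap:
    """Contact lifetime map of a peptide-GQ trajectory.

    ``residue_offset`` shifts the reported peptide residue numbers (reports
    often use the construct numbering of the parent protein rather than the
    1-based numbering of the fixture).
    """
    conf = config or cfg.DEFAULT_CONFIG
    topo = ens.topology
    roles = classify_residues(topo, conf)
    by_res = topo.atom_indices_by_residue()
    prot_res = [k for k, r in roles.items() if r == ResidueRole.PROTEIN]
    base_res = [
        k for k, r in roles.items()
        if r in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE)
    ]
    if not prot_res:
        raise GQKitError("no protein residues in ensemble")
    if not base_res:
        raise GQKitError("no nucleic residues in ensemble")

    resname = topo.resname_of()
    aa1 = {k: cfg.AA3_TO_1.get(resname[k].strip().upper(), "X") for k in prot_res}
    row_labels = [f"{aa1[k]}{k[1] + residue_offset}" for k in prot_res]
    col_labels = [f"{c}.{resname[(c, r)]}{r}" for c, r in base_res]

    prot_heavy = [
        np.array([i for i in by_res[k] if not topo.atoms[i].is_hydrogen()]) for k in prot_res
    ]
    base_heavy = [
        np.array([i for i in by_res[k] if not topo.atoms[i].is_hydrogen()]) for k in base_res
    ]

    counts = np.zeros((len(prot_res), len(base_res)), dtype=np.int64)
    for f in range(ens.frame_count):
        coords = ens.coords[f]
        trees = [cKDTree(coords[idx]) for idx in base_heavy]
        for i, pidx in enumerate(prot_heavy):
            pts = coords[pidx]
            for j, tree in enumerate(trees):
                d, _ = tree.query(pts)
                if np.min(d) <= cutoff:
                    counts[i, j] += 1
    return ContactMap(row_labels, col_labels, counts, ens.frame_count, cutoff, min_lifetime)


def merge_maps(maps: list[ContactMap]) -> ContactMap:
    """Pool lifetime maps: total contact frames over total frames.

    All inputs must share identical row/column labels; the persistence filter
    is re-applied after pooling.
    """
    if not maps:
        raise GQKitError("no maps to merge")
    first = maps[0]
    for m in maps[1:]:
        if m.row_labels != first.row_labels or m.col_labels != first.col_labels:
            raise GQKitError("contact-map labels do not match; cannot pool")
    counts = np.sum([m.counts for m in maps], axis=0)
    n_frames = int(sum(m.n_frames for m in maps))
    return ContactMap(
        list(first.row_labels), list(first.col_labels), counts, n_frames,
        first.cutoff, first.min_lifetime,
    )
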
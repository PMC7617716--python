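"""Three-dimensional occupancy density of peptide atoms around a G-quadruplex.

Every frame is least-squares superposed (Kabsch) onto the frame-0 GQ stem
heavy atoms, so the density lives in a GQ-fixed reference frame.  A voxel's
per-frame occupancy is 1 when at least one peptide heavy atom falls in the
voxel while lying within the proximity shell (default 6 A) of any GQ heavy
atom, else 0; grid values are the mean over frames — the fraction of the
trajectory during which the voxel is peptide-occupied near the GQ surface.
Grids are written as OpenDX scalar fields loadable by standard molecular
viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import config as cfg
from .errors import FormatError, GQKitError
from .structures import Ensemble, ResidueRole, classify_residues

__all__ = ["OccupancyGrid", "occupancy_grid", "write_dx", "read_dx"]


@dataclass
class OccupancyGrid:
    origin: np.ndarray       # corner of voxel (0,0,0), Angstrom
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray       # occupancy fraction per voxel, in [0, 1]
    cutoff: float = 6.0
    n_frames: int = 1

    def __post_init__(self):
        if any(d <= 0 for d in self.dims):
            raise GQKitError("grid dims must be positive")
        if self.values.shape != tuple(self.dims):
            raise GQKitError("grid value shape does not match dims")

    @property
    def mass(self) -> float:
        """Total occupancy mass: sum of values x frame count = counted
        atom-voxel incidences (distinct occupied voxels summed over frames)."""
        return float(self.values.sum() * self.n_frames)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of mobile onto reference (rotation, centroids)."""
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def occupancy_grid(
    ens: Ensemble,
    spacing: float = 1.0,
    cutoff: float = 6.0,
    margin: float = 2.0,
    config: cfg.PipelineConfig | None = None,
) -> OccupancyGrid:
    """Accumulate the peptide occupancy density around the GQ.

    Grid bounds cover the frame-0 GQ extent plus cutoff plus margin.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    conf = config or cfg.DEFAULT_CONFIG
    topo = ens.topology
    roles = classify_residues(topo, conf)
    nucleic_idx = np.array([
        i for i, a in enumerate(topo.atoms)
        if not a.is_hydrogen()
        and roles[(a.chain, a.resid)] in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE)
    ])
    stem_idx = np.array([
        i for i, a in enumerate(topo.atoms)
        if not a.is_hydrogen() and roles[(a.chain, a.resid)] == ResidueRole.GUANINE
    ])
    pep_idx = np.array([
        i for i, a in enumerate(topo.atoms)
        if not a.is_hydrogen() and roles[(a.chain, a.resid)] == ResidueRole.PROTEIN
    ])
    if nucleic_idx.size == 0 or pep_idx.size == 0:
        raise GQKitError("ensemble must contain both GQ and peptide atoms")
    if stem_idx.size == 0:
        stem_idx = nucleic_idx

    # canonical GQ-fixed frame: stem principal axes with a sign convention
    # tied to the first stem atom, so the grid is invariant under any rigid
    # transform applied uniformly to all frames
    raw_stem = ens.coords[0][stem_idx]
    c0 = raw_stem.mean(axis=0)
    _, _, vt = np.linalg.svd(raw_stem - c0)
    axes = vt.copy()
    anchor = raw_stem[0] - c0
    for k in range(2):
        if anchor @ axes[k] < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    to_canonical = lambda x: (x - c0) @ axes.T  # noqa: E731

    ref_stem = to_canonical(ens.coords[0][stem_idx])
    ref_nucleic = to_canonical(ens.coords[0][nucleic_idx])
    lo = ref_nucleic.min(axis=0) - cutoff - margin
    hi = ref_nucleic.max(axis=0) + cutoff + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    acc = np.zeros(dims, dtype=np.int64)

    gq_tree = cKDTree(ref_nucleic)
    for f in range(ens.frame_count):
        coords = ens.coords[f]
        rot, mc, rc = _kabsch(coords[stem_idx], ref_stem)
        pep = (coords[pep_idx] - mc) @ rot.T + rc
        d, _ = gq_tree.query(pep)
        near = pep[d <= cutoff]
        if near.size == 0:
            continue
        vox = np.floor((near - lo) / spacing).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(dims)), axis=1)
        vox = vox[inside]
        if vox.size:
            occupied = np.unique(vox, axis=0)  # binary per voxel per frame
            acc[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1

    values = acc / ens.frame_count
    return OccupancyGrid(lo, spacing, dims, values, cutoff, ens.frame_count)


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O
# ---------------------------------------------------------------------------

def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    """Write the grid as an OpenDX scalar field (regular positions/connections)."""
    nx, ny, nz = grid.dims
    n = nx * ny * nz
    lines = [
        "# OpenDX occupancy density written by gqkit",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    flat = grid.values.reshape(-1)  # x fastest-varying last (C order: z fastest)
    for i in range(0, n, 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> OccupancyGrid:
    """Parse an OpenDX scalar field written by :func:`write_dx`."""
    dims = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    reading = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if reading:
            if s.startswith(("attribute", "object", "component")):
                reading = False
            else:
                data.extend(float(t) for t in s.split())
                continue
        if s.startswith("object 1"):
            dims = tuple(int(t) for t in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(t) for t in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append([float(t) for t in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split()[-3])
            reading = True
    if dims is None or origin is None or len(deltas) != 3:
        raise FormatError(f"not a gqkit OpenDX file: {path}")
    if n_items != dims[0] * dims[1] * dims[2] or len(data) != n_items:
        raise FormatError("OpenDX item count mismatch")
    spacing = float(deltas[0][0])
    values = np.array(data).reshape(dims)
    return OccupancyGrid(origin, spacing, dims, values)
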
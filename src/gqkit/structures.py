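"""Structure containers and PDB input/output.

The in-memory model is deliberately small: an :class:`Atom` carries PDB v3
nomenclature (atom name, residue name, chain, residue number) plus Cartesian
coordinates in Angstrom; a :class:`StructureModel` is one frame; an
:class:`Ensemble` is an ordered stack of frames sharing one topology (a
pseudo-trajectory or a conformer set).  File I/O is delegated to biotite's PDB
reader/writer; this module adds the contracts the analyses rely on: a parse
error that names the offending line, a topology error for MODEL records that
disagree on atom content, and residue-role classification with a configurable
synonym table.

Coordinates are treated as pre-imaged: no periodic minimum-image convention is
applied anywhere (the fixtures are non-periodic whole molecules).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from . import config as cfg
from .errors import FormatError, ParseError, TopologyError

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "ResidueRole",
    "read_structure",
    "write_structure",
    "classify_residues",
]


@dataclass
class Atom:
    """One atom: PDB nomenclature plus coordinates (Angstrom)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    hetero: bool = False

    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class ResidueRole(str, Enum):
    PROTEIN = "protein"
    GUANINE = "guanine"
    LOOP_NUCLEOTIDE = "loop_nucleotide"
    ION = "ion"
    OTHER = "other"


@dataclass
class StructureModel:
    """A single structural frame: an ordered atom list plus optional box."""

    atoms: list[Atom]
    box: np.ndarray | None = None

    def __post_init__(self):
        self._coords: np.ndarray | None = None

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)
        return self._coords

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int]]:
        """Residue keys (chain, resid) in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resid), None)
        return list(seen)

    def atom_indices_by_residue(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.resid), []).append(i)
        return out

    def resname_of(self) -> dict[tuple[str, int], str]:
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.resid), a.resname)
        return out

    def validate(self) -> None:
        keys = set()
        for a in self.atoms:
            k = (a.chain, a.resid, a.name)
            if k in keys:
                raise TopologyError(f"duplicate atom {k}")
            keys.add(k)
            if not np.all(np.isfinite(a.xyz)):
                raise TopologyError(f"non-finite coordinates on atom {k}")

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this frame with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain,
                 coords[i].copy(), a.hetero)
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(atoms, None if self.box is None else self.box.copy())


@dataclass
class Ensemble:
    """Ordered frames over one topology; frame 0 defines the atom order."""

    topology: StructureModel
    coords: np.ndarray  # (frame, atom, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("ensemble coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise TopologyError(
                f"frame atom count {self.coords.shape[1]} does not match topology "
                f"({len(self.topology)} atoms)"
            )
        if self.frame_count < 1:
            raise TopologyError("ensemble needs at least one frame")

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])

    @classmethod
    def from_model(cls, model: StructureModel) -> "Ensemble":
        return cls(model, model.coords[None, :, :].copy())

    @classmethod
    def from_frames(cls, frames: list[StructureModel]) -> "Ensemble":
        if not frames:
            raise TopologyError("no frames")
        n = len(frames[0])
        for f in frames[1:]:
            if len(f) != n:
                raise TopologyError("frames differ in atom count")
        return cls(frames[0], np.stack([f.coords for f in frames]))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> None:
    """Check fixed-width coordinate fields of ATOM/HETATM records.

    Raises ParseError naming the first malformed line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record ({exc})") from exc


def read_structure(path: str | Path, format: str = "pdb") -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble, one frame per MODEL.

    Atom order is preserved from the file.  When several altlocs exist the
    highest-occupancy one is kept.  MODEL records with inconsistent atom sets
    raise :class:`TopologyError`; malformed ATOM/HETATM records raise
    :class:`ParseError` naming the line.
    """
    if format != "pdb":
        raise FormatError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises InvalidFileError on model mismatch
        raise TopologyError(f"inconsistent MODEL records in {path.name}: {exc}") from exc
    if isinstance(stack, bts.AtomArray):  # single model
        stack = bts.stack([stack])

    n = stack.array_length()
    atoms: list[Atom] = []
    first = stack.coord[0]
    for i in range(n):
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                resname=str(stack.res_name[i]),
                resid=int(stack.res_id[i]),
                chain=str(stack.chain_id[i]),
                xyz=first[i].astype(float).copy(),
                hetero=bool(stack.hetero[i]),
            )
        )
    topo = StructureModel(atoms)
    return Ensemble(topo, stack.coord.astype(float).copy())


def _to_atom_array(model: StructureModel) -> bts.AtomArray:
    n = len(model)
    arr = bts.AtomArray(n)
    for i, a in enumerate(model.atoms):
        if len(a.chain) != 1:
            raise FormatError(f"chain id {a.chain!r} not encodable in PDB (need 1 char)")
        if len(a.resname) > 4:
            raise FormatError(f"residue name {a.resname!r} too wide for PDB")
        if len(a.name) > 4:
            raise FormatError(f"atom name {a.name!r} too wide for PDB")
    arr.chain_id = np.array([a.chain for a in model.atoms])
    arr.res_id = np.array([a.resid for a in model.atoms])
    arr.res_name = np.array([a.resname for a in model.atoms])
    arr.atom_name = np.array([a.name for a in model.atoms])
    arr.element = np.array([a.element.upper() for a in model.atoms])
    arr.hetero = np.array([a.hetero for a in model.atoms])
    arr.coord = model.coords.astype(np.float32)
    return arr


def write_structure(ens: Ensemble | StructureModel, path: str | Path) -> None:
    """Write an Ensemble as a (multi-model) PDB file.

    Round-tripping through :func:`read_structure` reproduces all atom metadata
    and coordinates to PDB fixed-width precision (3 decimals).
    """
    if isinstance(ens, StructureModel):
        ens = Ensemble.from_model(ens)
    if len(ens.topology) == 0:
        raise FormatError("cannot write an empty ensemble")
    template = _to_atom_array(ens.topology)
    stack = bts.from_template(template, ens.coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# residue classification
# ---------------------------------------------------------------------------

def classify_residues(
    model: StructureModel, config: cfg.PipelineConfig | None = None
) -> dict[tuple[str, int], ResidueRole]:
    """Assign every residue one of {protein, guanine, loop_nucleotide, ion, other}.

    Classification is by residue name against the (configurable) synonym
    tables; unknown names map to ``other`` with a logged warning, never an
    error.  Total classified always equals the residue count.
    """
    config = config or cfg.DEFAULT_CONFIG
    roles: dict[tuple[str, int], ResidueRole] = {}
    for key, resname in model.resname_of().items():
        r = resname.strip().upper()
        if r in cfg.PROTEIN_RESNAMES:
            roles[key] = ResidueRole.PROTEIN
        elif r in config.guanine_resnames:
            roles[key] = ResidueRole.GUANINE
        elif r in config.loop_resnames:
            roles[key] = ResidueRole.LOOP_NUCLEOTIDE
        elif r in config.ion_resnames:
            roles[key] = ResidueRole.ION
        else:
            log.warning("unknown residue name %r at %s: classified as 'other'", resname, key)
            roles[key] = ResidueRole.OTHER
    return roles


def molecule_class(role: ResidueRole) -> str:
    """Coarse molecule class used for intermolecular bookkeeping."""
    if role == ResidueRole.PROTEIN:
        return "protein"
    if role in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE):
        return "nucleic"
    return "other"
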
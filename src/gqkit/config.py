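"""Pipeline configuration: residue nomenclature tables, hydrogen-bond donor/acceptor
tables and every distance/persistence threshold used by the analyses.

All thresholds live here (never hard-coded in the operators) so that a run log can
echo the exact criteria used.  The defaults follow common MD-analysis conventions:
heavy-atom contact cutoff 4.0 A, donor--acceptor H-bond cutoff 3.5 A, occupancy
shell 6.0 A, contact persistence 1% and a quartet instability cutoff of 15 H-bonds
out of the 24 of a three-layer stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# ---------------------------------------------------------------------------
# residue nomenclature (synonym tables, editable via config)
# ---------------------------------------------------------------------------

GUANINE_RESNAMES = frozenset({"DG", "G", "GUA"})
LOOP_NUCLEOTIDE_RESNAMES = frozenset(
    {"DT", "DA", "DC", "T", "U", "A", "C", "THY", "ADE", "URA", "CYT", "DU"}
)
ION_RESNAMES = frozenset({"K", "K+", "NA", "NA+"})
PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# ---------------------------------------------------------------------------
# hydrogen-bond donor / acceptor tables (heavy atoms)
# ---------------------------------------------------------------------------

# nucleobase donors/acceptors, keyed by base letter
NUCLEIC_BASE_DONORS = {
    "G": frozenset({"N1", "N2"}),
    "A": frozenset({"N6"}),
    "T": frozenset({"N3"}),
    "U": frozenset({"N3"}),
    "C": frozenset({"N4"}),
}
NUCLEIC_BASE_ACCEPTORS = {
    "G": frozenset({"O6", "N7", "N3"}),
    "A": frozenset({"N1", "N3", "N7"}),
    "T": frozenset({"O2", "O4"}),
    "U": frozenset({"O2", "O4"}),
    "C": frozenset({"O2", "N3"}),
}
# sugar-phosphate acceptors common to every nucleotide
NUCLEIC_BACKBONE_ACCEPTORS = frozenset({"OP1", "OP2", "O1P", "O2P", "O3'", "O5'", "O4'", "O2'"})

# protein: backbone amide N donates, carbonyl O accepts; sidechain tables below
PROTEIN_SIDECHAIN_DONORS = {
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
}
PROTEIN_SIDECHAIN_ACCEPTORS = {
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

# guanine atoms exposed in the grooves, used by the groove binding-mode rule.
# N7 faces the Hoogsteen edge and can be added via ``groove_include_n7``.
GROOVE_GUANINE_ATOMS = frozenset({"N2", "C2", "N3", "C4", "C8", "N9"})


def base_letter(resname: str) -> str | None:
    """Map a nucleotide residue name to its one-letter base code, or None."""
    r = resname.strip().upper()
    table = {
        "DG": "G", "G": "G", "GUA": "G",
        "DA": "A", "A": "A", "ADE": "A",
        "DT": "T", "T": "T", "THY": "T",
        "U": "U", "URA": "U", "DU": "U",
        "DC": "C", "C": "C", "CYT": "C",
    }
    return table.get(r)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the analysis pipeline, with defaults.

    Distances in Angstrom, lifetimes as fractions of the trajectory.
    """

    contact_cutoff: float = 4.0          # binding modes + contact maps
    occupancy_cutoff: float = 6.0        # occupancy-grid proximity shell
    occupancy_spacing: float = 1.0       # voxel edge length
    hbond_cutoff: float = 3.5            # donor--acceptor heavy-atom distance
    hbond_angle_max: float = 30.0        # H-donor-acceptor angle when H present
    min_lifetime: float = 0.01           # contact persistence filter
    instability_cutoff: int = 15         # mean quartet H-bonds at/below -> unstable
    first_residue_number: int = 197      # peptide numbering offset used in reports
    groove_include_n7: bool = False      # add N7 to the groove atom set
    end_stack_outer_only: bool = False   # restrict end-stacking rule to outer layers
    overhangs_are_loops: bool = True     # count 5'/3' overhang bases as loop residues
    count_atom_pairs: bool = False       # mode matrices: count atom pairs, not residues

    guanine_resnames: frozenset = GUANINE_RESNAMES
    loop_resnames: frozenset = LOOP_NUCLEOTIDE_RESNAMES
    ion_resnames: frozenset = ION_RESNAMES

    def groove_atoms(self) -> frozenset:
        if self.groove_include_n7:
            return GROOVE_GUANINE_ATOMS | {"N7"}
        return GROOVE_GUANINE_ATOMS

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("guanine_resnames", "loop_resnames", "ion_resnames"):
            d[k] = sorted(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("guanine_resnames", "loop_resnames", "ion_resnames"):
            if k in d:
                d[k] = frozenset(d[k])
        return cls(**d)


DEFAULT_CONFIG = PipelineConfig()
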
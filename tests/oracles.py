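"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's neighbor-list machinery: plain
all-pairs loops over the same donor/acceptor and nomenclature tables, so any
acceleration structure in the library is checked against exhaustive
enumeration.
"""

import numpy as np

from gqkit import config as cfg
from gqkit.structures import ResidueRole, classify_residues, molecule_class


def donor_acceptor_flags(frame):
    """Per-atom (is_donor, is_acceptor) from the residue-type tables."""
    roles = classify_residues(frame)
    donors, acceptors = set(), set()
    for i, a in enumerate(frame.atoms):
        if a.is_hydrogen():
            continue
        role = roles[(a.chain, a.resid)]
        if role == ResidueRole.PROTEIN:
            rn = a.resname.upper()
            if a.name == "N" or a.name in cfg.PROTEIN_SIDECHAIN_DONORS.get(rn, ()):
                donors.add(i)
            if a.name == "O" or a.name in cfg.PROTEIN_SIDECHAIN_ACCEPTORS.get(rn, ()):
                acceptors.add(i)
        elif role in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE):
            letter = cfg.base_letter(a.resname)
            if letter:
                if a.name in cfg.NUCLEIC_BASE_DONORS.get(letter, ()):
                    donors.add(i)
                if a.name in cfg.NUCLEIC_BASE_ACCEPTORS.get(letter, ()):
                    acceptors.add(i)
            if a.name in cfg.NUCLEIC_BACKBONE_ACCEPTORS:
                acceptors.add(i)
    return roles, donors, acceptors


def brute_force_hbonds(frame, max_dist=3.5):
    """Exhaustive O(n^2) donor-acceptor pairs (unordered, lower donor first
    when both directions qualify), as (donor, acceptor, distance, kind)."""
    roles, donors, acceptors = donor_acceptor_flags(frame)
    coords = frame.coords
    n = len(frame.atoms)
    found = {}
    for d in sorted(donors):
        for a in sorted(acceptors):
            if d == a:
                continue
            da, aa = frame.atoms[d], frame.atoms[a]
            if (da.chain, da.resid) == (aa.chain, aa.resid):
                continue
            dist = float(np.sqrt(((coords[d] - coords[a]) ** 2).sum()))
            if dist > max_dist:
                continue
            key = (min(d, a), max(d, a))
            if key in found and found[key][0] <= d:
                continue
            found[key] = (d, a, dist)
    out = []
    for d, a, dist in found.values():
        da, aa = frame.atoms[d], frame.atoms[a]
        d_role = roles[(da.chain, da.resid)]
        a_role = roles[(aa.chain, aa.resid)]
        if (
            d_role == ResidueRole.GUANINE
            and a_role == ResidueRole.GUANINE
            and da.name in ("N1", "N2")
            and aa.name in ("O6", "N7")
        ):
            kind = "hoogsteen_GG"
        elif {molecule_class(d_role), molecule_class(a_role)} == {"protein", "nucleic"}:
            kind = "intermolecular"
        else:
            kind = "other"
        out.append((d, a, round(dist, 9), kind))
    return sorted(out)


def brute_force_contact_counts(ens, cutoff=4.0):
    """Exhaustive residue x base contact-frame counts (heavy atoms)."""
    topo = ens.topology
    roles = classify_residues(topo)
    by_res = topo.atom_indices_by_residue()
    prot = [k for k, r in roles.items() if r == ResidueRole.PROTEIN]
    bases = [
        k for k, r in roles.items()
        if r in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE)
    ]
    counts = np.zeros((len(prot), len(bases)), dtype=int)
    for f in range(ens.frame_count):
        coords = ens.coords[f]
        for i, p in enumerate(prot):
            pi = [x for x in by_res[p] if not topo.atoms[x].is_hydrogen()]
            for j, b in enumerate(bases):
                bj = [x for x in by_res[b] if not topo.atoms[x].is_hydrogen()]
                hit = False
                for x in pi:
                    for y in bj:
                        if np.linalg.norm(coords[x] - coords[y]) <= cutoff:
                            hit = True
                            break
                    if hit:
                        break
                counts[i, j] += hit
    return prot, bases, counts
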
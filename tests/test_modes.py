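import numpy as np
import pytest

from gqkit import (
    Atom,
    Ensemble,
    PoseSpec,
    StructureModel,
    classify_residue_modes,
    detect_quartets,
    interaction_matrix,
    place_peptide,
)
from gqkit.errors import GQKitError


def _with_probe(gq3, name, resname, xyz, resid=500):
    atoms = list(gq3.atoms) + [Atom(0, "CA", "C", resname, resid, "P", np.asarray(xyz, float))]
    return StructureModel(atoms)


def _probe_near(gq3, atom_name, chain, offset):
    """GQ plus one ALA Calpha placed `offset` from a named GQ atom."""
    target = next(a.xyz for a in gq3.atoms if a.chain == chain and a.name == atom_name)
    return _with_probe(gq3, atom_name, "ALA", target + offset)


class TestClassifyResidueModes:
    def test_probe_near_o6_is_end_stacking(self, gq3, assign3):
        top = assign3.quartets[-1][0]
        o6 = next(a.xyz for a in gq3.atoms
                  if (a.chain, a.resid) == top and a.name == "O6")
        frame = _with_probe(gq3, "CA", "ALA", o6 + np.array([0, 0, 3.5]))
        flags = classify_residue_modes(frame, assign3)
        assert flags[("P", 500)].end_stack

    def test_probe_near_loop_atom_only_is_loop_binding(self, gq3, assign3):
        """Contact with any loop-nucleotide atom counts, irrespective of
        backbone, sugar or base; a probe near only a loop P has loop=True."""
        loop_p = next(a.xyz for a in gq3.atoms if a.resname == "DT" and a.name == "P")
        frame = _with_probe(gq3, "CA", "ALA", loop_p + np.array([0, 0, 3.9]))
        flags = classify_residue_modes(frame, assign3)
        f = flags[("P", 500)]
        assert f.loop and not f.end_stack and not f.groove

    def test_flags_not_exclusive(self, gq3, assign3):
        """One residue can explore several modes at once (modes overlap)."""
        # a probe wedged near a top-layer guanine touches O6 and groove atoms
        top = assign3.quartets[-1][0]
        c8 = next(a.xyz for a in gq3.atoms if (a.chain, a.resid) == top and a.name == "C8")
        o6 = next(a.xyz for a in gq3.atoms if (a.chain, a.resid) == top and a.name == "O6")
        mid = (c8 + o6) / 2 + np.array([0, 0, 2.5])
        frame = _with_probe(gq3, "CA", "ALA", mid)
        f = classify_residue_modes(frame, assign3)[("P", 500)]
        assert f.end_stack and f.groove

    def test_no_protein_is_error(self, gq3, assign3):
        with pytest.raises(GQKitError):
            classify_residue_modes(gq3, assign3)

    def test_empty_assignment_is_error(self, complex_groove):
        from gqkit.hbonds import QuartetAssignment

        with pytest.raises(GQKitError):
            classify_residue_modes(
                complex_groove, QuartetAssignment([], np.array([0, 0, 1.0]))
            )


class TestInteractionMatrix:
    def test_two_arg_normalization(self, gq3, assign3):
        """4 Arg-residue-frame contacts with one base over 2 Arg -> entry 2.0."""
        base = assign3.quartets[1][0]
        c8 = next(a.xyz for a in gq3.atoms if (a.chain, a.resid) == base and a.name == "C8")
        probe = c8 + np.array([2.5, 0, 0])
        faraway = np.array([80.0, 80.0, 80.0])
        atoms = list(gq3.atoms)
        atoms.append(Atom(0, "CA", "C", "ARG", 501, "P", probe.copy()))
        atoms.append(Atom(0, "CA", "C", "ARG", 502, "P", faraway.copy()))
        topo = StructureModel(atoms)
        # frames: res 501 contacts in frames 0+1, res 502 in frames 2+3
        coords = np.repeat(topo.coords[None], 4, axis=0)
        i501, i502 = len(atoms) - 2, len(atoms) - 1
        coords[2, i501], coords[2, i502] = faraway, probe
        coords[3, i501], coords[3, i502] = faraway, probe
        ens = Ensemble(topo, coords)
        mat = interaction_matrix(ens, assign3, "groove")
        label = next(c for c in mat.table.columns if c == f"{base[0]}.DG{base[1]}")
        assert mat.table.loc["R", label] == pytest.approx(2.0)

    def test_absent_type_row_omitted(self, complex_ensemble, assign3):
        assign = detect_quartets(complex_ensemble.frame(0))
        mat = interaction_matrix(complex_ensemble, assign, "groove")
        # peptide sequence has no Trp: no all-zero 0/0 row may appear
        assert "W" not in mat.table.index

    def test_far_pose_matrix_all_zero(self, gq3, peptide):
        c = place_peptide(gq3, peptide, PoseSpec(mode="far"), seed=2)
        assign = detect_quartets(c)
        ens = Ensemble.from_model(c)
        for mode in ("end_stack", "groove", "loop"):
            mat = interaction_matrix(ens, assign, mode)
            assert np.all(mat.table.values == 0)

    def test_cutoff_monotonicity(self, complex_ensemble):
        assign = detect_quartets(complex_ensemble.frame(0))
        lo = interaction_matrix(complex_ensemble, assign, "groove", cutoff=3.5)
        hi = interaction_matrix(complex_ensemble, assign, "groove", cutoff=4.5)
        assert np.all(hi.table.values >= lo.table.values - 1e-12)

    def test_invalid_mode_rejected(self, complex_ensemble, assign3):
        with pytest.raises(ValueError):
            interaction_matrix(complex_ensemble, assign3, "stacking")

    def test_matches_brute_force_oracle(self, complex_ensemble):
        """Every matrix entry equals exhaustive per-atom-pair enumeration."""
        from gqkit import config as cfg
        from gqkit.structures import ResidueRole, classify_residues

        assign = detect_quartets(complex_ensemble.frame(0))
        topo = complex_ensemble.topology
        roles = classify_residues(topo)
        by_res = topo.atom_indices_by_residue()
        resname = topo.resname_of()
        quartet_res = set(assign.layer_of)

        for mode in ("end_stack", "groove", "loop"):
            mat = interaction_matrix(complex_ensemble, assign, mode)
            for key, role in roles.items():
                if role not in (ResidueRole.GUANINE, ResidueRole.LOOP_NUCLEOTIDE):
                    continue
                label = f"{key[0]}.{resname[key]}{key[1]}"
                if mode == "end_stack":
                    tnames, ok = {"O6"}, role == ResidueRole.GUANINE and key in quartet_res
                elif mode == "groove":
                    tnames, ok = cfg.GROOVE_GUANINE_ATOMS, role == ResidueRole.GUANINE and key in quartet_res
                else:
                    tnames, ok = None, role == ResidueRole.LOOP_NUCLEOTIDE
                targets = [
                    i for i in by_res[key]
                    if (tnames is None or topo.atoms[i].name in tnames) and ok
                ]
                expected: dict[str, float] = {}
                comp: dict[str, int] = {}
                for pkey, prole in roles.items():
                    if prole != ResidueRole.PROTEIN:
                        continue
                    aa = cfg.AA3_TO_1[resname[pkey].upper()]
                    comp[aa] = comp.get(aa, 0) + 1
                for f in range(complex_ensemble.frame_count):
                    coords = complex_ensemble.coords[f]
                    for pkey, prole in roles.items():
                        if prole != ResidueRole.PROTEIN:
                            continue
                        hit = any(
                            np.linalg.norm(coords[x] - coords[y]) <= 4.0
                            for x in by_res[pkey]
                            for y in targets
                        )
                        if hit:
                            aa = cfg.AA3_TO_1[resname[pkey].upper()]
                            expected[aa] = expected.get(aa, 0) + 1
                for aa in mat.table.index:
                    want = expected.get(aa, 0) / comp[aa]
                    assert mat.table.loc[aa, label] == pytest.approx(want)
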
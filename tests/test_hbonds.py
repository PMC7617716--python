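import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gqkit import (
    Atom,
    Ensemble,
    HBondCriterion,
    StabilitySeries,
    StructureModel,
    classify_stability,
    detect_hbonds,
    detect_quartets,
    make_unfolding_trajectory,
    quartet_hbond_series,
    stability_scatter,
)
from gqkit.errors import GQKitError

from oracles import brute_force_hbonds


def _hoogsteen(bonds):
    return [b for b in bonds if b.kind == "hoogsteen_GG"]


class TestDetectHBonds:
    def test_ideal_quartet_reports_bond_at_2p9(self, gq1):
        bonds = _hoogsteen(detect_hbonds(gq1))
        n1_o6 = [b for b in bonds if b.donor_atom.name == "N1" and b.acceptor_atom.name == "O6"]
        assert len(n1_o6) == 4
        assert all(abs(b.distance - 2.9) < 0.1 for b in n1_o6)

    def test_stretched_bond_not_reported(self, gq1):
        # translate chain B along the A:N1 -> B:O6 direction to 3.8 A separation
        n1 = next(a.xyz for a in gq1.atoms if a.chain == "A" and a.name == "N1")
        o6 = next(a.xyz for a in gq1.atoms if a.chain == "B" and a.name == "O6")
        u = (o6 - n1) / np.linalg.norm(o6 - n1)
        shift = (3.8 - np.linalg.norm(o6 - n1)) * u
        model = gq1.with_coords(gq1.coords)
        for a in model.atoms:
            if a.chain == "B":
                a.xyz = a.xyz + shift
        bonds = _hoogsteen(detect_hbonds(model))
        assert not any(
            b.donor_atom.chain == "A" and b.donor_atom.name == "N1"
            and b.acceptor_atom.chain == "B" and b.acceptor_atom.name == "O6"
            for b in bonds
        )

    def test_protein_only_frame_is_empty(self, peptide):
        # a lone conformer: donors exist but every acceptor is > 3.5 A or same residue
        bonds = detect_hbonds(peptide)
        assert all(b.kind == "other" for b in bonds)

    def test_no_donors_gives_empty_list(self):
        m = StructureModel([Atom(1, "C1'", "C", "DG", 1, "A", np.zeros(3))])
        assert detect_hbonds(m) == []

    def test_angle_criterion_applies_when_hydrogens_present(self):
        """An H pointing away from the acceptor vetoes the bond; toward keeps it."""
        def frame(h_offset):
            return StructureModel([
                Atom(1, "N1", "N", "DG", 1, "A", np.zeros(3)),
                Atom(2, "H1", "H", "DG", 1, "A", np.array(h_offset)),
                Atom(3, "O6", "O", "DG", 2, "B", np.array([2.9, 0.0, 0.0])),
            ])
        toward = detect_hbonds(frame([1.0, 0.1, 0.0]))
        away = detect_hbonds(frame([-1.0, 0.1, 0.0]))
        assert len(toward) == 1
        assert len(away) == 0

    @pytest.mark.parametrize("fixture", ["gq1", "gq3", "complex_groove"])
    def test_matches_brute_force_oracle(self, fixture, request):
        """KD-tree accelerated detection equals exhaustive all-pairs enumeration."""
        frame = request.getfixturevalue(fixture)
        got = sorted(
            (b.donor, b.acceptor, round(b.distance, 9), b.kind)
            for b in detect_hbonds(frame)
        )
        assert got == brute_force_hbonds(frame)

    def test_oracle_equivalence_on_noisy_frames(self, complex_ensemble):
        for f in (0, complex_ensemble.frame_count - 1):
            frame = complex_ensemble.frame(f)
            got = sorted(
                (b.donor, b.acceptor, round(b.distance, 9), b.kind)
                for b in detect_hbonds(frame)
            )
            assert got == brute_force_hbonds(frame)


class TestDetectQuartets:
    def test_single_quartet_eight_bonds(self, gq1):
        assign = detect_quartets(gq1)
        assert assign.n_quartets == 1
        members = set(assign.quartets[0])
        incident = [
            b for b in _hoogsteen(detect_hbonds(gq1))
            if (b.donor_atom.chain, b.donor_atom.resid) in members
            and (b.acceptor_atom.chain, b.acceptor_atom.resid) in members
        ]
        assert len(incident) == 8

    def test_three_layer_stack(self, gq3, assign3):
        assert assign3.n_quartets == 3
        assert all(len(q) == 4 for q in assign3.quartets)
        # disjoint groups, layers ordered along the axis
        flat = [g for q in assign3.quartets for g in q]
        assert len(flat) == len(set(flat)) == 12

    def test_distant_guanines_give_empty_assignment(self):
        atoms = []
        k = 0
        for r in range(4):
            for name in ("N1", "N2", "O6", "N7", "N9"):
                k += 1
                atoms.append(
                    Atom(k, name, name[0], "DG", r + 1, "A",
                         np.array([20.0 * r, 0.1 * k, 0.0]))
                )
        assign = detect_quartets(StructureModel(atoms))
        assert assign.n_quartets == 0
        assert not assign

    def test_rigid_motion_invariance(self, gq3, assign3):
        rot = Rotation.from_euler("xyz", [31, -57, 12], degrees=True).as_matrix()
        moved = gq3.with_coords(gq3.coords @ rot.T + np.array([5.0, -3.0, 11.0]))
        assign = detect_quartets(moved)
        assert [set(q) for q in assign.quartets] in (
            [set(q) for q in assign3.quartets],
            [set(q) for q in assign3.quartets[::-1]],  # axis sign is free
        )

    def test_atom_permutation_invariance(self, gq3, assign3):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gq3))
        shuffled = StructureModel([gq3.atoms[i] for i in perm])
        assign = detect_quartets(shuffled)
        assert [set(q) for q in assign.quartets] in (
            [set(q) for q in assign3.quartets],
            [set(q) for q in assign3.quartets[::-1]],
        )


class TestStabilitySeries:
    def test_static_ideal_ensemble_counts_24_every_frame(self, gq3, assign3):
        ens = Ensemble(gq3, np.repeat(gq3.coords[None], 5, axis=0))
        series = quartet_hbond_series(ens, assign3)
        assert np.array_equal(series.per_frame_quartet_hbonds, np.full(5, 24))

    def test_single_frame_series(self, gq3, assign3):
        ens = Ensemble.from_model(gq3)
        series = quartet_hbond_series(ens, assign3)
        assert len(series.per_frame_quartet_hbonds) == 1
        assert series.mean_quartet == series.per_frame_quartet_hbonds[0]

    def test_unfolding_trend_non_increasing_after_smoothing(self, gq3, assign3):
        ens = make_unfolding_trajectory(gq3, 30, 0.5, 0.1, seed=12)
        series = quartet_hbond_series(ens, assign3)
        smoothed = np.convolve(series.per_frame_quartet_hbonds, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smoothed) <= 1e-9)

    def test_empty_assignment_is_error(self, gq3):
        from gqkit.hbonds import QuartetAssignment

        ens = Ensemble.from_model(gq3)
        with pytest.raises(GQKitError):
            quartet_hbond_series(ens, QuartetAssignment([], np.array([0, 0, 1.0])))

    def test_per_quartet_count_never_exceeds_eight(self, gq3, assign3):
        ens = make_unfolding_trajectory(gq3, 15, 0.0, 0.15, seed=2)
        series = quartet_hbond_series(ens, assign3)
        assert series.per_frame_quartet_hbonds.max() <= 8 * assign3.n_quartets


class TestClassifyStability:
    @pytest.mark.parametrize(
        "mean,expected", [(24.0, "stable"), (15.0, "unstable"), (15.2, "stable"), (14.9, "unstable")]
    )
    def test_cutoff_boundary_semantics(self, mean, expected):
        series = StabilitySeries(np.array([mean]), np.array([0]), 3)
        assert classify_stability(series, cutoff=15) == expected

    def test_monotone_in_cutoff(self):
        """Raising the cutoff never converts unstable -> stable."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            mean = rng.uniform(0, 24)
            series = StabilitySeries(np.array([mean]), np.array([0]), 3)
            lo, hi = sorted(rng.uniform(0, 24, size=2))
            if classify_stability(series, cutoff=lo) == "unstable":
                assert classify_stability(series, cutoff=hi) == "unstable"


class TestStabilityScatter:
    def test_planted_unstable_row(self):
        stable = StabilitySeries(np.array([24, 24]), np.array([1, 2]), 3, "stable")
        unstable = StabilitySeries(np.array([12, 14]), np.array([0, 0]), 3, "unstable")
        table = stability_scatter([stable, stable, stable, unstable])
        assert len(table) == 4
        assert (table["label"] == "unstable").sum() == 1

    def test_apo_complex_has_zero_intermolecular(self, gq3, assign3):
        ens = Ensemble.from_model(gq3)
        series = quartet_hbond_series(ens, assign3)
        table = stability_scatter([series], ids=["apo"])
        assert table.loc[0, "mean_intermolecular"] == 0.0

    def test_serializes_to_tsv(self, tmp_path):
        s = StabilitySeries(np.array([24]), np.array([0]), 3, "stable")
        table = stability_scatter([s, s])
        path = tmp_path / "scatter.tsv"
        table.to_csv(path, sep="\t", index=False)
        assert path.read_text().startswith("complex\t")
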
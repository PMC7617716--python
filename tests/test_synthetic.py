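import numpy as np
import pytest

from gqkit import (
    GQSpec,
    PoseSpec,
    build_gq,
    classify_residue_modes,
    detect_quartets,
    make_peptide_conformers,
    make_unfolding_trajectory,
    place_peptide,
    quartet_hbond_series,
)
from gqkit.errors import PlacementError


class TestBuildGQ:
    def test_tetramolecular_three_quartets(self, gq3):
        guanines = {(a.chain, a.resid) for a in gq3.atoms if a.resname == "DG"}
        assert len(guanines) == 12
        ions = [a for a in gq3.atoms if a.resname == "K"]
        assert len(ions) == 2

    def test_single_quartet_has_no_ions(self, gq1):
        assert not any(a.resname == "K" for a in gq1.atoms)

    def test_detector_recovers_planted_layer_count(self, gq3):
        assert detect_quartets(gq3).n_quartets == 3

    def test_hoogsteen_distance_within_spec(self, gq1):
        """Planted N1...O6 distances stay within 0.05 A of the 2.9 A target."""
        by = {}
        for a in gq1.atoms:
            if a.resname == "DG":
                by.setdefault(a.chain, {})[a.name] = a.xyz
        chains = sorted(by)
        dists = []
        for g in by.values():
            dists.append(min(
                np.linalg.norm(g["N1"] - other["O6"])
                for c, other in by.items() if other is not g
            ))
        assert all(abs(d - 2.9) <= 0.05 for d in dists)

    def test_rna_variant_builds_and_detects(self):
        gq = build_gq(GQSpec(nucleic_kind="RNA"), seed=0)
        assert detect_quartets(gq).n_quartets == 3
        assert any(a.resname == "U" for a in gq.atoms)

    def test_molecularity_variants(self):
        for n_strands in (1, 2, 4):
            gq = build_gq(GQSpec(n_strands=n_strands), seed=0)
            chains = {a.chain for a in gq.atoms if a.resname == "DG"}
            assert len(chains) == n_strands
            assert detect_quartets(gq).n_quartets == 3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GQSpec(n_quartets=0)
        with pytest.raises(ValueError):
            GQSpec(n_strands=3)


class TestPeptideConformers:
    def test_frame_count_and_determinism(self):
        a = make_peptide_conformers(n=4, seed=7)
        b = make_peptide_conformers(n=4, seed=7)
        assert a.frame_count == 4
        assert np.array_equal(a.coords, b.coords)

    def test_single_conformer(self):
        assert make_peptide_conformers(n=1, seed=0).frame_count == 1

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            make_peptide_conformers(n=0)
        with pytest.raises(ValueError):
            make_peptide_conformers(sequence="")

    def test_self_avoidance(self):
        ens = make_peptide_conformers(n=3, seed=2, backbone="trace")
        for f in range(ens.frame_count):
            frame = ens.frame(f)
            ca = np.array([a.xyz for a in frame.atoms if a.name == "CA"])
            d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            for i in range(len(ca) - 1):
                d[i, i + 1] = d[i + 1, i] = np.inf
            assert d.min() >= 4.0 - 1e-9


class TestPlacePeptide:
    @pytest.mark.parametrize("mode", ["end_stack", "groove", "loop"])
    def test_planted_mode_flag_raised(self, gq3, peptide, mode):
        c = place_peptide(gq3, peptide, PoseSpec(mode=mode, peptide_residue_index=26), seed=1)
        flags = classify_residue_modes(c, detect_quartets(c))
        assert getattr(flags[("P", 27)], mode)

    def test_far_pose_has_no_flags(self, gq3, peptide):
        c = place_peptide(gq3, peptide, PoseSpec(mode="far"), seed=1)
        flags = classify_residue_modes(c, detect_quartets(c))
        assert not any(f.any() for f in flags.values())

    def test_no_steric_clash(self, complex_groove):
        gq_xyz = np.array([a.xyz for a in complex_groove.atoms if a.chain != "P"])
        pep_xyz = np.array([a.xyz for a in complex_groove.atoms if a.chain == "P"])
        d = np.linalg.norm(gq_xyz[:, None] - pep_xyz[None, :], axis=-1)
        assert d.min() >= 2.0

    def test_impossible_anchor_distance_raises(self, gq3, peptide):
        with pytest.raises(PlacementError):
            place_peptide(gq3, peptide, PoseSpec(mode="groove", target_distance=0.5), seed=1)


class TestUnfoldingTrajectory:
    def test_low_noise_preserves_quartet_bonds(self, gq3, assign3):
        """0.1 A noise cannot break 2.9 A bonds against a 3.5 A cutoff."""
        ens = make_unfolding_trajectory(gq3, 20, 0.0, 0.1, seed=3)
        series = quartet_hbond_series(ens, assign3)
        assert series.mean_quartet >= 22

    def test_progressive_displacement_destabilizes(self, gq3, assign3):
        """14.5 A of strand displacement severs the strand's Hoogsteen bonds."""
        ens = make_unfolding_trajectory(gq3, 30, 0.5, 0.1, seed=3)
        series = quartet_hbond_series(ens, assign3)
        assert series.mean_quartet <= 15
        assert series.label == "unstable"

    def test_determinism(self, gq3):
        a = make_unfolding_trajectory(gq3, 5, 0.2, 0.1, seed=8)
        b = make_unfolding_trajectory(gq3, 5, 0.2, 0.1, seed=8)
        assert np.array_equal(a.coords, b.coords)

    def test_bad_arguments(self, gq3):
        with pytest.raises(ValueError):
            make_unfolding_trajectory(gq3, 1)
        with pytest.raises(ValueError):
            make_unfolding_trajectory(gq3, 5, strand_chain="Q")
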
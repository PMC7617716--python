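import numpy as np
import pytest

from gqkit import (
    GQSpec,
    PoseSpec,
    build_gq,
    detect_quartets,
    make_peptide_conformers,
    make_unfolding_trajectory,
    place_peptide,
)


@pytest.fixture(scope="session")
def gq1():
    """Idealized single-quartet tetramolecular DNA stem."""
    return build_gq(GQSpec(n_quartets=1), seed=0)


@pytest.fixture(scope="session")
def gq3():
    """Idealized three-quartet tetramolecular DNA G-quadruplex with overhangs."""
    return build_gq(GQSpec(n_quartets=3), seed=0)


@pytest.fixture(scope="session")
def assign3(gq3):
    return detect_quartets(gq3)


@pytest.fixture(scope="session")
def peptide():
    """One disordered 53-mer conformer with pseudo backbone + CB centroids."""
    return make_peptide_conformers(n=1, seed=11).frame(0)


@pytest.fixture(scope="session")
def complex_groove(gq3, peptide):
    return place_peptide(gq3, peptide, PoseSpec(mode="groove", peptide_residue_index=26), seed=4)


@pytest.fixture(scope="session")
def complex_ensemble(complex_groove):
    """Short stable pseudo-trajectory of a groove-bound complex."""
    return make_unfolding_trajectory(complex_groove, n_frames=8, noise_sigma=0.08, seed=9)


@pytest.fixture(scope="session")
def peptide_trace_complex(gq3):
    """Trajectory of a complex whose peptide is a Calpha/CB trace (all intra-
    peptide atom pairs exceed the 1 A voxel diagonal)."""
    trace = make_peptide_conformers(n=1, seed=13, backbone="trace").frame(0)
    c = place_peptide(gq3, trace, PoseSpec(mode="groove", peptide_residue_index=26), seed=6)
    return make_unfolding_trajectory(c, n_frames=6, noise_sigma=0.05, seed=14)
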
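import numpy as np
import pytest
from scipy.spatial import cKDTree

from crowdsim.initialization import (
    InitializationError,
    corrected_concentration,
    corrected_volume_nm3,
    hcp_initialize,
    hcp_sites,
    particle_counts,
)
from crowdsim.params import INERT, MONOMER, ParameterSet


class TestParticleCounts:
    def test_ten_percent_cube_holds_191_monomers(self):
        p = ParameterSet(c_r=0.1, box_nm=(50, 50, 50))
        assert particle_counts(p) == (191, 0)

    def test_empty_box(self):
        p = ParameterSet(c_r=0.0, c_i=0.0)
        assert particle_counts(p) == (0, 0)

    def test_thin_box_at_045_holds_88_monomers(self):
        p = ParameterSet(c_r=0.45, box_nm=(50, 50, 5.125))
        assert particle_counts(p) == (88, 0)

    def test_inert_counts_scale_with_beta(self):
        p = ParameterSet(c_r=0.0, c_i=0.2, beta=2.0, box_nm=(50, 50, 50))
        n_mono, n_inert = particle_counts(p)
        assert n_mono == 0
        assert n_inert == round(0.2 * 125000 / (2 * p.v_mono_nm3))


class TestCorrectedConcentration:
    def test_corrected_volume_adds_one_monomer_diameter_per_axis(self):
        p = ParameterSet(box_nm=(50, 50, 5.125))
        assert corrected_volume_nm3(p) == pytest.approx(55 * 55 * 10.125, rel=1e-12)

    def test_thin_box_endpoints(self):
        # nominal 0.45 -> ~0.188 and nominal 0.1 -> ~0.043
        p45 = ParameterSet(c_r=0.45, box_nm=(50, 50, 5.125))
        assert round(corrected_concentration(p45), 3) == 0.188
        p10 = ParameterSet(c_r=0.1, box_nm=(50, 50, 5.125))
        assert round(corrected_concentration(p10), 3) == 0.043

    def test_zero_particles_give_zero(self):
        p = ParameterSet(c_r=0.0, c_i=0.0)
        assert corrected_concentration(p) == 0.0


class TestHcpSites:
    def test_minimum_spacing_is_one_site_diameter(self):
        sites = hcp_sites((50.0, 50.0, 50.0), 2.5625)
        tree = cKDTree(sites)
        d, _ = tree.query(sites, k=2)
        assert d[:, 1].min() >= 2 * 2.5625 - 1e-9

    def test_thin_box_has_a_single_layer_on_the_short_axis(self):
        sites = hcp_sites((50.0, 50.0, 5.125), 2.5625)
        assert len(np.unique(sites[:, 2])) == 1
        assert sites[:, 2][0] == pytest.approx(2.5625)


class TestHcpInitialize:
    def test_dense_cube_places_859_without_interaction(self):
        p = ParameterSet(c_r=0.45, box_nm=(50, 50, 50), seed=1)
        init = hcp_initialize(p)
        assert len(init.positions) == 859
        tree = cKDTree(init.positions)
        d, _ = tree.query(init.positions, k=2)
        # pairwise separation >= r_i + r_j + d_th at t=0
        assert d[:, 1].min() >= 2 * 2.5 + 0.125 - 1e-9

    def test_lattice_radius_follows_dominant_species(self):
        p = ParameterSet(c_r=0.1, c_i=0.35, beta=1.0, box_nm=(50, 50, 50))
        init = hcp_initialize(p)
        assert init.site_radius == pytest.approx(2.5 + 0.0625)
        assert (init.species == MONOMER).sum() == 191
        assert (init.species == INERT).sum() == 668

    def test_random_assignment_depends_on_rng(self):
        p = ParameterSet(c_r=0.1, c_i=0.1, box_nm=(40, 40, 40))
        a = hcp_initialize(p, rng=np.random.default_rng(1))
        b = hcp_initialize(p, rng=np.random.default_rng(2))
        assert not np.array_equal(a.positions, b.positions)
        c = hcp_initialize(p, rng=np.random.default_rng(1))
        assert np.array_equal(a.positions, c.positions)

    def test_species_assignment_is_exchangeable(self):
        # species labels should be uncorrelated with position: the mean
        # monomer position matches the mean inert position within noise
        p = ParameterSet(c_r=0.15, c_i=0.15, box_nm=(50, 50, 50))
        diffs = []
        for seed in range(30):
            init = hcp_initialize(p, rng=np.random.default_rng(seed))
            mono = init.positions[init.species == MONOMER].mean(axis=0)
            inert = init.positions[init.species == INERT].mean(axis=0)
            diffs.append(mono - inert)
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.5  # nm

    def test_overfull_box_raises_with_feasibility_hint(self):
        p = ParameterSet(c_r=0.6, box_nm=(50, 50, 50))
        with pytest.raises(InitializationError, match="feasible"):
            hcp_initialize(p)
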
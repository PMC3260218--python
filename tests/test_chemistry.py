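import math

import numpy as np
import pytest

from crowdsim.chemistry import (
    BOUND,
    DISSOCIATED,
    NO_CONTACT,
    PLACEMENT_FAILED,
    REJECTED_BY_B,
    ParticleSystem,
    attempt_binding,
    dissociate,
    sample_dissociation_time,
)
from crowdsim.params import DIMER, MONOMER, ParameterSet


def pair_system(b=0.7, gap=0.05, box=(100.0, 100.0, 100.0), **kw):
    sys = ParticleSystem(ParameterSet(box_nm=box, b=b, **kw), capacity=32)
    c = np.asarray(box) / 2
    a = sys.add(MONOMER, c - [2.5 + gap / 2, 0, 0])
    bb = sys.add(MONOMER, c + [2.5 + gap / 2, 0, 0])
    return sys, a, bb


class TestAttemptBinding:
    def test_beyond_threshold_is_no_contact(self):
        sys, a, b = pair_system(b=1.0, gap=0.2)  # gap > d_th = 0.125
        assert attempt_binding(sys, a, b, 0.0, rng_seed=1).kind == NO_CONTACT

    def test_certain_binding_within_threshold(self):
        sys, a, b = pair_system(b=1.0, gap=0.05)
        out = attempt_binding(sys, a, b, 0.0, rng_seed=1)
        assert out.kind == BOUND
        assert sorted(out.removed) == sorted([a, b])
        (new,) = out.created
        assert sys.sp[new] == DIMER
        assert sys.alive.sum() == 1

    def test_impossible_binding_never_bound(self):
        for seed in range(20):
            sys, a, b = pair_system(b=0.0, gap=0.05)
            out = attempt_binding(sys, a, b, 0.0, rng_seed=seed)
            assert out.kind in (REJECTED_BY_B, NO_CONTACT)
            assert out.kind == REJECTED_BY_B

    def test_rejected_pair_ends_outside_interaction_range(self):
        sys, a, b = pair_system(b=0.0, gap=0.05)
        attempt_binding(sys, a, b, 0.0, rng_seed=3)
        d = np.linalg.norm(sys.pos[a] - sys.pos[b])
        assert d >= 5.125 - 1e-9

    def test_empirical_binding_probability_matches_b(self):
        b_prob, n, hits = 0.3, 1500, 0
        for seed in range(n):
            sys, a, bb = pair_system(b=b_prob, gap=0.05)
            if attempt_binding(sys, a, bb, 0.0, rng_seed=seed).kind == BOUND:
                hits += 1
        se = math.sqrt(b_prob * (1 - b_prob) / n)
        assert hits / n == pytest.approx(b_prob, abs=3.5 * se)

    def test_dimer_conserves_monomer_equivalents_and_com(self):
        sys, a, b = pair_system(b=1.0, gap=0.05)
        com = (sys.pos[a] + sys.pos[b]) / 2
        out = attempt_binding(sys, a, b, 0.0, rng_seed=1)
        np.testing.assert_allclose(sys.pos[out.created[0]], com, atol=1e-12)


class TestDissociationTime:
    def test_mean_matches_m(self, rng):
        draws = np.array([sample_dissociation_time(1.0, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.01)

    def test_survival_beyond_median_is_half(self, rng):
        draws = np.array([sample_dissociation_time(2.0, rng) for _ in range(50_000)])
        assert (draws > 2.0 * math.log(2)).mean() == pytest.approx(0.5, abs=0.01)

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_dissociation_time(0.0, rng)


class TestDissociate:
    def make_dimer(self, box=(100.0, 100.0, 100.0)):
        sys = ParticleSystem(ParameterSet(box_nm=box), capacity=64)
        d = sys.add(DIMER, np.asarray(box) / 2)
        return sys, d

    def test_isolated_dimer_splits_at_exact_separation(self):
        sys, d = self.make_dimer()
        centre = sys.pos[d].copy()
        out = dissociate(sys, d, 1.0, rng_seed=2)
        assert out.kind == DISSOCIATED
        m1, m2 = out.created
        sep = np.linalg.norm(sys.pos[m1] - sys.pos[m2])
        assert sep == pytest.approx(2 * 2.5 + 0.125, rel=1e-12)
        np.testing.assert_allclose((sys.pos[m1] + sys.pos[m2]) / 2, centre, atol=1e-9)

    def test_axes_are_isotropic(self):
        axes = []
        for seed in range(600):
            sys, d = self.make_dimer()
            out = dissociate(sys, d, 1.0, rng_seed=seed)
            m1, m2 = out.created
            u = sys.pos[m1] - sys.pos[m2]
            axes.append(u / np.linalg.norm(u))
        axes = np.asarray(axes)
        # random sign per axis: the resultant of n uniform unit vectors has
        # length ~ sqrt(n); 4*sqrt(n) bounds it at ~3.5 sigma per component
        assert np.linalg.norm(axes.sum(0)) < 4 * math.sqrt(len(axes))

    def test_wedged_dimer_fails_and_persists(self):
        sys, d = self.make_dimer()
        # cage the dimer with a tight shell of inert-sized monomers
        centre = sys.pos[d].copy()
        golden = np.pi * (3 - np.sqrt(5))
        for k in range(40):
            z = 1 - 2 * (k + 0.5) / 40
            r = np.sqrt(1 - z * z)
            th = golden * k
            sys.add(MONOMER, centre + 6.0 * np.array([r * np.cos(th), r * np.sin(th), z]))
        out = dissociate(sys, d, 1.0, rng_seed=4)
        assert out.kind == PLACEMENT_FAILED
        assert sys.alive[d]
        assert sys.sp[d] == DIMER
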
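import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdsim.engine import Trajectory
from crowdsim.observables import (
    NotEquilibratedError,
    equilibration_time,
    estimate_keq,
    idealized_dimer_count,
    mean_progress_curve,
    quasi_equilibrium_summary,
)
from crowdsim.params import ParameterSet


class TestEstimateKeq:
    def test_no_dimers_gives_zero(self):
        assert estimate_keq(0, 20, 1e-22) == 0.0

    def test_hand_computed_example(self):
        # [D]=5/V, [M]=10/V -> K = 0.05 V
        assert estimate_keq(5, 20, 1.25e-22) == pytest.approx(6.25e-24, rel=1e-12)

    def test_all_monomers_consumed_is_infinite(self):
        assert math.isinf(estimate_keq(10, 20, 1e-22))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_keq(11, 20, 1e-22)


class TestIdealizedDimerCount:
    def test_limits(self):
        assert idealized_dimer_count(0.0, 100, 1e-21) == 0.0
        assert idealized_dimer_count(math.inf, 100, 1e-21) == 50.0

    def test_inverse_of_keq_example(self):
        assert idealized_dimer_count(6.25e-24, 20, 1.25e-22) == pytest.approx(5.0, rel=1e-10)

    @settings(deadline=None, max_examples=200)
    @given(
        n_d=st.integers(0, 49),
        n0=st.just(100),
        v=st.floats(1e-24, 1e-19),
    )
    def test_roundtrip_with_estimate_keq(self, n_d, n0, v):
        k = estimate_keq(n_d, n0, v)
        assert idealized_dimer_count(k, n0, v) == pytest.approx(n_d, rel=1e-10, abs=1e-10)


def make_run(times, dimers, n0=40, params=None):
    params = params or ParameterSet(duration_us=float(times[-1]))
    data = pd.DataFrame(
        {"time_us": times, "n_dimer": dimers, "n_monomer": n0 - 2 * np.asarray(dimers)}
    )
    return Trajectory(data=data, params=params, seed=0, n_monomer0=n0, n_inert=0)


class TestQuasiEquilibriumSummary:
    def test_constant_series(self):
        t = np.linspace(0, 25, 161)
        run = make_run(t, np.full(161, 7))
        est = quasi_equilibrium_summary([run])
        assert est.mean_dimers == 7.0
        assert est.std_dimers == 0.0
        assert est.sample_times_us == (5.0, 10.0, 15.0, 20.0, 25.0)
        assert est.k_eq_m3 == pytest.approx(estimate_keq(7, 40, run.params.volume_m3))

    def test_permutation_invariance(self, rng):
        t = np.linspace(0, 25, 161)
        runs = [make_run(t, rng.integers(0, 15, size=161)) for _ in range(6)]
        a = quasi_equilibrium_summary(runs)
        b = quasi_equilibrium_summary(runs[::-1])
        assert a.k_eq_m3 == b.k_eq_m3
        assert a.mean_dimers == b.mean_dimers

    def test_short_run_rejected(self):
        t = np.linspace(0, 10, 65)
        run = make_run(t, np.zeros(65))
        with pytest.raises(ValueError, match="requires"):
            quasi_equilibrium_summary([run], sample_times_us=[5, 10, 15, 20, 25])


class TestEquilibrationTime:
    def test_constant_curve_is_equilibrated_at_zero(self):
        t = np.linspace(0, 25, 161)
        assert equilibration_time(t, np.full(161, 5.0)) == 0.0

    def test_saturating_curve_matches_analytic_crossing(self):
        # x(t) = x_inf (1 - exp(-t/tau)); with tau << window start the
        # late mean is ~x_inf and the band entry solves exp(-t/tau)=band
        tau, x_inf, band = 0.5, 30.0, 0.05
        t = np.linspace(0, 25, 1601)
        x = x_inf * (1 - np.exp(-t / tau))
        target = x_inf * (1 - (tau / 20.0) * (math.exp(-5 / tau) - math.exp(-25 / tau)))
        t_analytic = -tau * math.log(band * target / x_inf + (1 - target / x_inf))
        measured = equilibration_time(t, x, band=band)
        assert measured == pytest.approx(t_analytic, abs=t[1] - t[0] + 1e-12)

    def test_never_settling_curve_raises(self):
        t = np.linspace(0, 25, 161)
        x = np.where(np.arange(161) % 2 == 0, 0.0, 50.0)
        with pytest.raises(NotEquilibratedError):
            equilibration_time(t, x)


def test_mean_progress_curve_averages_runs():
    t = np.linspace(0, 1, 5)
    runs = [make_run(t, np.full(5, v), params=ParameterSet(duration_us=1.0)) for v in (2, 4)]
    curve = mean_progress_curve(runs)
    assert (curve.n_dimer_mean == 3.0).all()
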
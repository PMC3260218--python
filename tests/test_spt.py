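import math

import numpy as np
import pytest

from crowdsim.params import ParameterSet
from crowdsim.spt import (
    SPTComposition,
    SPTDomainError,
    gamma_exc_and_apparent_keq,
    quasi_equilibrium_composition,
    spt_log_activity,
    spt_table,
)

V_MONO = 4 / 3 * math.pi * 2.5**3


def one_component(phi, radius=2.5):
    rho = phi / (4 / 3 * math.pi * radius**3)
    return SPTComposition(rho=(rho,), radius=(radius,))


class TestLogActivity:
    def test_vacuum_is_ideal(self):
        comp = SPTComposition(rho=(0.0, 0.0), radius=(2.5, 3.15))
        assert spt_log_activity(2.5, comp) == 0.0

    def test_dilute_one_component_second_virial(self):
        # ln gamma -> 8 phi as phi -> 0 for equal spheres
        phi = 1e-4
        assert spt_log_activity(2.5, one_component(phi)) == pytest.approx(
            8 * phi, rel=0.01
        )

    def test_dilute_mixture_matches_pairwise_excluded_volume(self):
        radii = (2.5, 3.1498)
        rho = (1e-7, 5e-8)  # nm^-3, deeply dilute
        comp = SPTComposition(rho=rho, radius=radii)
        for r_ins in (2.5, 3.1498, 4.0):
            expected = sum(
                rj * 4 / 3 * math.pi * (r_ins + Rj) ** 3
                for rj, Rj in zip(rho, radii)
            )
            assert spt_log_activity(r_ins, comp) == pytest.approx(expected, rel=1e-3)

    def test_dense_phase_rejected(self):
        with pytest.raises(SPTDomainError):
            spt_log_activity(2.5, one_component(1.01))


class TestGammaExc:
    def test_vacuum_gives_unity_correction(self):
        comp = SPTComposition(rho=(0.0, 0.0, 0.0), radius=(2.5, 3.1498, 2.5))
        cf = gamma_exc_and_apparent_keq(comp, 2.5, 3.1498, k0_m3=2e-25)
        assert cf.gamma_exc == 1.0
        assert cf.k_app_m3 == 2e-25

    def test_dilute_reference_composition_gives_small_correction(self):
        # 1% pure-reactant equilibrium mixture: the correction is a few
        # percent, concretely ~1.04 at the measured ideal-state constant
        p = ParameterSet(c_r=0.01, box_nm=(100, 100, 100))
        comp = quasi_equilibrium_composition(p, 9.39e-25)
        cf = gamma_exc_and_apparent_keq(comp, p.r_mono_nm, p.r_dimer_nm)
        assert round(cf.gamma_exc, 2) == 1.04

    def test_correction_insensitive_to_k0_uncertainty(self):
        p = ParameterSet(c_r=0.01, box_nm=(100, 100, 100))
        lo = gamma_exc_and_apparent_keq(
            quasi_equilibrium_composition(p, 0.5 * 9.39e-25), 2.5, p.r_dimer_nm
        ).gamma_exc
        hi = gamma_exc_and_apparent_keq(
            quasi_equilibrium_composition(p, 2.0 * 9.39e-25), 2.5, p.r_dimer_nm
        ).gamma_exc
        assert lo == pytest.approx(hi, rel=0.005)

    def test_monotone_in_total_volume_fraction(self):
        p = ParameterSet()
        k0 = 9.39e-25
        gammas = []
        for c_i in np.arange(0.0, 0.36, 0.05):
            comp = quasi_equilibrium_composition(p.with_(c_r=0.1, c_i=float(c_i)), k0)
            gammas.append(
                gamma_exc_and_apparent_keq(comp, 2.5, p.r_dimer_nm).gamma_exc
            )
        assert all(b > a for a, b in zip(gammas, gammas[1:]))

    def test_inert_crowders_exert_stronger_correction_than_reactants(self):
        # crowders cannot reduce their excluded volume by dimerizing, so
        # 0.1 reactant + 0.35 inert beats 0.45 pure reactant
        p = ParameterSet()
        k0 = 9.39e-25
        mixed = gamma_exc_and_apparent_keq(
            quasi_equilibrium_composition(p.with_(c_r=0.1, c_i=0.35), k0),
            2.5, p.r_dimer_nm,
        ).gamma_exc
        pure = gamma_exc_and_apparent_keq(
            quasi_equilibrium_composition(p.with_(c_r=0.45, c_i=0.0), k0),
            2.5, p.r_dimer_nm,
        ).gamma_exc
        assert mixed > pure


def test_spt_table_columns_and_growth():
    p = ParameterSet()
    table = spt_table(p, 9.39e-25, [(0.1, 0.0), (0.1, 0.2), (0.1, 0.35)])
    assert list(table.columns) == [
        "c_r", "c_i", "phi", "gamma_m", "gamma_d", "gamma_exc", "k_app_m3",
    ]
    assert table.gamma_exc.is_monotonic_increasing
    assert (table.k_app_m3 > 9.39e-25).all()
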
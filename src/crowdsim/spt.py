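"""Scaled particle theory for hard-sphere mixtures.

SPT gives the reversible work of inserting a hard sphere of radius
``r`` into a mixture of hard spheres, hence the activity coefficient
``ln gamma = beta * mu_excess``.  With the scaled-particle moments

    xi_k = (pi/6) * sum_j rho_j (2 R_j)^k ,   k = 0..3

(``xi_3`` is the total volume fraction phi), the excess chemical
potential of the inserted sphere is the standard SPT polynomial in r
(third order, with the ideal-gas ``-ln(1 - phi)`` term).

For the homodimerization ``M + M <-> D`` the excluded-volume correction
factor is ``Gamma_exc = gamma_M^2 / gamma_D`` and the apparent
equilibrium constant ``K_app = Gamma_exc * K°``, where ``K°`` is the
ideal-state constant measured from dilute (1%) pure-reactant
simulations.  Because a dimer excludes less volume than two monomers
(alpha < 2 strictly so for alpha=2 by surface area), crowding favours
the dimer and ``Gamma_exc`` grows with total occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_replicates
from .initialization import particle_counts
from .observables import idealized_dimer_count, quasi_equilibrium_summary
from .params import ParameterSet


class SPTDomainError(ValueError):
    """Total volume fraction at or above 1: SPT undefined."""


@dataclass(frozen=True)
class SPTComposition:
    """Number densities (nm^-3) and radii (nm) of a hard-sphere mixture."""

    rho: tuple  # nm^-3 per species
    radius: tuple  # nm per species

    def xi(self, k: int) -> float:
        return math.pi / 6.0 * sum(
            r_ * (2.0 * R) ** k for r_, R in zip(self.rho, self.radius)
        )

    @property
    def phi(self) -> float:
        return self.xi(3)


@dataclass
class CorrectionFactor:
    gamma_m: float
    gamma_d: float
    gamma_exc: float
    k0_m3: float | None = None
    k_app_m3: float | None = None


def spt_log_activity(r_insert: float, comp: SPTComposition) -> float:
    """``ln gamma`` for inserting a hard sphere of radius ``r_insert``.

    Reduces to the hard-sphere second virial ``8 phi`` in the dilute
    one-component limit and to the pairwise excluded-volume sum
    ``sum_j rho_j (4 pi/3)(r + R_j)^3`` at first order in density.
    """
    xi0, xi1, xi2, xi3 = (comp.xi(k) for k in range(4))
    if xi3 >= 1.0:
        raise SPTDomainError(f"total volume fraction {xi3:.3f} >= 1")
    om = 1.0 - xi3
    r = r_insert
    return (
        -math.log(om)
        + (6.0 * xi2 / om) * r
        + (12.0 * xi1 / om + 18.0 * xi2**2 / om**2) * r**2
        + (8.0 * xi0 / om + 24.0 * xi1 * xi2 / om**2 + 24.0 * xi2**3 / om**3) * r**3
    )


def gamma_exc_and_apparent_keq(
    comp: SPTComposition,
    r_mono_nm: float,
    r_dimer_nm: float,
    k0_m3: float | None = None,
) -> CorrectionFactor:
    """Activity coefficients, ``Gamma_exc = gamma_M^2/gamma_D`` and, if a
    ``K°`` is given, the apparent ``K_app = Gamma_exc * K°``."""
    ln_m = spt_log_activity(r_mono_nm, comp)
    ln_d = spt_log_activity(r_dimer_nm, comp)
    gamma_exc = math.exp(2.0 * ln_m - ln_d)
    return CorrectionFactor(
        gamma_m=math.exp(ln_m),
        gamma_d=math.exp(ln_d),
        gamma_exc=gamma_exc,
        k0_m3=k0_m3,
        k_app_m3=None if k0_m3 is None else gamma_exc * k0_m3,
    )


def quasi_equilibrium_composition(params: ParameterSet, k0_m3: float) -> SPTComposition:
    """Monomer/dimer/inert composition of a condition at mass-action
    equilibrium: the monomer/dimer split solves the idealized quadratic
    with the given ``K°``; inert crowders enter unchanged."""
    n_mono, n_inert = particle_counts(params)
    v_nm3 = params.volume_nm3
    n_d = idealized_dimer_count(k0_m3, n_mono, params.volume_m3)
    rho = ((n_mono - 2.0 * n_d) / v_nm3, n_d / v_nm3, n_inert / v_nm3)
    radius = (params.r_mono_nm, params.r_dimer_nm, params.r_inert_nm)
    return SPTComposition(rho=rho, radius=radius)


def estimate_k0(
    dilute_runs: list | None = None,
    params: ParameterSet | None = None,
    sample_times_us=None,
) -> float:
    """Ideal-state ``K°`` (m^3/molecule) from dilute pure-reactant runs.

    Either pass completed trajectories or a dilute ParameterSet to
    simulate (``n_runs`` replicates).  A ~1% pure-reactant condition is
    dilute enough to stand in for the ideal state (its own SPT
    correction is only a few percent).
    """
    if dilute_runs is None:
        if params is None:
            raise ValueError("need either runs or params")
        dilute_runs = run_replicates(params)
    est = quasi_equilibrium_summary(dilute_runs, sample_times_us=sample_times_us)
    return est.k_eq_m3


def spt_table(
    params: ParameterSet,
    k0_m3: float,
    conditions: list[tuple[float, float]],
) -> pd.DataFrame:
    """Tabulate gamma_M, gamma_D, Gamma_exc and K_app over (c_r, c_i)
    conditions at the quasi-equilibrium composition of each."""
    rows = []
    for c_r, c_i in conditions:
        p = params.with_(c_r=c_r, c_i=c_i)
        comp = quasi_equilibrium_composition(p, k0_m3)
        cf = gamma_exc_and_apparent_keq(comp, p.r_mono_nm, p.r_dimer_nm, k0_m3)
        rows.append(
            {
                "c_r": c_r,
                "c_i": c_i,
                "phi": comp.phi,
                "gamma_m": cf.gamma_m,
                "gamma_d": cf.gamma_d,
                "gamma_exc": cf.gamma_exc,
                "k_app_m3": cf.k_app_m3,
            }
        )
    return pd.DataFrame(rows)
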
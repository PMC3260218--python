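"""Equilibrium-constant estimation and quasi-equilibrium summaries.

The reversible dimerization ``M + M <-> D`` has the idealized
mass-action equilibrium constant

    K_eq = [D] / [M]^2,       [X] in molecules per m^3,

so ``K_eq`` carries units of m^3 per molecule.  Concentrations are
number densities: the measured particle counts divided by the
simulation volume.  Because inert crowders do not enter the governing
equation, any crowding-induced shift of the dimer count shows up
directly as a shift of the apparent ``K_eq``.

A run starts from all monomers and relaxes into a fluctuating
quasi-equilibrium; summaries average the dimer count over five evenly
spaced late time points per run across replicate runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class NotEquilibratedError(RuntimeError):
    """The averaged progress curve never settles into the target band."""


@dataclass
class EquilibriumEstimate:
    k_eq_m3: float
    mean_dimers: float
    std_dimers: float
    n_monomer0: int
    volume_m3: float
    sample_times_us: tuple
    n_runs: int
    k_eq_per_sample_mean: float  # mean of per-sample K_eq (Jensen differs)


def estimate_keq(n_dimer: float, n_monomer0: int, volume_m3: float) -> float:
    """Mass-action ``K_eq`` from a dimer count.

    ``[D] = n_dimer / V`` and ``[M] = (N_M0 - 2 n_dimer) / V``; returns
    ``[D]/[M]^2`` in m^3/molecule.  All monomers consumed gives +inf.
    """
    if volume_m3 <= 0:
        raise ValueError("volume must be positive")
    if n_dimer < 0 or 2 * n_dimer > n_monomer0:
        raise ValueError("dimer count outside [0, N_M0/2]")
    n_free = n_monomer0 - 2.0 * n_dimer
    if n_free == 0:
        return math.inf
    return (n_dimer / volume_m3) / (n_free / volume_m3) ** 2


def idealized_dimer_count(k_eq_m3: float, n_monomer0: int, volume_m3: float) -> float:
    """Expected dimer count under idealized mass action.

    Solves ``K (N_M0 - 2 N_D)^2 = N_D V`` for the physical root in
    ``[0, N_M0/2]`` (written in the numerically stable form that is
    exact in both the K -> 0 and K -> inf limits).
    """
    if k_eq_m3 < 0:
        raise ValueError("K_eq must be non-negative")
    if k_eq_m3 == 0:
        return 0.0
    if math.isinf(k_eq_m3):
        return n_monomer0 / 2.0
    k, n0, v = k_eq_m3, float(n_monomer0), volume_m3
    b = 4.0 * k * n0 + v
    disc = b * b - 16.0 * k * k * n0 * n0
    root = 2.0 * k * n0 * n0 / (b + math.sqrt(disc))
    assert 0.0 <= root <= n0 / 2.0 + 1e-9
    return root


def default_sample_times(duration_us: float, n_points: int = 5) -> np.ndarray:
    """Evenly spaced late sample times: 5 points over the last 80% of the
    run (5, 10, 15, 20, 25 us for the standard 25 us duration)."""
    return np.linspace(duration_us / n_points, duration_us, n_points)


def quasi_equilibrium_summary(
    runs: list,
    sample_times_us=None,
) -> EquilibriumEstimate:
    """Pooled late-time dimer statistics and the resulting ``K_eq``.

    ``runs`` are :class:`~crowdsim.engine.Trajectory` objects (or any
    object with ``.data``, ``.params`` and ``.n_monomer0``).  Dimer
    counts are pooled over ``sample_times_us`` x runs; ``K_eq`` is
    computed from the pooled *mean* count.  The mean of per-sample
    ``K_eq`` values is also reported (the two differ by Jensen's
    inequality).
    """
    if not runs:
        raise ValueError("no runs supplied")
    params = runs[0].params
    if sample_times_us is None:
        # anchor on the recorded span (the record grid may stop short of
        # the nominal duration when it is not a multiple of the interval)
        t_last = min(tr.data.time_us.values[-1] for tr in runs)
        sample_times_us = default_sample_times(t_last)
    sample_times_us = np.asarray(sample_times_us, dtype=float)
    n0 = runs[0].n_monomer0
    v = params.volume_m3
    samples = []
    for tr in runs:
        t = tr.data.time_us.values
        if sample_times_us.max() > t.max() + 1e-9:
            raise ValueError(
                f"run covers only {t.max():.3g} us but sampling requires "
                f"{sample_times_us.max():.3g} us"
            )
        idx = np.searchsorted(t, sample_times_us - 1e-9)
        samples.extend(tr.data.n_dimer.values[idx].tolist())
    samples = np.asarray(samples, dtype=float)
    mean = float(samples.mean())
    per_sample = [estimate_keq(s, n0, v) for s in samples]
    return EquilibriumEstimate(
        k_eq_m3=estimate_keq(mean, n0, v),
        mean_dimers=mean,
        std_dimers=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        n_monomer0=n0,
        volume_m3=v,
        sample_times_us=tuple(sample_times_us.tolist()),
        n_runs=len(runs),
        k_eq_per_sample_mean=float(np.mean(per_sample)),
    )


def equilibration_time(
    times_us: np.ndarray,
    mean_dimers: np.ndarray,
    window_us: tuple[float, float] | None = None,
    band: float = 0.05,
) -> float:
    """First time the averaged dimer count enters and stays within
    ``+-band`` (relative) of its late-window mean.

    ``window_us`` defaults to the last 80% of the curve.  Raises
    :class:`NotEquilibratedError` if the curve never settles.
    """
    times_us = np.asarray(times_us, dtype=float)
    mean_dimers = np.asarray(mean_dimers, dtype=float)
    if window_us is None:
        window_us = (times_us[-1] / 5.0, times_us[-1])
    sel = (times_us >= window_us[0] - 1e-9) & (times_us <= window_us[1] + 1e-9)
    target = mean_dimers[sel].mean()
    tol = band * abs(target) if target != 0 else band
    inside = np.abs(mean_dimers - target) <= tol
    # last index that is outside the band
    outside = np.nonzero(~inside)[0]
    if len(outside) == 0:
        return float(times_us[0])
    first = outside[-1] + 1
    if first >= len(times_us):
        raise NotEquilibratedError(
            f"curve never stays within {band:.0%} of its late mean {target:.3g}"
        )
    return float(times_us[first])


def mean_progress_curve(runs: list) -> pd.DataFrame:
    """Run-averaged reaction progress (time_us, n_dimer mean/std)."""
    frames = [tr.data.set_index("time_us").n_dimer for tr in runs]
    mat = pd.concat(frames, axis=1)
    return pd.DataFrame(
        {"n_dimer_mean": mat.mean(axis=1), "n_dimer_std": mat.std(axis=1)}
    ).reset_index()
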
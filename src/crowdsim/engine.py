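"""High-level simulation driver.

Wraps the compiled event loop: builds the state arrays from an initial
configuration, runs the event queue to the configured duration, and
returns the recorded reaction progress as a tidy DataFrame.

A run is fully determined by its :class:`~crowdsim.params.ParameterSet`
and a seed; replicate seeds are derived from the configured master seed
by fixed increments and echoed in the result metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .initialization import InitialConfiguration, hcp_initialize
from .params import DIMER, INERT, MONOMER, ParameterSet, derive_species

#: offset separating the lattice-assignment RNG stream from the kernel's
SEED_MOD = 2**31 - 1


@dataclass
class Trajectory:
    """Recorded progress of one run: dimer/monomer counts over time."""

    data: pd.DataFrame  # columns: time_us, n_monomer, n_dimer
    params: ParameterSet
    seed: int
    n_monomer0: int
    n_inert: int
    stats: dict = field(default_factory=dict)
    final_positions: np.ndarray | None = None  # (n_alive, 3) nm at t_last
    final_species: np.ndarray | None = None
    final_radii: np.ndarray | None = None

    @property
    def final_counts(self) -> tuple[int, int]:
        last = self.data.iloc[-1]
        return int(last.n_monomer), int(last.n_dimer)


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed from the master seed by a fixed affine step."""
    return (master_seed * 100003 + 7919 * run_index + 1) % SEED_MOD


def run_simulation(
    params: ParameterSet,
    seed: int | None = None,
    init: InitialConfiguration | None = None,
) -> Trajectory:
    """Run one realization and return its recorded time series.

    ``seed`` drives both the lattice assignment and the event-loop RNG;
    identical ``(params, seed, init)`` give identical output.
    """
    if seed is None:
        seed = params.seed
    if init is None:
        init = hcp_initialize(params, rng=np.random.default_rng(seed))

    n0 = len(init.positions)
    cap = n0 + 4
    pos = np.zeros((cap, 3), dtype=np.float64)
    pos[:n0] = init.positions
    rad = np.zeros(cap, dtype=np.float64)
    rad[:n0] = init.radii
    species_table = derive_species(params)
    d_mono = float(species_table.loc["monomer", "d_nm2ns"])
    d_dimer = float(species_table.loc["dimer", "d_nm2ns"])
    d_inert = float(species_table.loc["inert", "d_nm2ns"])
    dif = np.zeros(cap, dtype=np.float64)
    sp = np.full(cap, -1, dtype=np.int8)
    sp[:n0] = init.species
    dif[:n0] = np.select(
        [init.species == MONOMER, init.species == DIMER, init.species == INERT],
        [d_mono, d_dimer, d_inert],
    )
    acoef = 3.0 * np.sqrt(2.0 * dif)
    tl = np.zeros(cap, dtype=np.float64)
    gen = np.zeros(cap, dtype=np.int64)
    epoch = np.zeros(cap, dtype=np.int64)
    alive = np.zeros(cap, dtype=np.bool_)
    alive[:n0] = True

    t_end = params.duration_us * 1e3  # ns
    rec_interval = params.record_us * 1e3
    n_rec_max = int(math.floor(t_end / rec_interval + 1e-9)) + 1
    rec_t = np.zeros(n_rec_max, dtype=np.float64)
    rec_nm = np.zeros(n_rec_max, dtype=np.int64)
    rec_nd = np.zeros(n_rec_max, dtype=np.int64)

    kernel_seed = int((seed * 2654435761 + 97) % SEED_MOD)
    n_rec, stats = _kernel.run_kernel(
        pos, rad, dif, acoef, tl, sp, gen, epoch, alive,
        np.asarray(params.box_nm, dtype=np.float64),
        params.b, params.m_ns, params.d_th_nm,
        params.r_mono_nm, d_mono, params.r_dimer_nm, d_dimer,
        t_end, rec_interval, params.refresh_ns, kernel_seed,
        {"shell": 0, "overlap": 1, "sticky": 2, "resample": 3}[params.collision_rule],
        params.d_th_nm if params.dissociation_gap_nm is None else params.dissociation_gap_nm,
        params.contact_offset_nm,
        rec_t, rec_nm, rec_nd,
    )

    n_monomer0 = int((init.species == MONOMER).sum())
    # mass conservation sanity check over the whole trajectory
    if not np.all(rec_nm[:n_rec] + 2 * rec_nd[:n_rec] == n_monomer0):
        raise AssertionError("monomer-equivalent count not conserved")

    frame = pd.DataFrame(
        {
            "time_us": rec_t[:n_rec] * 1e-3,
            "n_monomer": rec_nm[:n_rec],
            "n_dimer": rec_nd[:n_rec],
        }
    )
    stat_names = [
        "events", "pair_events", "contacts", "bound", "rejected",
        "dissociations", "dissociations_postponed", "sample_fallbacks",
        "dimer_placement_failures", "refreshes",
    ]
    return Trajectory(
        data=frame,
        params=params,
        seed=seed,
        n_monomer0=n_monomer0,
        n_inert=int((init.species == INERT).sum()),
        stats=dict(zip(stat_names, stats.tolist())),
        final_positions=pos[alive].copy(),
        final_species=sp[alive].copy(),
        final_radii=rad[alive].copy(),
    )


def run_replicates(params: ParameterSet, n_runs: int | None = None) -> list[Trajectory]:
    """Independent replicate runs with seeds derived from ``params.seed``."""
    if n_runs is None:
        n_runs = params.n_runs
    return [
        run_simulation(params, seed=derive_run_seed(params.seed, k))
        for k in range(n_runs)
    ]
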
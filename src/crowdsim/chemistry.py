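"""Reaction rules: binding on collision, dissociation, re-placement.

During a run these rules execute inside the compiled event loop; this
module exposes them on explicit particle arrays so they can be driven
and inspected directly (unit tests, custom harnesses).

The model's reaction semantics:

* two monomers *collide* when, at a pair event, their sampled centre
  distance is below ``r_A + r_B + d_th`` (a sampled hard-core overlap
  also counts — the spheres must have met during the interval);
* a collision binds with probability ``B``; the dimer (radius
  ``alpha^(1/3) r_mono``) is placed at the pair's centre of mass,
  overlap-checked with jittered retries;
* an unbound collision is resolved by *re-sampling* the pair's
  diffusion step until the configuration ends outside interaction
  range, per the post-reaction separation rule;
* a dimer dissociates after an exponential waiting time of mean ``M``,
  releasing two monomers symmetrically about its centre along a
  uniformly random axis at separation ``2 r_mono + d_th``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit as _njit

from . import _kernel
from .params import DIMER, INERT, MONOMER, ParameterSet, derive_species

NO_CONTACT = "NO_CONTACT"
BOUND = "BOUND"
REJECTED_BY_B = "REJECTED_BY_B"
DISSOCIATED = "DISSOCIATED"
PLACEMENT_FAILED = "PLACEMENT_FAILED"


@dataclass
class ReactionOutcome:
    kind: str
    created: list = field(default_factory=list)
    removed: list = field(default_factory=list)


class ParticleSystem:
    """Explicit array-of-particles state mirroring the kernel layout.

    Intended for driving the reaction rules outside the event loop.
    """

    def __init__(self, params: ParameterSet, capacity: int = 64):
        self.params = params
        self.box = np.asarray(params.box_nm, dtype=np.float64)
        cap = capacity
        self.pos = np.zeros((cap, 3))
        self.rad = np.zeros(cap)
        self.dif = np.zeros(cap)
        self.tl = np.zeros(cap)
        self.sp = np.full(cap, -1, dtype=np.int8)
        self.gen = np.zeros(cap, dtype=np.int64)
        self.epoch = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=np.bool_)
        self._species = derive_species(params)
        # grid sized exactly as the kernel sizes it
        r_max = max(params.r_mono_nm, params.r_dimer_nm, params.r_inert_nm)
        a_max = 3.0 * np.sqrt(2.0 * self._species.d_nm2ns.max())
        h = 2.0 * r_max + params.d_th_nm + 2.0 * a_max * np.sqrt(2.0 * params.refresh_ns)
        dims = np.maximum((self.box / h).astype(np.int64), 1)
        inv = dims / self.box
        ncells = int(dims.prod())
        self._grid = (
            np.full(ncells, -1, dtype=np.int64),
            np.full(cap, -1, dtype=np.int64),
            np.full(cap, -1, dtype=np.int64),
            np.full(cap, -1, dtype=np.int64),
            dims,
            inv,
        )

    def add(self, species: int, position, t: float = 0.0) -> int:
        name = {MONOMER: "monomer", DIMER: "dimer", INERT: "inert"}[species]
        i = int(np.argmin(self.alive))
        if self.alive[i]:
            raise RuntimeError("particle capacity exhausted")
        self.pos[i] = position
        self.rad[i] = self._species.loc[name, "radius_nm"]
        self.dif[i] = self._species.loc[name, "d_nm2ns"]
        self.tl[i] = t
        self.sp[i] = species
        self.alive[i] = True
        self.gen[i] += 1
        self.epoch[i] += 1
        head, nxt, prv, cellid, dims, inv = self._grid
        c = _kernel._cell_index(
            *self.pos[i], inv[0], inv[1], inv[2], dims[0], dims[1], dims[2]
        )
        _kernel._grid_insert(i, c, head, nxt, prv, cellid)
        return i

    def remove(self, i: int) -> None:
        self.alive[i] = False
        self.gen[i] += 1
        head, nxt, prv, cellid, *_ = self._grid
        _kernel._grid_remove(i, head, nxt, prv, cellid)


def sample_dissociation_time(m_ns: float, rng: np.random.Generator) -> float:
    """Exponential dissociation waiting time with mean ``m_ns`` (ns)."""
    if m_ns <= 0:
        raise ValueError("mean dissociation time must be positive")
    return float(rng.exponential(m_ns))


def attempt_binding(
    sys: ParticleSystem, a: int, b: int, t: float, rng_seed: int | None = None
) -> ReactionOutcome:
    """Resolve a pair event between two monomers whose positions were
    already sampled at time ``t``.  Returns the reaction outcome and
    mutates the system accordingly."""
    p = sys.params
    if sys.sp[a] != MONOMER or sys.sp[b] != MONOMER:
        raise ValueError("binding requires two monomers")
    if rng_seed is not None:
        _kernel.seed_rng(rng_seed)
    d = float(np.linalg.norm(sys.pos[a] - sys.pos[b]))
    if d >= sys.rad[a] + sys.rad[b] + p.d_th_nm:
        return ReactionOutcome(NO_CONTACT)
    if _kernel_random() < p.b:
        ok, x, y, z = _kernel._place_dimer(
            a, b, sys.pos, sys.rad, sys.alive, sys.box, p.r_dimer_nm, sys._grid
        )
        if ok:
            sys.remove(a)
            sys.remove(b)
            new = sys.add(DIMER, (x, y, z), t)
            return ReactionOutcome(BOUND, created=[new], removed=[a, b])
        _kernel._separate_pair(
            a, b, t, sys.pos, sys.rad, sys.tl, sys.gen, sys.alive, sys.box,
            p.d_th_nm, sys._grid,
        )
        return ReactionOutcome(PLACEMENT_FAILED)
    _kernel._separate_pair(
        a, b, t, sys.pos, sys.rad, sys.tl, sys.gen, sys.alive, sys.box,
        p.d_th_nm, sys._grid,
    )
    return ReactionOutcome(REJECTED_BY_B)


def _kernel_random() -> float:
    """A uniform draw from the kernel's RNG stream (seed via seed_rng)."""
    return float(_rand_njit())


@_njit(cache=True)
def _rand_njit():
    return np.random.random()


def dissociate(sys: ParticleSystem, dimer: int, t: float, rng_seed: int | None = None) -> ReactionOutcome:
    """Replace a dimer by two monomers at separation ``2 r_mono + d_th``
    (centre of mass preserved, uniformly random axis).  On geometric
    failure the dimer persists (caller reschedules)."""
    p = sys.params
    if sys.sp[dimer] != DIMER:
        raise ValueError("dissociate requires a dimer")
    if rng_seed is not None:
        _kernel.seed_rng(rng_seed)
    gap = p.d_th_nm if p.dissociation_gap_nm is None else p.dissociation_gap_nm
    ok, ax, ay, az, bx, by, bz = _kernel._place_dissociated(
        dimer, sys.pos, sys.rad, sys.alive, sys.box, p.r_mono_nm, gap, sys._grid
    )
    if not ok:
        return ReactionOutcome(PLACEMENT_FAILED)
    sys.remove(dimer)
    m1 = sys.add(MONOMER, (ax, ay, az), t)
    m2 = sys.add(MONOMER, (bx, by, bz), t)
    return ReactionOutcome(DISSOCIATED, created=[m1, m2], removed=[dimer])
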
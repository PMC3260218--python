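"""Model parameters and derived per-species quantities.

The simulator models a reversible homodimerization ``M + M <-> D`` among
hard spheres in a box, optionally surrounded by inert crowding spheres.
Seven physical parameters control the system: reactant and inert volume
fractions (``c_r``, ``c_i``), the binding probability per collision
(``b``), the mean dissociation waiting time (``m_ns``), the monomer
diffusion coefficient (``d_m2s``), and the dimer/inert-to-monomer volume
ratios (``alpha``, ``beta``), plus the interaction threshold distance
``d_th_nm``.

Public configuration is accepted in SI-flavoured units (m^2/s for
diffusion, microseconds for durations); everything internal runs in
nanometres and nanoseconds, where event times are O(0.1-10 ns) and
positions O(nm).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

#: close-packing volume fraction of equal spheres; configurations above
#: this bound cannot be realized.
CLOSE_PACKING = math.pi / math.sqrt(18.0)

#: conversion factor m^2 s^-1 -> nm^2 ns^-1  (1e18 nm^2/m^2 / 1e9 ns/s)
M2S_TO_NM2NS = 1e9

MONOMER, DIMER, INERT = 0, 1, 2
SPECIES_NAMES = ("monomer", "dimer", "inert")


class InvalidParameterError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """Full configuration of one simulation condition.

    Defaults reproduce the baseline condition: ``B=0.7``, ``M=1 ns``,
    ``D=4.63e-11 m^2/s``, ``alpha=2``, ``beta=1``, ``d_th=0.125 nm``,
    monomer radius 2.5 nm, a 50 nm cube, 25 us runs recorded every
    0.15625 us.
    """

    c_r: float = 0.1
    c_i: float = 0.0
    b: float = 0.7
    m_ns: float = 1.0
    d_m2s: float = 4.63e-11
    alpha: float = 2.0
    beta: float = 1.0
    d_th_nm: float = 0.125
    r_mono_nm: float = 2.5
    box_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    duration_us: float = 25.0
    record_us: float = 0.15625
    seed: int = 0
    n_runs: int = 10
    #: staleness horizon (ns): a particle with no upcoming collision is
    #: refreshed after this long, bounding how stale any position can be.
    refresh_ns: float = 5.0
    #: how a collided-but-unbound reactant pair is re-placed outside
    #: interaction range: "resample" redraws the pair's diffusion step
    #: until the configuration ends beyond the threshold (the default;
    #: see docs/methods.md), "overlap"/"shell" push the pair apart
    #: deterministically to the minimum legal separation (differing in
    #: whether a sampled hard-core overlap counts as a collision), and
    #: "sticky" leaves the pair in place.  The non-default rules are
    #: retained for sensitivity analysis.
    collision_rule: str = "resample"
    #: surface-to-surface gap (nm) between the two monomers released by a
    #: dissociation; None places them just outside interaction range at
    #: the threshold distance (the post-reaction separation rule).
    dissociation_gap_nm: float | None = None
    #: surface separation (nm) at which a reactive (monomer-monomer)
    #: pair's contact event fires: the pair collision time solves for the
    #: diffusion limit spheres reaching this gap instead of hard contact.
    #: Controls how finely binding attempts are resolved near the
    #: interaction shell; must be < d_th.  See docs/methods.md for how
    #: this constant is fixed.
    contact_offset_nm: float = 0.085

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise InvalidParameterError(f"binding probability b={self.b} not in [0, 1]")
        if self.m_ns <= 0:
            raise InvalidParameterError(f"mean dissociation time m_ns={self.m_ns} must be > 0")
        if self.d_m2s <= 0:
            raise InvalidParameterError(f"diffusion coefficient d_m2s={self.d_m2s} must be > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError(
                f"volume ratios must be positive (alpha={self.alpha}, beta={self.beta})"
            )
        if self.d_th_nm < 0:
            raise InvalidParameterError(f"threshold distance d_th_nm={self.d_th_nm} must be >= 0")
        if self.r_mono_nm <= 0:
            raise InvalidParameterError("monomer radius must be positive")
        if self.c_r < 0 or self.c_i < 0:
            raise InvalidParameterError("volume fractions must be non-negative")
        if self.c_r + self.c_i >= CLOSE_PACKING:
            raise InvalidParameterError(
                f"total volume fraction {self.c_r + self.c_i:.3f} exceeds the "
                f"close-packing bound {CLOSE_PACKING:.3f}"
            )
        if len(self.box_nm) != 3 or any(L <= 2 * self.r_mono_nm for L in self.box_nm):
            raise InvalidParameterError(
                f"box dimensions {self.box_nm} must all exceed one monomer diameter"
            )
        if self.duration_us <= 0 or self.record_us <= 0:
            raise InvalidParameterError("duration and record interval must be positive")
        if self.d_th_nm > 0 and not 0.0 <= self.contact_offset_nm < self.d_th_nm:
            raise InvalidParameterError(
                f"contact_offset_nm={self.contact_offset_nm} must lie in [0, d_th)"
            )
        if self.collision_rule not in ("resample", "overlap", "shell", "sticky"):
            raise InvalidParameterError(
                f"collision_rule must be one of 'resample', 'overlap', 'shell', 'sticky', got {self.collision_rule!r}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def d_nm2ns(self) -> float:
        """Monomer diffusion coefficient in internal units (nm^2/ns)."""
        return self.d_m2s * M2S_TO_NM2NS

    @property
    def r_dimer_nm(self) -> float:
        """Dimer radius: the dimer occupies ``alpha`` monomer volumes."""
        return self.alpha ** (1.0 / 3.0) * self.r_mono_nm

    @property
    def r_inert_nm(self) -> float:
        """Inert-crowder radius: ``beta`` monomer volumes."""
        return self.beta ** (1.0 / 3.0) * self.r_mono_nm

    @property
    def v_mono_nm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r_mono_nm**3

    @property
    def volume_nm3(self) -> float:
        return self.box_nm[0] * self.box_nm[1] * self.box_nm[2]

    @property
    def volume_m3(self) -> float:
        return self.volume_nm3 * 1e-27

    def with_(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- configuration I/O --------------------------------------------------

    _KEYMAP = {
        "c_r": "c_r", "c_i": "c_i", "b": "b", "m_ns": "m_ns", "d_m2s": "d_m2s",
        "alpha": "alpha", "beta": "beta", "d_th_nm": "d_th_nm",
        "r_mono_nm": "r_mono_nm", "box_nm": "box_nm",
        "duration_us": "duration_us", "record_us": "record_us",
        "seed": "seed", "runs": "n_runs", "refresh_ns": "refresh_ns",
        "collision_rule": "collision_rule",
        "dissociation_gap_nm": "dissociation_gap_nm",
        "contact_offset_nm": "contact_offset_nm",
    }

    @classmethod
    def from_dict(cls, cfg: dict) -> "ParameterSet":
        unknown = set(cfg) - set(cls._KEYMAP)
        if unknown:
            raise InvalidParameterError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {cls._KEYMAP[k]: v for k, v in cfg.items()}
        if "box_nm" in kwargs:
            kwargs["box_nm"] = tuple(float(x) for x in kwargs["box_nm"])
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ParameterSet":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        inv = {v: k for k, v in self._KEYMAP.items()}
        out = {}
        for f_ in self.__dataclass_fields__:
            out[inv[f_]] = getattr(self, f_)
        out["box_nm"] = list(self.box_nm)
        return out


def derive_species(params: ParameterSet) -> pd.DataFrame:
    """Per-species radii and diffusion coefficients (internal units).

    Radii follow from the volume ratios (``r_D = alpha^(1/3) r_M``,
    ``r_I = beta^(1/3) r_M``) and diffusion coefficients from
    Stokes-Einstein scaling, ``D proportional to 1/r``, anchored at the
    configured monomer value.

    Returns a DataFrame indexed by species name with columns
    ``radius_nm`` and ``d_nm2ns``.
    """
    r_m = params.r_mono_nm
    d_m = params.d_nm2ns
    rows = {
        "monomer": (r_m, d_m),
        "dimer": (params.r_dimer_nm, d_m * params.alpha ** (-1.0 / 3.0)),
        "inert": (params.r_inert_nm, d_m * params.beta ** (-1.0 / 3.0)),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["radius_nm", "d_nm2ns"])
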
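"""Diffusion-limit spheres and analytic pair collision times.

Between events a particle's position is unknown; it is bounded (with
97.07% probability, ``P(chi^2_3 <= 9)``) by its *diffusion limit
sphere*, whose radius grows as ``r + 3*sqrt(2*D*dt)`` with the time
``dt`` since the position was last sampled.  Two particles can first
interact when their diffusion limit spheres touch, so the next possible
interaction time of a pair solves

    r_A + 3*sqrt(2*D_A*(t - t_A)) + r_B + 3*sqrt(2*D_B*(t - t_B)) = d_AB

for the smallest admissible ``t``.  Isolating one square root and
squaring twice reduces this to a quadratic whose spurious roots are
rejected against the original equation; a root always exists because
both radii grow without bound.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "diffusion_limit_radius",
    "contact_delay",
    "pair_collision_time",
    "CONTAINMENT_PROBABILITY",
]

#: probability that an isotropic Gaussian displacement lies inside the
#: 3-sigma sphere: P(chi^2_3 <= 9).
CONTAINMENT_PROBABILITY = 0.9707


@njit(cache=True)
def diffusion_limit_radius(radius: float, d: float, dt: float) -> float:
    """Radius of the diffusion limit sphere after ``dt`` ns.

    ``radius`` is the particle's hard-sphere radius (nm), ``d`` its
    diffusion coefficient (nm^2/ns).  Raises for negative ``dt``.
    """
    if dt < 0.0:
        raise ValueError("dt must be non-negative")
    return radius + 3.0 * math.sqrt(2.0 * d * dt)


@njit(cache=True)
def _residual(u: float, a: float, b: float, s: float, c: float) -> float:
    return a * math.sqrt(u) + b * math.sqrt(u + s) - c


@njit(cache=True)
def _bisect(a: float, b: float, s: float, c: float) -> float:
    lo = 0.0
    hi = max(s, 1.0)
    while _residual(hi, a, b, s, c) < 0.0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if _residual(mid, a, b, s, c) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def contact_delay(c: float, a: float, b: float, s: float) -> float:
    """Smallest ``u >= 0`` with ``a*sqrt(u) + b*sqrt(u + s) = c``.

    ``c`` is the surface gap (centre distance minus both hard radii,
    nm), ``a = 3*sqrt(2*D_A)`` and ``b = 3*sqrt(2*D_B)`` the sphere
    growth coefficients, and ``s >= 0`` the head start (ns) of B's
    sphere.  Returns 0 when the spheres are already in contact.

    The left side is strictly increasing in ``u``, so the solution is
    unique; of the two roots of the squared equation only one satisfies
    the unsquared original.
    """
    if c <= 0.0:
        return 0.0
    if b * b * s >= c * c:
        return 0.0  # B's sphere alone has already closed the gap
    p = c * c - b * b * s
    q = a * a - b * b
    fourac = 4.0 * a * a * c * c
    if q == 0.0:
        r = p / (2.0 * a * c)
        u = r * r
    else:
        bq = 2.0 * p * q - fourac
        disc = bq * bq - 4.0 * q * q * p * p
        if disc < 0.0:
            disc = 0.0
        sq = math.sqrt(disc)
        u1 = (-bq - sq) / (2.0 * q * q)
        u2 = (-bq + sq) / (2.0 * q * q)
        u = -1.0
        best = 1e300
        for cand in (u1, u2):
            if cand >= 0.0:
                res = abs(_residual(cand, a, b, s, c))
                if res < best:
                    best = res
                    u = cand
        if u < 0.0:
            return _bisect(a, b, s, c)
    # Newton polish: the quadratic can be ill-conditioned when a ~ b.
    for _ in range(3):
        if u <= 0.0:
            break
        f = _residual(u, a, b, s, c)
        df = 0.5 * a / math.sqrt(u) + 0.5 * b / math.sqrt(u + s)
        step = f / df
        if u - step < 0.0:
            break
        u -= step
    if u < 0.0 or abs(_residual(u, a, b, s, c)) > 1e-9 * (c + 1.0):
        return _bisect(a, b, s, c)
    return u


def pair_collision_time(
    pos_a: np.ndarray,
    r_a: float,
    d_a: float,
    t_a: float,
    pos_b: np.ndarray,
    r_b: float,
    d_b: float,
    t_b: float,
    now: float = 0.0,
) -> float:
    """Absolute time at which the diffusion limit spheres of A and B meet.

    Positions are the last-sampled centres (nm) at times ``t_a`` and
    ``t_b`` (ns); the returned time is the smallest ``t >= max(t_a,
    t_b, now)`` at which the two growing spheres touch.  Raises if the
    particles overlap at their sampled positions.
    """
    d_ab = float(np.linalg.norm(np.asarray(pos_a, float) - np.asarray(pos_b, float)))
    c = d_ab - r_a - r_b
    if c < 0.0:
        raise ValueError(
            f"particles overlap at their sampled positions (gap {c:.3g} nm)"
        )
    t0 = max(t_a, t_b, now)
    s_a = t0 - t_a
    s_b = t0 - t_b
    a = 3.0 * math.sqrt(2.0 * d_a)
    b = 3.0 * math.sqrt(2.0 * d_b)
    # shift so the less-stale sphere starts at zero head start
    if s_a <= s_b:
        v = contact_delay(c, a, b, s_b - s_a)
        u = v - s_a
    else:
        v = contact_delay(c, b, a, s_a - s_b)
        u = v - s_b
    return t0 + max(u, 0.0)
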
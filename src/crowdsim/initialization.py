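"""Initial particle configurations.

Reactants always start as monomers.  To realize high volume fractions
without overlap, initial centres are drawn from a hexagonal
close-packed (HCP) lattice of spheres of radius ``r_sel + d_th/2``,
where ``r_sel`` is the radius of whichever species (reactant monomers
or inert crowders) occupies the larger total volume; the half-threshold
inflation keeps every pair out of interaction range at t = 0.
Particles are assigned to uniformly random distinct lattice sites.

Because the reflective boundary lets a particle body protrude one
radius beyond each wall (only the centre is confined), the *effective*
volume is larger than the nominal box; ``corrected_concentration``
reports volume fractions against that inflated volume, which matters
most for thin, quasi-2D boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DIMER, INERT, MONOMER, ParameterSet


class InitializationError(RuntimeError):
    pass


@dataclass
class InitialConfiguration:
    positions: np.ndarray  # (n, 3) nm
    species: np.ndarray  # int codes
    radii: np.ndarray  # nm
    site_radius: float  # nm, lattice sphere radius
    n_sites: int
    nominal_concentration: float
    corrected_concentration: float


def particle_counts(params: ParameterSet) -> tuple[int, int]:
    """Integer particle numbers realizing the requested volume fractions.

    Counts are rounded to the nearest integer of ``C * V_box / v_particle``.
    """
    v_m = params.v_mono_nm3
    n_mono = round(params.c_r * params.volume_nm3 / v_m)
    n_inert = round(params.c_i * params.volume_nm3 / (params.beta * v_m))
    if params.c_r > 0 and n_mono < 1:
        raise InitializationError("c_r > 0 but the box holds no whole monomer")
    if params.c_i > 0 and n_inert < 1:
        raise InitializationError("c_i > 0 but the box holds no whole inert particle")
    return int(n_mono), int(n_inert)


def corrected_volume_nm3(params: ParameterSet) -> float:
    """Box volume inflated by one monomer diameter per axis."""
    d = 2.0 * params.r_mono_nm
    lx, ly, lz = params.box_nm
    return (lx + d) * (ly + d) * (lz + d)


def corrected_concentration(params: ParameterSet, counts: tuple[int, int] | None = None) -> float:
    """Achieved volume fraction against the boundary-corrected volume."""
    if counts is None:
        counts = particle_counts(params)
    n_mono, n_inert = counts
    occupied = (n_mono + params.beta * n_inert) * params.v_mono_nm3
    return occupied / corrected_volume_nm3(params)


def hcp_sites(box: tuple[float, float, float], site_radius: float) -> np.ndarray:
    """All HCP lattice sphere centres of radius ``site_radius`` that fit
    in the box with every centre at least one site radius from each wall.

    Layers are stacked along the shortest box axis, which maximizes the
    usable site count in thin boxes.
    """
    a = 2.0 * site_radius
    order = np.argsort(box)  # layering axis first (shortest)
    lz, ly, lx = box[order[0]], box[order[1]], box[order[2]]
    r = site_radius
    tol = 1e-9
    dz = a * math.sqrt(6.0) / 3.0
    dy = a * math.sqrt(3.0) / 2.0
    nz = int(math.floor((lz - 2 * r) / dz + tol)) + 1
    ny = int(math.floor((ly - 2 * r) / dy + tol)) + 1
    pts = []
    for k in range(nz):
        z = r + k * dz
        off = k % 2
        zy = off * a * math.sqrt(3.0) / 6.0
        zx = off * a / 2.0
        for j in range(ny):
            y = r + j * dy + zy
            if y > ly - r + tol:
                continue
            x0 = r + (j % 2) * a / 2.0 + zx
            # wrap the row offset back into range where possible
            while x0 - a >= r - tol:
                x0 -= a
            if x0 < r - tol:
                x0 += a
            nx = int(math.floor((lx - r - x0) / a + tol)) + 1
            for i in range(nx):
                pts.append((x0 + i * a, y, z))
    sites_sorted = np.asarray(pts, dtype=float)
    if sites_sorted.size == 0:
        return sites_sorted.reshape(0, 3)
    # permute axes back to the original frame: pts columns are
    # (long axis, middle axis, layering/short axis)
    sites = np.empty_like(sites_sorted)
    sites[:, order[2]] = sites_sorted[:, 0]
    sites[:, order[1]] = sites_sorted[:, 1]
    sites[:, order[0]] = sites_sorted[:, 2]
    return sites


def hcp_initialize(
    params: ParameterSet,
    counts: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> InitialConfiguration:
    """Place monomers and inert crowders on random distinct HCP sites."""
    if counts is None:
        counts = particle_counts(params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_mono, n_inert = counts
    n_total = n_mono + n_inert

    vol_mono = n_mono * params.v_mono_nm3
    vol_inert = n_inert * params.beta * params.v_mono_nm3
    r_sel = params.r_mono_nm if vol_mono >= vol_inert else params.r_inert_nm
    site_radius = r_sel + 0.5 * params.d_th_nm

    sites = hcp_sites(params.box_nm, site_radius)
    n_sites = len(sites)
    if n_sites < n_total:
        max_c = n_sites * params.v_mono_nm3 / params.volume_nm3
        raise InitializationError(
            f"{n_total} particles requested but only {n_sites} lattice sites fit; "
            f"max feasible monomer-equivalent volume fraction ~{max_c:.3f}"
        )
    chosen = rng.permutation(n_sites)[:n_total]
    positions = sites[chosen]
    species = np.concatenate(
        [np.full(n_mono, MONOMER, dtype=np.int8), np.full(n_inert, INERT, dtype=np.int8)]
    )
    radii = np.where(species == MONOMER, params.r_mono_nm, params.r_inert_nm)
    nominal = params.c_r + params.c_i
    return InitialConfiguration(
        positions=positions,
        species=species,
        radii=radii,
        site_radius=site_radius,
        n_sites=n_sites,
        nominal_concentration=nominal,
        corrected_concentration=corrected_concentration(params, counts),
    )
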
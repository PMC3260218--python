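"""Polynomial metamodels of the equilibrium constant over parameter space.

Crowding simulations are expensive; a least-squares polynomial in the
condition variables (total concentration ``C``, or jointly ``(alpha,
C)``) serves as a cheap surrogate for the simulated ``K_eq`` surface.
The polynomial degree is chosen by leave-one-out cross-validation
(LOOCV) over the individual observations (each run x time point is one
observation).

Raw powers of ``C`` in [0.1, 0.45] are badly conditioned at degree 5,
so predictors are standardized internally; reported coefficients are
back-transformed to the raw monomial basis (graded-lexicographic order,
constant term first).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class RankDeficientDesignError(np.linalg.LinAlgError):
    pass


def monomial_exponents(dim: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials with total degree <= ``degree``,
    graded-lexicographic, constant first."""
    out = []
    for total in range(degree + 1):
        grade = [
            e
            for e in itertools.product(range(total + 1), repeat=dim)
            if sum(e) == total
        ]
        grade.sort(reverse=True)
        out.extend(grade)
    return out


@dataclass
class RegressionModel:
    dim: int
    degree: int
    coefficients: np.ndarray  # raw-basis, graded-lex order
    exponents: list = field(repr=False, default_factory=list)
    training_rmse: float = math.nan
    loocv_rmse: float = math.nan
    _mu: np.ndarray = field(repr=False, default=None)
    _sigma: np.ndarray = field(repr=False, default=None)
    _beta_std: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            # a vector is n samples of a single predictor, or one sample
            x = x[:, None] if self.dim == 1 else x[None, :]
        z = (x - self._mu) / self._sigma
        design = _design_matrix(z, self.exponents)
        return design @ self._beta_std


def _design_matrix(x: np.ndarray, exponents) -> np.ndarray:
    n = x.shape[0]
    cols = [np.prod(x**np.asarray(e), axis=1) for e in exponents]
    return np.column_stack(cols) if cols else np.ones((n, 0))


def _back_transform(beta_std, exponents, mu, sigma, dim):
    """Expand the standardized-basis polynomial into raw coefficients.

    Each standardized monomial prod_i ((x_i - mu_i)/sigma_i)^e_i is a
    polynomial in x; accumulate binomial expansions per variable.
    """
    raw = {e: 0.0 for e in exponents}
    for coef, e in zip(beta_std, exponents):
        # start with the scalar coefficient, expand variable by variable
        terms = {tuple([0] * dim): coef}
        for i, ei in enumerate(e):
            if ei == 0:
                continue
            new_terms: dict = {}
            s = sigma[i]
            m = mu[i]
            for k in range(ei + 1):
                c_k = math.comb(ei, k) * ((-m) ** (ei - k)) / (s**ei)
                for mono, c0 in terms.items():
                    mono2 = list(mono)
                    mono2[i] += k
                    mono2 = tuple(mono2)
                    new_terms[mono2] = new_terms.get(mono2, 0.0) + c0 * c_k
            terms = new_terms
        for mono, c0 in terms.items():
            raw[mono] = raw.get(mono, 0.0) + c0
    return np.array([raw[e] for e in exponents])


def fit_polynomial(x, y, degree: int) -> RegressionModel:
    """Ordinary least squares on the monomial design of ``degree``.

    ``x`` is (n, dim) (or 1-D for a single predictor), ``y`` (n,).
    Deterministic given the data; raises on rank deficiency.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    n, dim = x.shape
    exponents = monomial_exponents(dim, degree)
    p = len(exponents)
    if n < p:
        raise ValueError(f"{n} observations cannot identify {p} coefficients")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    sigma[sigma == 0] = 1.0
    z = (x - mu) / sigma
    design = _design_matrix(z, exponents)
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {p} monomials (collinear predictors)"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    model = RegressionModel(
        dim=dim,
        degree=degree,
        coefficients=_back_transform(beta, exponents, mu, sigma, dim),
        exponents=exponents,
        training_rmse=float(np.sqrt(np.mean(resid**2))),
        _mu=mu,
        _sigma=sigma,
        _beta_std=beta,
    )
    return model


def loocv_rmse(x, y, degree: int) -> float:
    """Leave-one-observation-out RMSE for the polynomial of ``degree``.

    Uses the exact hat-matrix identity for OLS (``e_i / (1 - h_ii)``),
    which equals refitting with observation i removed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    exponents = monomial_exponents(x.shape[1], degree)
    p = len(exponents)
    if len(y) <= p:
        return math.inf
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    sigma[sigma == 0] = 1.0
    design = _design_matrix((x - mu) / sigma, exponents)
    if np.linalg.matrix_rank(design) < p:
        return math.inf
    q, _ = np.linalg.qr(design)
    h = np.sum(q**2, axis=1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    loo = resid / (1.0 - h)
    return float(np.sqrt(np.mean(loo**2)))


def loocv_select(x, y, degrees) -> tuple[int, dict]:
    """Degree with minimum LOOCV RMSE (ties broken toward lower degree).

    Returns ``(best_degree, {degree: rmse})``.
    """
    rmse = {int(d): loocv_rmse(x, y, int(d)) for d in degrees}
    best = min(sorted(rmse), key=lambda d: rmse[d])
    if math.isinf(rmse[best]):
        raise ValueError("no candidate degree is identifiable from the data")
    # near-ties (e.g. all RMSEs at float noise on noiseless data) go to
    # the lowest qualifying degree
    tol = rmse[best] * (1 + 1e-6) + 1e-12 * float(np.std(y) + 1.0)
    best = min(d for d in rmse if rmse[d] <= tol)
    return best, rmse


def linear_scaling_r2(curves: dict, reference_key) -> float:
    """How well a family of K_eq(C) curves reduces to scalar multiples of
    a reference curve.

    ``curves`` maps parameter value -> array of K_eq over a common
    condition grid.  For each non-reference curve the best least-squares
    scalar multiple of the reference is removed; returns the pooled R^2
    of that one-parameter-per-curve reduction.
    """
    ref = np.asarray(curves[reference_key], dtype=float)
    ss_res = 0.0
    ss_tot = 0.0
    pooled = np.concatenate([np.asarray(v, float) for v in curves.values()])
    grand = pooled.mean()
    for key, v in curves.items():
        v = np.asarray(v, dtype=float)
        scale = float(v @ ref / (ref @ ref))
        ss_res += float(np.sum((v - scale * ref) ** 2))
        ss_tot += float(np.sum((v - grand) ** 2))
    return 1.0 - ss_res / ss_tot


def observation_table(conditions: dict) -> pd.DataFrame:
    """Assemble a tidy observation table from per-condition runs.

    ``conditions`` maps a condition key (scalar or tuple of predictor
    values) to a list of trajectories; emits one row per run x sample
    time with the per-observation K_eq.
    """
    from .observables import default_sample_times, estimate_keq

    rows = []
    for cond, runs in conditions.items():
        cond_t = cond if isinstance(cond, tuple) else (cond,)
        for run_id, tr in enumerate(runs):
            times = default_sample_times(tr.params.duration_us)
            t = tr.data.time_us.values
            idx = np.searchsorted(t, times - 1e-9)
            for time_us, nd in zip(times, tr.data.n_dimer.values[idx]):
                rows.append(
                    {
                        **{f"x{i}": v for i, v in enumerate(cond_t)},
                        "run": run_id,
                        "time_us": time_us,
                        "k_eq_m3": estimate_keq(
                            nd, tr.n_monomer0, tr.params.volume_m3
                        ),
                    }
                )
    return pd.DataFrame(rows)
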
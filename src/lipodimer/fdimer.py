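"""Dimer-fraction estimation from photobleaching step-count data.

At each density the experimental step-count distribution is modeled as a
linear mixture of the ideal all-monomer and all-dimer distributions,

    P_n(expt) ~ (1 - F) P_n(M) + F P_n(D),

and F is chosen to minimize the residual sum of squares R² over the
step categories. The minimizer has a closed form (projection of
P_expt - P^M onto P^D - P^M, clamped to [0, 1]); a grid scan is kept as
a verification mode and for plotting R²(F) curves. Each point's fit
weight for the downstream isotherm fit is 1/R²_min with a small floor so
exact fits do not produce infinite weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .capture import PhotobleachDistribution, ideal_pair_at_chi

__all__ = [
    "R2_FLOOR",
    "FdimerPoint",
    "estimate_fdimer",
    "estimate_fdimer_grid",
    "r2_curve",
    "titration_fdimer",
    "chisq_compare",
    "binomial_sd",
    "DimerFractionEstimator",
]

R2_FLOOR = 1e-6


@dataclass(frozen=True)
class FdimerPoint:
    """One density point: estimated dimer fraction and fit residual."""

    chi_star: float
    f_dimer: float
    r2_min: float
    weight: float


def _as_probs(p) -> np.ndarray:
    if isinstance(p, PhotobleachDistribution):
        return p.probs
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("distributions must be 1-d")
    return arr


def _check_triplet(p_expt, p_m, p_d):
    pe, pm, pd_ = _as_probs(p_expt), _as_probs(p_m), _as_probs(p_d)
    if not (pe.shape == pm.shape == pd_.shape):
        raise ValueError("all three distributions must share one category scheme")
    d = pd_ - pm
    if np.allclose(d, 0.0, atol=1e-12):
        raise ValueError(
            "monomer and dimer references are identical in every category; "
            "the dimer fraction is unidentifiable"
        )
    return pe, pm, pd_, d


def _r2(pe, pm, pd_, f) -> float:
    resid = pe - ((1.0 - f) * pm + f * pd_)
    return float(resid @ resid)


def estimate_fdimer(
    p_expt,
    p_m,
    p_d,
    chi_star: float = math.nan,
    r2_floor: float = R2_FLOOR,
) -> FdimerPoint:
    """Closed-form least-squares dimer fraction, clamped to [0, 1]."""
    pe, pm, pd_, d = _check_triplet(p_expt, p_m, p_d)
    f = float((pe - pm) @ d / (d @ d))
    f = min(max(f, 0.0), 1.0)
    r2 = _r2(pe, pm, pd_, f)
    return FdimerPoint(
        chi_star=chi_star,
        f_dimer=f,
        r2_min=r2,
        weight=1.0 / max(r2, r2_floor),
    )


def estimate_fdimer_grid(
    p_expt,
    p_m,
    p_d,
    chi_star: float = math.nan,
    resolution: float = 1e-3,
    r2_floor: float = R2_FLOOR,
) -> FdimerPoint:
    """Grid-scan verification mode for :func:`estimate_fdimer`."""
    pe, pm, pd_, _ = _check_triplet(p_expt, p_m, p_d)
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    r2s = np.array([_r2(pe, pm, pd_, f) for f in grid])
    i = int(np.argmin(r2s))
    return FdimerPoint(
        chi_star=chi_star,
        f_dimer=float(grid[i]),
        r2_min=float(r2s[i]),
        weight=1.0 / max(float(r2s[i]), r2_floor),
    )


def r2_curve(p_expt, p_m, p_d, resolution: float = 1e-3):
    """R²(F) over a grid, for diagnostic plots."""
    pe, pm, pd_, _ = _check_triplet(p_expt, p_m, p_d)
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    return grid, np.array([_r2(pe, pm, pd_, f) for f in grid])


def titration_fdimer(
    chi_star,
    counts,
    yields=None,
    radius_dist=None,
    r_min_dimer: float = 25.0,
    average_replicates: bool = True,
    r2_floor: float = R2_FLOOR,
) -> list[FdimerPoint]:
    """Dimer-fraction curve from a full titration of step counts.

    ``chi_star`` holds the reactive mole fraction of each row of
    ``counts`` (shape (n_rows, m)); the capture model sees the observed
    mole fraction 2*chi_star. Ideal references are computed once per
    distinct density. With ``average_replicates`` (the experimental
    practice: replicate samples and counters are averaged before the
    isotherm fit) rows sharing a density are combined into one point
    with the mean dimer fraction and mean minimal residual.
    """
    chi_star = np.asarray(chi_star, dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if chi_star.size != counts.shape[0]:
        raise ValueError("one chi_star per counts row is required")
    m = counts.shape[1]
    cache: dict[float, tuple] = {}
    per_density: dict[float, list[tuple[float, float]]] = {}
    points = []
    for chi, row in zip(chi_star, counts):
        chi_obs = 2.0 * chi
        if chi_obs not in cache:
            cache[chi_obs] = ideal_pair_at_chi(
                chi_obs, yields=yields, radius_dist=radius_dist,
                r_min_dimer=r_min_dimer, m=m,
            )
        p_m, p_d = cache[chi_obs]
        pt = estimate_fdimer(row / row.sum(), p_m, p_d, chi_star=chi,
                             r2_floor=r2_floor)
        if average_replicates:
            per_density.setdefault(float(chi), []).append(
                (pt.f_dimer, pt.r2_min)
            )
        else:
            points.append(pt)
    if average_replicates:
        for chi in sorted(per_density):
            reps = per_density[chi]
            f_mean = float(np.mean([r[0] for r in reps]))
            r2_mean = float(np.mean([r[1] for r in reps]))
            points.append(FdimerPoint(
                chi_star=chi, f_dimer=f_mean, r2_min=r2_mean,
                weight=1.0 / max(r2_mean, r2_floor),
            ))
    return points


def chisq_compare(counts_a, counts_b, pool_threshold: float = 5.0):
    """Two-sample Pearson chi-squared comparison of step-count vectors.

    Categories (other than the top bucket) where both expected counts
    fall below ``pool_threshold`` are pooled into the top bucket before
    computing the statistic.

    Returns ``(statistic, df, p_value)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be matching 1-d arrays")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    total = a.sum() + b.sum()
    if total <= 0:
        raise ValueError("all-zero contingency table")
    col = a + b
    expected_a = col * a.sum() / total
    expected_b = col * b.sum() / total
    pool = (expected_a < pool_threshold) & (expected_b < pool_threshold)
    pool[-1] = False  # the top bucket is the pooling destination
    if pool.any():
        a = np.concatenate([a[~pool][:-1], [a[-1] + a[pool].sum()]])
        b = np.concatenate([b[~pool][:-1], [b[-1] + b[pool].sum()]])
    if len(a) < 2:
        raise ValueError("fewer than 2 categories after pooling")
    stat, p, df, _ = stats.chi2_contingency(
        np.vstack([a, b]), correction=False
    )
    return float(stat), int(df), float(p)


def binomial_sd(p: float, n: float) -> float:
    """Counting (binary) uncertainty of a proportion: sqrt(p(1-p)/n)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return math.sqrt(p * (1.0 - p) / n)


class DimerFractionEstimator(BaseEstimator):
    """sklearn-style wrapper over the mixture least-squares estimator.

    Parameters
    ----------
    p_m, p_d : array-like
        Ideal monomer / dimer reference distributions. Either a single
        distribution of shape (k,) shared by all samples, or per-sample
        references of shape (n_samples, k).
    method : {"closed_form", "grid"}
    grid_resolution : float
        Grid spacing for the "grid" method.
    r2_floor : float
        Floor applied to R²_min before inverting into a weight.

    Attributes (after ``fit(X)`` with X of shape (n_samples, k))
    ----------
    f_dimer_ : ndarray of shape (n_samples,)
    r2_min_ : ndarray of shape (n_samples,)
    weight_ : ndarray of shape (n_samples,)
    """

    def __init__(
        self,
        p_m=None,
        p_d=None,
        method: str = "closed_form",
        grid_resolution: float = 1e-3,
        r2_floor: float = R2_FLOOR,
    ):
        self.p_m = p_m
        self.p_d = p_d
        self.method = method
        self.grid_resolution = grid_resolution
        self.r2_floor = r2_floor

    def fit(self, X, y=None):
        if self.p_m is None or self.p_d is None:
            raise ValueError("p_m and p_d references are required")
        if self.method not in ("closed_form", "grid"):
            raise ValueError("method must be 'closed_form' or 'grid'")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pm = np.asarray(self.p_m, dtype=float)
        pd_ = np.asarray(self.p_d, dtype=float)
        pm = np.broadcast_to(pm, X.shape) if pm.ndim == 1 else pm
        pd_ = np.broadcast_to(pd_, X.shape) if pd_.ndim == 1 else pd_
        points = []
        for row, m_row, d_row in zip(X, pm, pd_):
            if self.method == "closed_form":
                points.append(
                    estimate_fdimer(row, m_row, d_row, r2_floor=self.r2_floor)
                )
            else:
                points.append(
                    estimate_fdimer_grid(
                        row, m_row, d_row,
                        resolution=self.grid_resolution,
                        r2_floor=self.r2_floor,
                    )
                )
        self.f_dimer_ = np.array([p.f_dimer for p in points])
        self.r2_min_ = np.array([p.r2_min for p in points])
        self.weight_ = np.array([p.weight for p in points])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).f_dimer_
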
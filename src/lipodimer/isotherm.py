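"""Equilibrium dimerization isotherm and standard-state thermodynamics.

For the two-state reaction M + M <-> D on the mole-fraction scale, with
K = chi*_D / (chi*_M)² (lipids/subunit) and total reactive mole fraction
chi* = chi*_M + 2 chi*_D, the fraction of subunits in the dimer form is

    F(chi*) = (1 + 4 chi* K - sqrt(1 + 8 chi* K)) / (4 chi* K),

a saturating isotherm rising from 0 at infinite dilution to 1, passing
through 1/2 at chi* K = 1. Experimental titrations carry a baseline
offset Y0 (apparent dimer fraction at infinite dilution), giving the
fitted model F = (1 - Y0) F(chi*) + Y0.

The fit is a weighted nonlinear least squares parameterized in log10 K
(for positivity and conditioning), with per-point weights 1/R²_min from
the dimer-fraction estimation. The standard-state free energy is
dG° = -RT ln(chi° K) with chi° = 1 subunit/lipid; the area-density
scale uses K_rho = K SA_lipid / 2 (nm²/subunit) and rho° = 1
subunit/nm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .density import ConversionConstants

__all__ = [
    "R_GAS_CAL",
    "DEFAULT_TEMPERATURE_K",
    "IsothermFit",
    "ThermoSummary",
    "isotherm_fdimer",
    "fit_isotherm",
    "free_energy",
    "delta_delta_g",
    "thermo_summary",
    "IsothermRegressor",
]

R_GAS_CAL = 1.9872036  # cal / (mol K)
DEFAULT_TEMPERATURE_K = 298.0


def isotherm_fdimer(chi_star, k: float, y0: float = 0.0):
    """Dimer fraction at reactive mole fraction ``chi_star`` for
    equilibrium constant ``k`` (lipids/subunit) and baseline ``y0``.

    Evaluated in the cancellation-free form
    ``F0 = x / (1 + x + sqrt(1 + 2x))`` with ``x = 4 chi* K``, which is
    algebraically identical to ``(1 + x - sqrt(1 + 2x)) / x`` but stable
    as chi* -> 0. Accepts scalars or arrays.
    """
    if k <= 0:
        raise ValueError("k must be strictly positive")
    if not 0 <= y0 < 1:
        raise ValueError("y0 must lie in [0, 1)")
    chi = np.asarray(chi_star, dtype=float)
    if np.any(chi < 0):
        raise ValueError("chi_star must be non-negative")
    x = 4.0 * chi * k
    core = x / (1.0 + x + np.sqrt(1.0 + 2.0 * x))
    out = y0 + (1.0 - y0) * core
    return float(out) if np.isscalar(chi_star) else out


@dataclass(frozen=True)
class IsothermFit:
    """Fitted isotherm parameters with linearized uncertainties."""

    k_chi_star: float  # lipids/subunit
    y0: float
    log10_k: float
    se_log10_k: float
    se_y0: float
    ci95_log10_k: tuple[float, float]
    ci95_k: tuple[float, float]
    fixed_y0: bool
    n_points: int
    weights: np.ndarray
    converged: bool


def _curve_fit(chi, f, sigma, fix_y0, p0):
    if fix_y0 is None:

        def model(x, log10_k, y0):
            return isotherm_fdimer(x, 10.0**log10_k, y0)

        bounds = ([-6.0, 0.0], [16.0, 0.999])
    else:

        def model(x, log10_k):
            return isotherm_fdimer(x, 10.0**log10_k, fix_y0)

        bounds = ([-6.0], [16.0])
    return optimize.curve_fit(
        model, chi, f, p0=p0, sigma=sigma, absolute_sigma=False,
        bounds=bounds, maxfev=20000,
    )


def _jackknife_se(chi, f, sigma, fix_y0, popt) -> float | None:
    """Delete-1 jackknife standard error of log10 K.

    The 1/R² weights are noisy surrogates for inverse variances, which
    makes the linearized covariance anticonservative; the jackknife is
    calibrated under weight misspecification.
    """
    n = chi.size
    if n < 4:
        return None
    estimates = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            popt_i, _ = _curve_fit(chi[keep], f[keep], sigma[keep],
                                   fix_y0, list(popt))
            estimates.append(popt_i[0])
        except RuntimeError:
            continue
    if len(estimates) < 3:
        return None
    est = np.asarray(estimates)
    nj = est.size
    return float(np.sqrt((nj - 1) / nj * np.sum((est - est.mean()) ** 2)))


def _fit_core(chi_star, f_dimer, weights, fix_y0):
    chi = np.asarray(chi_star, dtype=float)
    f = np.asarray(f_dimer, dtype=float)
    if chi.shape != f.shape or chi.ndim != 1:
        raise ValueError("chi_star and f_dimer must be matching 1-d arrays")
    n = chi.size
    if n < 3:
        raise ValueError("at least 3 points are required")
    if np.any(chi <= 0):
        raise ValueError("chi_star values must be strictly positive")
    span = math.log10(chi.max() / chi.min())
    if span < 1.0:
        raise ValueError(
            "points must span at least one decade of chi_star "
            f"(got {span:.2f} decades)"
        )
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != chi.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match chi_star")
    if np.ptp(f) < 1e-3 and f.mean() < 0.05:
        raise ValueError(
            "no rise in the dimer fraction across the titration; "
            "the equilibrium constant is unidentifiable (all-monomer data)"
        )
    # starting point: K ~ 1/chi at the half-rise
    f_mid = 0.5 * (f.min() + f.max())
    i_mid = int(np.argmin(np.abs(f - f_mid)))
    log10_k0 = -math.log10(chi[i_mid])
    sigma = 1.0 / np.sqrt(w)

    if fix_y0 is None:
        p0 = [log10_k0, float(np.clip(f.min(), 0.0, 0.5))]
    else:
        if not 0 <= fix_y0 < 1:
            raise ValueError("fix_y0 must lie in [0, 1)")
        p0 = [log10_k0]

    try:
        popt, pcov = _curve_fit(chi, f, sigma, fix_y0, p0)
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
    except RuntimeError as exc:
        raise RuntimeError(
            f"isotherm fit did not converge (start log10 K = {log10_k0:.2f}): {exc}"
        ) from exc

    log10_k = float(popt[0])
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se_log10_k = float(se[0])
    if fix_y0 is None:
        y0_hat, se_y0 = float(popt[1]), float(se[1])
    else:
        y0_hat, se_y0 = float(fix_y0), 0.0
    dof = max(n - len(popt), 1)
    t_crit = float(stats.t.ppf(0.975, dof))
    # CI half-width from the delete-1 jackknife where possible: the
    # linearized covariance under-states the spread when the 1/R²
    # weights deviate from true inverse variances.
    se_ci = _jackknife_se(chi, f, sigma, fix_y0, popt)
    if se_ci is None:
        se_ci = se_log10_k
    ci_log = (log10_k - t_crit * se_ci, log10_k + t_crit * se_ci)
    return IsothermFit(
        k_chi_star=10.0**log10_k,
        y0=y0_hat,
        log10_k=log10_k,
        se_log10_k=se_log10_k,
        se_y0=se_y0,
        ci95_log10_k=ci_log,
        ci95_k=(10.0 ** ci_log[0], 10.0 ** ci_log[1]),
        fixed_y0=fix_y0 is not None,
        n_points=n,
        weights=w,
        converged=bool(converged),
    )


def fit_isotherm(points, fix_y0: float | None = None, weights=None) -> IsothermFit:
    """Weighted nonlinear fit of the baseline isotherm.

    ``points`` is either a sequence of :class:`~lipodimer.fdimer.FdimerPoint`
    (weights taken as each point's 1/R²_min weight unless overridden) or
    a ``(chi_star, f_dimer)`` pair of arrays.
    """
    if isinstance(points, tuple) and len(points) == 2:
        chi, f = points
    else:
        pts = list(points)
        chi = np.array([p.chi_star for p in pts])
        f = np.array([p.f_dimer for p in pts])
        if weights is None:
            weights = np.array([p.weight for p in pts])
    return _fit_core(chi, f, weights, fix_y0)


def free_energy(
    k: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    standard_density: float = 1.0,
) -> float:
    """Standard-state association free energy, kcal/mol:
    dG° = -RT ln(standard_density * K)."""
    if k <= 0:
        raise ValueError("k must be strictly positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be strictly positive")
    return -R_GAS_CAL * temperature_k * math.log(standard_density * k) / 1000.0


def delta_delta_g(dg_a: float, dg_b: float) -> float:
    """Destabilization of a relative to b, kcal/mol."""
    if not (math.isfinite(dg_a) and math.isfinite(dg_b)):
        raise ValueError("free energies must be finite")
    return dg_a - dg_b


@dataclass(frozen=True)
class ThermoSummary:
    """All derived equilibrium quantities on both density scales."""

    k_chi: float  # lipids/subunit
    kd_chi: float  # subunits/lipid
    dg_chi: float  # kcal/mol at chi° = 1 subunit/lipid
    k_rho: float  # nm²/subunit
    kd_rho: float  # subunits/nm²
    eq_box: float  # nm, sqrt(K_rho)
    dg_rho: float  # kcal/mol at rho° = 1 subunit/nm²
    temperature_k: float


def thermo_summary(
    fit,
    constants: ConversionConstants = ConversionConstants(),
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> ThermoSummary:
    """Tabulate dissociation constants, area-scale constants and free
    energies from a fitted (or bare) equilibrium constant."""
    k = fit.k_chi_star if isinstance(fit, IsothermFit) else float(fit)
    if k <= 0:
        raise ValueError("equilibrium constant must be strictly positive")
    sa = constants.sa_lipid
    k_rho = k * sa / 2.0
    return ThermoSummary(
        k_chi=k,
        kd_chi=1.0 / k,
        dg_chi=free_energy(k, temperature_k, 1.0),
        k_rho=k_rho,
        kd_rho=1.0 / k_rho,
        eq_box=math.sqrt(k_rho),
        dg_rho=free_energy(k_rho, temperature_k, 1.0),
        temperature_k=temperature_k,
    )


class IsothermRegressor(RegressorMixin, BaseEstimator):
    """sklearn-style regressor for the dimerization isotherm.

    ``fit(X, y, sample_weight)`` takes reactive mole fractions X of
    shape (n, 1) or (n,) and dimer fractions y; fitted attributes are
    ``k_chi_``, ``y0_``, ``log10_k_``, ``se_log10_k_``, ``ci95_log10_k_``,
    ``ci95_k_`` and the full ``fit_result_``.
    """

    def __init__(
        self,
        fix_y0: float | None = None,
        temperature_k: float = DEFAULT_TEMPERATURE_K,
    ):
        self.fix_y0 = fix_y0
        self.temperature_k = temperature_k

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have a single chi_star column")
            X = X[:, 0]
        return X

    def fit(self, X, y, sample_weight=None):
        chi = self._validate_X(X)
        result = _fit_core(chi, np.asarray(y, dtype=float), sample_weight,
                           self.fix_y0)
        self.fit_result_ = result
        self.k_chi_ = result.k_chi_star
        self.y0_ = result.y0
        self.log10_k_ = result.log10_k
        self.se_log10_k_ = result.se_log10_k
        self.se_y0_ = result.se_y0
        self.ci95_log10_k_ = result.ci95_log10_k
        self.ci95_k_ = result.ci95_k
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "fit_result_"):
            raise AttributeError("IsothermRegressor is not fitted yet")
        chi = self._validate_X(X)
        return isotherm_fdimer(chi, self.k_chi_, self.y0_)

    def thermo_summary(
        self, constants: ConversionConstants = ConversionConstants()
    ) -> ThermoSummary:
        if not hasattr(self, "fit_result_"):
            raise AttributeError("IsothermRegressor is not fitted yet")
        return thermo_summary(self.fit_result_, constants, self.temperature_k)
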
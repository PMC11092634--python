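"""Benchmark-concentration (BMC) modeling of per-feature dose-response.

For every morphological feature that survives a one-way ANOVA plus
fold-change prefilter, Hill, power and low-order polynomial mean models are
fitted by maximum likelihood under iid normal errors with constant
variance.  The benchmark concentration is the smallest positive dose at
which the fitted mean departs from the fitted baseline by
``bmr_factor * sigma`` (default 1.349 residual standard deviations, the
conventional benchmark response for a ~10% tail shift under normality).
A one-sided 95% profile-likelihood lower bound (BMCL) accompanies it.
The best model per feature is chosen by nested likelihood-ratio tests
within the polynomial family followed by lowest AIC across families.

The object layer follows the statsmodels convention: a model class is
constructed from data and ``fit()`` returns a results object::

    >>> res = HillModel(doses, values).fit()
    >>> res.aic, res.params
    >>> res.bmc(dose_max=25.0)

Mean functions
--------------
Hill:        mu(d) = gamma + nu * d^n / (k^n + d^n),   k > 0, 1 <= n <= 18
power:       mu(d) = gamma + beta * d^delta,           delta >= 1
polynomial:  mu(d) = beta_0 + beta_1 d + ... + beta_j d^j
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

BMR_FACTOR = 1.349
_SIGMA_FLOOR = 1e-12
_HILL_N_MAX = 18.0
_POWER_DELTA_MAX = 18.0


# ---------------------------------------------------------------------------
# data container


@dataclass
class DoseSeries:
    """Aligned doses (µM, 0 = vehicle) and per-well response values."""

    doses: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.doses.shape != self.values.shape or self.doses.ndim != 1:
            raise ValueError("doses and values must be aligned 1-d arrays")
        if not (np.isfinite(self.doses).all() and np.isfinite(self.values).all()):
            raise ValueError("non-finite doses or values")
        if (self.doses < 0).any():
            raise ValueError("doses must be non-negative")

    @property
    def unique_doses(self) -> np.ndarray:
        return np.unique(self.doses)

    @property
    def dose_max(self) -> float:
        return float(self.doses.max())

    @property
    def min_positive_dose(self) -> float:
        pos = self.doses[self.doses > 0]
        return float(pos.min()) if pos.size else math.nan

    def validate_for_fit(self) -> None:
        uniq = self.unique_doses
        if uniq.size < 3 or 0.0 not in uniq:
            raise ValueError(
                "need >=3 distinct doses including 0 for dose-response fitting"
            )


# ---------------------------------------------------------------------------
# ANOVA + fold-change prefilter


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA across dose groups plus the max |mean shift| vs vehicle."""

    f_stat: float
    p_value: float
    max_abs_diff: float
    passed: bool


def anova_prefilter(
    series: DoseSeries, p_cut: float = 0.05, fc_cut: float = 1.0
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across dose groups.

    The fold-change statistic is the largest absolute difference between a
    dose-group mean and the vehicle mean, interpreted on a log2-like scale
    (so ``fc_cut=1`` corresponds to a 2-fold change).  A feature passes
    only if both ``p < p_cut`` and ``max |diff| >= fc_cut``.
    Degenerate input (all values identical) fails with a warning rather
    than raising.
    """
    uniq = series.unique_doses
    groups = [series.values[series.doses == d] for d in uniq]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    vehicle_mean = float(np.mean(series.values[series.doses == 0.0]))
    diffs = [
        abs(float(np.mean(g)) - vehicle_mean) for d, g in zip(uniq, groups) if d > 0
    ]
    max_abs_diff = max(diffs) if diffs else 0.0
    if np.ptp(series.values) == 0:
        logger.warning("anova_prefilter: all values identical; F undefined")
        return AnovaResult(math.nan, math.nan, 0.0, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_value = stats.f_oneway(*groups)
    f_stat, p_value = float(f_stat), float(p_value)
    passed = bool(
        np.isfinite(p_value) and p_value < p_cut and max_abs_diff >= fc_cut
    )
    return AnovaResult(f_stat, p_value, max_abs_diff, passed)


# ---------------------------------------------------------------------------
# mean functions


def model_mean(family: str, params: dict, d) -> np.ndarray | float:
    """Evaluate a fitted family's mean response at dose(s) ``d`` (>= 0)."""
    d_arr = np.asarray(d, dtype=float)
    if (d_arr < 0).any():
        raise ValueError("dose must be non-negative")
    if family == "hill":
        g, nu, k, n = params["gamma"], params["nu"], params["k"], params["n"]
        with np.errstate(divide="ignore", invalid="ignore"):
            dn = np.where(d_arr > 0, d_arr, 1.0) ** n
            frac = np.where(d_arr > 0, dn / (k**n + dn), 0.0)
        out = g + nu * frac
    elif family == "power":
        g, beta, delta = params["gamma"], params["beta"], params["delta"]
        out = g + beta * np.where(d_arr > 0, d_arr, 1.0) ** delta * (d_arr > 0)
    elif family == "poly":
        coefs = params["coefs"]  # beta_0 .. beta_j
        out = np.polynomial.polynomial.polyval(d_arr, np.asarray(coefs, dtype=float))
    else:
        raise ValueError(f"unknown model family {family!r}")
    if np.ndim(d) == 0:
        return float(out)
    return out


def _n_mean_params(family: str, params: dict) -> int:
    if family == "hill":
        return 4
    if family == "power":
        return 3
    return len(params["coefs"])


# ---------------------------------------------------------------------------
# results object


@dataclass
class BmcResult:
    """Benchmark concentration of a fitted curve plus qualifying flags."""

    bmc: float  # µM; nan when the curve never reaches the BMR
    bmcl: float  # one-sided 95% lower bound; nan if not computed/defined
    direction: str  # "UP" or "DOWN": sign of mu(dose_max) - mu(0)
    hill_k_flag: bool  # Hill k below the lowest positive tested dose
    within_range: bool  # BMC <= max tested dose
    bmr_factor: float = BMR_FACTOR

    @property
    def defined(self) -> bool:
        return math.isfinite(self.bmc)


class DoseResponseResults:
    """Maximum-likelihood fit of one mean family to a dose series.

    Attributes
    ----------
    family : str
        "hill", "power" or "poly".
    params : dict
        Fitted mean parameters (see module docstring).
    sigma : float
        ML residual standard deviation (constant variance).
    llf : float
        Maximized log-likelihood.
    aic : float
        ``2 * (n_mean_params + 1) - 2 * llf`` (sigma counts as one).
    """

    def __init__(
        self,
        model: "DoseResponseModel",
        params: dict,
        sse: float,
        converged: bool,
        nit: int,
    ):
        self.model = model
        self.family = model.family
        self.params = params
        n = model.series.values.size
        self.sse = float(sse)
        sigma2 = max(self.sse / n, _SIGMA_FLOOR**2)
        self.sigma = math.sqrt(sigma2)
        self.llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + self.sse / (n * sigma2))
        self.n_mean_params = _n_mean_params(self.family, params)
        self.df_model = self.n_mean_params + 1
        self.aic = 2.0 * self.df_model - 2.0 * self.llf
        self.converged = bool(converged)
        self.nit = int(nit)

    # -- prediction -----------------------------------------------------

    def predict(self, d):
        return model_mean(self.family, self.params, d)

    # -- benchmark concentration ----------------------------------------

    def bmc(
        self,
        bmr_factor: float = BMR_FACTOR,
        dose_max: float | None = None,
        compute_bmcl: bool = False,
        level: float = 0.95,
    ) -> BmcResult:
        """Benchmark concentration at ``bmr_factor`` residual SDs.

        Closed-form inversion for Hill and power; safeguarded root-finding
        on ``[0, 10 * dose_max]`` for polynomials (smallest positive
        crossing).  Direction is the sign of ``mu(dose_max) - mu(0)``.
        """
        if self.sigma <= 0:
            raise ValueError("sigma must be positive to define a BMR")
        if dose_max is None:
            dose_max = self.model.series.dose_max
        bmr = bmr_factor * self.sigma
        bmc = self._invert_bmr(bmr, dose_max)

        delta_top = self.predict(dose_max) - self.predict(0.0)
        direction = "UP" if delta_top >= 0 else "DOWN"
        hill_k_flag = bool(
            self.family == "hill"
            and self.params["k"] < self.model.series.min_positive_dose
        )
        within = bool(math.isfinite(bmc) and bmc <= dose_max)
        bmcl = math.nan
        if compute_bmcl and math.isfinite(bmc):
            bmcl = self.bmcl(bmr_factor=bmr_factor, level=level, _bmc=bmc)
        return BmcResult(bmc, bmcl, direction, hill_k_flag, within, bmr_factor)

    def _invert_bmr(self, bmr: float, dose_max: float) -> float:
        p = self.params
        if self.family == "hill":
            nu = p["nu"]
            if abs(nu) <= bmr:
                return math.nan  # asymptote never reaches the BMR
            r = bmr / abs(nu)
            return float(p["k"] * (r / (1.0 - r)) ** (1.0 / p["n"]))
        if self.family == "power":
            beta = p["beta"]
            if beta == 0:
                return math.nan
            return float((bmr / abs(beta)) ** (1.0 / p["delta"]))
        # polynomial: smallest positive crossing of |mu(d) - mu(0)| = bmr
        mu0 = self.predict(0.0)
        hi = 10.0 * dose_max

        def g(d):
            return abs(self.predict(d) - mu0) - bmr

        grid = np.concatenate(
            [np.linspace(0.0, dose_max, 1024), np.linspace(dose_max, hi, 1024)[1:]]
        )
        vals = np.abs(self.predict(grid) - mu0) - bmr
        idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        if idx.size == 0:
            if vals[0] >= 0:  # already past the BMR at d -> 0+
                return math.nan
            return math.nan
        lo, hi_b = grid[idx[0]], grid[idx[0] + 1]
        if vals[idx[0] + 1] == 0:
            return float(hi_b)
        return float(optimize.brentq(g, lo, hi_b, xtol=1e-12, rtol=1e-12))

    # -- profile-likelihood BMCL ----------------------------------------

    def bmcl(
        self,
        bmr_factor: float = BMR_FACTOR,
        level: float = 0.95,
        rel_tol: float = 1e-3,
        _bmc: float | None = None,
    ) -> float:
        """One-sided profile-likelihood lower confidence bound on the BMC.

        The bound is the smallest BMC' <= BMC whose constrained maximum
        log-likelihood lies within ``chi2_1(2*level - 1) / 2`` of the
        unconstrained optimum; located by bisection to relative tolerance
        ``rel_tol``.  Returns nan (with a warning) when the profile cannot
        be bracketed.
        """
        bmc = self._bmc_value(bmr_factor) if _bmc is None else _bmc
        if not math.isfinite(bmc):
            return math.nan
        drop = stats.chi2.ppf(2 * level - 1, df=1) / 2.0

        def deficit(b: float) -> float:
            return (self.llf - self._profile_llf(b, bmr_factor)) - drop

        lo = None
        hi = bmc
        b = bmc
        for _ in range(25):
            b /= 2.0
            d = deficit(b)
            if d >= 0:
                lo = b
                break
            hi = b
        if lo is None:
            logger.warning("bmcl: profile never crossed the cutoff; returning nan")
            return math.nan
        while (hi - lo) > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            if deficit(mid) >= 0:
                lo = mid
            else:
                hi = mid
        return float(hi)

    def _bmc_value(self, bmr_factor: float) -> float:
        return self._invert_bmr(bmr_factor * self.sigma, self.model.series.dose_max)

    def _profile_llf(self, bmc_target: float, bmr_factor: float) -> float:
        """Max log-likelihood subject to BMC(theta, sigma) = bmc_target.

        The BMR-defining parameter is substituted from the constraint
        ``|mu(BMC') - mu(0)| = bmr_factor * sigma`` so the optimization is
        unconstrained in the remaining mean parameters and log(sigma).
        """
        series = self.model.series
        d, y = series.doses, series.values
        n = y.size
        p = self.params
        sgn = 1.0 if (self.predict(series.dose_max) - self.predict(0.0)) >= 0 else -1.0
        b = bmc_target

        if self.family == "power":
            def unpack(x):
                gamma, delta_raw, logsig = x
                delta = 1.0 + abs(delta_raw - 1.0) if delta_raw < 1.0 else delta_raw
                sigma = max(math.exp(logsig), _SIGMA_FLOOR)
                beta = sgn * bmr_factor * sigma / b**delta
                mu = gamma + beta * np.where(d > 0, d, 1.0) ** delta * (d > 0)
                return mu, sigma
            x0 = [p["gamma"], p["delta"], math.log(self.sigma)]
        elif self.family == "hill":
            def unpack(x):
                gamma, logk, n_raw, logsig = x
                nh = min(max(n_raw, 1.0), _HILL_N_MAX)
                k = math.exp(logk)
                sigma = max(math.exp(logsig), _SIGMA_FLOOR)
                frac_b = b**nh / (k**nh + b**nh)
                nu = sgn * bmr_factor * sigma / frac_b
                dn = np.where(d > 0, d, 1.0) ** nh
                mu = gamma + nu * np.where(d > 0, dn / (k**nh + dn), 0.0)
                return mu, sigma
            x0 = [p["gamma"], math.log(p["k"]), p["n"], math.log(self.sigma)]
        else:  # poly
            coefs = np.asarray(p["coefs"], dtype=float)
            j = len(coefs) - 1

            def unpack(x):
                beta0 = x[0]
                rest = np.asarray(x[1:j], dtype=float)  # beta_2..beta_j
                sigma = max(math.exp(x[j]), _SIGMA_FLOOR)
                higher = sum(rest[i] * b ** (i + 2) for i in range(rest.size))
                beta1 = (sgn * bmr_factor * sigma - higher) / b
                cf = np.concatenate([[beta0, beta1], rest])
                mu = np.polynomial.polynomial.polyval(d, cf)
                return mu, sigma
            x0 = [coefs[0], *coefs[2:], math.log(self.sigma)]

        def nll(x):
            mu, sigma = unpack(x)
            sigma = max(sigma, _SIGMA_FLOOR)
            resid = y - mu
            return 0.5 * n * math.log(2 * math.pi * sigma**2) + float(
                resid @ resid
            ) / (2 * sigma**2)

        best = math.inf
        for scale in (0.0, 0.1):
            start = np.asarray(x0, dtype=float)
            if scale:
                start = start + scale * np.where(start == 0, 1.0, np.abs(start))
            res = optimize.minimize(
                nll, start, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-9},
            )
            best = min(best, float(res.fun))
        return -best

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Dose-response fit: family={self.family}",
            f"  n obs            {self.model.series.values.size}",
            f"  converged        {self.converged} (iterations {self.nit})",
            f"  sigma            {self.sigma:.6g}",
            f"  logL             {self.llf:.6g}",
            f"  AIC              {self.aic:.6g}",
            "  parameters:",
        ]
        for name, val in self.params.items():
            if isinstance(val, (list, tuple, np.ndarray)):
                val = ", ".join(f"{v:.6g}" for v in np.asarray(val, dtype=float))
            else:
                val = f"{val:.6g}"
            lines.append(f"    {name:<8} {val}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DoseResponseResults family={self.family} aic={self.aic:.4g} "
            f"converged={self.converged}>"
        )


# ---------------------------------------------------------------------------
# model classes


class DoseResponseModel:
    """Base class: holds a :class:`DoseSeries` and fits by ML.

    Linear-in-mean parameters are profiled out exactly (least squares at
    fixed nonlinear parameters), so the optimizer works in at most two
    nonlinear dimensions; this makes the multi-start fits fast and robust.
    """

    family: str = ""

    def __init__(self, doses, values):
        self.series = (
            doses if isinstance(doses, DoseSeries) else DoseSeries(doses, values)
        )
        self.series.validate_for_fit()

    @classmethod
    def from_series(cls, series: DoseSeries, **kw):
        return cls(series, None, **kw)

    def fit(
        self, n_starts: int = 8, max_iter: int = 250, seed: int = 0
    ) -> DoseResponseResults:
        raise NotImplementedError

    # helpers shared by subclasses -------------------------------------

    def _lstsq_sse(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        y = self.series.values
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return coef, float(resid @ resid)


class PolynomialModel(DoseResponseModel):
    """Polynomial mean of fixed degree; ML fit is closed-form least squares."""

    family = "poly"

    def __init__(self, doses, values=None, degree: int = 1):
        super().__init__(doses, values)
        n_distinct = self.series.unique_doses.size
        if degree < 1 or degree >= n_distinct - 1:
            raise ValueError(
                f"polynomial degree must satisfy 1 <= degree < distinct doses - 1 "
                f"({n_distinct - 1}); got {degree}"
            )
        self.degree = degree

    def fit(self, n_starts: int = 8, max_iter: int = 250, seed: int = 0):
        d = self.series.doses
        X = np.vander(d, self.degree + 1, increasing=True)
        coef, sse = self._lstsq_sse(X)
        return DoseResponseResults(
            self, {"degree": self.degree, "coefs": coef.tolist()}, sse,
            converged=True, nit=0,
        )


class PowerModel(DoseResponseModel):
    """Power mean ``gamma + beta * d^delta`` with the exponent restricted
    to ``delta >= 1``; gamma and beta are profiled out, leaving a 1-d
    optimization over delta."""

    family = "power"

    def _sse_at(self, delta: float) -> tuple[np.ndarray, float]:
        d = self.series.doses
        reg = np.where(d > 0, d, 1.0) ** delta * (d > 0)
        X = np.column_stack([np.ones_like(d), reg])
        return self._lstsq_sse(X)

    def fit(self, n_starts: int = 8, max_iter: int = 250, seed: int = 0):
        rng = np.random.default_rng(seed)
        starts = [1.0, 2.0, 4.0, 8.0]
        starts += list(
            1.0 + rng.uniform(0, _POWER_DELTA_MAX - 1, max(0, n_starts - len(starts)))
        )
        best = (math.inf, None, None, 0, False)
        for s in starts[:max(n_starts, 4)]:
            res = optimize.minimize(
                lambda x: self._sse_at(float(x[0]))[1],
                [s], method="L-BFGS-B",
                bounds=[(1.0, _POWER_DELTA_MAX)],
                options={"maxiter": max_iter},
            )
            if res.fun < best[0]:
                best = (float(res.fun), float(res.x[0]), None, res.nit, res.success)
        sse, delta, _, nit, ok = best
        coef, sse = self._sse_at(delta)
        params = {"gamma": float(coef[0]), "beta": float(coef[1]), "delta": delta}
        return DoseResponseResults(self, params, sse, converged=ok, nit=nit)


class HillModel(DoseResponseModel):
    """Four-parameter Hill mean; gamma and nu are profiled out, leaving a
    2-d optimization over (log k, n) with ``1 <= n <= 18``."""

    family = "hill"

    def _sse_at(self, logk: float, n: float) -> tuple[np.ndarray, float]:
        d = self.series.doses
        k = math.exp(logk)
        dn = np.where(d > 0, d, 1.0) ** n
        frac = np.where(d > 0, dn / (k**n + dn), 0.0)
        X = np.column_stack([np.ones_like(d), frac])
        return self._lstsq_sse(X)

    def fit(self, n_starts: int = 8, max_iter: int = 250, seed: int = 0):
        rng = np.random.default_rng(seed)
        pos = self.series.doses[self.series.doses > 0]
        lo, hi = math.log(pos.min()), math.log(pos.max())
        span = hi - lo if hi > lo else 1.0
        base = [
            (lo + 0.25 * span, 1.0), (lo + 0.75 * span, 1.0),
            (lo + 0.5 * span, 3.0), (lo + 0.5 * span, 1.5),
        ]
        extra = [
            (rng.uniform(lo - 1, hi + 1), math.exp(rng.uniform(0, math.log(8.0))))
            for _ in range(max(0, n_starts - len(base)))
        ]
        bounds = [(lo - math.log(1e3), hi + math.log(1e3)), (1.0, _HILL_N_MAX)]
        best = (math.inf, None, 0, False)
        for x0 in (base + extra)[:max(n_starts, 4)]:
            res = optimize.minimize(
                lambda x: self._sse_at(float(x[0]), float(x[1]))[1],
                x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter},
            )
            if res.fun < best[0]:
                best = (float(res.fun), (float(res.x[0]), float(res.x[1])), res.nit, res.success)
        sse, (logk, nhill), nit, ok = best
        coef, sse = self._sse_at(logk, nhill)
        params = {
            "gamma": float(coef[0]), "nu": float(coef[1]),
            "k": math.exp(logk), "n": nhill,
        }
        n_distinct = self.series.unique_doses.size
        if n_distinct <= 4:
            logger.warning(
                "HillModel: 4 mean parameters with %d distinct doses; fit is saturated",
                n_distinct,
            )
        return DoseResponseResults(self, params, sse, converged=ok, nit=nit)


_FAMILIES = {"hill": HillModel, "power": PowerModel, "poly": PolynomialModel}


def fit_model(
    series: DoseSeries,
    family: str,
    degree: int = 1,
    n_starts: int = 8,
    max_iter: int = 250,
    seed: int = 0,
) -> DoseResponseResults:
    """Functional wrapper: fit one family to a dose series."""
    if family == "poly":
        model = PolynomialModel(series, None, degree=degree)
    elif family in _FAMILIES:
        model = _FAMILIES[family](series, None)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return model.fit(n_starts=n_starts, max_iter=max_iter, seed=seed)


def compute_bmc(
    fit: DoseResponseResults,
    bmr_factor: float = BMR_FACTOR,
    dose_max: float | None = None,
    **kw,
) -> BmcResult:
    """Functional wrapper for :meth:`DoseResponseResults.bmc`."""
    return fit.bmc(bmr_factor=bmr_factor, dose_max=dose_max, **kw)


def compute_bmcl(
    fit: DoseResponseResults, bmr_factor: float = BMR_FACTOR, level: float = 0.95
) -> float:
    """Functional wrapper for :meth:`DoseResponseResults.bmcl`."""
    return fit.bmcl(bmr_factor=bmr_factor, level=level)


# ---------------------------------------------------------------------------
# model selection


def select_best(
    fits: list[DoseResponseResults],
    lrt_cut: float = 0.05,
    aic_tie_tol: float = 1e-6,
) -> DoseResponseResults | None:
    """Pick the best fitted family for one feature.

    Within the polynomial family, ascending-degree likelihood-ratio tests
    (chi-square, df = parameter difference, cutoff ``lrt_cut``) choose the
    lowest adequate degree; the surviving polynomial then competes with
    Hill and power on lowest AIC.  AIC ties break toward fewer parameters,
    then the fixed order poly < power < hill.  Returns None when no fit
    converged (feature unmodelable).
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        logger.warning("select_best: no converged fits; feature unmodelable")
        return None

    polys = sorted(
        (f for f in converged if f.family == "poly"),
        key=lambda f: f.params["degree"],
    )
    survivors: list[DoseResponseResults] = []
    if polys:
        current = polys[0]
        for nxt in polys[1:]:
            lr = 2.0 * (nxt.llf - current.llf)
            df = nxt.n_mean_params - current.n_mean_params
            p = stats.chi2.sf(max(lr, 0.0), df=df)
            if p < lrt_cut:
                current = nxt
        survivors.append(current)
    survivors += [f for f in converged if f.family in ("power", "hill")]

    order = {"poly": 0, "power": 1, "hill": 2}
    survivors.sort(key=lambda f: (f.aic, f.n_mean_params, order[f.family]))
    best = survivors[0]
    near = [f for f in survivors if abs(f.aic - best.aic) < aic_tie_tol]
    near.sort(key=lambda f: (f.n_mean_params, order[f.family]))
    return near[0]


# ---------------------------------------------------------------------------
# per-chemical driver


def series_from_profiles(
    profiles: pd.DataFrame, chemical: str, feature: str
) -> DoseSeries:
    """Build a dose series for one feature: the chemical's wells plus the
    vehicle wells of its solvent (dose 0)."""
    chem_rows = profiles[profiles["Metadata_Chemical"] == chemical]
    if chem_rows.empty:
        raise ValueError(f"chemical {chemical!r} not present in profiles")
    vehicles = chem_rows["Metadata_Vehicle"].unique()
    veh_rows = profiles[
        (profiles["Metadata_Concentration"] == 0)
        & profiles["Metadata_Vehicle"].isin(vehicles)
    ]
    sub = pd.concat([veh_rows, chem_rows[chem_rows["Metadata_Concentration"] > 0]])
    return DoseSeries(
        sub["Metadata_Concentration"].to_numpy(dtype=float),
        sub[feature].to_numpy(dtype=float),
    )


def run_chemical(
    profiles: pd.DataFrame,
    chemical: str,
    features: list[str] | None = None,
    p_cut: float = 0.05,
    fc_cut: float = 1.0,
    bmr_factor: float = BMR_FACTOR,
    poly_degrees: tuple[int, ...] = (1, 2),
    compute_bmcl_flag: bool = True,
    level: float = 0.95,
    n_starts: int = 8,
    max_iter: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every feature of one chemical and return the per-feature table.

    Features failing the ANOVA + fold-change prefilter carry no fit; the
    rest carry the selected model, its BMC/BMCL, direction and flags.
    Deterministic given ``seed`` (the multi-start jitter is seeded per
    feature).  Assumes cytotoxic doses were already excluded upstream.
    """
    from .profiles import feature_columns  # local import to avoid cycle

    if features is None:
        features = [c for c in feature_columns(profiles) if c != "cell_count"]
    probe = series_from_profiles(profiles, chemical, features[0])
    n_distinct = probe.unique_doses.size
    if n_distinct < 3:
        logger.warning(
            "run_chemical(%s): only %d distinct doses remain; skipped",
            chemical, n_distinct,
        )
        return pd.DataFrame()
    degrees = tuple(d for d in poly_degrees if d < n_distinct - 1)

    rows = []
    ss = np.random.SeedSequence(seed)
    feature_seeds = ss.generate_state(len(features))
    for feat, fseed in zip(features, feature_seeds):
        series = series_from_profiles(profiles, chemical, feat)
        row: dict = {"chemical": chemical, "feature": feat}
        try:
            an = anova_prefilter(series, p_cut=p_cut, fc_cut=fc_cut)
        except ValueError:
            an = AnovaResult(math.nan, math.nan, math.nan, False)
        row.update(
            f_stat=an.f_stat, p_value=an.p_value,
            max_abs_diff=an.max_abs_diff, prefilter_pass=an.passed,
        )
        if an.passed:
            fits = []
            for deg in degrees:
                fits.append(fit_model(series, "poly", degree=deg, seed=int(fseed)))
            fits.append(
                fit_model(series, "power", n_starts=n_starts,
                          max_iter=max_iter, seed=int(fseed))
            )
            fits.append(
                fit_model(series, "hill", n_starts=n_starts,
                          max_iter=max_iter, seed=int(fseed))
            )
            best = select_best(fits)
            if best is not None:
                bmc = best.bmc(
                    bmr_factor=bmr_factor, compute_bmcl=compute_bmcl_flag,
                    level=level,
                )
                row.update(
                    family=best.family,
                    params=repr(best.params),
                    sigma=best.sigma, aic=best.aic,
                    bmc=bmc.bmc, bmcl=bmc.bmcl, direction=bmc.direction,
                    hill_k_flag=bmc.hill_k_flag, within_range=bmc.within_range,
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    for col, default in (
        ("family", None), ("params", None), ("sigma", math.nan),
        ("aic", math.nan), ("bmc", math.nan), ("bmcl", math.nan),
        ("direction", None), ("hill_k_flag", False), ("within_range", False),
    ):
        if col not in out.columns:
            out[col] = default
    for col in ("hill_k_flag", "within_range"):
        out[col] = out[col].map(lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else False)
    return out
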
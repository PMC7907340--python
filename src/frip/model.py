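"""Maximum-likelihood fitting of the Rogers random-predator model.

The central objects follow the statsmodels convention: a
:class:`RogersModel` is built from trial data (or a DataFrame via
:meth:`RogersModel.from_dataframe`), its :meth:`~RogersModel.fit` returns a
:class:`RogersResults` carrying estimates, standard errors, Wald tests and
a ``summary()`` table, and bootstrap resampling hangs off the results
object.

Likelihood.  Each trial offers ``N_O`` prey for ``T`` days; the number
consumed is modelled as Binomial(``N_O``, ``p``) with success probability
``p = N_e(a, h, T, N_O) / N_O`` from the Rogers expected-consumption
curve.  The likelihood is maximised over ``(log a, log h)`` so the search
is unconstrained and boundary-safe; standard errors come from the inverse
observed information evaluated on the natural ``(a, h)`` scale.

Between-group comparison uses the indicator parameterisation
``a = a_base + Da * I`` (``I = 1`` for comparator trials): because the two
datasets are disjoint the joint maximum coincides with the two separate
fits, and the differences are reported with the convention
``D = base - comparator`` together with Wald z and p from the joint
observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .rogers import _lambert_w0_of_exp, rogers_expected_consumption

__all__ = [
    "RogersModel",
    "RogersResults",
    "BootstrapEnsemble",
    "FRComparison",
    "FRTypeResult",
    "classify_fr_type",
    "fit_rogers",
    "compare_fits",
    "bootstrap_fit",
]

_PCLIP = 1e-9


def _prepare_trials(data: pd.DataFrame, duration=None):
    """Extract (offered, consumed, T) arrays from a trial table.

    Excluded trials (predator moulted or died) never enter fits.  Prey
    dead without signs of predation count as background mortality: they
    are neither consumed nor removed from the offered total.
    """
    df = data
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    offered = df["density_offered"].to_numpy(dtype=float)
    consumed = df["consumed"].to_numpy(dtype=float)
    if duration is None:
        durs = df["duration_days"].unique()
        if len(durs) != 1:
            raise ValueError(
                "trial table mixes durations %s; pass `duration` explicitly" % durs
            )
        duration = float(durs[0])
    return offered, consumed, float(duration)


def _suffstats(offered, consumed):
    """Collapse trials to per-density sufficient statistics."""
    ud, inv = np.unique(offered, return_inverse=True)
    eaten = np.bincount(inv, weights=consumed, minlength=len(ud))
    total = np.bincount(inv, weights=offered, minlength=len(ud))
    return ud, eaten, total


class RogersModel:
    """Rogers random-predator (Type II) functional-response model.

    Parameters
    ----------
    consumed, offered : array-like of int
        Per-trial prey consumed and initial prey density.
    duration : float
        Trial length in days (shared across trials).
    name : str
        Label used in summaries.
    """

    def __init__(self, consumed, offered, duration, name="predator"):
        self.consumed = np.asarray(consumed, dtype=float)
        self.offered = np.asarray(offered, dtype=float)
        if self.consumed.shape != self.offered.shape:
            raise ValueError("consumed and offered must have the same length")
        if np.any(self.consumed < 0) or np.any(self.consumed > self.offered):
            raise ValueError("consumed must lie in [0, offered] for every trial")
        if not duration > 0:
            raise ValueError("duration must be positive")
        self.duration = float(duration)
        self.name = name
        self.nobs = len(self.consumed)
        uniq = np.unique(self.offered)
        if len(uniq) < 3:
            raise ValueError("need >= 3 distinct prey densities to fit the model")
        if self.consumed.sum() == 0:
            raise ValueError("no prey consumed in any trial; the model is not fittable")
        if np.all((self.consumed == 0) | (self.consumed == self.offered)):
            raise ValueError(
                "all-or-nothing consumption at every trial places the optimum "
                "on the parameter boundary"
            )
        self._ud, self._eaten, self._total = _suffstats(self.offered, self.consumed)
        # binomial coefficient term: constant in (a, h)
        self._logbinom = float(
            np.sum(
                special.gammaln(self.offered + 1)
                - special.gammaln(self.consumed + 1)
                - special.gammaln(self.offered - self.consumed + 1)
            )
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, duration=None, name=None) -> "RogersModel":
        """Build from a trial table with the standard columns.

        Requires ``density_offered`` and ``consumed``; uses
        ``duration_days`` when ``duration`` is not given and drops rows
        flagged ``excluded``.
        """
        offered, consumed, T = _prepare_trials(data, duration)
        if name is None:
            groups = data.get("predator_group")
            name = str(groups.iloc[0]) if groups is not None and len(groups) else "predator"
        return cls(consumed, offered, T, name=name)

    # -- likelihood ----------------------------------------------------

    def _mean_proportion(self, a, h):
        # fast inline of the Lambert-W Rogers solution on the cached
        # unique densities (validation already done at construction)
        ud, T = self._ud, self.duration
        if h == 0:
            ne = ud * (-np.expm1(-a * T))
        else:
            log_arg = np.log(a * h * ud) - a * (T - h * ud)
            w = _lambert_w0_of_exp(log_arg)
            ne = np.clip(ud - w / (a * h), 0.0, ud)
        return np.clip(ne / ud, _PCLIP, 1.0 - _PCLIP)

    def loglike(self, params):
        """Binomial log-likelihood at ``params = (a, h)``."""
        a, h = params
        if a <= 0 or h < 0:
            return -np.inf
        p = self._mean_proportion(a, h)
        ll = np.sum(self._eaten * np.log(p) + (self._total - self._eaten) * np.log1p(-p))
        return ll + self._logbinom

    def _nll_log(self, theta):
        a, h = np.exp(theta)
        if not np.isfinite(a) or not np.isfinite(h) or a > 1e4 or h > 1e4:
            return 1e12
        return -self.loglike((a, h))

    def _start_values(self):
        """Moment-style starting values from the curve shape."""
        mean_by_d = self._eaten / (self._total / self._ud)
        h0 = np.clip(self.duration / max(mean_by_d.max(), 0.5), 1e-3, 50.0)
        k = max(2, len(self._ud) // 3)
        pbar = np.clip(np.mean((mean_by_d / self._ud)[:k]), 1e-3, 0.999)
        a0 = np.clip(-np.log1p(-pbar) / self.duration, 1e-3, 50.0)
        return a0, h0

    def fit(self, start=None, n_starts=5, compute_cov=True, options=None) -> "RogersResults":
        """Maximise the likelihood; multi-start Nelder-Mead on log scale.

        ``n_starts`` deterministic jittered starts guard against local
        optima; the best likelihood is kept.  ``compute_cov=False`` skips
        the observed-information standard errors (used by the bootstrap,
        which only needs point estimates per resample).
        """
        a0, h0 = start if start is not None else self._start_values()
        candidates = [
            (a0, h0),
            (2 * a0, h0 / 2),
            (a0 / 2, 2 * h0),
            (3 * a0, h0),
            (a0, 3 * h0),
        ][: max(1, n_starts)]
        if options is None:
            options = dict(xatol=1e-8, fatol=1e-10, maxiter=600)
        best = None
        for s in candidates:
            res = optimize.minimize(
                self._nll_log,
                np.log(np.maximum(s, 1e-8)),
                method="Nelder-Mead",
                options=options,
            )
            if best is None or res.fun < best.fun:
                best = res
        a, h = np.exp(best.x)
        if compute_cov:
            cov, converged = self._covariance(a, h)
        else:
            cov, converged = np.full((2, 2), np.nan), best.success
        return RogersResults(self, np.array([a, h]), cov, -best.fun,
                             converged=bool(converged and best.fun < 1e11))

    def _covariance(self, a, h):
        """Inverse observed information at (a, h), natural scale."""
        x = np.array([a, h])
        eps = 1e-4 * np.maximum(x, 1e-3)

        def f(p):
            if p[0] <= 0 or p[1] < 0:
                return 1e12
            return -self.loglike(p)

        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = eps[i]
                ej[j] = eps[j]
                H[i, j] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps[i] * eps[j])
        try:
            cov = np.linalg.inv(H)
            ok = np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0)
        except np.linalg.LinAlgError:
            cov, ok = np.full((2, 2), np.nan), False
        return cov, ok


class RogersResults:
    """Fit results for :class:`RogersModel`.

    Attributes mirror statsmodels results: ``params`` (Series with
    ``a`` and ``h``), ``bse``, ``zvalues``, ``pvalues``, ``llf``,
    ``converged``, plus the derived feeding-rate conventions
    ``max_feeding_rate`` (= 1/(T h), prey per experiment) and
    ``max_feeding_rate_per_day`` (= 1/h).
    """

    _names = ["a", "h"]

    def __init__(self, model, params, cov, llf, converged=True):
        self.model = model
        self.params = pd.Series(params, index=self._names)
        self.cov_params = pd.DataFrame(cov, index=self._names, columns=self._names)
        self.bse = pd.Series(np.sqrt(np.abs(np.diag(cov))), index=self._names)
        self.llf = float(llf)
        self.converged = converged
        self.nobs = model.nobs
        self.duration = model.duration
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self._names
        )

    @property
    def a(self):
        return float(self.params["a"])

    @property
    def h(self):
        return float(self.params["h"])

    @property
    def max_feeding_rate(self):
        """Asymptotic consumption per experiment, 1/(T h)."""
        return 1.0 / (self.duration * self.h)

    @property
    def max_feeding_rate_per_day(self):
        """Asymptotic consumption per day, 1/h."""
        return 1.0 / self.h

    def predict(self, density):
        """Expected consumption over the trial at the given density."""
        return rogers_expected_consumption(self.a, self.h, self.duration, density)

    def bootstrap(self, n_boot=2000, seed=None, stratify_by_density=False, grid=None):
        """Nonparametric bootstrap of the fit; see :func:`bootstrap_fit`."""
        return bootstrap_fit(
            self, n_boot=n_boot, seed=seed, stratify_by_density=stratify_by_density,
            grid=grid,
        )

    def summary(self) -> str:
        lines = [
            "Rogers random-predator model: %s" % self.model.name,
            "n trials = %d, T = %g days, log-likelihood = %.3f, converged = %s"
            % (self.nobs, self.duration, self.llf, self.converged),
            "",
            "%-24s %10s %10s %8s %10s" % ("parameter", "estimate", "SE", "z", "P>|z|"),
        ]
        label = {"a": "attack coefficient a", "h": "handling time h (d)"}
        for k in self._names:
            lines.append(
                "%-24s %10.4f %10.4f %8.3f %10.4g"
                % (label[k], self.params[k], self.bse[k], self.zvalues[k], self.pvalues[k])
            )
        lines += [
            "",
            "max feeding rate: %.4f prey/experiment (1/(T*h)), %.4f prey/day (1/h)"
            % (self.max_feeding_rate, self.max_feeding_rate_per_day),
        ]
        return "\n".join(lines)


# -- convenience wrappers ----------------------------------------------


def fit_rogers(trials: pd.DataFrame, duration=None, **fit_kw) -> RogersResults:
    """Fit the random-predator model to a trial table."""
    return RogersModel.from_dataframe(trials, duration=duration).fit(**fit_kw)


# -- bootstrap ----------------------------------------------------------


@dataclass
class BootstrapEnsemble:
    """Resampled Rogers fits and derived uncertainty summaries.

    ``params`` holds one (a, h) row per converged resample.  ``grid`` and
    the band arrays give the percentile confidence band of predicted
    consumption; feeding-rate means/SEs are reported in both conventions
    (per experiment, 1/(T h); per day, 1/h).
    """

    n_boot: int
    params: np.ndarray
    n_failed: int
    duration: float
    grid: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    point_prediction: np.ndarray
    level: float
    max_feeding_rate_mean: float
    max_feeding_rate_se: float
    max_feeding_rate_per_day_mean: float
    max_feeding_rate_per_day_se: float
    seed: object = None

    @property
    def n_converged(self):
        return len(self.params)

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.grid,
                "predicted": self.point_prediction,
                "lower": self.band_lower,
                "upper": self.band_upper,
            }
        )


def bootstrap_fit(
    results: RogersResults,
    n_boot=2000,
    seed=None,
    stratify_by_density=False,
    grid=None,
    level=0.95,
) -> BootstrapEnsemble:
    """Nonparametric bootstrap of a fitted random-predator model.

    Trials (rows) are resampled with replacement — optionally within
    density strata — and refit from the point estimate.  Percentile
    confidence bands of predicted consumption are computed on ``grid``
    (default: 100 points spanning the observed densities).  The
    feeding-rate mean +/- SE across resamples supports the small
    (n = 30) ensembles used to propagate per-capita effect uncertainty
    into impact metrics.
    """
    model = results.model
    rng = np.random.default_rng(seed)
    n = model.nobs
    offered, consumed = model.offered, model.consumed
    if grid is None:
        grid = np.linspace(max(offered.min(), 1e-6), offered.max(), 100)
    grid = np.asarray(grid, dtype=float)

    if stratify_by_density:
        strata = {d: np.flatnonzero(offered == d) for d in np.unique(offered)}

    draws = []
    preds = []
    n_failed = 0
    start = (results.a, results.h)
    for _ in range(int(n_boot)):
        if stratify_by_density:
            idx = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True) for ix in strata.values()]
            )
        else:
            idx = rng.integers(0, n, size=n)
        try:
            m = RogersModel(consumed[idx], offered[idx], model.duration, name=model.name)
            r = m.fit(start=start, n_starts=1, compute_cov=False,
                      options=dict(xatol=1e-6, fatol=1e-8, maxiter=300))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not np.isfinite(r.a) or not np.isfinite(r.h) or r.h <= 0:
            n_failed += 1
            continue
        draws.append((r.a, r.h))
        preds.append(rogers_expected_consumption(r.a, r.h, model.duration, grid))
    if n_failed > 0.5 * n_boot:
        raise RuntimeError(
            "bootstrap failed to converge on %d of %d resamples" % (n_failed, n_boot)
        )
    params = np.asarray(draws)
    preds = np.asarray(preds)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(preds, 100 * alpha, axis=0)
    upper = np.percentile(preds, 100 * (1 - alpha), axis=0)
    fr_exp = 1.0 / (model.duration * params[:, 1])
    fr_day = 1.0 / params[:, 1]
    k = len(params)
    return BootstrapEnsemble(
        n_boot=int(n_boot),
        params=params,
        n_failed=n_failed,
        duration=model.duration,
        grid=grid,
        band_lower=lower,
        band_upper=upper,
        point_prediction=rogers_expected_consumption(
            results.a, results.h, model.duration, grid
        ),
        level=level,
        max_feeding_rate_mean=float(fr_exp.mean()),
        max_feeding_rate_se=float(fr_exp.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
        max_feeding_rate_per_day_mean=float(fr_day.mean()),
        max_feeding_rate_per_day_se=float(fr_day.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
        seed=seed,
    )


# -- indicator-variable comparison --------------------------------------


@dataclass
class FRComparison:
    """Difference in (a, h) between two predator groups.

    ``Da = a_base - a_comparator`` and ``Dh = h_base - h_comparator``
    (the convention of the indicator-variable joint fit), with Wald z
    statistics and two-sided normal p-values from the joint observed
    information.
    """

    base: RogersResults
    comparator: RogersResults
    Da: float
    Dh: float
    se_Da: float
    se_Dh: float
    z_Da: float = field(init=False)
    z_Dh: float = field(init=False)
    p_Da: float = field(init=False)
    p_Dh: float = field(init=False)

    def __post_init__(self):
        self.z_Da = self.Da / self.se_Da if self.se_Da > 0 else np.nan
        self.z_Dh = self.Dh / self.se_Dh if self.se_Dh > 0 else np.nan
        self.p_Da = float(2 * stats.norm.sf(abs(self.z_Da)))
        self.p_Dh = float(2 * stats.norm.sf(abs(self.z_Dh)))

    def summary(self) -> str:
        rows = [
            ("Da (base - comparator)", self.Da, self.se_Da, self.z_Da, self.p_Da),
            ("Dh (base - comparator)", self.Dh, self.se_Dh, self.z_Dh, self.p_Dh),
        ]
        lines = [
            "Indicator-variable comparison: base = %s, comparator = %s"
            % (self.base.model.name, self.comparator.model.name),
            "%-24s %10s %10s %8s %10s" % ("difference", "estimate", "SE", "z", "P>|z|"),
        ]
        for name, est, se, z, p in rows:
            lines.append("%-24s %10.4f %10.4f %8.3f %10.4g" % (name, est, se, z, p))
        return "\n".join(lines)


def compare_fits(
    trials_base,
    trials_comparator,
    duration_base=None,
    duration_comparator=None,
    **fit_kw,
) -> FRComparison:
    """Joint indicator-variable comparison of two trial datasets.

    The joint model ``a = a_base + Da*I``, ``h = h_base + Dh*I`` with
    ``I = 1`` on comparator trials factorises over the two disjoint
    datasets, so the joint optimum equals the two separate fits and the
    reported differences are ``base - comparator``.  Standard errors of
    the differences come from the block-diagonal joint observed
    information, i.e. the separate-fit variances add.
    """
    try:
        rb = fit_rogers(trials_base, duration=duration_base, **fit_kw)
    except ValueError as exc:
        raise ValueError("base dataset is not fittable: %s" % exc) from exc
    try:
        rc = fit_rogers(trials_comparator, duration=duration_comparator, **fit_kw)
    except ValueError as exc:
        raise ValueError("comparator dataset is not fittable: %s" % exc) from exc
    return FRComparison(
        base=rb,
        comparator=rc,
        Da=rb.a - rc.a,
        Dh=rb.h - rc.h,
        se_Da=float(np.hypot(rb.bse["a"], rc.bse["a"])),
        se_Dh=float(np.hypot(rb.bse["h"], rc.bse["h"])),
    )


# -- phenomenological type classification --------------------------------


@dataclass
class FRTypeResult:
    """Outcome of the phenomenological response-type screen.

    The shape of proportion consumed versus density decides the type:
    a significantly negative first-order (linear) term marks a Type II
    (hyperbolic) response; a significant positive first-order term
    superseded by a significant negative second-order term marks Type
    III (sigmoid); anything else is reported as indeterminate.
    """

    first_order_coef: float
    first_order_se: float
    first_order_p: float
    classified_type: str
    dispersion: float
    second_order_coef: float | None = None
    second_order_se: float | None = None
    second_order_p: float | None = None
    alpha: float = 0.05


def classify_fr_type(
    trials: pd.DataFrame, include_quadratic=False, alpha=0.05
) -> FRTypeResult:
    """Classify the functional-response type from a trial table.

    Logistic regression of proportion consumed on prey density (and
    optionally density squared), with a quasibinomial dispersion
    estimated from the Pearson statistic and dispersion-adjusted t tests
    at significance level ``alpha``.
    """
    offered, consumed, _ = _prepare_trials(trials)
    if len(np.unique(offered)) < 2:
        raise ValueError("need >= 2 distinct prey densities to classify the response")
    if consumed.sum() == 0:
        warnings.warn("no prey consumed in any trial; response type indeterminate")
        return FRTypeResult(
            first_order_coef=np.nan,
            first_order_se=np.nan,
            first_order_p=np.nan,
            classified_type="indeterminate",
            dispersion=np.nan,
            alpha=alpha,
        )
    endog = np.column_stack([consumed, offered - consumed])
    cols = {"density": offered}
    if include_quadratic:
        cols["density2"] = offered**2
    exog = sm.add_constant(pd.DataFrame(cols))
    fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(scale="X2")
    df_resid = fit.df_resid
    coefs, bses = fit.params, fit.bse
    tvals = coefs / bses
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df_resid), index=coefs.index)
    p1, c1 = pvals["density"], coefs["density"]
    second = None
    if include_quadratic:
        second = (coefs["density2"], bses["density2"], pvals["density2"])
    if include_quadratic and c1 > 0 and p1 < alpha and second[0] < 0 and second[2] < alpha:
        ftype = "III"
    elif c1 < 0 and p1 < alpha:
        ftype = "II"
    else:
        ftype = "indeterminate"
    return FRTypeResult(
        first_order_coef=float(c1),
        first_order_se=float(bses["density"]),
        first_order_p=float(p1),
        classified_type=ftype,
        dispersion=float(fit.scale),
        second_order_coef=float(second[0]) if second else None,
        second_order_se=float(second[1]) if second else None,
        second_order_p=float(second[2]) if second else None,
        alpha=alpha,
    )
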
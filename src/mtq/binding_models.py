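"""Model fitting and statistics for membrane-binding measurements.

Two statsmodels-style model classes form the core:

* :class:`HillBindingModel` — nonlinear least-squares fit of the Langmuir
  adsorption isotherm with Hill expansion,

      B_bound = Bmax · [Domain]^H / ([Domain]^H + Kd'^H),

  estimating the apparent dissociation constant Kd', the saturation
  amplitude Bmax and the apparent Hill coefficient H, with 95% confidence
  intervals from the asymptotic covariance (t quantile, n − 3 df).

* :class:`BindingRateModel` — ordinary least squares on the linear part of
  a binding-ratio time course; the linear part is located by a sliding
  window (documented rule, reported in the result so rates are auditable).

Also here: the Welch (unequal-variance) two-tailed t-test with the usual
star categories, the FOV-to-nucleus join used for correlation plots (every
nucleus in a field of view inherits that FOV's ER metric), and the osmotic
dilution arithmetic for hypoosmotic-shock media.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .nuclear_binding import BindingTimeSeries
from .synthdata import hill_curve

# ---------------------------------------------------------------------------
# Hill-Langmuir isotherm


@dataclass
class HillFitResult:
    """Point estimates, 95% CIs and diagnostics of a Hill-Langmuir fit."""

    kd_prime: float
    bmax: float
    h: float
    ci95: dict[str, tuple[float, float]]
    bse: dict[str, float]
    rss: float
    n: int

    def __post_init__(self) -> None:
        if not (self.kd_prime > 0 and self.bmax > 0 and self.h > 0):
            raise ValueError("Hill parameters must be positive")
        for name, est in (("kd_prime", self.kd_prime), ("bmax", self.bmax), ("h", self.h)):
            lo, hi = self.ci95[name]
            if not (lo <= est <= hi):
                raise ValueError(f"CI for {name} does not bracket the estimate")

    def predict(self, concentrations) -> np.ndarray:
        return hill_curve(concentrations, self.bmax, self.kd_prime, self.h)


class HillBindingResults:
    """Results wrapper with statsmodels-flavoured accessors."""

    param_names = ("bmax", "kd_prime", "h")

    def __init__(self, model: "HillBindingModel", params: np.ndarray, rss: float):
        self.model = model
        self.params = pd.Series(params, index=self.param_names)
        self.rss = float(rss)
        self.nobs = len(model.endog)
        self.df_resid = self.nobs - 3
        self._cov = self._asymptotic_cov(params)
        self.bse = pd.Series(np.sqrt(np.diag(self._cov)), index=self.param_names)

    def _jacobian(self, params: np.ndarray) -> np.ndarray:
        bmax, kd, h = params
        c = self.model.exog
        u = hill_curve(c, 1.0, kd, h)
        with np.errstate(divide="ignore"):
            log_ratio = np.where(c > 0, np.log(np.where(c > 0, kd / c, 1.0)), 0.0)
        d_bmax = u
        d_kd = -bmax * u * (1 - u) * h / kd
        d_h = -bmax * u * (1 - u) * log_ratio
        return np.column_stack([d_bmax, d_kd, d_h])

    def _asymptotic_cov(self, params: np.ndarray) -> np.ndarray:
        J = self._jacobian(params)
        s2 = self.rss / max(self.df_resid, 1)
        JtJ = J.T @ J
        try:
            return s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            return s2 * np.linalg.pinv(JtJ)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tq = stats.t.ppf(1 - alpha / 2, max(self.df_resid, 1))
        lo = self.params - tq * self.bse
        hi = self.params + tq * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def fittedvalues(self) -> np.ndarray:
        return hill_curve(self.model.exog, *self.params)

    def predict(self, concentrations) -> np.ndarray:
        return hill_curve(concentrations, *self.params)

    def as_fit_result(self) -> HillFitResult:
        ci = self.conf_int()
        # CI lower bounds can cross zero for weakly identified fits; the
        # parameters themselves are positive by construction
        return HillFitResult(
            kd_prime=self.params["kd_prime"],
            bmax=self.params["bmax"],
            h=self.params["h"],
            ci95={
                k: (min(ci.loc[k, "lower"], self.params[k]),
                    max(ci.loc[k, "upper"], self.params[k]))
                for k in self.param_names
            },
            bse=dict(self.bse),
            rss=self.rss,
            n=self.nobs,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Hill-Langmuir adsorption isotherm fit",
            f"  n = {self.nobs} concentrations, RSS = {self.rss:.6g}, df = {self.df_resid}",
            f"  {'param':<9}{'estimate':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        for k in self.param_names:
            lines.append(
                f"  {k:<9}{self.params[k]:>12.5g}{self.bse[k]:>12.4g}"
                f"{ci.loc[k, 'lower']:>12.5g}{ci.loc[k, 'upper']:>12.5g}"
            )
        return "\n".join(lines)


class HillBindingModel:
    """Nonlinear least-squares Hill-Langmuir isotherm model.

    Parameters are optimised in log space (positivity enforced), with a
    multi-start over Kd' at the concentration quartiles and H in
    {0.5, 1, 2}; the best converged start (lowest RSS) wins.
    """

    def __init__(self, bound, concentrations):
        self.endog = np.asarray(bound, dtype=float)
        self.exog = np.asarray(concentrations, dtype=float)
        if self.endog.shape != self.exog.shape or self.endog.ndim != 1:
            raise ValueError("bound and concentrations must be equal-length 1D")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("bound values must be finite")
        if np.any(self.exog < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.exog)) < 4:
            raise ValueError("need >= 4 distinct concentrations (3 parameters)")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        bound: str = "bound",
        concentration: str = "concentration_nM",
    ) -> "HillBindingModel":
        return cls(data[bound].to_numpy(), data[concentration].to_numpy())

    def _residuals(self, log_params: np.ndarray) -> np.ndarray:
        bmax, kd, h = np.exp(log_params)
        return hill_curve(self.exog, bmax, kd, h) - self.endog

    def fit(self) -> HillBindingResults:
        pos = self.exog[self.exog > 0]
        kd_starts = np.unique(np.percentile(pos, [25, 50, 75]))
        bmax0 = max(self.endog.max(), 1e-9)
        best = None
        diagnostics = []
        for kd0 in kd_starts:
            for h0 in (0.5, 1.0, 2.0):
                x0 = np.log([bmax0, kd0, h0])
                try:
                    sol = optimize.least_squares(
                        self._residuals, x0, method="lm", xtol=1e-14, ftol=1e-14
                    )
                except Exception as exc:  # pragma: no cover - solver edge
                    diagnostics.append(f"start(kd={kd0:g},h={h0:g}): {exc}")
                    continue
                if not sol.success:
                    diagnostics.append(f"start(kd={kd0:g},h={h0:g}): {sol.message}")
                    continue
                rss = float(2 * sol.cost)
                if best is None or rss < best[1]:
                    best = (np.exp(sol.x), rss)
        if best is None:
            raise RuntimeError(
                "Hill fit failed to converge from every start:\n" + "\n".join(diagnostics)
            )
        return HillBindingResults(self, best[0], best[1])


def fit_hill(
    curve: pd.DataFrame,
    bound: str = "bound",
    concentration: str = "concentration_nM",
) -> HillFitResult:
    """Fit the Hill-Langmuir isotherm to a (concentration, bound) table."""
    return HillBindingModel.from_dataframe(curve, bound, concentration).fit().as_fit_result()


# ---------------------------------------------------------------------------
# binding rate (OLS on the linear part)


@dataclass
class RateEstimate:
    """OLS slope of the linear part of a binding-ratio time course."""

    slope: float  # ratio units per minute
    intercept: float
    window: tuple[int, int]  # frame indices, end exclusive
    r_squared: float
    stderr: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r² out of [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))


class BindingRateResults(RateEstimate):
    pass


class BindingRateModel:
    """Locate the linear rise of a binding time course and fit its slope.

    The published-figure readout reports an adsorption rate from the linear
    portion of ratio(t).  "Linear part" is defined here as the sliding
    window of ceil(window_fraction·n) frames that maximises
    slope·sign(net change) among windows with r² >= 0.9 (falling back to
    the maximum-r² window when none qualifies); the chosen window bounds
    are part of the result.
    """

    def __init__(self, series: BindingTimeSeries | pd.DataFrame, column: str = "ratio_norm"):
        if isinstance(series, BindingTimeSeries):
            self.times = np.asarray(series.times_min, dtype=float)
            self.values = np.asarray(getattr(series, column), dtype=float)
        else:
            self.times = series["time_min"].to_numpy(dtype=float)
            self.values = series[column].to_numpy(dtype=float)
        if len(self.times) < 5:
            raise ValueError("need at least 5 frames to estimate a rate")

    def _ols(self, t: np.ndarray, y: np.ndarray):
        res = sm.OLS(y, sm.add_constant(t)).fit()
        return res.params[1], res.params[0], res.rsquared, res.bse[1]

    def fit(self, window_fraction: float = 0.3, r2_min: float = 0.9) -> BindingRateResults:
        n = len(self.times)
        w = max(int(np.ceil(window_fraction * n)), 3)
        if w > n:
            raise ValueError("window longer than series")
        net_sign = np.sign(self.values[-1] - self.values[0]) or 1.0
        candidates = []
        for start in range(0, n - w + 1):
            t = self.times[start : start + w]
            y = self.values[start : start + w]
            if np.allclose(y, y[0]):
                slope, icpt, r2, se = 0.0, float(y[0]), 1.0, 0.0
            else:
                slope, icpt, r2, se = self._ols(t, y)
            candidates.append((start, slope, icpt, r2, se))
        eligible = [c for c in candidates if c[3] >= r2_min]
        if eligible:
            best = max(eligible, key=lambda c: c[1] * net_sign)
        else:
            best = max(candidates, key=lambda c: c[3])
        start, slope, icpt, r2, se = best
        return BindingRateResults(
            slope=float(slope),
            intercept=float(icpt),
            window=(start, start + w),
            r_squared=float(r2),
            stderr=float(se),
        )


def estimate_rate(
    ts: BindingTimeSeries | pd.DataFrame,
    window_fraction: float = 0.3,
    column: str = "ratio_norm",
) -> RateEstimate:
    """OLS binding rate on the linear part of a ratio time course."""
    return BindingRateModel(ts, column=column).fit(window_fraction=window_fraction)


# ---------------------------------------------------------------------------
# Welch test with star categories


STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    stars: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value out of [0, 1]")


def star_category(p: float) -> str:
    """Significance stars: *P≤0.05, **P≤0.01, ***P≤0.001, ****P≤0.0001."""
    for thresh, stars in STAR_THRESHOLDS:
        if p <= thresh:
            return stars
    return "ns"


def welch_ttest(a, b) -> TestResult:
    """Two-tailed t-test assuming unequal variances (Welch).

    Degenerate zero-variance equal-mean input returns t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(t), pvalue=float(p), stars=star_category(float(p)),
        n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------------------------
# FOV-to-nucleus correlation join


def join_fov_correlation(
    nucleus_table: pd.DataFrame,
    fov_table: pd.DataFrame,
    on: tuple[str, ...] = ("fov_id",),
) -> pd.DataFrame:
    """Broadcast per-FOV ER metrics to every nucleus in that FOV.

    ER morphology is quantified per field of view while binding is per
    nucleus; for correlation plots every nucleus inherits its FOV's value.
    Nuclei without a matching FOV are excluded (logged); duplicate FOV rows
    per key are an error.
    """
    keys = list(on)
    if fov_table.duplicated(subset=keys).any():
        dups = fov_table.loc[fov_table.duplicated(subset=keys), keys]
        raise ValueError(f"duplicate FOV rows for keys:\n{dups}")
    merged = nucleus_table.merge(fov_table, on=keys, how="left", indicator=True)
    missing = merged["_merge"] == "left_only"
    if missing.any():
        import logging

        logging.getLogger("mtq").warning(
            "join_fov_correlation: %d nuclei without FOV match excluded", missing.sum()
        )
    return merged.loc[~missing].drop(columns="_merge").reset_index(drop=True)


# ---------------------------------------------------------------------------
# osmolarity arithmetic

#: osmolarity of the dilution medium (water + 1.26 mM CaCl2), assuming ideal
#: full dissociation into three osmolytes: 3 x 1.26 = 3.78 mOsm
WATER_CACL2_OSM = 3.78
#: isosmotic stock imaging-medium osmolarity, mOsm
ISOSMOTIC_MEDIUM_OSM = 341.0


def dilution_osmolarity(
    start_osm: float,
    v_start: float,
    v_diluent: float,
    diluent_osm: float = WATER_CACL2_OSM,
) -> float:
    """Osmotic shock Δπ (mOsm) from volumetric mixing of two media.

    final = (v_start·start_osm + v_diluent·diluent_osm) / (v_start + v_diluent);
    Δπ = start_osm − final.  Returns the unrounded value.
    """
    if v_start <= 0 or v_diluent < 0:
        raise ValueError("volumes must be positive (diluent may be zero)")
    if start_osm < 0 or diluent_osm < 0:
        raise ValueError("osmolarities must be non-negative")
    final = (v_start * start_osm + v_diluent * diluent_osm) / (v_start + v_diluent)
    return start_osm - final
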
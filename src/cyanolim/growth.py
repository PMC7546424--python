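"""Exponential growth-rate estimation and quota-Monod nutrient kinetics.

Growth rates are computed from optical-density (OD) time series the way
batch-culture studies report them: the specific growth rate over the
exponential window is the endpoint log-slope

    mu = (ln OD_f - ln OD_i) / (T_f - T_i)        [day^-1]

and the generation time is Tg = ln(2)/mu.  Nutrient dependence of mu is
modelled with the Monod equation with a minimum cell quota,

    mu(Q) = mu'_max * (Q - Q_min) / Q

where Q is the initial nutrient concentration (e.g. NO3- or PO4(3-)),
Q_min the minimal concentration supporting growth, and mu'_max the
maximum specific growth rate.  The half-velocity concentration K_mu is
the Q at which mu reaches mu'_max/2; under this model that is exactly
2*Q_min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "MonodFit",
    "ExponentialGrowthModel",
    "MonodModel",
    "fit_exponential",
    "fit_monod",
    "half_velocity",
    "empirical_half_velocity",
    "generation_time",
    "fit_replicates",
    "summarize_treatments",
    "read_growth_csv",
]


class FittingError(RuntimeError):
    """Nonlinear fit failed or is degenerate; message carries diagnostics."""


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate's (time, OD) trajectory.

    times are in days and must be strictly increasing; OD is dimensionless
    and strictly positive.  wavelength_nm records the read wavelength
    (750 nm for unicellular, 975 nm for filamentous cultures).
    """

    treatment_id: str
    replicate_id: str
    times: tuple
    od: tuple
    wavelength_nm: float = 750.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.size != y.size:
            raise ValueError("times and od must have equal length")
        if t.size < 3:
            raise ValueError("a growth series needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(y > 0):
            raise ValueError("optical densities must be strictly positive")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "od", tuple(y))


@dataclass(frozen=True)
class GrowthFit:
    """Endpoint exponential fit over one window of a growth series."""

    mu_per_day: float
    tg_days: float  # NaN when mu <= 0 (declining or flat culture)
    window: tuple  # (i, j) inclusive indices into the series
    r_squared_loglinear: float
    treatment_id: str = ""
    replicate_id: str = ""

    @property
    def tg_defined(self) -> bool:
        return math.isfinite(self.tg_days)


@dataclass(frozen=True)
class MonodFit:
    """Fitted quota-Monod parameters for one nutrient-response curve."""

    mu_max_prime: float
    q_min: float
    k_mu: float
    residual_sse: float
    k_mu_empirical: float = float("nan")

    def predict(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.mu_max_prime * (q - self.q_min) / q


def generation_time(mu: float) -> float:
    """Tg = ln(2)/mu in days; NaN for non-growing cultures (mu <= 0)."""
    if mu <= 0:
        return float("nan")
    return math.log(2.0) / mu


def _loglinear_r2(t: np.ndarray, logy: np.ndarray) -> float:
    if t.size == 2:
        return 1.0
    res = stats.linregress(t, logy)
    return float(res.rvalue**2)


def _auto_window(t: np.ndarray, logy: np.ndarray, min_r2: float = 0.95):
    """Pick the exponential window of a log-OD curve.

    All contiguous windows of >= 3 points are ranked by endpoint slope,
    subject to log-linearity R^2 >= min_r2; ties prefer the longer window,
    then the earlier start.  If no window is log-linear enough, the most
    log-linear window wins (same tie-breaks) so a fit is always produced,
    with its R^2 exposing the quality.
    """
    n = t.size
    qualified, fallback = [], []
    for i in range(n - 2):
        for j in range(i + 2, n):
            slope = (logy[j] - logy[i]) / (t[j] - t[i])
            r2 = _loglinear_r2(t[i : j + 1], logy[i : j + 1])
            key = (slope, j - i, -i)
            fallback.append(((r2, j - i, -i), (i, j)))
            if r2 >= min_r2:
                qualified.append((key, (i, j)))
    if qualified:
        return max(qualified)[1]
    return max(fallback)[1]


def fit_exponential(series: GrowthSeries, window=None) -> GrowthFit:
    """Endpoint exponential fit (mu, Tg) of one OD series.

    With an explicit ``window=(i, j)`` the rate uses exactly those two
    endpoints; otherwise the window is auto-selected (see
    :func:`_auto_window`).  mu may come out <= 0 for declining cultures,
    in which case Tg is NaN.
    """
    t = np.asarray(series.times, dtype=float)
    logy = np.log(np.asarray(series.od, dtype=float))
    if window is not None:
        i, j = int(window[0]), int(window[1])
        if not (0 <= i < j < t.size):
            raise ValueError(f"window {window!r} does not index >= 2 points")
        if t[j] == t[i]:
            raise ValueError("zero time span in window")
    else:
        i, j = _auto_window(t, logy)
    mu = float((logy[j] - logy[i]) / (t[j] - t[i]))
    return GrowthFit(
        mu_per_day=mu,
        tg_days=generation_time(mu),
        window=(i, j),
        r_squared_loglinear=_loglinear_r2(t[i : j + 1], logy[i : j + 1]),
        treatment_id=series.treatment_id,
        replicate_id=series.replicate_id,
    )


class ExponentialGrowthModel(BaseEstimator, RegressorMixin):
    """Estimator wrapper around the endpoint exponential fit.

    Parameters
    ----------
    window : tuple of int, optional
        Explicit (i, j) index pair; auto-selected when None.
    min_r2 : float
        Log-linearity requirement for window auto-selection.
    """

    def __init__(self, window=None, min_r2=0.95):
        self.window = window
        self.min_r2 = min_r2

    def fit(self, times, od):
        series = GrowthSeries("", "", tuple(np.ravel(times)), tuple(np.ravel(od)))
        t = np.asarray(series.times)
        logy = np.log(np.asarray(series.od))
        if self.window is None:
            i, j = _auto_window(t, logy, self.min_r2)
        else:
            i, j = self.window
        res = fit_exponential(series, window=(i, j))
        self.mu_ = res.mu_per_day
        self.tg_ = res.tg_days
        self.window_ = res.window
        self.r_squared_ = res.r_squared_loglinear
        self.od0_ = float(series.od[i] * math.exp(-self.mu_ * t[i]))
        return self

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.od0_ * np.exp(self.mu_ * t)


def _monod(q, mu_max, q_min):
    return mu_max * (q - q_min) / q


class MonodModel(BaseEstimator, RegressorMixin):
    """Quota-Monod model mu(Q) = mu'_max (Q - Q_min)/Q fitted by
    unweighted nonlinear least squares.

    Initialisation is mu'_max = max(mu), Q_min = min(Q)/2; bounds are
    mu'_max in (0, 10*max(mu)] and Q_min in [0, max(Q)).  Predicted mu is
    allowed to be negative below Q_min (extreme-limitation regime).

    Fitted attributes: ``mu_max_``, ``q_min_``, ``k_mu_`` (= 2*Q_min,
    the model-consistent half-velocity concentration), ``k_mu_empirical_``
    (spline half-max crossing of the data) and ``residual_sse_``.
    """

    def fit(self, q, mu):
        q = np.ravel(np.asarray(q, dtype=float))
        mu = np.ravel(np.asarray(mu, dtype=float))
        if q.size != mu.size:
            raise ValueError("q and mu must have equal length")
        if np.unique(q).size < 3:
            raise ValueError("need >= 3 distinct nutrient concentrations")
        if not np.all(q > 0):
            raise ValueError("nutrient concentrations must be positive")
        if np.allclose(mu, mu[0]):
            raise FittingError("all growth rates equal: Monod fit is degenerate")
        mu_hi = float(mu.max())
        p0 = (mu_hi, float(q.min()) / 2.0)
        bounds = ([1e-12, 0.0], [10.0 * mu_hi, float(q.max()) * (1 - 1e-12)])
        try:
            popt, _ = optimize.curve_fit(_monod, q, mu, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - scipy wording
            raise FittingError(
                f"Monod fit did not converge (n={q.size}, p0={p0}): {exc}"
            ) from exc
        self.mu_max_ = float(popt[0])
        self.q_min_ = float(popt[1])
        self.k_mu_ = 2.0 * self.q_min_
        self.residual_sse_ = float(np.sum((mu - _monod(q, *popt)) ** 2))
        self.k_mu_empirical_ = empirical_half_velocity(q, mu)
        return self

    def predict(self, q):
        return _monod(np.asarray(q, dtype=float), self.mu_max_, self.q_min_)

    def to_fit(self) -> MonodFit:
        return MonodFit(
            mu_max_prime=self.mu_max_,
            q_min=self.q_min_,
            k_mu=self.k_mu_,
            residual_sse=self.residual_sse_,
            k_mu_empirical=self.k_mu_empirical_,
        )


def fit_monod(q_values, mu_values) -> MonodFit:
    """Least-squares quota-Monod fit; see :class:`MonodModel`."""
    return MonodModel().fit(q_values, mu_values).to_fit()


def half_velocity(fit: MonodFit, numeric: bool = False) -> float:
    """Concentration Q* with mu(Q*) = mu'_max/2.

    Analytically 2*Q_min under the quota-Monod model.  With
    ``numeric=True`` the root is found by bisection on the model curve
    instead, for cross-checking; both agree to ~1e-12 relative.
    """
    if fit.mu_max_prime <= 0:
        raise ValueError("half_velocity requires mu'_max > 0")
    if not numeric:
        return 2.0 * fit.q_min
    if fit.q_min == 0.0:
        return 0.0  # mu(Q) = mu'_max for all Q > 0; boundary convention
    lo = fit.q_min * (1.0 + 1e-15)
    hi = fit.q_min * 4.0
    f = lambda q: _monod(q, fit.mu_max_prime, fit.q_min) - fit.mu_max_prime / 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-300, rtol=1e-15))


def empirical_half_velocity(q, mu) -> float:
    """Data-driven half-velocity: the smallest concentration at which a
    monotone (PCHIP) interpolant of the observed (Q, mu) points reaches
    half of the observed maximum mu.  NaN when the curve never crosses.

    This is deliberately model-free; it is reported alongside the
    model-consistent K_mu = 2*Q_min because published half-velocity values
    are often read off the data curve rather than the fitted model.
    """
    q = np.asarray(q, dtype=float)
    mu = np.asarray(mu, dtype=float)
    order = np.argsort(q)
    q, mu = q[order], mu[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    q, mu = q[keep], mu[keep]
    if q.size < 3:
        return float("nan")
    target = mu.max() / 2.0
    spline = PchipInterpolator(q, mu)
    grid = np.linspace(q[0], q[-1], 2048)
    vals = spline(grid) - target
    sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
    if vals[0] >= 0:
        return float(q[0])
    if sign_change.size == 0:
        return float("nan")
    k = sign_change[0]
    return float(optimize.brentq(lambda x: spline(x) - target, grid[k], grid[k + 1]))


# ---------------------------------------------------------------------------
# replicate/treatment bookkeeping and CSV I/O


def fit_replicates(series_list, window=None) -> pd.DataFrame:
    """Fit every replicate series; one row per (treatment, replicate)."""
    rows = []
    for s in series_list:
        f = fit_exponential(s, window=window)
        rows.append(
            {
                "treatment": s.treatment_id,
                "replicate": s.replicate_id,
                "mu_per_day": f.mu_per_day,
                "tg_days": f.tg_days,
                "window_start": f.window[0],
                "window_end": f.window[1],
                "r_squared": f.r_squared_loglinear,
            }
        )
    return pd.DataFrame(rows)


def summarize_treatments(replicate_fits: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level mean mu with its spanning range (max - min), the
    dispersion convention used for duplicate cultures."""
    g = replicate_fits.groupby("treatment")["mu_per_day"]
    out = pd.DataFrame(
        {
            "mu_mean": g.mean(),
            "mu_spanning_range": g.max() - g.min(),
            "n_replicates": g.size(),
        }
    ).reset_index()
    out["tg_days"] = [generation_time(m) for m in out["mu_mean"]]
    return out


def read_growth_csv(path) -> list:
    """Read growth series from CSV with columns
    treatment, replicate, time_days, od[, wavelength_nm]."""
    df = pd.read_csv(path)
    required = {"treatment", "replicate", "time_days", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    out = []
    for (trt, rep), sub in df.groupby(["treatment", "replicate"], sort=False):
        sub = sub.sort_values("time_days")
        wl = float(sub["wavelength_nm"].iloc[0]) if "wavelength_nm" in sub else 750.0
        out.append(
            GrowthSeries(
                treatment_id=str(trt),
                replicate_id=str(rep),
                times=tuple(sub["time_days"]),
                od=tuple(sub["od"]),
                wavelength_nm=wl,
            )
        )
    return out
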
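"""Log growth-response ratios and nutrient co-limitation classification.

A 2x2 factorial nutrient-addition design (control, +A, +B, +AB) is
summarised by three log response ratios against the control cell,

    resp_A  = ln( mean(mu_A)  / mean(mu_00) )
    resp_B  = ln( mean(mu_B)  / mean(mu_00) )
    resp_AB = ln( mean(mu_AB) / mean(mu_00) )

Each ratio is trichotomised against a critical threshold (the minimum
|log ratio| significant at level alpha) and the sign pattern maps onto
the limitation taxonomy: single limitation, serial limitation (the
second nutrient's effect appears only after the first is supplied),
independent co-limitation (both single additions respond), simultaneous
co-limitation (only the joint addition responds), negative responses,
or no response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "FactorialResponse",
    "ResponseProfile",
    "ColimitationClassifier",
    "log_responses",
    "critical_threshold",
    "classify",
    "CATEGORIES",
    "read_factorial_csv",
]

CELLS = ("00", "10", "01", "11")

CATEGORIES = (
    "no_response",
    "single_limitation_A",
    "single_limitation_B",
    "serial_limitation_A_then_B",
    "serial_limitation_B_then_A",
    "independent_colimitation",
    "simultaneous_colimitation",
    "negative_response_A",
    "negative_response_B",
)

# sign pattern of (resp_A, resp_B, resp_AB) -> category
_PATTERN_MAP = {
    ("0", "0", "0"): "no_response",
    ("+", "0", "0"): "single_limitation_A",
    ("0", "+", "0"): "single_limitation_B",
    ("+", "0", "+"): "serial_limitation_A_then_B",
    ("0", "+", "+"): "serial_limitation_B_then_A",
    ("+", "+", "+"): "independent_colimitation",
    ("0", "0", "+"): "simultaneous_colimitation",
    ("-", "0", "0"): "negative_response_A",
    ("0", "-", "0"): "negative_response_B",
}


@dataclass(frozen=True)
class FactorialResponse:
    """Replicate growth rates of the four cells of a factorial design.

    Cell codes follow A-level then B-level: mu_00 control, mu_10 = +A,
    mu_01 = +B, mu_11 = +AB.
    """

    label_a: str
    label_b: str
    mu_00: tuple
    mu_10: tuple
    mu_01: tuple
    mu_11: tuple

    def __post_init__(self):
        for cell in CELLS:
            vals = np.asarray(getattr(self, f"mu_{cell}"), dtype=float)
            if vals.size < 1:
                raise ValueError(f"cell {cell} has no replicates")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"cell {cell} contains non-finite growth rates")
            object.__setattr__(self, f"mu_{cell}", tuple(vals))

    def cell(self, code: str) -> np.ndarray:
        return np.asarray(getattr(self, f"mu_{code}"), dtype=float)

    def cell_means(self) -> dict:
        return {c: float(self.cell(c).mean()) for c in CELLS}


@dataclass(frozen=True)
class ResponseProfile:
    """Log response ratios plus threshold and limitation category."""

    label_a: str
    label_b: str
    resp_a: float
    resp_b: float
    resp_ab: float
    replicate_responses: dict = field(default_factory=dict)
    threshold: float = float("nan")
    alpha: float = 0.05
    category: str = ""

    @property
    def pattern(self):
        return _trichotomize((self.resp_a, self.resp_b, self.resp_ab), self.threshold)


def log_responses(fr: FactorialResponse) -> ResponseProfile:
    """Cell-mean log response ratios (threshold and category left unset).

    Per-replicate ratios (each replicate against the control mean) are
    also emitted for plotting; classification only ever uses cell means.
    """
    means = fr.cell_means()
    for code, m in means.items():
        if m <= 0 or np.any(fr.cell(code) <= 0):
            raise ValueError(
                f"cell {code} has non-positive growth rates; log ratios undefined"
            )
    m0 = means["00"]
    reps = {
        code: tuple(np.log(fr.cell(code) / m0)) for code in CELLS if code != "00"
    }
    return ResponseProfile(
        label_a=fr.label_a,
        label_b=fr.label_b,
        resp_a=math.log(means["10"] / m0),
        resp_b=math.log(means["01"] / m0),
        resp_ab=math.log(means["11"] / m0),
        replicate_responses=reps,
    )


def _pooled_variance(fr: FactorialResponse):
    cells = [fr.cell(c) for c in CELLS]
    n_total = sum(c.size for c in cells)
    df = n_total - len(cells)
    if df <= 0:
        return None, 0
    ss = sum(float(np.sum((c - c.mean()) ** 2)) for c in cells)
    return ss / df, df


def critical_threshold(
    fr: FactorialResponse,
    alpha: float = 0.05,
    pooled_variance: float | None = None,
    pooled_df: int | None = None,
) -> float:
    """Minimum |log response ratio| significant at level alpha.

    Delta method on the log of a cell mean: under the no-effect null,
    Var(ln(m_t/m_c)) ~ s^2 (1/(n_t m^2) + 1/(n_c m^2)) with s^2 the
    pooled per-cell variance (df = total replicates - number of cells)
    and m the control mean.  The threshold is t_{1-alpha/2, df} * SE.
    Treatment cell sizes enter through their harmonic mean.

    Designs with one replicate per cell carry no dispersion; supply
    ``pooled_variance`` (and ``pooled_df``) from elsewhere in that case.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if pooled_variance is None:
        s2, df = _pooled_variance(fr)
        if s2 is None:
            raise ValueError(
                "no within-cell dispersion estimable (single replicates); "
                "supply pooled_variance= and pooled_df= explicitly"
            )
    else:
        s2 = float(pooled_variance)
        df = int(pooled_df) if pooled_df is not None else max(
            sum(fr.cell(c).size for c in CELLS) - len(CELLS), 1
        )
    if s2 == 0.0:
        return 0.0
    m0 = float(fr.cell("00").mean())
    n0 = fr.cell("00").size
    n_treat = [fr.cell(c).size for c in CELLS if c != "00"]
    nt = len(n_treat) / sum(1.0 / n for n in n_treat)  # harmonic mean
    se = math.sqrt(s2 * (1.0 / nt + 1.0 / n0)) / m0
    return float(stats.t.ppf(1.0 - alpha / 2.0, df) * se)


def _trichotomize(values, threshold):
    if not math.isfinite(threshold) or threshold < 0:
        raise ValueError("threshold must be a finite non-negative number")
    out = []
    for v in values:
        if v > threshold:
            out.append("+")
        elif v < -threshold:
            out.append("-")
        else:
            out.append("0")
    return tuple(out)


def classify(profile: ResponseProfile) -> ResponseProfile:
    """Set the limitation category from the thresholded sign pattern.

    Patterns outside the named taxonomy are labelled verbatim as
    ``unclassified(<pattern>)`` rather than forced into a category.
    """
    pattern = profile.pattern  # validates threshold
    category = _PATTERN_MAP.get(pattern, f"unclassified({','.join(pattern)})")
    return replace(profile, category=category)


class ColimitationClassifier(BaseEstimator):
    """Factorial-design co-limitation classifier.

    Parameters
    ----------
    alpha : float
        Significance level of the critical threshold.
    threshold : float, optional
        User-supplied constant threshold; overrides the internal
        delta-method construction when given.

    After ``fit(fr)``: ``profile_``, ``threshold_``, ``category_``.
    """

    def __init__(self, alpha: float = 0.05, threshold: float | None = None):
        self.alpha = alpha
        self.threshold = threshold

    def fit(self, fr: FactorialResponse, pooled_variance=None, pooled_df=None):
        profile = log_responses(fr)
        if self.threshold is not None:
            thr = float(self.threshold)
        else:
            thr = critical_threshold(
                fr, self.alpha, pooled_variance=pooled_variance, pooled_df=pooled_df
            )
        profile = replace(profile, threshold=thr, alpha=self.alpha)
        profile = classify(profile)
        self.profile_ = profile
        self.threshold_ = thr
        self.category_ = profile.category
        return self

    def predict(self, fr: FactorialResponse) -> str:
        """Category of a new design under this classifier's settings."""
        return type(self)(alpha=self.alpha, threshold=self.threshold).fit(fr).category_


def read_factorial_csv(path) -> list:
    """Read factorial designs from CSV with columns
    nutrient_a, nutrient_b, cell (00/10/01/11), replicate, mu."""
    df = pd.read_csv(path, dtype={"cell": str})
    required = {"nutrient_a", "nutrient_b", "cell", "replicate", "mu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"factorial CSV missing columns: {sorted(missing)}")
    out = []
    for (a, b), sub in df.groupby(["nutrient_a", "nutrient_b"], sort=False):
        cells = {}
        for code in CELLS:
            vals = sub.loc[sub["cell"] == code, "mu"].to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"design {a}x{b}: cell {code} missing")
            cells[code] = tuple(vals)
        out.append(
            FactorialResponse(
                label_a=str(a),
                label_b=str(b),
                mu_00=cells["00"],
                mu_10=cells["10"],
                mu_01=cells["01"],
                mu_11=cells["11"],
            )
        )
    return out
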
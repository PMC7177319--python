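"""Inter-rater reliability and odd-vs-even concordance statistics.

Intraclass correlation coefficients come from the standard one-way and
two-way ANOVA mean-square decompositions (single-rater forms), with exact
F-based 95% confidence intervals; negative lower bounds are reported as
computed, never truncated.  ICC values are classified with the Cicchetti
bands: excellent (>= 0.75), good (0.60-0.74), fair (0.40-0.59),
poor (< 0.40).  Concordance between odd and even street sides uses
Pearson's product-moment correlation by default, with Spearman's rank
correlation for designated non-normal measures.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MapsSNError, UndefinedStatisticError

ICC_MODELS = ("one_way", "two_way_agreement", "two_way_consistency")

#: Cicchetti classification bands, lower-bound inclusive.
ICC_BANDS = (("excellent", 0.75), ("good", 0.60), ("fair", 0.40))


def classify_icc(value: float) -> str:
    """Cicchetti category of an ICC value (boundaries inclusive)."""
    if value > 1 + 1e-9:
        raise MapsSNError("ICC cannot exceed 1")
    value = min(value, 1.0)
    for name, lo in ICC_BANDS:
        if value >= lo:
            return name
    return "poor"


@dataclass(frozen=True)
class ReliabilityResult:
    measure: str
    icc: float
    ci95: tuple[float, float]
    classification: str
    icc_model: str
    rater_means: tuple[tuple[float, float], ...]  # (mean, sd) per rater
    n_targets: int


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    """ANOVA mean squares for an n x k ratings matrix.

    Returns (MSR, MSC, MSE, MSW): rows (targets), columns (raters),
    residual, and one-way within-target mean squares.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1) if k > 1 else 0.0
    mse = ss_err / ((n - 1) * (k - 1)) if k > 1 else 0.0
    msw = ss_within / (n * (k - 1)) if k > 1 else 0.0
    return msr, msc, mse, msw


def icc(ratings: pd.DataFrame | np.ndarray,
        model: str = "two_way_agreement",
        measure: str = "score",
        alpha: float = 0.05) -> ReliabilityResult:
    """Single-rater intraclass correlation for a targets x raters matrix.

    ``model`` selects ICC(1), ICC(A,1) or ICC(C,1); rows with missing cells
    are dropped (logged).  Zero between-target variance yields ICC 0 with a
    warning rather than an undefined ratio.
    """
    if model not in ICC_MODELS:
        raise MapsSNError(f"unknown ICC model {model!r}")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise MapsSNError("ratings must be a 2-D targets x raters matrix")
    complete = ~np.isnan(x).any(axis=1)
    if (~complete).any():
        warnings.warn(f"{(~complete).sum()} target(s) with missing cells"
                      " dropped", stacklevel=2)
        x = x[complete]
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("ICC needs >= 2 complete targets")

    msr, msc, mse, msw = _mean_squares(x)
    if math.isclose(msr, 0.0, abs_tol=1e-300) or np.ptp(x.mean(axis=1)) == 0:
        warnings.warn("zero between-target variance: ICC reported as 0",
                      stacklevel=2)
        value, lo, hi = 0.0, 0.0, 0.0
    else:
        value, lo, hi = _icc_ci(model, msr, msc, mse, msw, n, k, alpha)

    rater_means = tuple((float(x[:, j].mean()), float(x[:, j].std(ddof=1)))
                        for j in range(k))
    return ReliabilityResult(measure=measure, icc=float(value),
                             ci95=(float(lo), float(hi)),
                             classification=classify_icc(float(value)),
                             icc_model=model, rater_means=rater_means,
                             n_targets=n)


def _icc_ci(model: str, msr: float, msc: float, mse: float, msw: float,
            n: int, k: int, alpha: float) -> tuple[float, float, float]:
    """ICC point estimate and exact F-based CI (McGraw & Wong forms)."""
    if model == "one_way":
        value = (msr - msw) / (msr + (k - 1) * msw) if msw > 0 else 1.0
        if msw <= 0:
            return value, 1.0, 1.0
        f_obs = msr / msw
        df1, df2 = n - 1, n * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return value, lo, hi

    if model == "two_way_consistency":
        value = (msr - mse) / (msr + (k - 1) * mse) if mse > 0 else 1.0
        if mse <= 0:
            return value, 1.0, 1.0
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return value, lo, hi

    # two-way random, absolute agreement, single rater: ICC(A,1)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    value = (msr - mse) / denom if denom != 0 else 1.0
    if mse <= 0 and msc <= 0:
        return value, 1.0, 1.0
    a = (k * value) / (n * (1 - value)) if value != 1 else np.inf
    b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value != 1 else np.inf
    if not np.isfinite(a):
        return value, 1.0, 1.0
    # Satterthwaite df for the denominator combination
    num_v = (a * msc + b * mse) ** 2
    den_v = ((a * msc) ** 2 / (k - 1)
             + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    v = num_v / den_v if den_v > 0 else 1.0
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_inv = stats.f.ppf(1 - alpha / 2, v, n - 1)
    fl = f_star
    lo = (n * (msr - fl * mse)) / (
        fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi_f = f_star_inv
    hi = (n * (hi_f * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * hi_f * msr)
    return value, lo, hi


# ---------------------------------------------------------------------------
# correlations

def correlate(x: Sequence[float], y: Sequence[float],
              method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson product-moment or Spearman rank (average ranks for ties); the
    p-value uses the t-approximation in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MapsSNError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise MapsSNError(f"unknown method {method!r}")
    return float(r), float(p)


#: Measures analysed with Spearman's rank correlation (non-normal scores).
SPEARMAN_MEASURES = ("destinations_land_use", "bicycle_facilities")


def concordance(paired: pd.DataFrame,
                method_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Odd-vs-even concordance table from a paired per-school score table.

    ``paired`` has columns ``<measure>_odd`` / ``<measure>_even`` (as built
    by :func:`mapssn.scoring.concordance_inputs`).  Each measure row carries
    odd/even/combined mean +- sd and the correlation; the crossing measure is
    reported combined-only (crossing audits cannot be attributed to a side).
    """
    if method_map is None:
        method_map = {m: "spearman" for m in SPEARMAN_MEASURES}
    measures = sorted({c[:-4] for c in paired.columns if c.endswith("_odd")})
    rows = []
    for m in measures:
        odd = paired[f"{m}_odd"].astype(float).to_numpy()
        even = paired[f"{m}_even"].astype(float).to_numpy()
        combined = (odd + even) / 2.0
        row = {"measure": m,
               "odd_mean": odd.mean(), "odd_sd": odd.std(ddof=1),
               "even_mean": even.mean(), "even_sd": even.std(ddof=1),
               "combined_mean": combined.mean(),
               "combined_sd": combined.std(ddof=1),
               "method": None, "r": None, "p": None}
        if m == "crossing_score":
            rows.append(row)  # shared data: no odd/even correlation
            continue
        method = method_map.get(m, "pearson")
        row["method"] = method
        try:
            row["r"], row["p"] = correlate(odd, even, method)
        except UndefinedStatisticError:
            warnings.warn(f"measure {m}: constant scores, correlation"
                          " undefined", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)


def reliability_table(ratings: Mapping[str, pd.DataFrame | np.ndarray],
                      model: str = "two_way_agreement") -> pd.DataFrame:
    """ICC report (one row per measure) mirroring a reliability table layout."""
    rows = []
    for measure, mat in ratings.items():
        res = icc(mat, model=model, measure=measure)
        row = {"measure": measure, "icc": res.icc,
               "ci95_low": res.ci95[0], "ci95_high": res.ci95[1],
               "classification": res.classification,
               "n_targets": res.n_targets}
        for j, (mean, sd) in enumerate(res.rater_means, start=1):
            row[f"rater{j}_mean"] = mean
            row[f"rater{j}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def crossing_type_shares(counts: Mapping[int, int] | Sequence[int]
                         ) -> pd.DataFrame:
    """Percentage of crossing audits by intersection type (3-way, 4-way, ...).

    Returns both the exact share and the one-decimal rounded share; exact
    shares always sum to 100.
    """
    if isinstance(counts, Mapping):
        items = sorted(counts.items())
    else:
        items = list(enumerate(counts, start=3))
    total = sum(c for _, c in items)
    if total <= 0:
        raise MapsSNError("no crossing audits to tally")
    if any(c < 0 for _, c in items):
        raise MapsSNError("counts must be >= 0")
    rows = [{"ways": w, "count": c,
             "share_pct": 100.0 * c / total,
             "share_pct_rounded": round(100.0 * c / total, 1)}
            for w, c in items]
    return pd.DataFrame(rows)
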
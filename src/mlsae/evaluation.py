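"""Validation of model-based SAEs against direct survey estimates.

Direct estimates are weighted sample proportions with linearized design-based
standard errors, screened by the CDC-style reliability rule (at least 30
sampled children and relative standard error below 0.3).  Model-based and
direct estimates are then compared by paired t-test, quartiles of the
per-geography differences, a count of significant discrepancies
(non-overlapping 95% intervals), and a correlation-versus-minimum-sample-size
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GEO_COLUMN = {"county": "county_id", "state": "state_id", "zip": "zip_id"}


def direct_estimate(records: pd.DataFrame, use_weights: bool = True) -> dict:
    """Weighted prevalence and linearization SE for one geography's records.

    estimate = sum(w*y)/sum(w); Var = sum(w_i^2 (y_i - p)^2) / (sum w)^2,
    which reduces to p(1-p)/n under equal weights.  Weights are treated as
    fixed (no finite-population correction or design-stratum variance).
    """
    if len(records) == 0:
        raise ValueError("no records")
    y = records["obese"].to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(y))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    p = float((w * y).sum() / w.sum())
    se = float(np.sqrt((w**2 * (y - p) ** 2).sum()) / w.sum())
    return {"estimate": p, "se": se, "n": int(len(y))}


def direct_estimates(
    records: pd.DataFrame, level: str = "county", use_weights: bool = True
) -> pd.DataFrame:
    """Per-geography direct estimates at county/state/zip level.

    Output columns: geo_id, estimate, se, n, reliable (see
    :func:`apply_reliability_filter` for the reliability rule; the flag here
    uses the default thresholds).
    """
    if level == "national":
        groups = [("national", records)]
    else:
        groups = records.groupby(GEO_COLUMN[level])
    rows = []
    for gid, sub in groups:
        d = direct_estimate(sub, use_weights=use_weights)
        rows.append({"geo_id": gid, **d})
    out = pd.DataFrame(rows)
    out["reliable"] = (
        (out["n"] >= 30)
        & (out["estimate"] > 0)
        & (out["se"] / out["estimate"].where(out["estimate"] > 0) < 0.3)
    )
    return out


def apply_reliability_filter(
    estimates: pd.DataFrame, min_n: int = 30, max_rse: float = 0.3
) -> pd.DataFrame:
    """Keep estimates with n >= min_n and SE/estimate < max_rse.

    Zero-prevalence entries are excluded (relative SE undefined).
    """
    est = estimates["estimate"]
    keep = (estimates["n"] >= min_n) & (est > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = estimates["se"] / est
    keep &= rse < max_rse
    return estimates[keep.fillna(False)].reset_index(drop=True)


@dataclass
class PairedComparison:
    """Model-vs-direct comparison over matched geographies."""

    n_matched: int
    differences_pp: pd.Series       # model - direct, percentage points
    quartiles_pp: tuple[float, float, float]
    t_statistic: float
    p_value: float
    n_significant: int              # non-overlapping 95% intervals
    degenerate: bool                # zero-variance differences: t undefined

    def to_dict(self) -> dict:
        q1, med, q3 = self.quartiles_pp
        return {
            "n_matched": self.n_matched,
            "diff_q1_pp": q1,
            "diff_median_pp": med,
            "diff_q3_pp": q3,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_significant": self.n_significant,
            "degenerate": self.degenerate,
        }


def compare_paired(
    model_estimates: pd.DataFrame, direct: pd.DataFrame
) -> PairedComparison:
    """Paired t-test and difference summaries, matched on ``geo_id``.

    ``model_estimates`` needs columns geo_id/estimate and, for the
    significant-discrepancy count, ci_low/ci_high; ``direct`` needs
    geo_id/estimate/se.  Discrepancy = model MC interval and direct
    estimate +/- 1.96 SE do not overlap.
    """
    merged = model_estimates.merge(
        direct, on="geo_id", suffixes=("_model", "_direct")
    )
    if len(merged) < 2:
        raise ValueError("need at least 2 matched geographies")
    diff = (merged["estimate_model"] - merged["estimate_direct"]) * 100.0
    q1, med, q3 = np.quantile(diff, [0.25, 0.5, 0.75], method="median_unbiased")
    degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
    if degenerate:
        t_stat, p_val = float("nan"), float("nan")
    else:
        t_stat, p_val = stats.ttest_rel(merged["estimate_model"], merged["estimate_direct"])
        t_stat, p_val = float(t_stat), float(p_val)
    n_sig = 0
    if {"ci_low", "ci_high"} <= set(merged.columns):
        d_lo = merged["estimate_direct"] - 1.96 * merged["se"]
        d_hi = merged["estimate_direct"] + 1.96 * merged["se"]
        n_sig = int(((merged["ci_low"] > d_hi) | (merged["ci_high"] < d_lo)).sum())
    return PairedComparison(
        n_matched=len(merged),
        differences_pp=diff.rename("difference_pp"),
        quartiles_pp=(float(q1), float(med), float(q3)),
        t_statistic=t_stat,
        p_value=p_val,
        n_significant=n_sig,
        degenerate=degenerate,
    )


DEFAULT_THRESHOLDS = (15, 30, 50, 100, 150, 200)


def correlation_curve(
    model_estimates: pd.DataFrame,
    direct: pd.DataFrame,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Pearson r between model and direct estimates vs minimum sample size.

    For each threshold m, r is computed over geographies whose direct-sample
    size is at least m; entries with fewer than 3 such geographies get NaN.
    Output columns: min_n, r, n_geographies.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be increasing")
    merged = model_estimates.merge(direct, on="geo_id", suffixes=("_model", "_direct"))
    rows = []
    for m in thresholds:
        sub = merged[merged["n"] >= m]
        if len(sub) < 3 or sub["estimate_model"].std() == 0 or sub["estimate_direct"].std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(sub["estimate_model"], sub["estimate_direct"])[0, 1])
        rows.append({"min_n": m, "r": r, "n_geographies": len(sub)})
    return pd.DataFrame(rows)


def plot_correlation_curve(curve: pd.DataFrame, ax=None):
    """Line plot of the correlation-vs-minimum-sample-size curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["min_n"], curve["r"], marker="o")
    ax.set_xlabel("minimum county sample size")
    ax.set_ylabel("Pearson r (model vs direct)")
    ax.set_ylim(0, 1)
    return ax
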
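"""Post-stratified small-area prevalence prediction with Monte-Carlo intervals.

A fitted reduced model (individual demographics + sub-county income octile and
lifestyle class + state random intercepts) supplies a predicted obesity risk
for every census demographic cell (block group x sex x age group x
race/ethnicity); zip-level coefficients are applied to the block-group
covariates (coefficient transfer).  The block-group prevalence is the
census-count-weighted average of its cell risks.  Uncertainty comes from a
parametric Monte-Carlo: each fixed-effect coefficient is redrawn from
Normal(estimate, SE), the whole post-stratification is recomputed per draw,
and 95% intervals are the 2.5th/97.5th percentiles of the draws.  County,
state and national results aggregate the per-draw prevalences (never the
interval endpoints).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import categories as cat
from .geography import GeographyFrame
from .glmm import GLMMResults

logger = logging.getLogger(__name__)

LEVELS = ("bg", "county", "state", "national")

RESULT_COLUMNS = [
    "geo_id",
    "level",
    "n_children",
    "estimate",
    "ci_low",
    "ci_high",
    "ci_width",
    "cv",
    "n_draws",
    "seed",
]


@dataclass
class PredictiveModel:
    """Reduced fixed-effect set plus fitted state random intercepts.

    ``coefficients``/``standard_errors`` map term -> {non-reference level ->
    value} for exactly the reduced terms (age, sex, race, income octile,
    lifestyle); ``state_effects`` holds each state's random-intercept value
    used as an offset in prediction.
    """

    intercept: float
    intercept_se: float
    coefficients: dict[str, dict]
    standard_errors: dict[str, dict]
    state_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.coefficients) != set(cat.PREDICTIVE_TERMS):
            raise ValueError(
                f"predictive model terms must be exactly {cat.PREDICTIVE_TERMS}, "
                f"got {sorted(self.coefficients)}"
            )

    @classmethod
    def from_results(cls, results: GLMMResults, geo: GeographyFrame | None = None
                     ) -> "PredictiveModel":
        """Extract the reduced predictive model from a refitted GLMM."""
        frame = results.coef_frame()
        fitted_terms = [t for t in frame["term"].unique() if t != "intercept"]
        if sorted(fitted_terms) != sorted(cat.PREDICTIVE_TERMS):
            raise ValueError(
                "fit does not carry the reduced predictive term set; refit with "
                f"fixed_terms={cat.PREDICTIVE_TERMS}"
            )
        if "state" not in results.re_modes:
            raise ValueError("predictive model requires a state random intercept")
        coefs: dict[str, dict] = {t: {} for t in cat.PREDICTIVE_TERMS}
        ses: dict[str, dict] = {t: {} for t in cat.PREDICTIVE_TERMS}
        intercept = intercept_se = None
        for _, row in frame.iterrows():
            if row["term"] == "intercept":
                intercept, intercept_se = float(row["coefficient"]), float(row["se"])
            else:
                lv = row["level"]
                # octile levels round-trip through str in the design columns
                if row["term"] in ("zip_income_octile",):
                    lv = int(lv)
                coefs[row["term"]][lv] = float(row["coefficient"])
                ses[row["term"]][lv] = float(row["se"])
        if not np.isfinite(intercept_se) or any(
            not np.isfinite(v) for t in ses for v in ses[t].values()
        ):
            raise ValueError("fit has missing standard errors; MC intervals undefined")
        state_effects = {str(k): float(v) for k, v in results.re_modes["state"].items()}
        if geo is not None:
            for s in geo.states["state_id"]:
                state_effects.setdefault(str(s), 0.0)  # unsurveyed state: population average
        return cls(intercept, intercept_se, coefs, ses, state_effects)

    # vectors in the canonical design order -----------------------------
    def _column_layout(self) -> list[tuple[str, object]]:
        cols: list[tuple[str, object]] = [("intercept", "")]
        for t in cat.PREDICTIVE_TERMS:
            cols += [(t, lv) for lv in cat.nonreference_levels(t)]
        return cols

    def beta_vector(self) -> np.ndarray:
        out = [self.intercept]
        for t in cat.PREDICTIVE_TERMS:
            out += [self.coefficients[t].get(lv, 0.0) for lv in cat.nonreference_levels(t)]
        return np.asarray(out, dtype=float)

    def se_vector(self) -> np.ndarray:
        out = [self.intercept_se]
        for t in cat.PREDICTIVE_TERMS:
            out += [self.standard_errors[t].get(lv, np.nan) for lv in cat.nonreference_levels(t)]
        return np.asarray(out, dtype=float)


def cell_risk(
    model: PredictiveModel,
    sex: str,
    age_group: str,
    race: str,
    income_octile: int,
    lifestyle_class: str,
    state_id: str | None = None,
    state_effect: float | None = None,
) -> float:
    """Predicted obesity risk for one demographic cell profile.

    ``expit(intercept + sex + age + race + income octile + lifestyle + state
    effect)``; the income-octile and lifestyle coefficients were estimated at
    the zip level and are applied to the block group's covariate values.
    """
    if state_effect is None:
        if state_id is None:
            state_effect = 0.0
        else:
            if state_id not in model.state_effects:
                raise KeyError(f"no state effect for {state_id!r}")
            state_effect = model.state_effects[state_id]
    eta = model.intercept + state_effect
    for term, level in (
        ("sex", sex),
        ("age", age_group),
        ("race", race),
        ("zip_income_octile", income_octile),
        ("zip_lifestyle", lifestyle_class),
    ):
        if level not in cat.levels(term):
            raise KeyError(f"unknown level {level!r} for term {term!r}")
        eta += model.coefficients[term].get(level, 0.0)
    return float(expit(eta))


def _cell_design(model: PredictiveModel, cells: pd.DataFrame, geo: GeographyFrame):
    """Design matrix and state-effect offset for a census cell table.

    Cells whose block group lacks covariates are logged and dropped.
    """
    bgcov = geo.bg_covariates()
    known = cells["bg_id"].isin(bgcov.index)
    if not known.all():
        dropped = sorted(cells.loc[~known, "bg_id"].unique())
        logger.warning("dropping %d cells in unknown block groups: %s...",
                       (~known).sum(), dropped[:3])
        cells = cells[known]
    cells = cells.reset_index(drop=True)
    bg = bgcov.loc[cells["bg_id"]].reset_index()

    columns = model._column_layout()
    X = np.zeros((len(cells), len(columns)))
    X[:, 0] = 1.0
    values = {
        "sex": cells["sex"].to_numpy(),
        "age": cells["age_group"].to_numpy(),
        "race": cells["race"].to_numpy(),
        "zip_income_octile": bg["income_octile"].to_numpy(),
        "zip_lifestyle": bg["lifestyle_class"].to_numpy(),
    }
    for j, (term, lv) in enumerate(columns):
        if term == "intercept":
            continue
        X[:, j] = values[term] == lv
    offsets = bg["state_id"].map(model.state_effects)
    if offsets.isna().any():
        missing = sorted(bg.loc[offsets.isna(), "state_id"].unique())
        raise KeyError(f"no state effect for state(s) {missing[:3]}")
    return cells, X, offsets.to_numpy(dtype=float)


@dataclass
class SAEDraws:
    """Point estimates plus per-draw prevalences for one geography level.

    ``draws`` has one row per geography and one column per Monte-Carlo draw;
    aggregation to coarser levels averages rows draw-wise with child-count
    weights, so intervals at every level come from the same simulated
    coefficient sets.
    """

    level: str
    geo_ids: np.ndarray
    estimate: np.ndarray           # (m,) point prevalence (fitted coefficients)
    draws: np.ndarray              # (m, n_draws)
    n_children: np.ndarray         # (m,)
    seed: int
    geo: GeographyFrame

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def aggregate(self, level: str) -> "SAEDraws":
        """Population-weighted aggregation of estimates and draws."""
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        if self.level != "bg":
            raise ValueError("aggregate from block-group draws")
        bg = self.geo.bg_covariates()
        orphans = sorted(set(self.geo_ids) - set(bg.index))
        if orphans:
            raise ValueError(f"block group(s) without geography parent: {orphans[:3]}")
        if level == "bg":
            return self
        if level == "national":
            keys = np.full(len(self.geo_ids), "national")
        else:
            col = {"county": "county_id", "state": "state_id"}[level]
            keys = bg.loc[self.geo_ids, col].to_numpy()
        order = pd.factorize(keys, sort=True)
        codes, uniques = order
        m = len(uniques)
        w = self.n_children.astype(float)
        wsum = np.bincount(codes, weights=w, minlength=m)
        est = np.bincount(codes, weights=w * self.estimate, minlength=m) / wsum
        agg_draws = np.empty((m, self.n_draws))
        for j in range(self.n_draws):
            agg_draws[:, j] = np.bincount(codes, weights=w * self.draws[:, j], minlength=m) / wsum
        return SAEDraws(
            level=level,
            geo_ids=np.asarray(uniques),
            estimate=est,
            draws=agg_draws,
            n_children=wsum,
            seed=self.seed,
            geo=self.geo,
        )

    def to_frame(self) -> pd.DataFrame:
        """SAEResult table with percentile CIs and coefficients of variation."""
        lo = np.quantile(self.draws, 0.025, axis=1)
        hi = np.quantile(self.draws, 0.975, axis=1)
        sd = self.draws.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(self.estimate > 0, sd / self.estimate, np.nan)
        return pd.DataFrame(
            {
                "geo_id": self.geo_ids,
                "level": self.level,
                "n_children": self.n_children,
                "estimate": self.estimate,
                "ci_low": lo,
                "ci_high": hi,
                "ci_width": hi - lo,
                "cv": cv,
                "n_draws": self.n_draws,
                "seed": self.seed,
            }
        )


def block_group_prevalence(
    model: PredictiveModel, cells: pd.DataFrame, geo: GeographyFrame
) -> pd.DataFrame:
    """Point post-stratified prevalence per block group (no intervals).

    Returns a frame with ``bg_id``, ``estimate`` and ``n_children``; block
    groups whose cells sum to zero children are suppressed.
    """
    cells, X, offset = _cell_design(model, cells, geo)
    risk = expit(X @ model.beta_vector() + offset)
    w = cells["count"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(cells["bg_id"], sort=True)
    m = len(uniques)
    wsum = np.bincount(codes, weights=w, minlength=m)
    num = np.bincount(codes, weights=w * risk, minlength=m)
    keep = wsum > 0
    if (~keep).any():
        logger.info("suppressing %d block groups with zero children", int((~keep).sum()))
    return pd.DataFrame(
        {
            "bg_id": np.asarray(uniques)[keep],
            "estimate": num[keep] / wsum[keep],
            "n_children": wsum[keep],
        }
    )


def mc_prevalence_draws(
    model: PredictiveModel,
    cells: pd.DataFrame,
    geo: GeographyFrame,
    n_draws: int = 1000,
    seed: int = 0,
) -> SAEDraws:
    """Block-group draws: redraw each coefficient from Normal(beta, SE).

    Coefficients are drawn independently; the fitted state effects are held
    fixed across draws.  Deterministic given ``seed``.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    beta = model.beta_vector()
    se = model.se_vector()
    if not np.all(np.isfinite(se)):
        raise ValueError("missing coefficient standard errors; intervals undefined")
    cells, X, offset = _cell_design(model, cells, geo)
    rng = np.random.default_rng(seed)
    B = beta[:, None] + se[:, None] * rng.standard_normal((beta.size, n_draws))
    risk_draws = expit(X @ B + offset[:, None])          # (n_cells, n_draws)
    risk_point = expit(X @ beta + offset)

    w = cells["count"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(cells["bg_id"], sort=True)
    m = len(uniques)
    wsum = np.bincount(codes, weights=w, minlength=m)
    keep = wsum > 0
    est = np.bincount(codes, weights=w * risk_point, minlength=m)
    draws = np.empty((m, n_draws))
    for j in range(n_draws):
        draws[:, j] = np.bincount(codes, weights=w * risk_draws[:, j], minlength=m)
    est = est[keep] / wsum[keep]
    draws = draws[keep] / wsum[keep, None]
    return SAEDraws(
        level="bg",
        geo_ids=np.asarray(uniques)[keep],
        estimate=est,
        draws=draws,
        n_children=wsum[keep],
        seed=seed,
        geo=geo,
    )


def mc_intervals(
    model: PredictiveModel,
    cells: pd.DataFrame,
    geo: GeographyFrame,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Block-group SAEResult table with Monte-Carlo 95% CIs and CVs."""
    return mc_prevalence_draws(model, cells, geo, n_draws=n_draws, seed=seed).to_frame()


def aggregate(draws: SAEDraws, level: str) -> pd.DataFrame:
    """SAEResult table at ``level`` from block-group draws."""
    return draws.aggregate(level).to_frame()


def summarize_sae(results: pd.DataFrame, level: str | None = None) -> pd.DataFrame:
    """Distribution summary of CI widths and CVs, one row per statistic.

    Order statistics use median-unbiased quantiles; IQR = Q3 - Q1.  Matches
    the layout of standard CI/CV summary tables (values on the estimate's
    own scale; multiply widths by 100 for percentage points).
    """
    if level is not None:
        results = results[results["level"] == level]
    if len(results) == 0:
        raise ValueError("no results at requested level")
    rows = []
    for stat in ("ci_width", "cv"):
        x = results[stat].dropna().to_numpy()
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="median_unbiased")
        rows.append(
            {
                "statistic": stat,
                "n": len(x),
                "min": x.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": x.max(),
                "mean": x.mean(),
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows)
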
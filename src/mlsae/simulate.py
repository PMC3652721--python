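"""Synthetic survey and census generation from a known multilevel logit model.

The generator mirrors the structure of a state-stratified national child
health survey joined to census demographic products: ~51 strata (states) with
several hundred sampled children each, nested county/zip geography, and a
block-group population table of child counts per sex x age-group x
race/ethnicity cell.  Outcomes are drawn from an explicit ``TrueModel`` so
every downstream stage (model fitting, post-stratified prediction, interval
calibration, validation against direct estimates) can be tested against known
truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import categories as cat
from . import coefficients as coef
from .geography import GeographyFrame

SURVEY_COLUMNS = [
    "child_id",
    "sex",
    "age_group",
    "race",
    "obese",
    "weight",
    "state_id",
    "county_id",
    "zip_id",
]

CELL_COLUMNS = ["bg_id", "sex", "age_group", "race", "count"]


@dataclass
class TrueModel:
    """A fully known multilevel logistic risk surface.

    ``fixed_effects`` maps term name -> {level: coefficient}; reference levels
    are implicit zeros.  ``state_effects`` / ``county_effects`` are the
    realized random intercepts (mean-zero normal with the stated variances).
    """

    intercept: float
    fixed_effects: dict[str, dict]
    sigma2_state: float = 0.0
    sigma2_county: float = 0.0
    state_effects: dict[str, float] = field(default_factory=dict)
    county_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma2_state < 0 or self.sigma2_county < 0:
            raise ValueError("random-effect variances must be non-negative")
        for term, values in self.fixed_effects.items():
            if term not in cat.TERMS:
                raise ValueError(f"unknown model term {term!r}")
            known = set(cat.levels(term))
            bad = set(values) - known
            if bad:
                raise ValueError(f"unknown level(s) {bad!r} for term {term!r}")
            ref = cat.reference(term)
            if values.get(ref, 0.0) != 0.0:
                raise ValueError(f"reference level of {term!r} must carry coefficient 0")

    @classmethod
    def draw(
        cls,
        geo: GeographyFrame,
        seed: int,
        intercept: float = coef.INTERCEPT,
        fixed_effects: dict | None = None,
        sigma2_state: float = coef.SIGMA2_STATE_NULL,
        sigma2_county: float = 0.0,
    ) -> "TrueModel":
        """Realize state/county random intercepts for ``geo`` under a seed.

        Defaults use the reference national childhood-obesity coefficient
        surface and the between-state variance of its null state model.
        """
        rng = np.random.default_rng(seed)
        fx = coef.COEFFICIENTS if fixed_effects is None else fixed_effects
        s_ids = list(geo.states["state_id"])
        c_ids = list(geo.counties["county_id"])
        return cls(
            intercept=intercept,
            fixed_effects=fx,
            sigma2_state=sigma2_state,
            sigma2_county=sigma2_county,
            state_effects=dict(
                zip(s_ids, np.sqrt(sigma2_state) * rng.standard_normal(len(s_ids)))
            ),
            county_effects=dict(
                zip(c_ids, np.sqrt(sigma2_county) * rng.standard_normal(len(c_ids)))
            ),
        )

    def coefficient(self, term: str, level) -> float:
        return float(self.fixed_effects.get(term, {}).get(level, 0.0))

    def terms(self) -> list[str]:
        return [t for t in cat.FULL_TERMS if t in self.fixed_effects]


def _lookup_vector(term: str, levels_seen: pd.Series, model: TrueModel) -> np.ndarray:
    table = model.fixed_effects.get(term, {})
    return levels_seen.map(lambda lv: float(table.get(lv, 0.0))).to_numpy()


def _check_schema(model: TrueModel, geo: GeographyFrame) -> None:
    zc = geo.zips
    for term, col in (
        ("zip_income_octile", "income_octile"),
        ("zip_lifestyle", "lifestyle_class"),
        ("zip_urbanization", "urbanization_class"),
    ):
        if term in model.fixed_effects:
            bad = set(model.fixed_effects[term]) - set(zc[col].unique()) - {cat.reference(term)}
            # levels in the model but absent from the geography are fine;
            # the reverse (geography level unknown to the category system)
            # is caught by GeographyFrame.validate
            _ = bad
    missing_states = set(geo.states["state_id"]) - set(model.state_effects)
    if model.sigma2_state > 0 and missing_states:
        raise ValueError(f"TrueModel lacks state effects for {sorted(missing_states)[:3]}...")


def linear_predictor(
    model: TrueModel,
    sex: pd.Series,
    age_group: pd.Series,
    race: pd.Series,
    income_octile: pd.Series,
    lifestyle: pd.Series,
    urbanization: pd.Series | None,
    county_income: pd.Series | None,
    county_urban_rural: pd.Series | None,
    state_id: pd.Series,
    county_id: pd.Series | None,
) -> np.ndarray:
    """True logit-scale risk for arbitrary demographic/area profiles."""
    eta = np.full(len(sex), model.intercept, dtype=float)
    eta += _lookup_vector("sex", sex, model)
    eta += _lookup_vector("age", age_group, model)
    eta += _lookup_vector("race", race, model)
    eta += _lookup_vector("zip_income_octile", income_octile, model)
    eta += _lookup_vector("zip_lifestyle", lifestyle, model)
    if urbanization is not None:
        eta += _lookup_vector("zip_urbanization", urbanization, model)
    if county_income is not None:
        eta += _lookup_vector("county_income_octile", county_income, model)
    if county_urban_rural is not None:
        eta += _lookup_vector("county_urban_rural", county_urban_rural, model)
    eta += state_id.map(lambda s: model.state_effects.get(s, 0.0)).to_numpy()
    if county_id is not None:
        eta += county_id.map(lambda c: model.county_effects.get(c, 0.0)).to_numpy()
    return eta


def simulate_survey(
    geo: GeographyFrame,
    true: TrueModel,
    n_per_state: int,
    seed: int,
    demographic_marginals: dict[str, dict] | None = None,
    county_concentration: float | None = None,
    state_child_population: dict[str, float] | float = 100_000.0,
) -> pd.DataFrame:
    """Draw a state-stratified survey of children under the true model.

    Within each state, every child is assigned a county (uniformly by
    default, or with Dirichlet(``county_concentration``) sampling weights to
    mimic unequal county sample sizes), then a zip uniformly within the
    county.  Demographics come from ``demographic_marginals`` (uniform over
    categories by default).  Obesity is Bernoulli(expit(eta)) with eta the
    true fixed-effect predictor at the child's zip/county covariates plus the
    state and county random intercepts.  Survey weights are state child
    population divided by the state sample size (inverse sampling fraction).
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    _check_schema(true, geo)
    rng = np.random.default_rng(seed)
    marg = demographic_marginals or {}

    def _sample(levels: list, name: str, n: int) -> np.ndarray:
        probs = marg.get(name)
        if probs is None:
            p = None
        else:
            p = np.array([probs[lv] for lv in levels], dtype=float)
            p = p / p.sum()
        return rng.choice(levels, size=n, p=p)

    zip_lookup = {c: z.to_numpy() for c, z in geo.zips.groupby("county_id")["zip_id"]}
    frames = []
    offset = 0
    for state in geo.states["state_id"]:
        sub = geo.counties[geo.counties["state_id"] == state]
        county_ids = sub["county_id"].to_numpy()
        if county_concentration is None:
            probs = None
        else:
            probs = rng.dirichlet(np.full(len(county_ids), county_concentration))
        counties = rng.choice(county_ids, size=n_per_state, p=probs)
        zipc = np.array([zip_lookup[c][rng.integers(len(zip_lookup[c]))] for c in counties])
        if isinstance(state_child_population, dict):
            pop = state_child_population[state]
        else:
            pop = float(state_child_population)
        frames.append(
            pd.DataFrame(
                {
                    "child_id": np.arange(offset, offset + n_per_state),
                    "sex": _sample(cat.SEX_LEVELS, "sex", n_per_state),
                    "age_group": _sample(cat.AGE_LEVELS, "age", n_per_state),
                    "race": _sample(cat.RACE_LEVELS, "race", n_per_state),
                    "weight": pop / n_per_state,
                    "state_id": state,
                    "county_id": counties,
                    "zip_id": zipc,
                }
            )
        )
        offset += n_per_state
    records = pd.concat(frames, ignore_index=True)

    zc = geo.zip_covariates().loc[records["zip_id"]]
    cc = geo.county_covariates().loc[records["county_id"]]
    eta = linear_predictor(
        true,
        sex=records["sex"],
        age_group=records["age_group"],
        race=records["race"],
        income_octile=zc["income_octile"].reset_index(drop=True),
        lifestyle=zc["lifestyle_class"].reset_index(drop=True),
        urbanization=zc["urbanization_class"].reset_index(drop=True)
        if "zip_urbanization" in true.fixed_effects
        else None,
        county_income=cc["income_octile"].reset_index(drop=True)
        if "county_income_octile" in true.fixed_effects
        else None,
        county_urban_rural=cc["urban_rural_class"].reset_index(drop=True)
        if "county_urban_rural" in true.fixed_effects
        else None,
        state_id=records["state_id"],
        county_id=records["county_id"],
    )
    records["obese"] = rng.binomial(1, expit(eta))
    return records[SURVEY_COLUMNS]


def generate_population_cells(
    geo: GeographyFrame,
    mean_children_per_bg: float,
    seed: int,
    demographic_marginals: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Poisson child counts per block group x sex x age-group x race cell.

    Each of the 2 x 2 x 8 = 32 demographic cells of a block group gets an
    independent Poisson count with mean ``mean_children_per_bg`` apportioned
    by the (default uniform) demographic marginals.
    """
    if mean_children_per_bg <= 0:
        raise ValueError("mean_children_per_bg must be > 0")
    rng = np.random.default_rng(seed)
    marg = demographic_marginals or {}

    def _probs(levels: list, name: str) -> np.ndarray:
        probs = marg.get(name)
        if probs is None:
            return np.full(len(levels), 1.0 / len(levels))
        p = np.array([probs[lv] for lv in levels], dtype=float)
        return p / p.sum()

    p_sex = _probs(cat.SEX_LEVELS, "sex")
    p_age = _probs(cat.AGE_LEVELS, "age")
    p_race = _probs(cat.RACE_LEVELS, "race")

    combos = list(itertools.product(range(2), range(2), range(8)))
    cell_p = np.array([p_sex[s] * p_age[a] * p_race[r] for s, a, r in combos])
    bg_ids = geo.block_groups["bg_id"].to_numpy()
    n_bg, n_cell = len(bg_ids), len(combos)
    counts = rng.poisson(mean_children_per_bg * cell_p, size=(n_bg, n_cell))
    return pd.DataFrame(
        {
            "bg_id": np.repeat(bg_ids, n_cell),
            "sex": np.tile([cat.SEX_LEVELS[s] for s, _, _ in combos], n_bg),
            "age_group": np.tile([cat.AGE_LEVELS[a] for _, a, _ in combos], n_bg),
            "race": np.tile([cat.RACE_LEVELS[r] for _, _, r in combos], n_bg),
            "count": counts.ravel(),
        }
    )


def census_totals(cells: pd.DataFrame, geo: GeographyFrame, level: str = "state") -> pd.Series:
    """Total child population per area at ``level`` (bg/county/state/national)."""
    bg = geo.bg_covariates()
    if level == "bg":
        key = cells["bg_id"]
    elif level == "county":
        key = bg.loc[cells["bg_id"], "county_id"].to_numpy()
    elif level == "state":
        key = bg.loc[cells["bg_id"], "state_id"].to_numpy()
    elif level == "national":
        return pd.Series({"national": float(cells["count"].sum())})
    else:
        raise ValueError(f"unknown level {level!r}")
    return cells.groupby(key)["count"].sum().astype(float)


def true_block_group_prevalence(
    true: TrueModel, geo: GeographyFrame, cells: pd.DataFrame
) -> pd.Series:
    """Population-weighted true prevalence per block group.

    Evaluates the TrueModel at each demographic cell's block-group covariates
    (all terms the model carries, including any county-level terms and the
    realized state/county random intercepts) and averages over cells with the
    census counts as weights.  Block groups with zero children are dropped.
    """
    bg = geo.bg_covariates().loc[cells["bg_id"]].reset_index()
    cc = geo.county_covariates().loc[bg["county_id"]].reset_index()
    eta = linear_predictor(
        true,
        sex=cells["sex"].reset_index(drop=True),
        age_group=cells["age_group"].reset_index(drop=True),
        race=cells["race"].reset_index(drop=True),
        income_octile=bg["income_octile"],
        lifestyle=bg["lifestyle_class"],
        urbanization=bg["urbanization_class"]
        if "zip_urbanization" in true.fixed_effects
        else None,
        county_income=cc["income_octile"] if "county_income_octile" in true.fixed_effects else None,
        county_urban_rural=cc["urban_rural_class"]
        if "county_urban_rural" in true.fixed_effects
        else None,
        state_id=bg["state_id"],
        county_id=bg["county_id"],
    )
    risk = expit(eta)
    w = cells["count"].to_numpy(dtype=float)
    num = pd.Series(risk * w).groupby(cells["bg_id"].to_numpy()).sum()
    den = pd.Series(w).groupby(cells["bg_id"].to_numpy()).sum()
    return (num / den).dropna()
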
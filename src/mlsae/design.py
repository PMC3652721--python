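"""Design construction: survey records + area covariates -> model matrices.

All covariates are categorical and enter as dummies against a declared
reference level, in the fixed level order of :mod:`mlsae.categories`, so the
column layout of every design matrix is reproducible and round-trips to
(term, level) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import categories as cat
from .geography import GeographyFrame

#: the four random-intercept structures considered for model selection
RANDOM_STRUCTURES = {
    "state": ["state"],
    "county": ["county"],
    "state+county": ["state", "county"],
    "zip": ["zip"],
}


@dataclass
class ModelSpec:
    """Fixed-term list plus one of the supported random-intercept structures.

    ``fixed_terms`` is an ordered subset of :data:`mlsae.categories.FULL_TERMS`
    (empty list = null model, intercept + random effects only).
    ``random_terms`` is one of [], ["state"], ["county"], ["zip"],
    ["state", "county"] (county nested in state).
    """

    fixed_terms: list[str] = field(default_factory=lambda: list(cat.FULL_TERMS))
    random_terms: list[str] = field(default_factory=lambda: ["state", "county"])

    def __post_init__(self):
        for t in self.fixed_terms:
            if t not in cat.TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        allowed = [[], ["state"], ["county"], ["zip"], ["state", "county"]]
        if list(self.random_terms) not in allowed:
            raise ValueError(
                f"random_terms must be one of {allowed}, got {self.random_terms!r}"
            )

    @property
    def n_fixed_params(self) -> int:
        return 1 + sum(len(cat.nonreference_levels(t)) for t in self.fixed_terms)

    def column_names(self) -> list[tuple[str, str]]:
        cols = [("intercept", "")]
        for t in self.fixed_terms:
            cols += [(t, str(lv)) for lv in cat.nonreference_levels(t)]
        return cols


@dataclass
class DesignBundle:
    """Response, fixed-effect matrix and random-term index vectors."""

    y: np.ndarray                     # (n,) 0/1 response
    X: np.ndarray                     # (n, p) dummies incl. intercept column
    columns: list[tuple[str, str]]    # (term, level) per column
    random_terms: list[str]
    group_index: dict[str, np.ndarray]   # term -> (n,) int codes
    group_ids: dict[str, np.ndarray]     # term -> level code -> area id
    spec: "ModelSpec" = None

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> dict[str, int]:
        return {t: len(self.group_ids[t]) for t in self.random_terms}


_TERM_COLUMN = {
    "zip_income_octile": ("zip", "income_octile"),
    "zip_lifestyle": ("zip", "lifestyle_class"),
    "zip_urbanization": ("zip", "urbanization_class"),
    "county_income_octile": ("county", "income_octile"),
    "county_urban_rural": ("county", "urban_rural_class"),
}


def _dummy_block(values: pd.Series, term: str) -> np.ndarray:
    lv = cat.nonreference_levels(term)
    known = set(map(str, cat.levels(term)))
    seen = set(values.astype(str).unique())
    bad = seen - known
    if bad:
        raise ValueError(f"unseen level(s) {sorted(bad)} for term {term!r}")
    vals = values.astype(str).to_numpy()
    out = np.zeros((len(vals), len(lv)))
    for j, level in enumerate(lv):
        out[:, j] = vals == str(level)
    return out


def covariate_frame(records: pd.DataFrame, geo: GeographyFrame) -> pd.DataFrame:
    """Join each record's zip- and county-level covariates onto the records."""
    zc = geo.zip_covariates()
    cc = geo.county_covariates()
    missing = set(records["zip_id"]) - set(zc.index)
    if missing:
        raise ValueError(f"records reference unknown zip(s) {sorted(missing)[:3]}")
    missing = set(records["county_id"]) - set(cc.index)
    if missing:
        raise ValueError(f"records reference unknown county(s) {sorted(missing)[:3]}")
    out = records.reset_index(drop=True).copy()
    for area, prefix in (("zip", "zip"), ("county", "county")):
        src = zc if area == "zip" else cc
        joined = src.loc[out[f"{area}_id"]].reset_index(drop=True)
        for col in joined.columns:
            if col in ("county_id", "state_id"):
                continue
            out[f"{prefix}__{col}"] = joined[col].to_numpy()
    return out


def build_design(
    records: pd.DataFrame, geo: GeographyFrame, spec: ModelSpec
) -> DesignBundle:
    """Assemble the model matrices for ``spec`` from survey records.

    Child-level terms are read off the records; zip/county terms are joined
    from the geography.  Random-term index vectors code each record's area as
    an integer into a sorted area-id list.
    """
    cov = covariate_frame(records, geo)
    n = len(cov)
    blocks = [np.ones((n, 1))]
    for term in spec.fixed_terms:
        if cat.TERM_AREA[term] == "child":
            col = {"age": "age_group"}.get(term, term)
            series = cov[col]
        else:
            area, column = _TERM_COLUMN[term]
            series = cov[f"{area}__{column}"]
        blocks.append(_dummy_block(series, term))
    X = np.hstack(blocks)

    group_index, group_ids = {}, {}
    for term in spec.random_terms:
        ids_col = {"state": "state_id", "county": "county_id", "zip": "zip_id"}[term]
        codes, uniques = pd.factorize(cov[ids_col], sort=True)
        group_index[term] = codes.astype(np.int64)
        group_ids[term] = np.asarray(uniques)

    y = cov["obese"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be 0/1")
    return DesignBundle(
        y=y,
        X=X,
        columns=spec.column_names(),
        random_terms=list(spec.random_terms),
        group_index=group_index,
        group_ids=group_ids,
        spec=spec,
    )
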
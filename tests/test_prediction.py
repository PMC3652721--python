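"""Post-stratified prediction: cell risks, weighting, MC intervals, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from mlsae import (
    ModelSpec,
    BinomialGLMM,
    PredictiveModel,
    block_group_prevalence,
    cell_risk,
    generate_geography,
    generate_population_cells,
    mc_prevalence_draws,
    summarize_sae,
)
from mlsae import categories as cat
from mlsae import coefficients as coefmod


def _flat_model(intercept=0.0, se=0.0, state_effects=None, **coef_overrides):
    coefs = {t: {} for t in cat.PREDICTIVE_TERMS}
    ses = {t: {lv: se for lv in cat.nonreference_levels(t)} for t in cat.PREDICTIVE_TERMS}
    for term, d in coef_overrides.items():
        coefs[term] = d
    return PredictiveModel(
        intercept=intercept,
        intercept_se=se,
        coefficients=coefs,
        standard_errors=ses,
        state_effects=state_effects or {},
    )


def reference_model(se=0.0):
    coefs = {t: dict(coefmod.COEFFICIENTS[t]) for t in cat.PREDICTIVE_TERMS}
    ses = {
        t: {lv: (coefmod.STANDARD_ERRORS[t][lv] if se is None else se)
            for lv in cat.nonreference_levels(t)}
        for t in cat.PREDICTIVE_TERMS
    }
    return PredictiveModel(
        intercept=coefmod.INTERCEPT,
        intercept_se=coefmod.INTERCEPT_SE if se is None else se,
        coefficients=coefs,
        standard_errors=ses,
    )


def test_all_zero_coefficients_give_one_half():
    m = _flat_model()
    assert cell_risk(m, "M", "10-14", "black", 3, "Global Roots") == pytest.approx(0.5)


def test_reference_cell_risk_is_inverse_logit_of_intercept():
    m = reference_model()
    r = cell_risk(m, "F", "15-17", "white", 8, "Solo Acts", state_effect=0.0)
    assert r == pytest.approx(expit(-3.4529), abs=1e-12)
    assert r == pytest.approx(0.0307, abs=5e-4)


def test_mixed_profile_risk_sums_printed_coefficients():
    m = reference_model()
    r = cell_risk(m, "M", "10-14", "black", 1, "Global Roots", state_effect=0.0)
    eta = -3.4529 + 0.5753 + 0.4117 + 0.6804 + 0.8478 + 0.4404
    assert eta == pytest.approx(-0.4973, abs=1e-12)
    assert r == pytest.approx(expit(eta), abs=1e-12)
    assert r == pytest.approx(0.378, abs=1e-3)


def test_unknown_level_raises():
    with pytest.raises(KeyError):
        cell_risk(_flat_model(), "M", "10-14", "martian", 1, "Global Roots")
    with pytest.raises(KeyError):
        cell_risk(_flat_model(), "M", "10-14", "black", 1, "Global Roots", state_id="S99")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(delta=st.floats(0.01, 2.0))
def test_risk_monotone_in_active_coefficient(delta):
    base = _flat_model(sex={"M": 0.2})
    bumped = _flat_model(sex={"M": 0.2 + delta})
    lo = cell_risk(base, "M", "15-17", "white", 8, "Solo Acts")
    hi = cell_risk(bumped, "M", "15-17", "white", 8, "Solo Acts")
    assert hi > lo


# ------------------------------------------------------------ weighting
@pytest.fixture(scope="module")
def one_bg_geo():
    return generate_geography(1, 1, 1, 1, seed=23)


def _cells(geo, rows):
    bg = geo.block_groups["bg_id"].iloc[0]
    return pd.DataFrame(
        [{"bg_id": bg, "sex": s, "age_group": a, "race": r, "count": c} for s, a, r, c in rows]
    )


def test_single_cell_estimate_equals_its_risk(one_bg_geo):
    m = _flat_model(intercept=-1.3, state_effects={"S00": 0.0})
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 17)])
    out = block_group_prevalence(m, cells, one_bg_geo)
    assert out["estimate"].iloc[0] == pytest.approx(expit(-1.3), abs=1e-12)
    assert out["n_children"].iloc[0] == 17


def test_two_cell_weighted_average(one_bg_geo):
    # risks 0.1 and 0.3 with counts 10 and 30 -> (10*0.1+30*0.3)/40 = 0.25
    from scipy.special import logit

    m = _flat_model(intercept=logit(0.1), sex={"M": logit(0.3) - logit(0.1)},
                    state_effects={"S00": 0.0})
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 10), ("M", "15-17", "white", 30)])
    out = block_group_prevalence(m, cells, one_bg_geo)
    assert out["estimate"].iloc[0] == pytest.approx(0.25, abs=1e-12)


def test_constant_risk_independent_of_counts(one_bg_geo):
    m = _flat_model(intercept=-0.7, state_effects={"S00": 0.0})
    for counts in ([1, 1], [5, 500]):
        cells = _cells(one_bg_geo, [("F", "15-17", "white", counts[0]),
                                    ("M", "10-14", "black", counts[1])])
        out = block_group_prevalence(m, cells, one_bg_geo)
        assert out["estimate"].iloc[0] == pytest.approx(expit(-0.7), abs=1e-12)


def test_zero_population_block_group_suppressed(one_bg_geo):
    m = _flat_model(state_effects={"S00": 0.0})
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 0)])
    out = block_group_prevalence(m, cells, one_bg_geo)
    assert len(out) == 0


# ------------------------------------------------------------ MC intervals
def test_zero_se_degenerates_to_point(one_bg_geo):
    m = _flat_model(intercept=-1.0, state_effects={"S00": 0.0})
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 50)])
    frame = mc_prevalence_draws(m, cells, one_bg_geo, n_draws=200, seed=5).to_frame()
    assert frame["ci_width"].iloc[0] == pytest.approx(0.0, abs=1e-15)
    assert frame["cv"].iloc[0] == pytest.approx(0.0, abs=1e-15)


def test_intercept_only_interval_matches_normal_quantiles(one_bg_geo):
    """beta0=0, se=1: CI -> (expit(-1.96), expit(1.96)) by monotone transform."""
    m = _flat_model(intercept=0.0, se=0.0, state_effects={"S00": 0.0})
    m.intercept_se = 1.0
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 10)])
    frame = mc_prevalence_draws(m, cells, one_bg_geo, n_draws=100_000, seed=6).to_frame()
    assert frame["ci_low"].iloc[0] == pytest.approx(expit(-1.959964), abs=0.01)
    assert frame["ci_high"].iloc[0] == pytest.approx(expit(1.959964), abs=0.01)


def test_mc_draws_are_seed_reproducible(one_bg_geo):
    m = _flat_model(intercept=-1.0, se=0.2, state_effects={"S00": 0.0})
    m.intercept_se = 0.15
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 25), ("M", "10-14", "black", 12)])
    a = mc_prevalence_draws(m, cells, one_bg_geo, n_draws=300, seed=9)
    b = mc_prevalence_draws(m, cells, one_bg_geo, n_draws=300, seed=9)
    assert np.array_equal(a.draws, b.draws)
    assert a.to_frame().to_csv() == b.to_frame().to_csv()


def test_missing_se_rejected(one_bg_geo):
    m = _flat_model(intercept=-1.0, state_effects={"S00": 0.0})
    m.standard_errors["sex"]["M"] = float("nan")
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 25)])
    with pytest.raises(ValueError, match="standard error"):
        mc_prevalence_draws(m, cells, one_bg_geo, n_draws=10, seed=0)


# ------------------------------------------------------------ aggregation
@pytest.fixture(scope="module")
def multi_geo():
    return generate_geography(3, 2, 2, 3, seed=31)


@pytest.fixture(scope="module")
def multi_setup(multi_geo):
    m = reference_model(se=None)
    m.state_effects = {s: 0.05 * i for i, s in enumerate(multi_geo.states["state_id"])}
    cells = generate_population_cells(multi_geo, mean_children_per_bg=40.0, seed=32)
    draws = mc_prevalence_draws(m, cells, multi_geo, n_draws=400, seed=33)
    return m, cells, draws


def test_estimates_and_intervals_lie_in_unit_interval(multi_setup):
    _, _, draws = multi_setup
    for level in ("bg", "county", "state", "national"):
        f = draws.aggregate(level).to_frame()
        assert ((f["estimate"] >= 0) & (f["estimate"] <= 1)).all()
        assert ((f["ci_low"] >= 0) & (f["ci_high"] <= 1)).all()
        assert (f["ci_low"] <= f["estimate"] + 0.005).all()
        assert (f["estimate"] <= f["ci_high"] + 0.005).all()


def test_aggregation_weights_by_population(multi_setup):
    _, _, draws = multi_setup
    bg = draws.to_frame()
    county = draws.aggregate("county").to_frame()
    bgmap = draws.geo.bg_covariates()
    for _, row in county.iterrows():
        sub = bg[bgmap.loc[bg["geo_id"], "county_id"].to_numpy() == row["geo_id"]]
        hand = np.average(sub["estimate"], weights=sub["n_children"])
        assert row["estimate"] == pytest.approx(hand, abs=1e-12)


def test_national_estimate_conserved_under_two_aggregation_routes(multi_setup):
    m, cells, draws = multi_setup
    national = draws.aggregate("national").to_frame()["estimate"].iloc[0]
    state = draws.aggregate("state").to_frame()
    via_states = np.average(state["estimate"], weights=state["n_children"])
    assert national == pytest.approx(via_states, abs=1e-12)
    bg = draws.to_frame()
    via_bgs = np.average(bg["estimate"], weights=bg["n_children"])
    assert national == pytest.approx(via_bgs, abs=1e-12)


def test_intervals_aggregate_drawwise_not_by_averaging_bounds(multi_setup):
    _, _, draws = multi_setup
    county = draws.aggregate("county")
    f = county.to_frame()
    # draw-wise aggregation narrows intervals relative to averaging bg bounds
    bg = draws.to_frame()
    bgmap = draws.geo.bg_covariates()
    for gid in f["geo_id"].head(3):
        sub = bg[bgmap.loc[bg["geo_id"], "county_id"].to_numpy() == gid]
        avg_width = np.average(sub["ci_width"], weights=sub["n_children"])
        width = f.loc[f["geo_id"] == gid, "ci_width"].iloc[0]
        assert width <= avg_width + 1e-9


def test_single_bg_county_aggregate_equals_bg(one_bg_geo):
    m = _flat_model(intercept=-1.2, se=0.1, state_effects={"S00": 0.0})
    m.intercept_se = 0.1
    cells = _cells(one_bg_geo, [("F", "15-17", "white", 30)])
    draws = mc_prevalence_draws(m, cells, one_bg_geo, n_draws=250, seed=3)
    bg, county = draws.to_frame(), draws.aggregate("county").to_frame()
    assert county["estimate"].iloc[0] == pytest.approx(bg["estimate"].iloc[0], abs=1e-15)
    assert county["ci_width"].iloc[0] == pytest.approx(bg["ci_width"].iloc[0], abs=1e-15)


# ------------------------------------------------------------ summaries
def test_summary_order_statistics_by_hand():
    frame = pd.DataFrame(
        {"level": "bg", "ci_width": [1.0, 2.0, 3.0, 4.0, 5.0], "cv": [0.1] * 5}
    )
    s = summarize_sae(frame).set_index("statistic")
    assert s.loc["ci_width", "median"] == pytest.approx(3.0)
    # median-unbiased (Hyndman-Fan type 8) quartiles of {1..5}: 5/3 and 13/3
    assert s.loc["ci_width", "q1"] == pytest.approx(5.0 / 3.0)
    assert s.loc["ci_width", "q3"] == pytest.approx(13.0 / 3.0)
    assert s.loc["ci_width", "iqr"] == pytest.approx(8.0 / 3.0)
    assert s.loc["ci_width", "min"] == 1.0 and s.loc["ci_width", "max"] == 5.0
    assert s.loc["cv", "iqr"] == pytest.approx(0.0)


def test_single_result_summary_is_flat():
    frame = pd.DataFrame({"level": "state", "ci_width": [0.12], "cv": [0.05]})
    s = summarize_sae(frame, level="state").set_index("statistic")
    row = s.loc["ci_width"]
    assert row["min"] == row["median"] == row["max"] == pytest.approx(0.12)
    assert row["iqr"] == 0.0


def test_predictive_model_requires_reduced_term_set(small_survey, small_geo):
    spec = ModelSpec(fixed_terms=["sex", "age"], random_terms=["state"])
    res = BinomialGLMM.from_records(small_survey, small_geo, spec).fit()
    with pytest.raises(ValueError, match="reduced"):
        PredictiveModel.from_results(res)
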
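"""GLMM engine: closed forms, oracle agreement, invariances, selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from mlsae import (
    BinomialGLMM,
    ModelSpec,
    SelectionError,
    TrueModel,
    build_design,
    generate_geography,
    is_adequate,
    select_model,
    simulate_survey,
    variance_explained,
)
from mlsae.design import DesignBundle

from conftest import make_tiny_instance
from oracles import fit_agq


def _bundle_from_arrays(y, X, g):
    return DesignBundle(
        y=y,
        X=X,
        columns=[("intercept", "")] + [("x", str(j)) for j in range(1, X.shape[1])],
        random_terms=["g"] if g is not None else [],
        group_index={"g": g} if g is not None else {},
        group_ids={"g": np.unique(g)} if g is not None else {},
        spec=None,
    )


def test_intercept_only_matches_closed_form_logit():
    from mlsae import fit_laplace

    y = np.array([1.0] * 7 + [0.0] * 13)
    X = np.ones((20, 1))
    res = fit_laplace(_bundle_from_arrays(y, X, None))
    assert res.params.iloc[0] == pytest.approx(logit(7 / 20), abs=1e-8)
    assert res.aic == pytest.approx(-2 * res.llf + 2)


def test_summary_reports_fit_and_variances(small_survey, small_geo):
    spec = ModelSpec(fixed_terms=["sex"], random_terms=["state"])
    res = BinomialGLMM.from_records(small_survey, small_geo, spec).fit()
    text = res.summary()
    assert "log-likelihood" in text and "AIC" in text
    assert "sigma2" in text and "state" in text
    frame = res.coef_frame()
    assert list(frame["term"]) == ["intercept", "sex"]
    assert ((frame["p"] >= 0) & (frame["p"] <= 1)).all()


def test_no_random_terms_matches_irls_logistic(small_survey, small_geo):
    """sigma2 -> 0 reduction: plain fit equals an independent IRLS fit."""
    sm = pytest.importorskip("statsmodels.api")
    spec = ModelSpec(fixed_terms=["age", "sex", "race"], random_terms=[])
    bundle = build_design(small_survey, small_geo, spec)
    res = BinomialGLMM(bundle).fit()
    ref = sm.GLM(bundle.y, bundle.X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(res.params.to_numpy(), ref.params, atol=1e-6)
    np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, rtol=1e-4)
    assert res.llf == pytest.approx(ref.llf, abs=1e-6)


@pytest.mark.parametrize("seed", [100, 104, 109, 116])
def test_laplace_tracks_quadrature_oracle(seed):
    """Laplace fit agrees with an adaptive 25-node quadrature fit."""
    y, X, g = make_tiny_instance(seed)
    res = BinomialGLMM(_bundle_from_arrays(y, X, g)).fit(refine=True)
    orc = fit_agq(y, X, g, n_nodes=25)
    assert abs(res.llf - orc["loglik"]) <= 0.05
    assert np.max(np.abs(res.params.to_numpy() - orc["beta"])) <= 0.02


def test_record_order_invariance(small_geo, small_true):
    sv = simulate_survey(small_geo, small_true, n_per_state=150, seed=33)
    spec = ModelSpec(fixed_terms=["sex", "age"], random_terms=["state"])
    res1 = BinomialGLMM.from_records(sv, small_geo, spec).fit()
    shuffled = sv.sample(frac=1.0, random_state=1).reset_index(drop=True)
    res2 = BinomialGLMM.from_records(shuffled, small_geo, spec).fit()
    np.testing.assert_allclose(res1.params.to_numpy(), res2.params.to_numpy(), atol=1e-8)
    assert res1.llf == pytest.approx(res2.llf, abs=1e-7)
    assert res1.sigma2["state"] == pytest.approx(res2.sigma2["state"], abs=1e-8)


def test_nested_state_county_fit_runs_and_reports_two_variances(small_survey, small_geo):
    spec = ModelSpec(fixed_terms=["sex", "age"], random_terms=["state", "county"])
    res = BinomialGLMM.from_records(small_survey, small_geo, spec).fit()
    assert set(res.sigma2) == {"state", "county"}
    assert all(v >= 0 for v in res.sigma2.values())
    assert res.aic == pytest.approx(-2 * res.llf + 2 * (res.model.p + 2))
    assert set(res.re_modes["county"].index) <= set(small_geo.counties["county_id"])


def test_single_area_random_term_rejected():
    y = np.array([0.0, 1.0, 1.0, 0.0])
    X = np.ones((4, 1))
    g = np.zeros(4, dtype=int)
    with pytest.raises(ValueError, match="at least 2"):
        BinomialGLMM(_bundle_from_arrays(y, X, g))


def test_separation_raises_diagnostic_error():
    from mlsae import ConvergenceError

    # x perfectly separates y: the likelihood is unbounded
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = x.copy()
    X = np.column_stack([np.ones(20), x])
    res = None
    try:
        res = BinomialGLMM(_bundle_from_arrays(y, X, None)).fit()
    except ConvergenceError:
        return
    # if no exception, the fit must at least flag non-convergence
    assert res is not None and not res.converged


# ---------------------------------------------------------- model adequacy
def test_variance_explained_arithmetic():
    def stub(s2):
        r = BinomialGLMM.__new__(BinomialGLMM)
        from mlsae.glmm import GLMMResults

        return GLMMResults(
            model=r, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            cov_params=np.empty((0, 0)), sigma2={"state": s2}, sigma2_se={"state": np.nan},
            boundary={"state": False}, re_modes={}, llf=0.0, aic=0.0, n_params=1,
            converged=True,
        )

    assert variance_explained(stub(0.1), stub(0.1), "state") == pytest.approx(0.0)
    with pytest.raises(ZeroDivisionError):
        variance_explained(stub(0.0), stub(0.0), "state")
    with pytest.raises(ValueError):
        variance_explained(stub(0.1), stub(0.1), "zip")


@pytest.mark.parametrize(
    "pct,expected",
    [(93.1, True), (39.999, False), (40.0, True), ([55.0, 41.0], True), ([55.0, 39.0], False)],
)
def test_adequacy_threshold_is_inclusive_forty_percent(pct, expected):
    assert is_adequate(pct) is expected


def test_adequacy_rejects_non_finite():
    with pytest.raises(ValueError):
        is_adequate(float("nan"))


def test_select_model_minimal_aic_with_ties():
    from mlsae.glmm import GLMMResults

    def stub(aic, n_params, converged=True):
        return GLMMResults(
            model=None, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            cov_params=np.empty((0, 0)), sigma2={}, sigma2_se={}, boundary={},
            re_modes={}, llf=0.0, aic=aic, n_params=n_params, converged=converged,
        )

    a, b = stub(100.0, 5), stub(90.0, 7)
    assert select_model([a, b]) is b
    assert select_model([a]) is a
    tie1, tie2 = stub(90.0, 4), stub(90.0, 7)
    assert select_model([tie2, tie1]) is tie1  # fewer parameters wins the tie
    with pytest.raises(SelectionError):
        select_model([stub(50.0, 2, converged=False)])


def test_model_selection_recovers_generating_structure():
    """Data generated with state+county effects selects the nested model."""
    geo = generate_geography(30, 3, 2, 1, seed=50)
    true = TrueModel.draw(geo, seed=51, intercept=-1.2, fixed_effects={"sex": {"M": 0.4}},
                          sigma2_state=0.15, sigma2_county=0.3)
    sv = simulate_survey(geo, true, n_per_state=400, seed=52)
    fits = []
    for rt in (["state"], ["county"], ["state", "county"]):
        spec = ModelSpec(fixed_terms=["sex"], random_terms=rt)
        fits.append(BinomialGLMM.from_records(sv, geo, spec).fit())
    chosen = select_model(fits)
    assert chosen.sigma2.get("county", 0.0) > 0.0


def test_lme4_cross_check(small_geo, small_true, tmp_path):
    """Laplace objective matches R glmer (nAGQ=1) on a shared dataset."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not on PATH")
    sv = simulate_survey(small_geo, small_true, n_per_state=200, seed=77)
    d = sv.assign(male=(sv["sex"] == "M").astype(int))[["obese", "male", "state_id"]]
    csv = tmp_path / "d.csv"
    d.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- glmer(obese ~ male + (1|state_id), data=d, family=binomial, nAGQ=1)\n"
        "cat(as.numeric(logLik(m)), fixef(m), as.numeric(VarCorr(m)$state_id), sep=',')\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=240)
    assert out.returncode == 0, out.stderr
    llf_r, b0_r, b1_r, s2_r = map(float, out.stdout.strip().split(","))
    spec = ModelSpec(fixed_terms=["sex"], random_terms=["state"])
    res = BinomialGLMM.from_records(sv, small_geo, spec).fit(refine=True)
    assert res.llf == pytest.approx(llf_r, abs=5e-3)
    assert res.params.iloc[0] == pytest.approx(b0_r, abs=5e-3)
    assert res.params.iloc[1] == pytest.approx(b1_r, abs=5e-3)
    assert res.sigma2["state"] == pytest.approx(s2_r, abs=2e-2)
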
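"""Pipeline stages binding generation, fitting, prediction and evaluation.

Each stage is a plain function over a validated :class:`RunConfig` and a data
directory, so the command-line layer stays thin and the stages are directly
testable.  Sub-seeds for the independent random stages are derived from the
run seed by fixed offsets, so one seed reproduces every artifact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import categories as cat
from . import coefficients as coefmod
from . import io
from .config import RunConfig
from .design import RANDOM_STRUCTURES, ModelSpec
from .evaluation import (
    apply_reliability_filter,
    compare_paired,
    correlation_curve,
    direct_estimates,
)
from .geography import GeographyFrame, generate_geography
from .glmm import BinomialGLMM, GLMMResults, is_adequate, select_model, variance_explained
from .prediction import PredictiveModel, mc_prevalence_draws, summarize_sae
from .simulate import TrueModel, generate_population_cells, simulate_survey

logger = logging.getLogger(__name__)

SEED_TRUTH, SEED_SURVEY, SEED_CELLS, SEED_MC = 1, 2, 3, 4


def _subseed(seed: int, offset: int) -> int:
    return (seed * 10 + offset) % (2**31 - 1)


def true_model_from_config(cfg: RunConfig, geo: GeographyFrame) -> TrueModel:
    t = cfg.true_model
    fixed = coefmod.COEFFICIENTS if t["coefficients"] == "default" else t["coefficients"]
    if t["reduced"]:
        fixed = {k: v for k, v in fixed.items() if k in cat.PREDICTIVE_TERMS}
    return TrueModel.draw(
        geo,
        seed=_subseed(cfg.seed, SEED_TRUTH),
        intercept=t["intercept"],
        fixed_effects=fixed,
        sigma2_state=t["sigma2_state"],
        sigma2_county=t["sigma2_county"],
    )


def simulate_stage(cfg: RunConfig, out_dir: Path) -> dict:
    """Generate geography, truth, census cells and survey; write the CSVs."""
    out_dir = Path(out_dir)
    chash = io.config_hash(cfg.to_dict())
    g = cfg.geography
    geo = generate_geography(
        g["n_states"],
        g["counties_per_state"],
        g["zips_per_county"],
        g["bgs_per_county"],
        seed=cfg.seed,
        bg_covariate_source=g["bg_covariate_source"],
    )
    true = true_model_from_config(cfg, geo)
    cells = generate_population_cells(
        geo, cfg.population["mean_children_per_bg"], seed=_subseed(cfg.seed, SEED_CELLS)
    )
    survey = simulate_survey(
        geo,
        true,
        n_per_state=cfg.survey["n_per_state"],
        seed=_subseed(cfg.seed, SEED_SURVEY),
        county_concentration=cfg.survey["county_concentration"],
        state_child_population=cfg.survey["state_child_population"],
    )
    io.write_geography(geo, out_dir, chash)
    io.write_csv(survey, out_dir / "survey.csv", chash)
    io.write_csv(cells, out_dir / "population_cells.csv", chash)
    io.write_json(
        {
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "n_survey_records": len(survey),
            "n_population_cells": len(cells),
            "true_state_effects": true.state_effects,
            "true_county_effects": true.county_effects,
        },
        out_dir / "provenance.json",
        chash,
    )
    logger.info("simulate: %d records, %d cells -> %s", len(survey), len(cells), out_dir)
    return {"geo": geo, "true": true, "survey": survey, "cells": cells}


def _fit_structure(
    survey: pd.DataFrame, geo: GeographyFrame, structure: str, full: bool
) -> GLMMResults:
    spec = ModelSpec(
        fixed_terms=list(cat.FULL_TERMS) if full else [],
        random_terms=RANDOM_STRUCTURES[structure],
    )
    return BinomialGLMM.from_records(survey, geo, spec).fit()


def fit_stage(cfg: RunConfig, data_dir: Path, out_dir: Path | None = None) -> dict:
    """Fit the null+full model roster, pick by AIC, refit the reduced model."""
    data_dir = Path(data_dir)
    out_dir = Path(out_dir) if out_dir is not None else data_dir
    chash = io.config_hash(cfg.to_dict())
    geo = io.read_geography(data_dir)
    survey = io.read_csv(data_dir / "survey.csv")

    adequacy_rows, candidates, meta = [], [], {}
    for structure in cfg.models:
        null = _fit_structure(survey, geo, structure, full=False)
        fullm = _fit_structure(survey, geo, structure, full=True)
        candidates.append((structure, fullm))
        meta[structure] = {
            "aic_full": fullm.aic,
            "llf_full": fullm.llf,
            "converged": fullm.converged,
        }
        for term in RANDOM_STRUCTURES[structure]:
            try:
                pct = variance_explained(null, fullm, term)
            except ZeroDivisionError:
                pct = float("nan")
            adequacy_rows.append(
                {
                    "model": structure,
                    "random_term": term,
                    "sigma2_null": null.sigma2[term],
                    "se_null": null.sigma2_se[term],
                    "sigma2_full": fullm.sigma2[term],
                    "se_full": fullm.sigma2_se[term],
                    "pct_explained": pct,
                    "adequate": is_adequate(pct) if np.isfinite(pct) else None,
                }
            )
    selected_res = select_model([c for _, c in candidates])
    selected = next(s for s, c in candidates if c is selected_res)

    reduced_spec = ModelSpec(fixed_terms=list(cat.PREDICTIVE_TERMS), random_terms=["state"])
    reduced = BinomialGLMM.from_records(survey, geo, reduced_spec).fit()
    predictive = PredictiveModel.from_results(reduced, geo)

    io.write_csv(pd.DataFrame(adequacy_rows), out_dir / "adequacy.csv", chash)
    io.write_csv(selected_res.coef_frame(), out_dir / "coefficients.csv", chash)
    io.write_json(
        {
            "models": meta,
            "selected": selected,
            "selected_aic": selected_res.aic,
            "reduced_llf": reduced.llf,
            "reduced_sigma2_state": reduced.sigma2["state"],
            "reduced_converged": reduced.converged,
        },
        out_dir / "fit_summary.json",
        chash,
    )
    io.write_json(
        {
            "intercept": predictive.intercept,
            "intercept_se": predictive.intercept_se,
            "coefficients": predictive.coefficients,
            "standard_errors": predictive.standard_errors,
            "state_effects": predictive.state_effects,
        },
        out_dir / "predictive_model.json",
        chash,
    )
    logger.info("fit: selected %r (AIC %.2f)", selected, selected_res.aic)
    return {
        "adequacy": pd.DataFrame(adequacy_rows),
        "selected": selected,
        "selected_results": selected_res,
        "reduced_results": reduced,
        "predictive": predictive,
    }


def load_predictive_model(path: Path) -> PredictiveModel:
    d = io.read_json(path)
    coefs = {
        t: {(int(k) if t == "zip_income_octile" else k): v for k, v in lv.items()}
        for t, lv in d["coefficients"].items()
    }
    ses = {
        t: {(int(k) if t == "zip_income_octile" else k): v for k, v in lv.items()}
        for t, lv in d["standard_errors"].items()
    }
    return PredictiveModel(
        intercept=d["intercept"],
        intercept_se=d["intercept_se"],
        coefficients=coefs,
        standard_errors=ses,
        state_effects={k: float(v) for k, v in d["state_effects"].items()},
    )


def predict_stage(cfg: RunConfig, data_dir: Path, out_dir: Path | None = None) -> dict:
    """Post-stratified SAEs with MC intervals at every geography level."""
    data_dir = Path(data_dir)
    out_dir = Path(out_dir) if out_dir is not None else data_dir
    chash = io.config_hash(cfg.to_dict())
    geo = io.read_geography(data_dir)
    cells = io.read_csv(data_dir / "population_cells.csv")
    predictive = load_predictive_model(data_dir / "predictive_model.json")

    bg_draws = mc_prevalence_draws(
        predictive, cells, geo, n_draws=cfg.n_draws, seed=_subseed(cfg.seed, SEED_MC)
    )
    frames = {"bg": bg_draws.to_frame()}
    for level in ("county", "state", "national"):
        frames[level] = bg_draws.aggregate(level).to_frame()
    summaries = []
    for level in ("bg", "county", "state"):
        s = summarize_sae(frames[level])
        s.insert(0, "level", level)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    for level, frame in frames.items():
        io.write_csv(frame, out_dir / f"sae_{level}.csv", chash)
    io.write_csv(summary, out_dir / "sae_summary.csv", chash)
    logger.info(
        "predict: %d block groups, national estimate %.4f",
        len(frames["bg"]),
        frames["national"]["estimate"].iloc[0],
    )
    return {"frames": frames, "summary": summary, "draws": bg_draws}


def evaluate_stage(cfg: RunConfig, data_dir: Path, out_dir: Path | None = None) -> dict:
    """Compare model-based SAEs with direct survey estimates."""
    data_dir = Path(data_dir)
    out_dir = Path(out_dir) if out_dir is not None else data_dir
    chash = io.config_hash(cfg.to_dict())
    survey = io.read_csv(data_dir / "survey.csv")
    sae_county = io.read_csv(data_dir / "sae_county.csv")
    sae_national = io.read_csv(data_dir / "sae_national.csv")

    direct = direct_estimates(survey, level="county")
    reliable = apply_reliability_filter(
        direct, min_n=cfg.reliability["min_n"], max_rse=cfg.reliability["max_rse"]
    )
    n_all, n_rel = len(direct), len(reliable)
    summary: dict = {
        "n_counties": n_all,
        "n_reliable": n_rel,
        "n_suppressed": n_all - n_rel,
    }
    comparison_frame = pd.DataFrame()
    if n_rel >= 2:
        comp = compare_paired(sae_county, reliable)
        summary.update(comp.to_dict())
        comparison_frame = sae_county.merge(
            reliable, on="geo_id", suffixes=("_model", "_direct")
        )
        comparison_frame["difference_pp"] = (
            comparison_frame["estimate_model"] - comparison_frame["estimate_direct"]
        ) * 100.0
    else:
        summary["note"] = "fewer than 2 reliable counties; paired comparison skipped"

    direct_national = direct_estimates(survey, level="national")
    summary["national_model"] = float(sae_national["estimate"].iloc[0])
    summary["national_direct"] = float(direct_national["estimate"].iloc[0])

    curve = correlation_curve(
        sae_county, direct, thresholds=tuple(cfg.correlation_thresholds)
    )
    io.write_csv(comparison_frame, out_dir / "comparison.csv", chash)
    io.write_csv(curve, out_dir / "correlation_curve.csv", chash)
    io.write_json(summary, out_dir / "comparison_summary.json", chash)
    logger.info(
        "evaluate: %d/%d reliable counties, p=%s",
        n_rel,
        n_all,
        summary.get("p_value"),
    )
    return {"summary": summary, "curve": curve, "comparison": comparison_frame}


def run_all(cfg: RunConfig, out_dir: Path) -> dict:
    out_dir = Path(out_dir)
    simulate_stage(cfg, out_dir)
    fit = fit_stage(cfg, out_dir)
    pred = predict_stage(cfg, out_dir)
    ev = evaluate_stage(cfg, out_dir)
    return {"fit": fit, "predict": pred, "evaluate": ev}
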
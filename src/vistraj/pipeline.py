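"""End-to-end five-step pipeline runner and report writer.

Stages: cohort loading/filtering; one-class growth-curve fit with SEM fit
indices; class enumeration; label assignment and class trajectory means;
univariate screening; predictor logistic regression (with an optional
spline dose-response for a continuous exposure); distal-outcome models
(unadjusted "model1" and covariate-adjusted "model2"). Each stage's
output is kept in a bundle; a stage failure marks the bundle failed at
that stage but preserves earlier results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vistraj import association, growth, io, mixture, screening, synth
from vistraj._version import __version__
from vistraj.errors import VistrajError

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("vistraj.pipeline")

# covariate set of the adjusted distal-outcome model
MODEL2_DEFAULT = [
    "sex_female",
    "birthplace_urban",
    "residence",
    "occupation_professional",
    "education_formal",
    "economic_good",
    "married",
]


@dataclass
class PipelineConfig:
    input_csv: str | None = None
    sim_config: object | None = None  # path, dict or SimConfig
    time_scores: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    filter: str | int = "complete"  # "complete" or minimum observed waves
    k_max: int = 4
    alpha: float = 0.05
    min_share: float = 0.05
    b_boot: int = 100
    n_starts: int = 50
    seed: int | None = None
    screening_threshold: float = 0.05
    model2_covariates: list[str] = field(default_factory=lambda: list(MODEL2_DEFAULT))
    spline_exposure: str | None = "bmi"
    spline_reference: float | None = 21.0
    mi_m: int = 0  # 0 disables multiple imputation
    mi_cycles: int = 5
    em_max_iter: int = 500
    em_tol: float = 1e-6

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(bundle, name):
    bundle["stages"][name] = {"status": "ok"}
    return bundle["stages"][name]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the five analysis steps; returns the report bundle."""
    bundle: dict = {
        "stages": {},
        "config": {k: v for k, v in asdict(config).items() if k != "sim_config"},
        "version": __version__,
        "seed": config.seed,
    }
    design = growth.GrowthDesign(tuple(config.time_scores))
    allow_partial = config.filter != "complete"
    try:
        table = _load_cohort(config, bundle)
        fit1 = _stage_growth(bundle, table, design, allow_partial, config)
        report = _stage_enumeration(bundle, table, design, config, allow_partial)
        labels = _stage_labels(bundle, table, report, design)
        rows = _stage_screening(bundle, table, labels, config, report)
        _stage_predictors(bundle, table, labels, rows, config, report)
        _stage_outcomes(bundle, table, labels, config, report)
    except _StageFailure:
        pass
    bundle["failed"] = any(s["status"] == "failed" for s in bundle["stages"].values())
    return bundle


class _StageFailure(Exception):
    pass


def _fail(bundle, name, exc):
    logger.error("stage %s failed: %s", name, exc)
    bundle["stages"][name] = {"status": "failed", "error": str(exc)}
    raise _StageFailure from exc


def _load_cohort(config, bundle) -> synth.CohortTable:
    name = "cohort"
    try:
        if config.input_csv:
            table = io.read_cohort_csv(config.input_csv)
        elif config.sim_config is not None:
            cfg = synth.load_config(config.sim_config)
            if config.seed is not None:
                cfg = cfg.with_overrides(seed=config.seed)
            table = synth.simulate_cohort(cfg)
        else:
            raise VistrajError("config needs input_csv or sim_config")
        n0 = table.n_subjects
        if config.filter == "complete":
            table = table.complete_cases()
        else:
            table = table.with_min_waves(int(config.filter))
        _stage(bundle, name).update(n_input=n0, n_retained=table.n_subjects)
        logger.info("cohort: %d subjects retained of %d", table.n_subjects, n0)
        return table
    except (VistrajError, OSError) as exc:
        _fail(bundle, name, exc)


def _stage_growth(bundle, table, design, allow_partial, config):
    name = "growth_curve"
    try:
        fit = growth.fit_lgcm(table.vision_matrix(), design, allow_partial=allow_partial)
        info = _stage(bundle, name)
        info.update(
            alpha=fit.params.alpha.tolist(),
            psi=fit.params.psi.tolist(),
            theta=fit.params.theta.tolist(),
            loglik=fit.loglik,
            indices=asdict(fit.indices),
            converged=fit.converged,
        )
        bundle["growth_fit"] = fit
        logger.info(
            "growth curve: intercept %.3f slope %.3f (CFI %.3f RMSEA %.3f)",
            fit.params.alpha[0], fit.params.alpha[1],
            fit.indices.cfi, fit.indices.rmsea,
        )
        return fit
    except VistrajError as exc:
        _fail(bundle, name, exc)


def _stage_enumeration(bundle, table, design, config, allow_partial):
    name = "enumeration"
    try:
        report = mixture.enumerate_classes(
            table.vision_matrix(), design,
            k_max=config.k_max, alpha=config.alpha, min_share=config.min_share,
            b=config.b_boot, seed=config.seed, n_starts=config.n_starts,
            allow_partial=allow_partial, max_iter=config.em_max_iter, tol=config.em_tol,
        )
        _stage(bundle, name).update(
            selected_k=report.selected_k, trace=report.selection_trace
        )
        bundle["enumeration"] = report
        logger.info("enumeration: selected K=%d", report.selected_k)
        return report
    except VistrajError as exc:
        _fail(bundle, name, exc)


def _stage_labels(bundle, table, report, design):
    name = "labels"
    try:
        fit = report.fits[report.selected_k]
        assign = mixture.assign_labels(fit)
        lam = design.loading_matrix
        rows = []
        for j, lbl in enumerate(assign.labels):
            mu = lam @ fit.params.alpha[j]
            for w, m in enumerate(mu):
                rows.append(
                    {"class": lbl, "wave": w + 1, "implied_mean": m,
                     "share": assign.shares[lbl]}
                )
        bundle["trajectories"] = pd.DataFrame(rows)
        bundle["labels"] = assign
        _stage(bundle, name).update(shares=assign.shares)
        return assign
    except (VistrajError, KeyError) as exc:
        _fail(bundle, name, exc)


def _stage_screening(bundle, table, labels, config, report):
    name = "screening"
    if report.selected_k < 2:
        bundle["stages"][name] = {
            "status": "skipped",
            "reason": "one trajectory class selected; no class contrast to screen",
        }
        return None
    try:
        df = table.estimation_view()
        rows = screening.build_screening_table(
            df, labels.named, predictors=table.predictor_names or None,
            threshold=config.screening_threshold,
        )
        bundle["screening"] = rows
        _stage(bundle, name).update(
            n_selected=sum(r.selected for r in rows), n_tested=len(rows)
        )
        return rows
    except VistrajError as exc:
        _fail(bundle, name, exc)


def _stage_predictors(bundle, table, labels, rows, config, report):
    name = "predictors"
    if report.selected_k < 2:
        bundle["stages"][name] = {"status": "skipped", "reason": "no class contrast"}
        return
    try:
        selected = [r.variable for r in rows if r.selected]
        if not selected:
            bundle["stages"][name] = {"status": "skipped", "reason": "no predictor passed screening"}
            return
        df = table.estimation_view().copy()
        # outcome = 1 for the high-baseline (canonical first) class
        df["class_high"] = (labels.assignments == 0).astype(int)
        fitter = (
            association.impute_and_pool if config.mi_m > 0 else None
        )
        if fitter:
            res = association.impute_and_pool(
                df, "logistic", "class_high", selected, m=config.mi_m,
                seed=config.seed, cycles=config.mi_cycles,
            )
        else:
            res = association.logistic_fit(df, "class_high", selected)
        bundle["predictors"] = res
        _stage(bundle, name).update(n_terms=len(selected))
        exp = config.spline_exposure
        if exp and exp in df.columns and exp in selected:
            covs = [c for c in selected if c != exp]
            spec = association.SplineSpec(reference=config.spline_reference)
            dose = association.rcs_dose_response(df, exp, "class_high", covs, spec)
            bundle["spline"] = dose
            bundle["stages"][name]["spline_p_nonlinearity"] = dose.p_nonlinearity
    except VistrajError as exc:
        _fail(bundle, name, exc)


def _stage_outcomes(bundle, table, labels, config, report):
    name = "outcomes"
    if report.selected_k < 2:
        bundle["stages"][name] = {"status": "skipped", "reason": "no class contrast"}
        return
    if not table.outcome_names:
        bundle["stages"][name] = {"status": "skipped", "reason": "no outcomes in cohort"}
        return
    try:
        df = table.estimation_view().copy()
        df["class_high"] = (labels.assignments == 0).astype(int)
        model2 = [c for c in config.model2_covariates if c in df.columns]
        results = []
        skipped = []
        for out in table.outcome_names:
            vals = pd.to_numeric(df[out], errors="coerce").dropna().unique()
            kind = "logistic" if set(vals) <= {0.0, 1.0} else "linear"
            fitter = association.linear_fit if kind == "linear" else association.logistic_fit
            for tag, covs in (("model1", []), ("model2", model2)):
                try:
                    if config.mi_m > 0 and df[[out, "class_high", *covs]].isna().any().any():
                        res = association.impute_and_pool(
                            df, kind, out, ["class_high"], covs, m=config.mi_m,
                            seed=config.seed, cycles=config.mi_cycles, covariate_tag=tag,
                        )
                    else:
                        res = fitter(df, out, ["class_high"], covs, covariate_tag=tag)
                except VistrajError as exc:
                    # e.g. separation in a sparse categorical cell: record
                    # the failed model without abandoning the other outcomes
                    skipped.append(f"{out}/{tag}: {exc}")
                    continue
                frame = res.table.copy()
                frame.insert(0, "model", tag)
                frame.insert(0, "outcome", out)
                frame.insert(2, "kind", kind)
                results.append(frame)
        if not results:
            raise VistrajError("no outcome model estimable: " + "; ".join(skipped))
        bundle["outcomes"] = pd.concat(results, ignore_index=True)
        info = _stage(bundle, name)
        info.update(n_outcomes=len(table.outcome_names))
        if skipped:
            info.update(not_estimable=skipped)
    except VistrajError as exc:
        _fail(bundle, name, exc)


# ---------------------------------------------------------------------------
# report writing


def _round6(obj):
    """Round floats to 6 significant digits for stable report output."""
    if isinstance(obj, float):
        return float(f"{obj:.6g}") if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round6(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round6(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round6(float(obj))
    return obj


def write_report(bundle: dict, outdir) -> list[str]:
    """Write per-table CSVs, the master JSON summary, and a plain log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(df: pd.DataFrame, fname: str):
        path = outdir / fname
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(fname)

    if "growth_fit" in bundle:
        fit = bundle["growth_fit"]
        idx = asdict(fit.indices)
        save(
            pd.DataFrame(
                [{"intercept_mean": fit.params.alpha[0], "slope_mean": fit.params.alpha[1],
                  "loglik": fit.loglik, **idx}]
            ),
            "growth_fit.csv",
        )
    if "enumeration" in bundle:
        save(bundle["enumeration"].table, "enumeration.csv")
    if "trajectories" in bundle:
        save(bundle["trajectories"], "trajectories.csv")
    if "screening" in bundle:
        save(screening.screening_frame(bundle["screening"]), "screening.csv")
    if "predictors" in bundle:
        save(bundle["predictors"].table, "predictors.csv")
    if "outcomes" in bundle:
        save(bundle["outcomes"], "outcomes.csv")

    summary = {
        "version": bundle.get("version"),
        "seed": bundle.get("seed"),
        "config": bundle.get("config"),
        "stages": bundle["stages"],
        "failed": bundle.get("failed", False),
    }
    if "spline" in bundle:
        dose = bundle["spline"]
        summary["spline"] = {
            "p_nonlinearity": dose.p_nonlinearity,
            "knots": list(dose.knots),
            "reference": dose.reference,
            "curve": dose.curve.to_dict(orient="list"),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round6(summary), fh, indent=1, sort_keys=True)
    written.append("summary.json")

    with open(outdir / "pipeline.log", "w") as fh:
        for sname, info in bundle["stages"].items():
            fh.write(f"{sname}: {info.get('status')}\n")
            for k, v in info.items():
                if k != "status":
                    fh.write(f"  {k}: {_round6(v)}\n")
    written.append("pipeline.log")
    return written
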
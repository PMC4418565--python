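"""End-to-end orchestration: simulate → estimate → censor → evaluate.

Builds the per-subject, per-timepoint predictor table (raw markers,
steady-state eGFR, kinetic GFR), applies dialysis censoring before each
timepoint's analysis, and emits the report tables: AUC grid with DeLong
comparisons, base-model augmentation with IDI, diagnostic cutoff
tables, production-method sensitivity comparison, Bland-Altman
agreement summaries, and the long-term Spearman correlation. A run is
reproducible from its config and seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .gfr_equations import Subject, ckd_epi_creatinine, ckd_epi_cystatin
from .kinetic import KineticConfig, series_kegfr
from .synthetic import (
    TRUTH_PREFIX,
    SimulatedCohort,
    SimulationParams,
    generate_cohort,
    read_cohort,
    write_cohort,
)

__all__ = [
    "RunConfig",
    "PREDICTOR_DIRECTIONS",
    "build_prediction_dataset",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger(__name__)

#: Predictor → ROC direction. GFR estimates fall with graft failure,
#: raw concentrations rise; never inferred from data.
PREDICTOR_DIRECTIONS: dict[str, str] = {
    "sCr": "higher_predicts_event",
    "pCysC": "higher_predicts_event",
    "eGFR_sCr": "lower_predicts_event",
    "eGFR_pCysC": "lower_predicts_event",
    "KeGFR_sCr": "lower_predicts_event",
    "KeGFR_pCysC": "lower_predicts_event",
}

REQUIRED_SUBJECT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "race_black",
    "weight_kg",
    "height_cm",
    "base_risk",
    "dgf",
    "dialysis_time_h",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to YAML."""

    seed: int = 0
    simulation: SimulationParams | None = None
    input_dir: str | None = None
    output_dir: str = "results"
    timepoints: tuple[float, ...] = (4.0, 8.0, 12.0)
    markers: tuple[str, ...] = ("creatinine", "cystatin_c")
    kinetic_creatinine: KineticConfig = field(default_factory=KineticConfig)
    kinetic_cystatin: KineticConfig = field(default_factory=KineticConfig)
    n_bootstrap: int = 500
    base_mode: str = "recalibrate"
    sensitivity_methods: tuple[str, ...] = (
        "ckd_epi_backcalc",
        "cockcroft_gault",
        "fixed_max_delta",
    )

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            self.simulation = SimulationParams(seed=self.seed)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", None)
    kc = raw.pop("kinetic_creatinine", None)
    ky = raw.pop("kinetic_cystatin", None)
    for key in ("timepoints", "markers", "sensitivity_methods"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    if sim is not None:
        for key, value in list(sim.items()):
            if isinstance(value, list):
                sim[key] = tuple(value)
        cfg.simulation = SimulationParams(**sim)
    if kc is not None:
        cfg.kinetic_creatinine = KineticConfig(**kc)
    if ky is not None:
        cfg.kinetic_cystatin = KineticConfig(**ky)
    return cfg


def _validate_subjects(subjects: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table missing required columns: {missing}")


def build_prediction_dataset(
    cohort: SimulatedCohort,
    kinetic_creatinine: KineticConfig | None = None,
    kinetic_cystatin: KineticConfig | None = None,
    timepoints: tuple[float, ...] = (4.0, 8.0, 12.0),
) -> pd.DataFrame:
    """One row per (subject, timepoint) with every predictor.

    Columns: sCr, pCysC, eGFR_sCr, eGFR_pCysC, KeGFR_sCr, KeGFR_pCysC
    (NaN where not computable — e.g. no kinetic cystatin estimate at
    4 h because there is no 0 h cystatin sample), the pre-clamp kinetic
    values for audit, base_risk, dgf, dialysis_time_h and egfr_12mo.
    Ground-truth (``truth_``) columns never enter this table.
    """
    _validate_subjects(cohort.subjects)
    kc = kinetic_creatinine or KineticConfig()
    ky = kinetic_cystatin or KineticConfig()

    rows: list[dict] = []
    meta = cohort.subjects.set_index("subject_id")
    for sid in meta.index:
        subject = cohort.subject(sid)
        values: dict[float, dict] = {t: {} for t in timepoints}

        for marker, cfg, conc_col, kegfr_col, egfr_fn in (
            ("creatinine", kc, "sCr", "KeGFR_sCr", ckd_epi_creatinine),
            ("cystatin_c", ky, "pCysC", "KeGFR_pCysC", ckd_epi_cystatin),
        ):
            series = cohort.series(sid, marker)
            if series is None:
                continue
            for t, c in series.samples:
                if t in values:
                    values[t][conc_col] = c
                    values[t][f"eGFR_{conc_col}"] = egfr_fn(c, subject).value
            if len(series.samples) >= 2:
                try:
                    for est in series_kegfr(series, subject, cfg):
                        if est.time in values:
                            values[est.time][kegfr_col] = est.kegfr
                            values[est.time][f"{kegfr_col}_preclamp"] = (
                                est.pre_clamp_value
                            )
                except ValueError as exc:
                    logger.warning("subject %s %s: %s", sid, marker, exc)

        for t in timepoints:
            row = {
                "subject_id": sid,
                "timepoint_h": t,
                "base_risk": float(meta.loc[sid, "base_risk"]),
                "dgf": bool(meta.loc[sid, "dgf"]),
                "dialysis_time_h": float(meta.loc[sid, "dialysis_time_h"])
                if pd.notna(meta.loc[sid, "dialysis_time_h"])
                else np.nan,
                "egfr_12mo": float(meta.loc[sid, "egfr_12mo"])
                if "egfr_12mo" in meta.columns
                else np.nan,
            }
            row.update(values[t])
            rows.append(row)

    dataset = pd.DataFrame.from_records(rows)
    for col in ("sCr", "pCysC", "eGFR_sCr", "eGFR_pCysC", "KeGFR_sCr", "KeGFR_pCysC"):
        if col not in dataset.columns:
            dataset[col] = np.nan
    truthy = [c for c in dataset.columns if c.startswith(TRUTH_PREFIX)]
    assert not truthy, f"ground-truth columns leaked into predictors: {truthy}"
    return dataset


def _analysis_set(dataset: pd.DataFrame, timepoint: float) -> pd.DataFrame:
    censored = ev.censor_after_dialysis(dataset, timepoint)
    return censored[censored["timepoint_h"] == timepoint]


def _auc_table(dataset: pd.DataFrame, timepoints) -> pd.DataFrame:
    """AUC per predictor per timepoint, with DeLong CI and p vs raw sCr."""
    records = []
    for t in timepoints:
        sub = _analysis_set(dataset, t)
        labels = sub["dgf"].to_numpy()
        for pred, direction in PREDICTOR_DIRECTIONS.items():
            scores = sub[pred].to_numpy()
            ok = np.isfinite(scores)
            if ok.sum() < 3 or len(set(labels[ok])) < 2:
                continue
            if np.unique(scores[ok]).size == 1:
                logger.warning("predictor %s at %g h has zero variance", pred, t)
            roc = ev.empirical_auc(scores[ok], labels[ok], direction)
            rec = {
                "timepoint_h": t,
                "predictor": pred,
                "n": int(ok.sum()),
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
            }
            ref = sub["sCr"].to_numpy()
            both = ok & np.isfinite(ref)
            if pred != "sCr" and both.sum() >= 3:
                oriented = scores if direction == "higher_predicts_event" else -scores
                cmp = ev.delong_variance_and_test(
                    oriented[both], ref[both], labels[both]
                )
                rec["p_vs_scr"] = cmp["p_value"]
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _idi_table(
    dataset: pd.DataFrame, timepoints, n_bootstrap: int, seed: int, base_mode: str
) -> pd.DataFrame:
    """Base-model augmentation per predictor per timepoint."""
    records = []
    for t in timepoints:
        sub = _analysis_set(dataset, t)
        labels = sub["dgf"].to_numpy()
        base = sub["base_risk"].to_numpy()
        if len(set(labels)) < 2:
            continue
        p_base, _ = ev.fit_augmented_model(base, None, labels, base_mode=base_mode)
        base_roc = ev.empirical_auc(p_base, labels)
        records.append(
            {
                "timepoint_h": t,
                "model": "base",
                "n": int(labels.size),
                "auc": base_roc.auc,
                "ci_low": base_roc.ci_low,
                "ci_high": base_roc.ci_high,
            }
        )
        for pred in ("sCr", "KeGFR_sCr", "pCysC", "KeGFR_pCysC"):
            x = sub[pred].to_numpy()
            ok = np.isfinite(x)
            if ok.sum() < 3:
                continue
            xs, bs, ys = x[ok], base[ok], labels[ok]
            if len(set(ys)) < 2 or np.unique(xs).size < 2:
                continue
            pb, pn = ev.fit_augmented_model(bs, xs, ys, base_mode=base_mode)
            result = ev.idi(
                pb,
                pn,
                ys,
                n_bootstrap=n_bootstrap,
                seed=seed,
                refit_inputs=(bs, xs),
                base_mode=base_mode,
            )
            records.append(
                {
                    "timepoint_h": t,
                    "model": f"base+{pred}",
                    "n": int(ok.sum()),
                    "auc": result.auc_augmented,
                    "p_vs_base": result.p_auc_difference,
                    "idi_dgf": result.idi_events,
                    "idi_dgf_ci_low": result.idi_events_ci[0],
                    "idi_dgf_ci_high": result.idi_events_ci[1],
                    "idi_nondgf": result.idi_nonevents,
                    "idi_nondgf_ci_low": result.idi_nonevents_ci[0],
                    "idi_nondgf_ci_high": result.idi_nonevents_ci[1],
                }
            )
    return pd.DataFrame.from_records(records)


def _cutoff_tables(dataset: pd.DataFrame, timepoints) -> pd.DataFrame:
    records = []
    for t in timepoints:
        sub = _analysis_set(dataset, t)
        labels = sub["dgf"].to_numpy()
        for pred in ("KeGFR_sCr", "KeGFR_pCysC"):
            x = sub[pred].to_numpy()
            ok = np.isfinite(x)
            if ok.sum() < 3 or len(set(labels[ok])) < 2:
                continue
            if np.unique(x[ok]).size < 2:
                continue
            table = ev.cutoff_table(
                x[ok], labels[ok], PREDICTOR_DIRECTIONS[pred]
            )
            table.insert(0, "predictor", pred)
            table.insert(0, "timepoint_h", t)
            records.append(table)
    if not records:
        return pd.DataFrame()
    return pd.concat(records, ignore_index=True)


def _sensitivity_table(
    cohort: SimulatedCohort,
    base_cfg_cr: KineticConfig,
    base_cfg_cy: KineticConfig,
    methods,
    timepoints,
) -> pd.DataFrame:
    """AUCs of the kinetic estimates under alternative production
    assumptions (the MaxΔBc/d sensitivity analysis)."""
    from dataclasses import replace

    records = []
    for method in methods:
        cfg_map = {}
        if method != "sjostrom":
            cfg_map["creatinine"] = replace(base_cfg_cr, production_method=method)
        if method in ("ckd_epi_backcalc", "fixed_max_delta"):
            cfg_map["cystatin_c"] = replace(base_cfg_cy, production_method=method)
        elif method == "sjostrom" and base_cfg_cy.sjostrom_production is not None:
            cfg_map["cystatin_c"] = replace(base_cfg_cy, production_method=method)
        dataset = build_prediction_dataset(
            cohort,
            kinetic_creatinine=cfg_map.get("creatinine", base_cfg_cr),
            kinetic_cystatin=cfg_map.get("cystatin_c", base_cfg_cy),
            timepoints=tuple(timepoints),
        )
        for t in timepoints:
            sub = _analysis_set(dataset, t)
            labels = sub["dgf"].to_numpy()
            for pred, marker in (("KeGFR_sCr", "creatinine"), ("KeGFR_pCysC", "cystatin_c")):
                if marker not in cfg_map:
                    continue
                x = sub[pred].to_numpy()
                ok = np.isfinite(x)
                if ok.sum() < 3 or len(set(labels[ok])) < 2:
                    continue
                roc = ev.empirical_auc(x[ok], labels[ok], "lower_predicts_event")
                cutoff, sens, spec = ev.youden_optimal_cutoff(
                    x[ok], labels[ok], "lower_predicts_event"
                )
                records.append(
                    {
                        "production_method": method,
                        "predictor": pred,
                        "timepoint_h": t,
                        "n": int(ok.sum()),
                        "auc": roc.auc,
                        "optimal_cutoff": cutoff,
                        "sensitivity": sens,
                        "specificity": spec,
                    }
                )
    return pd.DataFrame.from_records(records)


def _bland_altman_table(dataset: pd.DataFrame, timepoints) -> pd.DataFrame:
    pairs = (
        ("KeGFR_sCr", "eGFR_sCr"),
        ("KeGFR_pCysC", "eGFR_pCysC"),
        ("KeGFR_sCr", "KeGFR_pCysC"),
    )
    records = []
    for a, b in pairs:
        frames = [_analysis_set(dataset, t) for t in timepoints]
        pooled = pd.concat(frames, ignore_index=True)
        ok = np.isfinite(pooled[a]) & np.isfinite(pooled[b])
        if ok.sum() < 2:
            continue
        result = ev.bland_altman(pooled.loc[ok, a], pooled.loc[ok, b])
        records.append(
            {
                "comparison": f"{a} - {b}",
                "bias": result.bias,
                "loa_low": result.loa_low,
                "loa_high": result.loa_high,
                "pairs": result.pairs_used,
            }
        )
    return pd.DataFrame.from_records(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle in memory
    and writes CSV/JSON artefacts under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        cohort = read_cohort(config.input_dir)
    else:
        cohort = generate_cohort(config.simulation)
        write_cohort(cohort, out / "cohort")

    dataset = build_prediction_dataset(
        cohort,
        kinetic_creatinine=config.kinetic_creatinine,
        kinetic_cystatin=config.kinetic_cystatin,
        timepoints=config.timepoints,
    )

    analysed_n = {
        t: int(len(_analysis_set(dataset, t))) for t in config.timepoints
    }
    clamped = {
        col: int((dataset[f"{col}_preclamp"] < 0).sum())
        for col in ("KeGFR_sCr", "KeGFR_pCysC")
        if f"{col}_preclamp" in dataset.columns
    }
    for t, n in analysed_n.items():
        logger.info("analysis set at %g h: %d subjects", t, n)
    for col, k in clamped.items():
        logger.info("%s: %d negative estimates clamped to 0", col, k)

    aucs = _auc_table(dataset, config.timepoints)
    idis = _idi_table(
        dataset,
        config.timepoints,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        base_mode=config.base_mode,
    )
    cutoffs = _cutoff_tables(dataset, config.timepoints)
    sensitivity = _sensitivity_table(
        cohort,
        config.kinetic_creatinine,
        config.kinetic_cystatin,
        config.sensitivity_methods,
        config.timepoints,
    )
    bland = _bland_altman_table(dataset, config.timepoints)

    # long-term correlation: latest kinetic creatinine estimate vs 12-month eGFR
    t_last = max(config.timepoints)
    sub = _analysis_set(dataset, t_last)
    spearman = None
    ok = np.isfinite(sub["KeGFR_sCr"]) & np.isfinite(sub["egfr_12mo"])
    if ok.sum() >= 3 and np.unique(sub.loc[ok, "KeGFR_sCr"]).size > 1:
        rho, p = ev.spearman_correlation(
            sub.loc[ok, "KeGFR_sCr"], sub.loc[ok, "egfr_12mo"]
        )
        spearman = {"rho": rho, "p": p, "n": int(ok.sum()), "timepoint_h": t_last}

    dataset.to_csv(out / "prediction_dataset.csv", index=False)
    aucs.to_csv(out / "auc_table.csv", index=False)
    idis.to_csv(out / "idi_table.csv", index=False)
    cutoffs.to_csv(out / "cutoff_tables.csv", index=False)
    sensitivity.to_csv(out / "sensitivity_production_methods.csv", index=False)
    bland.to_csv(out / "bland_altman.csv", index=False)

    summary = {
        "seed": config.seed,
        "n_subjects": int(cohort.subjects.shape[0]),
        "analysed_n": {str(k): v for k, v in analysed_n.items()},
        "negative_clamped": clamped,
        "spearman_12mo": spearman,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    return {
        "cohort": cohort,
        "dataset": dataset,
        "auc_table": aucs,
        "idi_table": idis,
        "cutoff_tables": cutoffs,
        "sensitivity": sensitivity,
        "bland_altman": bland,
        "spearman": spearman,
        "summary": summary,
    }
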
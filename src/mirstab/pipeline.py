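"""One-command orchestration: QC -> filter -> hemolysis -> calibration ->
batch -> normalization -> stability -> metadata, with per-stage outputs,
a run summary and logging. Deterministic under a fixed seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import filtering, metadata, normalize, stability
from .config import PipelineConfig, SimulationConfig, config_to_dict
from .datatypes import ACCEPTABLE, StudyTable
from .ingest import parse_expression_export, verify_controls
from .simulate import read_metadata, simulate_study

log = logging.getLogger("mirstab")


@dataclass
class PipelineResult:
    study: StudyTable
    coverage: pd.DataFrame
    retained: list[str]
    always_observed: list[str]
    hemolysis: pd.DataFrame
    calibrated: StudyTable
    audits: dict
    correlations: dict
    normalization: normalize.NormalizationResult
    stability: pd.DataFrame
    breakpoint: stability.BreakpointResult
    metadata: dict
    variance_audit: dict
    summary: dict = field(default_factory=dict)


def dropout_table(study: StudyTable, stab: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA mean Cq and dropout counts for the breakpoint scan."""
    wells = study.wells[study.wells["assay_id"].isin(stab["mirna_id"])]
    counts = wells.groupby("assay_id")["status"].agg(
        total="count", ok=lambda s: (s == ACCEPTABLE).sum()
    )
    out = stab.set_index("mirna_id")[["grand_mean_cq"]].join(counts)
    out["dropout"] = out["total"] - out["ok"]
    return out.reset_index()


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    input_dir: str | Path | None = None,
    seed: int | None = None,
    pipe_config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated study or a directory of
    per-participant exports (with samples.csv / participants.csv)."""
    pc = pipe_config or PipelineConfig()

    if (sim_config is None) == (input_dir is None):
        raise ValueError("give exactly one of sim_config or input_dir")
    if sim_config is not None:
        log.info("simulating study (seed=%s)", seed if seed is not None else sim_config.seed)
        study, _truth = simulate_study(sim_config, seed=seed)
    else:
        input_dir = Path(input_dir)
        paths = sorted(input_dir.glob("*_export.csv"))
        if not paths:
            raise ValueError(f"no *_export.csv files under {input_dir}")
        samples, participants = read_metadata(input_dir)
        study = parse_expression_export(
            paths, samples=samples, participants=participants, qc=pc.qc
        )
    log.info("study: %d participants, %d samples, %d wells",
             len(study.participant_ids), study.n_samples, len(study.wells))

    controls = verify_controls(study)
    if not controls.clean:
        log.warning("control report not clean: %s", controls.to_dict())

    coverage = filtering.longitudinal_coverage(study)
    selection = filtering.select_by_coverage(coverage, study, pc.coverage_cutoff)
    retained = filtering.retained_assays(selection)
    always = filtering.always_observed(study, retained)
    log.info("retained %d scientific miRNAs; %d always observed",
             len(retained), len(always))

    hemolysis = filtering.hemolysis_scores(study, pc.hemolysis_threshold)

    factors = cal.exogenous_calibration_factor(study, always)
    raw_corr = cal.control_correlations(study, always)
    aligned, align_audit = cal.median_align(study, factors)
    aligned_corr = cal.control_correlations(aligned, always)
    detrended, detrend_audit = cal.sequence_detrend(aligned, retained)
    adjusted, batch_audit = cal.batch_adjust(
        detrended, retained, hemolysis, pc.baseline_distance_flag
    )

    variance_audit = {
        "raw": cal.shared_technical_sd(study, retained),
        "spikein_aligned": cal.shared_technical_sd(aligned, retained),
        "sequence_detrended": cal.shared_technical_sd(detrended, retained),
        "batch_adjusted": cal.shared_technical_sd(adjusted, retained),
    }
    log.info("shared technical SD by stage: %s", variance_audit)

    sets = normalize.build_normalizer_sets(adjusted)
    covariates = normalize.build_covariates(adjusted, sets, hemolysis)
    norm = normalize.normalize_study(
        adjusted, covariates, retained, max_cq=pc.qc.max_cq
    )

    cov_map = selection.set_index("assay_id")["mean_coverage"]
    sigma_map = norm.summaries.set_index("mirna_id")["sigma"]
    stab = stability.analyze_stability(
        norm.normalized,
        coverage=cov_map.to_dict(),
        days_per_visit=pc.days_per_visit,
        sd_cutoff=pc.sd_cutoff,
        sigma=sigma_map.to_dict(),
    )

    drop = dropout_table(study, stab)
    bp = stability.breakpoint_supremum(
        drop["grand_mean_cq"], drop["dropout"], drop["total"]
    )

    meta = metadata.analyze_metadata(
        norm.normalized, study.samples, study.participants, hemolysis,
        random_state=0 if seed is None else int(seed),
    )

    summary = {
        "seed": seed,
        "n_participants": len(study.participant_ids),
        "n_samples": study.n_samples,
        "n_assays": int(study.assay_roster["assay_id"].nunique()),
        "n_retained": len(retained),
        "n_always_observed": len(always),
        "n_stable": int(stab["stable"].sum()),
        "breakpoint_cq": bp.breakpoint_cq,
        "coverage_cutoff": pc.coverage_cutoff,
        "control_report": controls.to_dict(),
        "correlations_raw": raw_corr,
        "correlations_aligned": aligned_corr,
        "variance_audit": variance_audit,
        "bias_flags": meta["bias_flags"],
        "variance_flags": meta["variance_flags"],
    }

    return PipelineResult(
        study=study,
        coverage=selection,
        retained=retained,
        always_observed=always,
        hemolysis=hemolysis,
        calibrated=adjusted,
        audits={
            "align": align_audit,
            "detrend": detrend_audit,
            "batch": batch_audit,
        },
        correlations={"raw": raw_corr, "aligned": aligned_corr},
        normalization=norm,
        stability=stab,
        breakpoint=bp,
        metadata=meta,
        variance_audit=variance_audit,
        summary=summary,
    )


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all stage outputs as CSV/JSON (deterministic formatting)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.6g")

    result.study.wells.to_csv(out / "unified_wells.csv", **kw)
    result.coverage.sort_values("assay_id").to_csv(out / "coverage.csv", **kw)
    result.hemolysis.to_csv(out / "hemolysis.csv", **kw)
    result.calibrated.wells.to_csv(out / "calibrated_wells.csv", **kw)
    result.normalization.normalized.to_csv(out / "normalized.csv", **kw)
    result.normalization.summaries.to_csv(out / "normalization_models.csv", **kw)
    result.stability.to_csv(out / "stability.csv", **kw)
    result.metadata["bias_effects"].round(6).to_csv(out / "bias_effects.csv")
    result.metadata["variance_effects"].round(6).to_csv(out / "variance_effects.csv")

    with open(out / "control_report.json", "w") as fh:
        json.dump(result.summary["control_report"], fh, indent=2, sort_keys=True)
    audit = {
        "align": {k: v for k, v in result.audits["align"].items() if k != "shifts"},
        "detrend": {
            k: v for k, v in result.audits["detrend"].items() if k != "curve"
        },
        "batch": result.audits["batch"],
    }
    with open(out / "calibration_audit.json", "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True, default=float)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=float)
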
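"""Shared test drivers: stage-wise pipeline runner, reduced study
configurations, generator ground-truth helpers and constructed studies."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mirstab import calibration as cal
from mirstab import filtering, metadata, normalize, stability
from mirstab.config import SimulationConfig
from mirstab.datatypes import ACCEPTABLE, StudyTable
from mirstab.simulate import NAMED_BASELINES, simulate_study


def tiny_config(**kw) -> SimulationConfig:
    """8 donors, 15 assays: fast end-to-end runs."""
    base = dict(
        n_participants=8,
        visits_per_participant=(5, 6, 7, 6, 5, 6, 7, 6),
        n_female=5,
        n_regular_tobacco=2,
        n_assays=15,
        n_measurable=12,
    )
    base.update(kw)
    return SimulationConfig(**base)


def reduced_config(**kw) -> SimulationConfig:
    """Study-scale cohort with a reduced assay panel."""
    base = dict(n_assays=60, n_measurable=40)
    base.update(kw)
    return SimulationConfig(**base)


def zero_noise_config(**kw) -> SimulationConfig:
    """Fully deterministic latent values; nothing drops out."""
    base = dict(
        n_participants=8,
        visits_per_participant=(5, 6, 7, 6, 5, 6, 7, 6),
        n_female=5,
        n_regular_tobacco=0,
        n_assays=15,
        n_measurable=12,
        participant_sd=0.0,
        participant_background_sd=0.0,
        sample_shift_sd=0.0,
        batch_sd=0.0,
        test_retest_sd_range=(0.0, 0.0),
        drift_pct_per_month_range=(0.0, 0.0),
        hemolysis_sd=0.0,
        hemolysis_sensitive_fraction=0.0,
        n_tobacco_bias_mirnas=0,
        n_tobacco_moderated_mirnas=0,
        n_sex_moderated_mirnas=0,
        dropout_location=np.inf,
        baseline_flag_prob=0.0,
        baseline_cq_range=(20.0, 32.0),
        spikein_rep_sd=0.0,
        mir16_rep_sd=0.0,
        control_noise_sd=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def run_stages(study, pc=None, mirnas=None, with_metadata=False, seed=0):
    """Run filter -> hemolysis -> calibration -> normalization -> stability
    on an existing study; returns a dict of stage outputs."""
    cov = filtering.longitudinal_coverage(study)
    sel = filtering.select_by_coverage(cov, study)
    retained = filtering.retained_assays(sel)
    always = filtering.always_observed(study, retained)
    hem = filtering.hemolysis_scores(study)
    factors = cal.exogenous_calibration_factor(study, always)
    aligned, align_audit = cal.median_align(study, factors)
    detrended, detrend_audit = cal.sequence_detrend(aligned, retained)
    adjusted, batch_audit = cal.batch_adjust(detrended, retained, hem)
    sets = normalize.build_normalizer_sets(adjusted)
    covs = normalize.build_covariates(adjusted, sets, hem)
    norm = normalize.normalize_study(adjusted, covs, mirnas or retained)
    sigma = norm.summaries.set_index("mirna_id")["sigma"]
    covmap = sel.set_index("assay_id")["mean_coverage"]
    stab = stability.analyze_stability(
        norm.normalized, coverage=covmap.to_dict(), sigma=sigma.to_dict()
    )
    out = dict(
        selection=sel, retained=retained, always=always, hemolysis=hem,
        factors=factors, aligned=aligned, detrended=detrended,
        adjusted=adjusted, audits=dict(align=align_audit,
                                       detrend=detrend_audit,
                                       batch=batch_audit),
        covariates=covs, normalization=norm, stability=stab,
    )
    if with_metadata:
        out["metadata"] = metadata.analyze_metadata(
            norm.normalized, study.samples, study.participants, hem,
            random_state=seed,
        )
    return out


def high_coverage_generic(selection, retained, cutoff=0.9):
    """Retained non-normalizer miRNAs with mean coverage >= cutoff."""
    covmap = selection.set_index("assay_id")["mean_coverage"]
    return [
        m for m in retained
        if covmap[m] >= cutoff and m not in NAMED_BASELINES
    ]


def effective_within_sd(truth) -> pd.Series:
    """True within-donor (test-retest) SD per measurable miRNA, pooling the
    donor-specific moderation factors with ANOVA degrees-of-freedom
    weights."""
    cfg = truth.config
    parts = truth.participants
    assays = truth.assays.set_index("assay_id")
    visits = dict(zip(parts["participant_id"], cfg.visits_per_participant))
    n_i = np.array([visits[p] for p in parts["participant_id"]], float)
    w = (n_i - 1) / (n_i - 1).sum()
    out = {}
    for aid, row in assays.iterrows():
        if not row["measurable"]:
            continue
        mod = np.ones(len(parts))
        if row["tobacco_moderated"]:
            mod *= np.where(
                parts["regular_tobacco"], cfg.tobacco_moderation_factor, 1.0
            )
        if row["sex_moderated"]:
            mod *= np.where(parts["sex"] == "M", cfg.sex_moderation_factor, 1.0)
        out[aid] = row["sigma"] * np.sqrt(np.sum(w * mod**2))
    return pd.Series(out)


def residual_study(seed, n_participants=22, n_visits=6, n_mirnas=50,
                   batch_sd=0.3, noise_sd=0.3, batch_size=8) -> tuple[StudyTable, pd.Series]:
    """Constructed study of detrended-style residuals with known isolation
    batch effects: cq = donor-miRNA level + g_b + noise, wave batching."""
    rng = np.random.default_rng(seed)
    pids = [f"P{i:02d}" for i in range(n_participants)]
    recs = [(p, v + 1) for p in pids for v in range(n_visits)]
    samples = pd.DataFrame(recs, columns=["participant_id", "visit_index"])
    iso = samples.sort_values(["visit_index", "participant_id"]).index
    batch_idx = pd.Series(np.arange(len(samples)) // batch_size, index=iso).sort_index()
    samples["isolation_batch"] = [f"B{b:02d}" for b in batch_idx]
    samples["process_order"] = np.arange(1, len(samples) + 1)
    labels = sorted(samples["isolation_batch"].unique())
    g = pd.Series(rng.normal(0.0, batch_sd, len(labels)), index=labels)
    base = rng.normal(25.0, 2.0, (n_participants, n_mirnas))

    rows = []
    for pid, vi, ib, po in samples[
        ["participant_id", "visit_index", "isolation_batch", "process_order"]
    ].itertuples(index=False):
        p = pids.index(pid)
        cq = base[p] + g[ib] + rng.normal(0.0, noise_sd, n_mirnas)
        for m in range(n_mirnas):
            rows.append((pid, vi, f"m{m:03d}", 1, cq[m], 1.5, 0.95, "", po, ib,
                         ACCEPTABLE))
    wells = pd.DataFrame(rows, columns=[
        "participant_id", "visit_index", "assay_id", "replicate_index", "cq",
        "amp_score", "cq_conf", "qualitative_flags", "process_order",
        "isolation_batch", "status",
    ])
    sample_table = samples.assign(
        fasting=True, stress_level=3, sleep_quality=3, recent_tobacco=False
    )[["participant_id", "visit_index", "process_order", "isolation_batch",
       "fasting", "stress_level", "sleep_quality", "recent_tobacco"]]
    participants = pd.DataFrame({
        "participant_id": pids, "sex": "F", "age": 40.0, "regular_tobacco": False,
    })
    roster = pd.DataFrame({
        "assay_id": [f"m{m:03d}" for m in range(n_mirnas)], "role": "target",
    })
    study = StudyTable(wells=wells, samples=sample_table,
                       participants=participants, assay_roster=roster)
    return study, g


def empty_hemolysis(study) -> pd.DataFrame:
    return study.sample_index().assign(score=np.nan)
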
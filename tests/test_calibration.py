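"""Spike-in alignment, sequence detrending and batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from mirstab import calibration as cal
from mirstab.datatypes import ACCEPTABLE, CENSORED, MISSING
from mirstab.filtering import (
    always_observed,
    hemolysis_scores,
    longitudinal_coverage,
    retained_assays,
    select_by_coverage,
)
from mirstab.simulate import simulate_study

from _driver import (
    empty_hemolysis,
    reduced_config,
    residual_study,
    run_stages,
    tiny_config,
    zero_noise_config,
)


def test_calibration_factor_arithmetic():
    """Factor = average of the spike-in duplicate mean and the
    always-observed median: ((20.0+20.2)/2 + 25.9)/2 = 23.0."""
    from mirstab.datatypes import SPIKEIN, StudyTable

    rows = []
    for rep, cq in ((1, 20.0), (2, 20.2)):
        rows.append(("A", 1, SPIKEIN, rep, cq))
    for i, cq in enumerate((25.8, 25.9, 26.0)):
        rows.append(("A", 1, f"m{i}", 1, cq))
    wells = pd.DataFrame(
        rows, columns=["participant_id", "visit_index", "assay_id",
                       "replicate_index", "cq"]
    ).assign(amp_score=1.5, cq_conf=0.95, qualitative_flags="",
             process_order=1, isolation_batch="b", status=ACCEPTABLE)
    samples = pd.DataFrame(
        {"participant_id": ["A"], "visit_index": [1], "process_order": [1],
         "isolation_batch": ["b"], "fasting": [True], "stress_level": [3],
         "sleep_quality": [3], "recent_tobacco": [False]}
    )
    participants = pd.DataFrame(
        {"participant_id": ["A"], "sex": ["F"], "age": [40.0],
         "regular_tobacco": [False]}
    )
    roster = pd.DataFrame(
        {"assay_id": [SPIKEIN, "m0", "m1", "m2"],
         "role": ["spikein_control", "target", "target", "target"]}
    )
    study = StudyTable(wells, samples, participants, roster)
    factors = cal.exogenous_calibration_factor(study, ["m0", "m1", "m2"])
    assert factors.loc[0, "factor"] == pytest.approx(23.0)


def test_zero_noise_factor_constant():
    study, truth = simulate_study(zero_noise_config(), seed=5)
    cov = longitudinal_coverage(study)
    retained = retained_assays(select_by_coverage(cov, study))
    always = always_observed(study, retained)
    factors = cal.exogenous_calibration_factor(study, always)
    assert factors["factor"].std() < 0.02  # only 2-decimal recording noise


def test_factor_tracks_latent_sample_shift(reduced_stages):
    study, truth, stages = reduced_stages
    merged = truth.samples.merge(
        stages["factors"], on=["participant_id", "visit_index"]
    )
    assert np.corrcoef(merged["tau"], merged["factor"])[0, 1] > 0.95


def test_median_align_shifts():
    """Factors {22, 23, 24} -> shifts {+1, 0, -1}; equal factors -> identity."""
    study, _ = simulate_study(tiny_config(), seed=2)
    pids = study.participant_ids[:1]
    factors = study.sample_index()
    factors["factor"] = np.resize([22.0, 23.0, 24.0], len(factors))
    aligned, audit = cal.median_align(study, factors)
    shifts = pd.Series(audit["shifts"])
    lookup = factors.set_index(
        factors["participant_id"] + "|" + factors["visit_index"].astype(str)
    )["factor"]
    expected = 23.0 - lookup
    pd.testing.assert_series_equal(
        shifts.sort_index(), expected.sort_index(), check_names=False
    )
    factors["factor"] = 23.0
    identity, _ = cal.median_align(study, factors)
    pd.testing.assert_series_equal(identity.wells["cq"], study.wells["cq"])


def test_alignment_preserves_contrasts_and_statuses(reduced_stages):
    """Within-sample Cq differences and all status counts are untouched."""
    study, _, stages = reduced_stages
    aligned = stages["aligned"]
    raw = study.wells.set_index(
        ["participant_id", "visit_index", "assay_id", "replicate_index"]
    )["cq"]
    post = aligned.wells.set_index(
        ["participant_id", "visit_index", "assay_id", "replicate_index"]
    )["cq"]
    sample = study.wells[
        (study.wells["participant_id"] == study.participant_ids[0])
        & (study.wells["visit_index"] == 1)
        & study.wells["cq"].notna()
    ]
    keys = list(
        sample[["participant_id", "visit_index", "assay_id", "replicate_index"]]
        .itertuples(index=False, name=None)
    )
    diffs_raw = np.diff([raw[k] for k in keys])
    diffs_post = np.diff([post[k] for k in keys])
    assert np.allclose(diffs_raw, diffs_post, atol=1e-9)
    for stage in ("aligned", "detrended", "adjusted"):
        counts = stages[stage].wells["status"].value_counts()
        pd.testing.assert_series_equal(
            counts.sort_index(), study.wells["status"].value_counts().sort_index()
        )


def test_post_alignment_factors_equal_global_median(reduced_stages):
    study, _, stages = reduced_stages
    aligned = stages["aligned"]
    factors2 = cal.exogenous_calibration_factor(aligned, stages["always"])
    assert factors2["factor"].std() < 1e-9


def test_control_correlations_raw_strong_residual_weak(reduced_stages):
    study, _, stages = reduced_stages
    raw = cal.control_correlations(study, stages["always"])
    assert raw["always_observed_median_vs_spikein"] > 0.8
    assert raw["mir16_vs_spikein"] > 0.8
    aligned = cal.control_correlations(stages["aligned"], stages["always"])
    assert abs(aligned["mir16_vs_spikein"]) < abs(raw["mir16_vs_spikein"])


def test_control_correlations_need_three_samples():
    study, _ = simulate_study(tiny_config(), seed=2)
    keep = study.samples.iloc[:2]
    wells = study.wells.merge(keep[["participant_id", "visit_index"]])
    small = study.copy_with_wells(wells)
    small.samples = keep
    with pytest.raises(ValueError, match="3 samples"):
        cal.control_correlations(small, ["miR-24-3p"])


class TestSequenceDetrend:
    def test_null_trend_curve_is_flat(self, reduced_stages):
        _, _, stages = reduced_stages
        audit = stages["audits"]["detrend"]
        assert not audit["skipped"]
        assert np.max(np.abs(audit["curve"]["curve"])) < 0.05

    def test_smoother_recovers_known_curve(self):
        """The kernel smoother tracks a known smooth sequence artifact."""
        rng = np.random.default_rng(0)
        order = np.arange(1, 137, dtype=float)
        trend = 0.01 * (order - order.mean()) + 0.3 * np.sin(order / 20.0)
        values = trend + rng.normal(0, 0.1, len(order))
        detr = cal.KernelDetrender().fit(order, values)
        fitted = detr.predict(order)
        assert np.sqrt(np.mean((fitted - trend) ** 2)) < 0.08
        assert np.corrcoef(fitted, trend)[0, 1] > 0.98

    def test_injected_trend_leaves_no_residual_slope(self):
        """After alignment, centring and detrending, an injected linear
        processing-sequence drift leaves no residual slope."""
        cfg = reduced_config(sequence_trend_slope=0.01, seed=42)
        study, _ = simulate_study(cfg)
        cov = longitudinal_coverage(study)
        retained = retained_assays(select_by_coverage(cov, study))
        always = always_observed(study, retained)
        factors = cal.exogenous_calibration_factor(study, always)
        aligned, _ = cal.median_align(study, factors)
        detrended, audit = cal.sequence_detrend(aligned, retained)
        wells = detrended.wells
        sub = wells[wells["assay_id"].isin(retained)
                    & wells["status"].isin((ACCEPTABLE, CENSORED))].copy()
        centred = sub["cq"] - sub.groupby(
            ["participant_id", "assay_id"])["cq"].transform("mean")
        per = centred.groupby(sub["process_order"]).mean()
        resid_slope = np.polyfit(per.index, per.values, 1)[0]
        assert abs(resid_slope) < 0.002

    def test_constant_order_skips_with_warning(self, tiny_study):
        study, _ = tiny_study
        wells = study.wells.copy()
        wells["process_order"] = 1
        flat = study.copy_with_wells(wells)
        with pytest.warns(UserWarning, match="constant"):
            out, audit = cal.sequence_detrend(flat, flat.target_assays[:5])
        assert audit["skipped"]

    def test_single_participant_small_n_runs(self):
        cfg = tiny_config(
            n_participants=1, visits_per_participant=(5,), n_female=1,
            n_regular_tobacco=0,
        )
        study, _ = simulate_study(cfg, seed=8)
        cov = longitudinal_coverage(study)
        retained = retained_assays(select_by_coverage(cov, study))
        _, audit = cal.sequence_detrend(study, retained)
        assert audit["bandwidth"] > 0


class TestBatchAdjust:
    def test_null_batch_effects_give_null_blups(self):
        study, g = residual_study(seed=1, batch_sd=0.0, n_mirnas=30)
        _, audit = cal.batch_adjust(
            study, sorted(study.target_assays), empty_hemolysis(study)
        )
        assert np.max(np.abs(list(audit["blups"].values()))) < 0.05

    def test_injected_batch_effects_recovered(self):
        study, g = residual_study(seed=2, batch_sd=0.3, n_mirnas=40)
        _, audit = cal.batch_adjust(
            study, sorted(study.target_assays), empty_hemolysis(study)
        )
        blups = pd.Series(audit["blups"])
        assert np.corrcoef(blups[g.index], g)[0, 1] > 0.9

    def test_recentering_preserves_global_median(self, reduced_stages):
        study, _, stages = reduced_stages
        detrended, adjusted = stages["detrended"], stages["adjusted"]
        retained = stages["retained"]

        def med(s):
            w = s.wells
            mask = w["assay_id"].isin(retained) & w["status"].isin(
                (ACCEPTABLE, CENSORED)
            )
            return float(w.loc[mask, "cq"].median())

        assert med(adjusted) == pytest.approx(med(detrended), abs=1e-9)

    def test_single_batch_is_noop_with_warning(self):
        study, _ = residual_study(seed=3, batch_sd=0.0, batch_size=10**6)
        with pytest.warns(UserWarning, match="single"):
            adjusted, audit = cal.batch_adjust(
                study, sorted(study.target_assays), empty_hemolysis(study)
            )
        assert np.allclose(
            adjusted.wells["cq"], study.wells["cq"], atol=1e-9
        )


def test_shared_technical_sd_drops_after_alignment(reduced_stages):
    study, _, stages = reduced_stages
    raw = cal.shared_technical_sd(study, stages["retained"])
    aligned = cal.shared_technical_sd(stages["aligned"], stages["retained"])
    assert aligned < raw * 0.3
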
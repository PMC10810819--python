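"""Endogenous normalization: covariates, per-donor normalizer subsets and
the properties of the normalized matrix."""

import numpy as np
import pandas as pd
import pytest

from mirstab.datatypes import (
    ACCEPTABLE,
    MIR16,
    MISSING,
    SET1,
    SET2,
    StudyTable,
)
from mirstab.normalize import (
    COVARIATES,
    build_covariates,
    build_normalizer_sets,
)

from _driver import run_stages, zero_noise_config
from mirstab.simulate import simulate_study


def _normalizer_study(missing_members=(), n_visits=3):
    """One donor study carrying all normalizer assays."""
    rows = []
    for v in range(1, n_visits + 1):
        for rep in range(1, 6):
            rows.append(("A", v, MIR16, rep, 25.0, ACCEPTABLE))
        for cq, assay in zip((24.0, 26.0), SET1):
            rows.append(("A", v, assay, 1, cq, ACCEPTABLE))
        for i, assay in enumerate(SET2):
            status = MISSING if assay in missing_members else ACCEPTABLE
            cq = np.nan if status == MISSING else 27.0 + i
            rows.append(("A", v, assay, 1, cq, status))
    wells = pd.DataFrame(
        rows, columns=["participant_id", "visit_index", "assay_id",
                       "replicate_index", "cq", "status"]
    ).assign(amp_score=1.5, cq_conf=0.95, qualitative_flags="",
             process_order=1, isolation_batch="b")
    samples = wells[["participant_id", "visit_index"]].drop_duplicates().assign(
        process_order=1, isolation_batch="b", fasting=True, stress_level=3,
        sleep_quality=3, recent_tobacco=False,
    )
    participants = pd.DataFrame(
        {"participant_id": ["A"], "sex": ["F"], "age": [40.0],
         "regular_tobacco": [False]}
    )
    roster = pd.DataFrame({"assay_id": sorted(wells["assay_id"].unique()),
                           "role": "target"})
    return StudyTable(wells, samples, participants, roster)


def test_covariate_arithmetic():
    study = _normalizer_study()
    sets = build_normalizer_sets(study)
    hem = study.sample_index().assign(score=5.0)
    cov = build_covariates(study, sets, hem)
    assert (cov["mir16"] == 25.0).all()
    assert (cov["set1_median"] == 25.0).all()   # median of {24, 26}
    assert (cov["set2_median"] == 29.0).all()   # median of 27..31
    assert (cov["hemolysis"] == 5.0).all()


def test_participant_specific_subset():
    """Members of set 2 missing in some visit are excluded from that
    donor's subset; the median uses the remaining members."""
    dropped = (SET2[0], SET2[4])
    study = _normalizer_study(missing_members=dropped)
    sets = build_normalizer_sets(study)
    assert sets.set2_subsets["A"] == sorted(set(SET2) - set(dropped))
    hem = study.sample_index().assign(score=5.0)
    cov = build_covariates(study, sets, hem)
    assert (cov["set2_median"] == 29.0).all()  # median of {28, 29, 30}


def test_empty_subset_names_participant():
    study = _normalizer_study(missing_members=SET2)
    with pytest.raises(ValueError, match="A"):
        build_normalizer_sets(study)


def test_missing_hemolysis_imputed_and_flagged():
    study = _normalizer_study()
    sets = build_normalizer_sets(study)
    hem = study.sample_index().assign(score=[6.0, np.nan, 8.0])
    cov = build_covariates(study, sets, hem)
    assert cov.loc[1, "hemolysis"] == pytest.approx(7.0)  # cohort median
    assert bool(cov.loc[1, "hemolysis_imputed"])


def test_normalized_matrix_complete_with_positive_se(reduced_stages):
    """Every sample of every normalized miRNA has a definite value and a
    strictly positive SE; imputed SEs exceed exact SEs miRNA by miRNA."""
    study, _, stages = reduced_stages
    norm = stages["normalization"].normalized
    expected = study.n_samples * norm["mirna_id"].nunique()
    assert len(norm) == expected
    assert norm["normalized_cq"].notna().all()
    assert (norm["se"] > 0).all()
    for _, grp in norm.groupby("mirna_id"):
        imputed = grp[grp["kind"] != "exact"]
        exact = grp[grp["kind"] == "exact"]
        if len(imputed) and len(exact):
            assert imputed["se"].min() > exact["se"].max()


def test_normalization_removes_normalizer_variance(default_run):
    """Post-normalization, the covariates explain under 1% of the
    within-donor variance of the normalized values (normalizer assays
    excluded: their own values sit inside their covariates)."""
    from mirstab.simulate import NAMED_BASELINES

    covs = build_covariates(
        default_run.calibrated,
        build_normalizer_sets(default_run.calibrated),
        default_run.hemolysis,
    )
    norm = default_run.normalization.normalized
    norm = norm[~norm["mirna_id"].isin(NAMED_BASELINES)]
    nn = norm.merge(covs, on=["participant_id", "visit_index"])
    key = ["mirna_id", "participant_id"]
    y = (nn["normalized_cq"]
         - nn.groupby(key)["normalized_cq"].transform("mean")).to_numpy()
    X = np.column_stack([
        (nn[c] - nn.groupby(key)[c].transform("mean")).to_numpy()
        for c in COVARIATES
    ])
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    r2 = 1.0 - np.sum((y - X @ coef) ** 2) / np.sum(y**2)
    assert r2 < 0.01


def test_hemolysis_effect_removed_from_normalized_values(default_run, default_truth):
    """miRNAs with injected hemolysis sensitivity track the hemolysis score
    before normalization and no longer do afterwards."""
    _, truth = default_truth
    sens = truth.assays[truth.assays["hemolysis_delta"].abs() > 0.2]
    hem = default_run.hemolysis.set_index(["participant_id", "visit_index"])[
        "score"
    ]

    def within_slope(frame, value_col):
        key = pd.MultiIndex.from_frame(
            frame[["participant_id", "visit_index"]]
        )
        frame = frame.assign(score=hem.reindex(key).values).dropna(
            subset=["score", value_col]
        )
        grp = ["assay_id", "participant_id"] if "assay_id" in frame else [
            "mirna_id", "participant_id"]
        y = (frame[value_col]
             - frame.groupby(grp)[value_col].transform("mean")).to_numpy()
        x = (frame["score"]
             - frame.groupby(grp)["score"].transform("mean")).to_numpy()
        return float(x @ y / (x @ x))

    raw = default_run.study.wells
    raw = raw[raw["assay_id"].isin(sens["assay_id"])
              & (raw["status"] == "acceptable")]
    pre = within_slope(raw, "cq")
    norm = default_run.normalization.normalized
    norm = norm[norm["mirna_id"].isin(sens["assay_id"])]
    post = within_slope(norm, "normalized_cq")
    mean_delta = float(sens["hemolysis_delta"].mean())
    assert pre == pytest.approx(mean_delta, abs=0.15)
    assert abs(post) < 0.05


def test_zero_noise_recovery():
    """On a noiseless study the normalized values reproduce the latent
    levels to the recorded precision."""
    study, truth = simulate_study(zero_noise_config(), seed=5)
    stages = run_stages(study)
    norm = stages["normalization"].normalized
    lat = truth.assays.set_index("assay_id")
    merged = norm.merge(
        truth.samples[["participant_id", "visit_index"]],
        on=["participant_id", "visit_index"],
    )
    expected = (
        merged["mirna_id"].map(lat["mu"])
        + merged["mirna_id"].map(lat["hemolysis_delta"]) * 5.8
    )
    # calibration recentring can add a single global constant
    offset = float((merged["normalized_cq"] - expected).median())
    assert (merged["normalized_cq"] - expected - offset).abs().max() < 0.05
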
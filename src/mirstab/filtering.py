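"""Longitudinal coverage filtering and the hemolysis proxy score.

Coverage of an assay for one donor is the fraction of that donor's visits
with an acceptable Cq; the filter keeps assays whose unweighted mean
coverage across donors reaches 1 - 1/e (~63.2%), the threshold that
approximates greedy sequential selection by coverage improvement. The
always-observed set is the subset acceptable in every sample of every
donor, and anchors the exogenous calibration factor.

The hemolysis score of a sample is Cq(miR-23a-3p) - Cq(miR-451a) on raw
(uncalibrated) values; miR-451a is erythrocyte-derived, so the score rises
with red-cell lysis. Scores above 7 indicate appreciable hemolysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COVERAGE_CUTOFF
from .datatypes import (
    ACCEPTABLE,
    HEMOLYSIS_INSENSITIVE,
    HEMOLYSIS_SENSITIVE,
    TARGET,
    StudyTable,
)


def longitudinal_coverage(study: StudyTable) -> pd.DataFrame:
    """Per-assay coverage: donor-level fractions and their unweighted mean.

    Returns a frame (assay_id, participant coverage columns aggregated as
    mean_coverage) plus the per-donor fractions in long form under
    ``per_participant``. An assay counts as observed at a visit when at
    least one of its reactions there is acceptable.
    """
    visits_per = study.samples.groupby("participant_id")["visit_index"].nunique()
    if (visits_per == 0).any():
        raise ValueError("participant with zero visits")

    wells = study.wells
    ok = wells[wells["status"] == ACCEPTABLE]
    seen = (
        ok.groupby(["assay_id", "participant_id"])["visit_index"]
        .nunique()
        .rename("n_seen")
        .reset_index()
    )
    assays = study.assay_roster["assay_id"]
    full = pd.MultiIndex.from_product(
        [assays, visits_per.index], names=["assay_id", "participant_id"]
    ).to_frame(index=False)
    full = full.merge(seen, how="left", on=["assay_id", "participant_id"])
    full["n_seen"] = full["n_seen"].fillna(0)
    full["n_visits"] = full["participant_id"].map(visits_per)
    full["coverage"] = full["n_seen"] / full["n_visits"]

    mean_cov = (
        full.groupby("assay_id", sort=True)["coverage"].mean().rename("mean_coverage")
    )
    out = mean_cov.reset_index()
    out.attrs["per_participant"] = full
    return out


def select_by_coverage(
    coverage: pd.DataFrame,
    study: StudyTable | None = None,
    cutoff: float = COVERAGE_CUTOFF,
) -> pd.DataFrame:
    """Apply the coverage cutoff (inclusive >=).

    Adds a ``retained`` column; when the study is given, a ``scientific``
    column additionally excludes control-role assays from the retained set.
    """
    out = coverage.copy()
    out["retained"] = out["mean_coverage"] >= cutoff
    if study is not None:
        targets = set(study.target_assays)
        out["scientific"] = out["retained"] & out["assay_id"].isin(targets)
    return out


def retained_assays(selection: pd.DataFrame, scientific: bool = True) -> list[str]:
    col = "scientific" if scientific and "scientific" in selection.columns else "retained"
    return sorted(selection.loc[selection[col], "assay_id"])


def always_observed(study: StudyTable, retained: list[str]) -> list[str]:
    """Assays (from the retained scientific set) acceptable in 100% of all
    samples of all donors."""
    if not retained:
        raise ValueError("retained set is empty")
    wells = study.wells[study.wells["assay_id"].isin(retained)]
    n_samples = study.n_samples
    ok = wells[wells["status"] == ACCEPTABLE]
    per_assay = ok.groupby("assay_id")[["participant_id", "visit_index"]].apply(
        lambda g: g.drop_duplicates().shape[0]
    )
    return sorted(per_assay[per_assay == n_samples].index)


def hemolysis_scores(
    study: StudyTable,
    threshold: float = 7.0,
) -> pd.DataFrame:
    """Per-sample hemolysis score from the raw proxy-pair Cq difference.

    Requires both proxy assays acceptable in the sample (replicate means
    are used when replicated); otherwise the score is NaN and the sample is
    flagged unavailable.
    """
    wells = study.wells
    ok = wells[wells["status"] == ACCEPTABLE]

    def _mean_cq(assay):
        sub = ok[ok["assay_id"] == assay]
        return sub.groupby(["participant_id", "visit_index"])["cq"].mean()

    insens = _mean_cq(HEMOLYSIS_INSENSITIVE)
    sens = _mean_cq(HEMOLYSIS_SENSITIVE)
    out = study.sample_index().set_index(["participant_id", "visit_index"])
    out["score"] = insens - sens
    out["available"] = out["score"].notna()
    out["appreciable"] = out["score"] > threshold
    return out.reset_index()
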
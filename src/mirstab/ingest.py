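"""Parsing of per-participant qPCR export tables and reaction-level QC.

Each participant's instrument export is a delimited long-form table (one row
per well). Column names are mapped onto the unified schema through a
configurable dictionary so the parser is export-dialect agnostic; the
defaults follow an ExpressionSuite-style export.

A reaction is *acceptable* when AmpScore >= 1, CqConf >= 0.8 and the
recorded Cq is below the censoring boundary (34 cycles); *censored* when QC
passes but Cq >= 34 (the true value lies between the recorded Cq and the
instrument maximum of 40); and *missing* when QC fails or no Cq was
recorded ("Undetermined"), regardless of any recorded Cq value.
"""

from __future__ import annotations

import numbers
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QCConfig
from .datatypes import (
    ACCEPTABLE,
    CENSORED,
    ENDOGENOUS_CONTROL,
    MIR16,
    MISSING,
    NEGATIVE,
    NEGATIVE_CONTROL,
    PARTICIPANT_COLUMNS,
    SAMPLE_COLUMNS,
    SPIKEIN,
    SPIKEIN_CONTROL,
    TARGET,
    WELL_COLUMNS,
    ControlReport,
    StudyTable,
)

#: Default export-column mapping (internal field -> export column).
DEFAULT_COLUMN_MAP = {
    "participant_id": "Participant",
    "visit_index": "Visit",
    "assay_id": "Target Name",
    "replicate_index": "Replicate",
    "cq": "Cq",
    "amp_score": "AmpScore",
    "cq_conf": "CqConf",
    "qualitative_flags": "Flags",
    "process_order": "ProcessOrder",
    "isolation_batch": "IsolationBatch",
}

_REQUIRED = [
    "participant_id",
    "visit_index",
    "assay_id",
    "replicate_index",
    "cq",
    "amp_score",
    "cq_conf",
]


def _parse_cq(value) -> float:
    """Parse a Cq cell; 'Undetermined' (or blank) becomes NaN."""
    if value is None or (isinstance(value, numbers.Number) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        text = value.strip()
        if not text or text.lower() in {"undetermined", "undet", "na", "nan"}:
            return np.nan
        return float(text)
    return float(value)


def classify_reaction(amp_score, cq_conf, cq, qc: QCConfig | None = None) -> str:
    """Classify one reaction as acceptable / censored / missing.

    Classification is total: every input combination receives exactly one
    status. Thresholds are inclusive.
    """
    qc = qc or QCConfig()
    if amp_score is None or cq_conf is None or np.isnan(amp_score) or np.isnan(cq_conf):
        return MISSING
    if amp_score < qc.min_amp_score or cq_conf < qc.min_cq_conf:
        return MISSING
    if cq is None or np.isnan(cq):
        return MISSING
    if cq >= qc.censor_cq:
        return CENSORED
    return ACCEPTABLE


def classify_wells(wells: pd.DataFrame, qc: QCConfig | None = None) -> pd.Series:
    """Vectorized QC classification of a well table."""
    qc = qc or QCConfig()
    amp = pd.to_numeric(wells["amp_score"], errors="coerce")
    conf = pd.to_numeric(wells["cq_conf"], errors="coerce")
    cq = pd.to_numeric(wells["cq"], errors="coerce")
    qc_pass = (amp >= qc.min_amp_score) & (conf >= qc.min_cq_conf)
    status = pd.Series(MISSING, index=wells.index, dtype=object)
    status[qc_pass & cq.notna() & (cq >= qc.censor_cq)] = CENSORED
    status[qc_pass & cq.notna() & (cq < qc.censor_cq)] = ACCEPTABLE
    return status


def default_roster(assay_ids) -> pd.DataFrame:
    """Assign roles from the canonical card layout: known control names,
    everything else a target."""
    roles = []
    for a in sorted(set(assay_ids)):
        if a == MIR16:
            roles.append(ENDOGENOUS_CONTROL)
        elif a == SPIKEIN:
            roles.append(SPIKEIN_CONTROL)
        elif a == NEGATIVE:
            roles.append(NEGATIVE_CONTROL)
        else:
            roles.append(TARGET)
    return pd.DataFrame({"assay_id": sorted(set(assay_ids)), "role": roles})


def parse_expression_export(
    paths,
    column_map: dict | None = None,
    samples: pd.DataFrame | None = None,
    participants: pd.DataFrame | None = None,
    assay_roster: pd.DataFrame | None = None,
    qc: QCConfig | None = None,
    sep: str = ",",
) -> StudyTable:
    """Parse per-participant export files into one classified StudyTable.

    Parameters
    ----------
    paths : list of path-like
        One delimited long-form file per participant.
    column_map : dict, optional
        Internal field name -> export column name; defaults to the
        ExpressionSuite-style names in ``DEFAULT_COLUMN_MAP``.
    samples, participants : DataFrame, optional
        Visit-level and donor-level metadata. When omitted, minimal tables
        are derived from the wells (metadata columns left missing).
    """
    qc = qc or QCConfig()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    frames = []
    for path in paths:
        raw = pd.read_csv(path, sep=sep, dtype={cmap["cq"]: object})
        missing_cols = [
            field for field in _REQUIRED if cmap[field] not in raw.columns
        ]
        if missing_cols:
            raise ValueError(
                f"{Path(path).name}: unmappable required column(s) "
                f"{missing_cols} (expected export columns "
                f"{[cmap[f] for f in missing_cols]})"
            )
        out = pd.DataFrame()
        for field, col in cmap.items():
            if col in raw.columns:
                out[field] = raw[col]
        out["cq"] = out["cq"].map(_parse_cq)
        frames.append(out)

    wells = pd.concat(frames, ignore_index=True)
    for field in ("qualitative_flags",):
        if field not in wells.columns:
            wells[field] = ""
    wells["qualitative_flags"] = wells["qualitative_flags"].fillna("")
    for field in ("process_order", "isolation_batch"):
        if field not in wells.columns:
            wells[field] = np.nan

    dup = wells.duplicated(
        subset=["participant_id", "visit_index", "assay_id", "replicate_index"]
    )
    if dup.any():
        first = wells.loc[dup.idxmax(), ["participant_id", "visit_index", "assay_id"]]
        raise ValueError(
            "duplicate (participant, visit, assay, replicate) rows, e.g. "
            f"{tuple(first)}"
        )

    # Renumber visits so the ordinal index is contiguous (1..k) per donor.
    wells["visit_index"] = wells["visit_index"].astype(int)
    for pid, grp in wells.groupby("participant_id"):
        order = {v: i + 1 for i, v in enumerate(sorted(grp["visit_index"].unique()))}
        wells.loc[grp.index, "visit_index"] = grp["visit_index"].map(order)

    wells["status"] = classify_wells(wells, qc)
    wells = wells[WELL_COLUMNS].sort_values(
        ["participant_id", "visit_index", "assay_id", "replicate_index"]
    ).reset_index(drop=True)

    if samples is None:
        samples = (
            wells.groupby(["participant_id", "visit_index"], as_index=False)
            .agg(process_order=("process_order", "first"),
                 isolation_batch=("isolation_batch", "first"))
        )
        for col in SAMPLE_COLUMNS:
            if col not in samples.columns:
                samples[col] = np.nan
        samples = samples[SAMPLE_COLUMNS]
    if participants is None:
        participants = pd.DataFrame(
            {"participant_id": sorted(wells["participant_id"].unique())}
        )
        for col in PARTICIPANT_COLUMNS:
            if col not in participants.columns:
                participants[col] = np.nan
        participants = participants[PARTICIPANT_COLUMNS]
    if assay_roster is None:
        assay_roster = default_roster(wells["assay_id"])

    return StudyTable(
        wells=wells,
        samples=samples.reset_index(drop=True),
        participants=participants.reset_index(drop=True),
        assay_roster=assay_roster.reset_index(drop=True),
    )


def verify_controls(study: StudyTable) -> ControlReport:
    """Check control wells sample by sample.

    Flags (report-only): the exogenous negative control amplifying with
    acceptable QC (contamination); the spike-in or the primary endogenous
    control not 100% acceptable in a sample.
    """
    report = ControlReport()
    wells = study.wells
    for (pid, visit), grp in wells.groupby(["participant_id", "visit_index"]):
        neg = grp[grp["assay_id"] == NEGATIVE]
        if (neg["status"] == ACCEPTABLE).any():
            report.contamination.append(
                {"participant_id": pid, "visit_index": int(visit)}
            )
        for assay, bucket in ((SPIKEIN, report.spikein_incomplete),
                              (MIR16, report.endogenous_incomplete)):
            ctrl = grp[grp["assay_id"] == assay]
            if len(ctrl) == 0 or (ctrl["status"] != ACCEPTABLE).any():
                bucket.append({"participant_id": pid, "visit_index": int(visit)})
    return report


def unified_table(study: StudyTable) -> pd.DataFrame:
    """Long-form unified study table (the wells with their status column)."""
    return study.wells.copy()
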
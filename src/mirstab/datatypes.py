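"""Core containers for a longitudinal qPCR study.

A study is held in long ("tidy") form: one row per qPCR reaction (well),
one row per blood-draw sample for the visit-level metadata, and an assay
roster mapping each assay on the array card to its role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# Reaction status after QC classification
ACCEPTABLE = "acceptable"
CENSORED = "censored"
MISSING = "missing"
STATUSES = (ACCEPTABLE, CENSORED, MISSING)

# Assay roles on the array card
TARGET = "target"
ENDOGENOUS_CONTROL = "endogenous_control"
SPIKEIN_CONTROL = "spikein_control"
NEGATIVE_CONTROL = "negative_control"

# Canonical control assay names (TaqMan Advanced miRNA Human A card layout)
MIR16 = "miR-16-5p"
SPIKEIN = "cel-miR-39-3p"
NEGATIVE = "ath-miR159a"

# Hemolysis proxy pair: miR-23a-3p is insensitive to red-cell lysis,
# miR-451a is erythrocyte-derived and highly sensitive.
HEMOLYSIS_INSENSITIVE = "miR-23a-3p"
HEMOLYSIS_SENSITIVE = "miR-451a"

# Endogenous normalizer sets
SET1 = ("miR-24-3p", "miR-484")
SET2 = ("miR-103a-3p", "miR-126-3p", "miR-191-5p", "miR-30e-5p", "miR-93-5p")

WELL_COLUMNS = [
    "participant_id",
    "visit_index",
    "assay_id",
    "replicate_index",
    "cq",
    "amp_score",
    "cq_conf",
    "qualitative_flags",
    "process_order",
    "isolation_batch",
    "status",
]

SAMPLE_COLUMNS = [
    "participant_id",
    "visit_index",
    "process_order",
    "isolation_batch",
    "fasting",
    "stress_level",
    "sleep_quality",
    "recent_tobacco",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "regular_tobacco",
]


@dataclass
class StudyTable:
    """Unified study: wells, per-sample metadata, per-participant metadata,
    and the assay roster.

    ``wells`` has one row per reaction with the columns in ``WELL_COLUMNS``;
    ``samples`` one row per (participant, visit); ``participants`` one row per
    donor; ``assay_roster`` columns (assay_id, role).
    """

    wells: pd.DataFrame
    samples: pd.DataFrame
    participants: pd.DataFrame
    assay_roster: pd.DataFrame

    def __post_init__(self) -> None:
        well_keys = set(
            map(tuple, self.wells[["participant_id", "visit_index"]].drop_duplicates().values)
        )
        sample_keys = set(
            map(tuple, self.samples[["participant_id", "visit_index"]].values)
        )
        orphans = well_keys - sample_keys
        if orphans:
            raise ValueError(
                f"wells reference samples absent from the sample table: {sorted(orphans)[:5]}"
            )

    def assays_with_role(self, role: str) -> list[str]:
        r = self.assay_roster
        return sorted(r.loc[r["role"] == role, "assay_id"])

    @property
    def target_assays(self) -> list[str]:
        return self.assays_with_role(TARGET)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.samples["participant_id"].unique())

    def sample_index(self) -> pd.DataFrame:
        return self.samples[["participant_id", "visit_index"]].copy()

    def copy_with_wells(self, wells: pd.DataFrame) -> "StudyTable":
        return StudyTable(
            wells=wells,
            samples=self.samples.copy(),
            participants=self.participants.copy(),
            assay_roster=self.assay_roster.copy(),
        )


@dataclass
class ControlReport:
    """Per-sample control QC findings, report-only."""

    contamination: list[dict] = field(default_factory=list)
    spikein_incomplete: list[dict] = field(default_factory=list)
    endogenous_incomplete: list[dict] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.contamination or self.spikein_incomplete or self.endogenous_incomplete)

    def to_dict(self) -> dict:
        return {
            "contamination": self.contamination,
            "spikein_incomplete": self.spikein_incomplete,
            "endogenous_incomplete": self.endogenous_incomplete,
            "clean": self.clean,
        }
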
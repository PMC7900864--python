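"""Enrollment funnel: daily cap, exclusion cascade, study IDs, funnel report.

Flagged encounters are dispositioned in three stages mirroring the screening
workflow of the EHR-embedded cohort:

1. **Daily enrollment cap** — per calendar day of arrival, only the first
   ``cap_per_day`` flags (by flag time, ties by encounter id) are screened;
   the remainder are *eligible, not screened*.
2. **Exclusion cascade** — screened encounters are excluded, in this fixed
   printed order, if (1) no specimen was collected within the 6-hour window,
   (2) a required remnant tube present in the window has insufficient volume,
   or (3) a required tube type is absent from the window. Survivors are
   enrolled. Reasons are mutually exclusive (first failing rule wins).
3. **De-identification** — enrolled encounters receive sequential study IDs;
   the bijection back to patient identifiers is held in a crosswalk stored
   separately from de-identified exports.

The funnel report enforces exact conservation at every level (flagged =
screened + capped; screened = enrolled + excluded) and formats percentages
with the reporting convention used throughout: >=1% to the nearest integer,
<1% to one decimal place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_TUBE_RULES",
    "EnrollmentRecord",
    "Crosswalk",
    "FunnelReport",
    "apply_daily_cap",
    "classify_exclusions",
    "assign_study_ids",
    "build_funnel_report",
    "format_percentage",
]

#: Required blood tube types with (minimum volume in uL, strict inequality?).
#: The required-labs alert criterion exists precisely to ensure these tubes
#: are drawn; an encounter is enrolled only if each type has at least one
#: in-window specimen meeting its volume minimum. Heparin is strict (>550),
#: the others are non-strict. Urine never affects enrollment.
REQUIRED_TUBE_RULES: dict[str, tuple[float, bool]] = {
    "heparin": (550.0, True),
    "edta": (450.0, False),
    "sodium_fluoride": (225.0, False),
}

EXCLUSION_REASONS = ("none", "specimen_window", "insufficient_volume", "tube_types_absent")

STUDY_ID_PREFIX = "VESPRE"


@dataclass
class EnrollmentRecord:
    encounter_id: str
    status: str  # enrolled | eligible_not_screened_cap | excluded
    exclusion_reason: str = "none"
    study_id: str | None = None


@dataclass
class Crosswalk:
    """Separately stored bijection study_id <-> (patient_id, encounter_id)."""

    table: pd.DataFrame  # columns: study_id, patient_id, encounter_id
    created_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def __post_init__(self) -> None:
        for col in ("study_id", "encounter_id"):
            if self.table[col].duplicated().any():
                raise ValueError(f"crosswalk is not a bijection: duplicate {col}")

    def to_identified(self, deidentified: pd.DataFrame) -> pd.DataFrame:
        """Re-join a de-identified export back to patient identifiers."""
        return deidentified.merge(self.table, on="study_id", how="left")


def apply_daily_cap(flags: pd.DataFrame, cap_per_day: int = 4
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition flags into (screened, not_screened_cap) by calendar day.

    Per day, the first ``cap_per_day`` flags by flag time are screened, ties
    broken by encounter id ascending; the cap resets at local midnight.
    ``flags`` must carry ``day``, ``flag_time_minutes`` and ``encounter_id``.
    Idempotent: re-applying the cap to the screened partition is a no-op.
    """
    if cap_per_day < 0:
        raise ValueError("cap_per_day must be >= 0")
    if len(flags) == 0:
        return flags.copy(), flags.copy()
    ordered = flags.sort_values(
        ["day", "flag_time_minutes", "encounter_id"], kind="mergesort")
    rank = ordered.groupby("day").cumcount()
    screened = ordered[rank < cap_per_day]
    capped = ordered[rank >= cap_per_day]
    return screened.reset_index(drop=True), capped.reset_index(drop=True)


def classify_exclusions(screened_flags: pd.DataFrame, specimens: pd.DataFrame,
                        window_minutes: int = 360,
                        tube_rules: dict[str, tuple[float, bool]] | None = None
                        ) -> pd.DataFrame:
    """Apply the three-reason exclusion cascade to screened flags.

    Returns one record per screened flag with columns ``encounter_id``,
    ``status`` and ``exclusion_reason``. Specimen rows with no matching
    screened encounter are ignored with a warning. The recorded reason is the
    first failing rule in the printed order and is invariant to specimen row
    order.
    """
    rules = tube_rules or REQUIRED_TUBE_RULES
    known = set(screened_flags["encounter_id"].astype(str))
    spec = specimens.copy()
    spec["encounter_id"] = spec["encounter_id"].astype(str)
    orphans = ~spec["encounter_id"].isin(known)
    if orphans.any():
        warnings.warn(
            f"{int(orphans.sum())} specimen rows have no matching screened "
            "encounter and were ignored", stacklevel=2)
        spec = spec[~orphans]
    in_window = spec[spec["t_minutes"] < window_minutes]

    # per encounter per tube type: best in-window volume
    best = (in_window.groupby(["encounter_id", "tube_type"])["remnant_volume_ul"]
            .max().unstack(fill_value=np.nan)
            if len(in_window) else pd.DataFrame())
    has_any_window = set(in_window["encounter_id"]) if len(in_window) else set()

    records = []
    for enc in screened_flags["encounter_id"].astype(str):
        if enc not in has_any_window:
            records.append((enc, "excluded", "specimen_window"))
            continue
        reason = "none"
        present_fail = False
        absent = False
        for tube, (vol_min, strict) in rules.items():
            vol = best.at[enc, tube] if (tube in best.columns and enc in best.index) else np.nan
            if np.isnan(vol):
                absent = True
            else:
                ok = vol > vol_min if strict else vol >= vol_min
                if not ok:
                    present_fail = True
        if present_fail:
            reason = "insufficient_volume"
        elif absent:
            reason = "tube_types_absent"
        if reason == "none":
            records.append((enc, "enrolled", "none"))
        else:
            records.append((enc, "excluded", reason))
    return pd.DataFrame(records, columns=["encounter_id", "status", "exclusion_reason"])


def assign_study_ids(records: pd.DataFrame, encounters: pd.DataFrame
                     ) -> tuple[Crosswalk, pd.DataFrame]:
    """Assign sequential zero-padded study IDs to enrolled records.

    Returns the crosswalk (kept apart from any de-identified export) and the
    de-identified records: study_id + disposition only, with no patient_id
    and no absolute arrival datetime. Raises on duplicate enrollment of one
    encounter.
    """
    enrolled = records[records["status"] == "enrolled"].copy()
    if enrolled["encounter_id"].duplicated().any():
        dup = enrolled.loc[enrolled["encounter_id"].duplicated(), "encounter_id"].iloc[0]
        raise ValueError(f"encounter {dup} enrolled more than once")
    enrolled = enrolled.sort_values("encounter_id", kind="mergesort").reset_index(drop=True)
    enrolled["study_id"] = [
        f"{STUDY_ID_PREFIX}-{i + 1:04d}" for i in range(len(enrolled))]

    lookup = encounters.set_index(encounters["encounter_id"].astype(str))["patient_id"]
    crosswalk = Crosswalk(table=pd.DataFrame({
        "study_id": enrolled["study_id"],
        "patient_id": enrolled["encounter_id"].astype(str).map(lookup),
        "encounter_id": enrolled["encounter_id"].astype(str),
    }))

    deidentified = records.merge(
        enrolled[["encounter_id", "study_id"]], on="encounter_id", how="left")
    deidentified = deidentified.drop(
        columns=[c for c in ("patient_id", "arrival_datetime") if c in deidentified],
        errors="ignore")
    return crosswalk, deidentified


@dataclass
class FunnelReport:
    """Aggregate funnel counts with conservation identities enforced."""

    counts: dict[str, int]
    percentages: dict[str, str]
    denominators: dict[str, int]

    def __post_init__(self) -> None:
        c = self.counts
        if any(v < 0 for v in c.values()):
            raise ValueError("funnel counts must be non-negative")
        if c["flagged"] != c["eligible_screened"] + c["not_screened_cap"]:
            raise ValueError("conservation violated: flagged != screened + capped")
        excluded_total = sum(
            c[f"excluded_{r}"] for r in EXCLUSION_REASONS if r != "none")
        if c["eligible_screened"] != c["enrolled"] + excluded_total:
            raise ValueError("conservation violated: screened != enrolled + excluded")


def format_percentage(numerator: int, denominator: int) -> str:
    """Reporting convention: >=1% to the nearest integer, <1% to one decimal;
    undefined denominators yield 'n/a'."""
    if denominator <= 0:
        return "n/a"
    pct = 100.0 * numerator / denominator
    if pct >= 1.0:
        return f"{int(np.floor(pct + 0.5))}%"
    return f"{pct:.1f}%"


def build_funnel_report(records: pd.DataFrame, capped: pd.DataFrame | None = None,
                        context_counts: dict[str, int] | None = None) -> FunnelReport:
    """Aggregate disposition records into a funnel report.

    ``records`` holds the screened dispositions (enrolled/excluded);
    ``capped`` the eligible-not-screened partition. Optional context counts
    (``ed_encounters``, ``clinical_lab_specimens``, ``remnant_samples``)
    add denominator percentages for flag and remnant yield.
    """
    n_capped = len(capped) if capped is not None else 0
    by_reason = records[records["status"] == "excluded"]["exclusion_reason"].value_counts()
    counts = {
        "eligible_screened": int((records["status"] != "eligible_not_screened_cap").sum()),
        "not_screened_cap": n_capped,
        "enrolled": int((records["status"] == "enrolled").sum()),
    }
    counts["flagged"] = counts["eligible_screened"] + n_capped
    for reason in EXCLUSION_REASONS:
        if reason != "none":
            counts[f"excluded_{reason}"] = int(by_reason.get(reason, 0))
    counts["excluded"] = int((records["status"] == "excluded").sum())

    if context_counts:
        for k, v in context_counts.items():
            if v < 0:
                raise ValueError(f"context count {k} must be non-negative")

    percentages = {
        "eligible_screened_of_flagged": format_percentage(
            counts["eligible_screened"], counts["flagged"]),
        "not_screened_cap_of_flagged": format_percentage(
            counts["not_screened_cap"], counts["flagged"]),
        "enrolled_of_screened": format_percentage(
            counts["enrolled"], counts["eligible_screened"]),
        "excluded_of_screened": format_percentage(
            counts["excluded"], counts["eligible_screened"]),
    }
    denominators = {
        "eligible_screened_of_flagged": counts["flagged"],
        "not_screened_cap_of_flagged": counts["flagged"],
        "enrolled_of_screened": counts["eligible_screened"],
        "excluded_of_screened": counts["eligible_screened"],
    }
    for reason in EXCLUSION_REASONS:
        if reason != "none":
            key = f"excluded_{reason}_of_screened"
            percentages[key] = format_percentage(
                counts[f"excluded_{reason}"], counts["eligible_screened"])
            denominators[key] = counts["eligible_screened"]
    if context_counts:
        if "ed_encounters" in context_counts:
            percentages["flagged_of_ed_encounters"] = format_percentage(
                counts["flagged"], context_counts["ed_encounters"])
            denominators["flagged_of_ed_encounters"] = context_counts["ed_encounters"]
        if {"remnant_samples", "clinical_lab_specimens"} <= context_counts.keys():
            percentages["remnant_of_lab_specimens"] = format_percentage(
                context_counts["remnant_samples"],
                context_counts["clinical_lab_specimens"])
            denominators["remnant_of_lab_specimens"] = context_counts["clinical_lab_specimens"]
    return FunnelReport(counts=counts, percentages=percentages,
                        denominators=denominators)
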
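"""End-to-end orchestration: generate -> screen -> enroll -> biorepository ->
analytics, with conservation checks at every funnel level."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analytics, biorepository, digital_alert, enrollment, synthetic_ehr

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: synthetic_ehr.CohortData
    flags: pd.DataFrame            # all encounters with criteria + flag
    screened: pd.DataFrame
    capped: pd.DataFrame
    records: pd.DataFrame          # screened dispositions
    crosswalk: enrollment.Crosswalk
    deidentified: pd.DataFrame
    funnel: enrollment.FunnelReport
    biorepo: biorepository.BiorepositoryReport
    rejects: pd.DataFrame
    clinical: pd.DataFrame | None
    factor_screen: analytics.FactorScreenResult | None
    reachability: analytics.ReachabilityProfile | None
    smoothness: tuple[float, str] | None
    logfold: analytics.LogFoldMatrix | None


def run_pipeline(config: synthetic_ehr.GeneratorConfig, cap_per_day: int = 4,
                 window_minutes: int = digital_alert.WINDOW_MINUTES,
                 min_pts: int = 5, missingness_threshold: float = 0.25,
                 run_analytics: bool = True) -> PipelineResult:
    """Run the full synthetic study once.

    Analytics stages degrade gracefully (set to ``None``) when the enrolled
    cohort is too small to support them.
    """
    cohort = synthetic_ehr.generate_cohort(config)
    flags = digital_alert.screen_cohort(
        cohort.encounters, cohort.events, window_minutes)
    flagged = flags[flags["flagged"]].reset_index(drop=True)
    screened, capped = enrollment.apply_daily_cap(flagged, cap_per_day)
    screened_spec = cohort.specimens[
        cohort.specimens["encounter_id"].isin(set(screened["encounter_id"]))]
    records = enrollment.classify_exclusions(
        screened, screened_spec, window_minutes)
    crosswalk, deid = enrollment.assign_study_ids(records, cohort.encounters)
    funnel = enrollment.build_funnel_report(records, capped)

    # biorepository over enrolled patients' eligible remnants
    enrolled_ids = crosswalk.table["encounter_id"]
    spec_enrolled = cohort.specimens[
        cohort.specimens["encounter_id"].isin(set(enrolled_ids))]
    eligible, rejects = biorepository.assess_remnant_eligibility(spec_enrolled)
    id_map = crosswalk.table.set_index("encounter_id")["study_id"]
    eligible = eligible.assign(study_id=eligible["encounter_id"].map(id_map))
    biorepo = biorepository.aliquot_accounting(eligible, n_enrolled=len(crosswalk.table))

    clinical = factor = profile = smooth = logfold = None
    if run_analytics and len(enrolled_ids) >= max(min_pts, 10):
        clinical = analytics.clinical_table(
            cohort.events, encounter_ids=enrolled_ids, window_minutes=window_minutes)
        retained = analytics.filter_by_missingness(clinical, missingness_threshold)
        filtered = clinical[retained]
        nonconstant = [c for c in filtered.columns
                       if filtered[c].dropna().nunique() > 1]
        filtered = filtered[nonconstant]
        if filtered.shape[1] >= 2:
            factor = analytics.kaiser_factor_screen(filtered)
        complete = filtered.dropna()
        if len(complete) >= min_pts and complete.shape[1] >= 1:
            z = (complete - complete.mean()) / complete.std(ddof=0)
            profile = analytics.optics_reachability(z.to_numpy(), min_pts=min_pts)
            if np.isfinite(profile.reachability).sum() >= 3:
                smooth = analytics.smoothness_score(profile)
        panel = synthetic_ehr.generate_biomarker_panel(
            config, list(crosswalk.table["study_id"]))
        logfold = analytics.logfold_matrix(panel)

    return PipelineResult(
        cohort=cohort, flags=flags, screened=screened, capped=capped,
        records=records, crosswalk=crosswalk, deidentified=deid, funnel=funnel,
        biorepo=biorepo, rejects=rejects, clinical=clinical,
        factor_screen=factor, reachability=profile, smoothness=smooth,
        logfold=logfold)
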
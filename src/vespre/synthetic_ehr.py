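"""Synthetic emergency-department EHR stream generator.

Produces seeded, fully synthetic ED populations — encounters, timestamped
clinical event streams, remnant specimens, and biomarker panels — with known
per-encounter ground truth, so that the digital sepsis alert, the enrollment
funnel, the biorepository accounting, and the cohort analytics can all be
exercised without any protected data.

Time is represented as integer minutes from ED arrival; the calendar day of
arrival (needed by the daily enrollment cap) comes from a simulated arrival
datetime. Continuous vitals and labs are drawn from per-variable marginals
matching a sepsis-enriched ED population: symmetric variables from truncated
normals (mean/SD), skewed variables from log-normals parameterized by their
median and interquartile range. Variables are drawn independently; an
explicit latent factor structure is available separately via
:func:`vespre.analytics.simulate_factor_cohort`.

Ground truth is generated *by construction*: each encounter first receives an
intent for every alert criterion (ED location, age >= 18, cultures in window,
antibiotics in window, >= 1 modified SOFA element, required labs), and events
are then emitted so that each intent is satisfied or violated — e.g. an
encounter whose organ-dysfunction intent is false has every SOFA-governing
value clamped into its non-qualifying range, while a true intent forces one
randomly chosen element into its qualifying range. Re-running the alert logic
on the emitted events therefore reproduces the stored truth labels exactly,
and that equality is asserted by the test suite rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "GeneratorConfig",
    "TubeVolumeParams",
    "BiomarkerParams",
    "CohortData",
    "generate_cohort",
    "generate_biomarker_panel",
    "write_cohort",
    "load_cohort",
    "BIOMARKER_NAMES",
    "CLINICAL_VARIABLES",
]

# --------------------------------------------------------------------------
# Variable marginals (sepsis-enriched ED population)
# --------------------------------------------------------------------------

#: (code, kind, dist, params, lo, hi, decimals, unit)
#: dist "normal": params = (mean, sd); dist "lognormal": params = (median, q1, q3).
_VARIABLE_TABLE = [
    ("bands", "lab", "lognormal", (10.0, 4.0, 21.0), 0.1, 80.0, 1, "%"),
    ("crp", "lab", "normal", (12.5, 12.1), 0.1, 80.0, 1, "mg/L"),
    ("esr", "lab", "normal", (46.0, 52.3), 1.0, 140.0, 0, "mm/h"),
    ("wbc", "lab", "normal", (13.4, 8.8), 0.5, 80.0, 1, "1e9/L"),
    ("rr", "vital", "normal", (23.6, 6.5), 8.0, 60.0, 0, "breaths/min"),
    ("spo2", "vital", "normal", (92.9, 5.3), 50.0, 100.0, 0, "%"),
    ("pao2", "lab", "normal", (134.3, 74.1), 40.0, 500.0, 0, "mmHg"),
    ("fio2", "lab", "normal", (0.21, 0.0), 0.21, 1.0, 2, "fraction"),
    ("hr", "vital", "normal", (104.8, 22.5), 30.0, 220.0, 0, "beats/min"),
    ("sbp", "vital", "normal", (104.9, 24.3), 50.0, 220.0, 0, "mmHg"),
    ("dbp", "vital", "normal", (62.0, 15.0), 25.0, 130.0, 0, "mmHg"),
    ("map", "vital", "derived", None, 30.0, 200.0, 0, "mmHg"),
    ("temperature", "vital", "normal", (37.1, 0.9), 33.0, 42.0, 1, "C"),
    ("troponin", "lab", "lognormal", (0.1, 0.1, 0.2), 0.01, 50.0, 2, "ng/mL"),
    ("lactate", "lab", "lognormal", (1.4, 1.0, 2.2), 0.2, 20.0, 1, "mmol/L"),
    ("bicarbonate", "lab", "normal", (22.9, 4.7), 5.0, 45.0, 0, "mEq/L"),
    ("creatinine", "lab", "lognormal", (1.4, 1.0, 2.3), 0.2, 15.0, 1, "mg/dL"),
    ("bun", "lab", "lognormal", (25.0, 16.0, 41.0), 2.0, 150.0, 0, "mg/dL"),
    ("albumin", "lab", "normal", (3.3, 0.7), 0.8, 6.0, 1, "g/dL"),
    ("alt", "lab", "lognormal", (21.0, 12.0, 42.0), 3.0, 2000.0, 0, "U/L"),
    ("ast", "lab", "lognormal", (29.0, 17.0, 52.0), 3.0, 2000.0, 0, "U/L"),
    ("bilirubin", "lab", "lognormal", (0.8, 0.5, 1.5), 0.1, 30.0, 1, "mg/dL"),
    ("hemoglobin", "lab", "normal", (10.9, 2.3), 3.0, 20.0, 1, "g/dL"),
    ("inr", "lab", "normal", (1.5, 0.9), 0.8, 12.0, 1, ""),
    ("platelets", "lab", "lognormal", (208.0, 144.0, 278.0), 5.0, 1200.0, 0, "1e3/uL"),
    ("chloride", "lab", "normal", (101.6, 5.7), 75.0, 130.0, 0, "mEq/L"),
    ("glucose", "lab", "lognormal", (129.0, 104.0, 171.0), 30.0, 900.0, 0, "mg/dL"),
    ("sodium", "lab", "normal", (135.3, 7.3), 105.0, 165.0, 0, "mEq/L"),
    ("gcs", "vital", "normal", (11.8, 4.3), 3.0, 15.0, 0, ""),
]

CLINICAL_VARIABLES = [row[0] for row in _VARIABLE_TABLE]

# Default fraction of encounters with the variable entirely unmeasured
# (missing completely at random). Chosen so 23 of the 29 clinical variables
# fall below 25% missing: arterial gases, sed rate, bands, troponin and CRP
# are the realistically sparse measurements in an ED stream. Hemoglobin,
# lactate and sodium carry 0 here because their presence is governed by the
# required-labs criterion intent instead.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bands": 0.45,
    "crp": 0.30,
    "esr": 0.55,
    "wbc": 0.05,
    "rr": 0.02,
    "spo2": 0.02,
    "pao2": 0.30,
    "fio2": 0.30,
    "hr": 0.02,
    "sbp": 0.02,
    "dbp": 0.03,
    "map": 0.20,
    "temperature": 0.05,
    "troponin": 0.40,
    "lactate": 0.0,
    "bicarbonate": 0.05,
    "creatinine": 0.03,
    "bun": 0.03,
    "albumin": 0.10,
    "alt": 0.10,
    "ast": 0.10,
    "bilirubin": 0.08,
    "hemoglobin": 0.0,
    "inr": 0.12,
    "platelets": 0.02,
    "chloride": 0.04,
    "glucose": 0.04,
    "sodium": 0.0,
    "gcs": 0.08,
}

REQUIRED_LAB_CODES = ("hemoglobin", "lactate", "sodium")

ANTIBIOTIC_CODES = (
    "vancomycin",
    "ceftriaxone",
    "piperacillin_tazobactam",
    "cefepime",
)

VASOPRESSOR_CODES = (
    "norepinephrine",
    "epinephrine",
    "vasopressin",
    "phenylephrine",
    "dopamine",
    "dobutamine",
)

TUBE_TYPES = ("heparin", "edta", "sodium_fluoride", "citrate", "urine")

#: The 17-marker remnant-specimen panel (damage, resistance/innate immunity,
#: and tolerance axes of the host response), with log-normal marginals
#: (median in native units, sigma on the natural-log scale).
BIOMARKER_NAMES = (
    "pai1",
    "antithrombin_iii",
    "il6",
    "il8",
    "il10",
    "e_selectin",
    "angiopoietin_1",
    "angiopoietin_2",
    "icam",
    "ho1",
    "timp2",
    "igfbp7",
    "lactate",
    "bicarbonate",
    "uric_acid",
    "crp",
    "procalcitonin",
)

_DEFAULT_BIOMARKERS: dict[str, tuple[float, float]] = {
    "pai1": (40.0, 0.9),
    "antithrombin_iii": (80.0, 0.3),
    "il6": (120.0, 1.2),
    "il8": (60.0, 1.1),
    "il10": (15.0, 1.2),
    "e_selectin": (70.0, 0.7),
    "angiopoietin_1": (8.0, 0.8),
    "angiopoietin_2": (5.0, 0.9),
    "icam": (450.0, 0.6),
    "ho1": (15.0, 0.8),
    "timp2": (90.0, 0.6),
    "igfbp7": (120.0, 0.8),
    "lactate": (1.5, 0.5),
    "bicarbonate": (23.0, 0.15),
    "uric_acid": (5.5, 0.4),
    "crp": (100.0, 0.9),
    "procalcitonin": (1.5, 1.4),
}

# Per-criterion intent probabilities for encounters that are not true sepsis.
# A fix-up forces the SOFA-element intent false whenever all six would hold,
# so sepsis prevalence is controlled exactly by the config.
_NONSEPSIS_CRITERION_P = {
    "ed_location": 0.92,
    "cultures_in_window": 0.45,
    "antibiotics_in_window": 0.50,
    "sofa_element": 0.55,
    "required_labs": 0.85,
}

_SOFA_ELEMENT_NAMES = ("pf_ratio", "gcs", "map_or_pressor", "bilirubin", "platelets", "creatinine")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


class TubeVolumeParams(BaseModel):
    """Remnant-volume distribution (truncated normal, μL) and presence
    probability for one tube type."""

    presence: float = Field(ge=0.0, le=1.0)
    loc: float = Field(gt=0.0)
    scale: float = Field(ge=0.0)


class BiomarkerParams(BaseModel):
    """Log-normal marginal for one panel marker: median in native units and
    sigma on the natural-log scale (sigma = 0 collapses to the median)."""

    median: float = Field(gt=0.0)
    sigma: float = Field(ge=0.0)


def _default_tube_params() -> dict[str, TubeVolumeParams]:
    # Locations/scales chosen so roughly 10% of specimens of each required
    # blood tube fall under its volume minimum, i.e. about a quarter of
    # otherwise-eligible patients fail the volume rule jointly.
    return {
        "heparin": TubeVolumeParams(presence=0.90, loc=740.0, scale=150.0),
        "edta": TubeVolumeParams(presence=0.90, loc=640.0, scale=150.0),
        "sodium_fluoride": TubeVolumeParams(presence=0.90, loc=320.0, scale=75.0),
        "citrate": TubeVolumeParams(presence=0.70, loc=560.0, scale=150.0),
        "urine": TubeVolumeParams(presence=0.60, loc=420.0, scale=180.0),
    }


def _default_biomarker_params() -> dict[str, BiomarkerParams]:
    return {
        name: BiomarkerParams(median=m, sigma=s)
        for name, (m, s) in _DEFAULT_BIOMARKERS.items()
    }


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic ED population.

    Defaults reproduce the marginals of the sepsis-enriched nested sample the
    infrastructure was characterized on (age 59 (17) years, 56% male, 4.0
    (2.3) Elixhauser comorbidities, ...), a configurable sepsis prevalence,
    per-variable missingness, and per-tube-type remnant-volume distributions.
    Output is a pure function of the config including ``seed``.
    """

    n_encounters: int = Field(default=1000, ge=0)
    sepsis_prevalence: float = Field(default=0.08, ge=0.0, le=1.0)
    age_mean: float = 59.0
    age_sd: float = Field(default=17.0, gt=0.0)
    age_min: float = 18.0
    age_max: float = 105.0
    male_fraction: float = Field(default=0.56, ge=0.0, le=1.0)
    under18_fraction: float = Field(default=0.02, ge=0.0, le=1.0)
    comorbidity_mean: float = Field(default=4.0, ge=0.0)
    comorbidity_sd: float = Field(default=2.3, gt=0.0)
    missingness: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    tube_volume_params: dict[str, TubeVolumeParams] = Field(default_factory=_default_tube_params)
    event_rate_params: dict[str, float] = Field(default_factory=lambda: {"vital": 3.0, "lab": 1.0})
    specimen_out_of_window_fraction: float = Field(default=0.08, ge=0.0, le=1.0)
    biomarker_params: dict[str, BiomarkerParams] = Field(default_factory=_default_biomarker_params)
    biomarker_missingness: float = Field(default=0.03, ge=0.0, le=1.0)
    study_days: int | None = Field(default=None, ge=1)
    arrival_start: str = "2017-10-17"
    seed: int = Field(default=0, ge=0, lt=2**63)

    @field_validator("missingness")
    @classmethod
    def _check_missingness(cls, v: dict[str, float]) -> dict[str, float]:
        for key, frac in v.items():
            if key not in DEFAULT_MISSINGNESS:
                raise ValueError(f"missingness: unknown clinical variable {key!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"missingness[{key!r}] must be in [0, 1], got {frac}")
        merged = dict(DEFAULT_MISSINGNESS)
        merged.update(v)
        return merged

    @field_validator("tube_volume_params")
    @classmethod
    def _check_tubes(cls, v: dict[str, TubeVolumeParams]) -> dict[str, TubeVolumeParams]:
        for key in v:
            if key not in TUBE_TYPES:
                raise ValueError(f"tube_volume_params: unknown tube type {key!r}")
        merged = _default_tube_params()
        merged.update(v)
        return merged

    @field_validator("biomarker_params")
    @classmethod
    def _check_biomarkers(cls, v: dict[str, BiomarkerParams]) -> dict[str, BiomarkerParams]:
        for key in v:
            if key not in BIOMARKER_NAMES:
                raise ValueError(f"biomarker_params: unknown marker {key!r}")
        merged = _default_biomarker_params()
        merged.update(v)
        return merged


@dataclass
class CohortData:
    """One generated cohort: the three CSV-shaped tables plus truth labels."""

    encounters: pd.DataFrame
    events: pd.DataFrame
    specimens: pd.DataFrame
    truth_labels: pd.DataFrame


# --------------------------------------------------------------------------
# Marginal draws
# --------------------------------------------------------------------------


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR."""
    mu = math.log(median)
    # 0.6744898 is the 75th-percentile z of the standard normal.
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * 0.6744897501960817)
    return mu, max(sigma, 1e-12)


def _draw_variable(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    code, _kind, dist, params, lo, hi, _dec, _unit = spec
    if dist == "normal":
        mean, sd = params
        vals = rng.normal(mean, sd, n) if sd > 0 else np.full(n, mean)
    elif dist == "lognormal":
        mu, sigma = _lognormal_params(*params)
        vals = rng.lognormal(mu, sigma, n)
    else:  # derived (map) — placeholder, filled later
        vals = np.zeros(n)
    return np.clip(vals, lo, hi)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int, max_iter: int = 50) -> np.ndarray:
    vals = rng.normal(mean, sd, n)
    for _ in range(max_iter):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(vals, lo, hi)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> CohortData:
    """Generate one synthetic ED cohort.

    Returns encounters, a long timestamped event stream, a specimen table and
    per-encounter truth labels. For every true-sepsis encounter the stream is
    guaranteed to contain at least one blood-culture order, one antibiotic
    administration, and one qualifying organ-dysfunction value inside the
    6-hour screening window, plus the three required labs; conversely an
    encounter with a false criterion intent contains nothing that would
    satisfy that criterion.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    if n == 0:
        return _empty_cohort()

    enc_ids = np.array([f"E{i:06d}" for i in range(n)])
    pat_ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- demographics -----------------------------------------------------
    minor = rng.random(n) < config.under18_fraction
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            config.age_min, config.age_max, n)
    age = np.round(age, 0)
    age[minor] = rng.integers(1, 18, int(minor.sum()))
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    race = rng.choice(["white", "black", "other"], size=n, p=[0.825, 0.157, 0.018])
    comorbid = np.round(_truncated_normal(
        rng, config.comorbidity_mean, config.comorbidity_sd, 0.0, 20.0, n), 0)

    study_days = config.study_days or max(1, round(n / 75))
    day_idx = rng.integers(0, study_days, n)
    tod = rng.integers(0, 1440, n)
    start = datetime.fromisoformat(config.arrival_start)
    arrival = np.array([
        (start + timedelta(days=int(d), minutes=int(m))).isoformat(sep=" ")
        for d, m in zip(day_idx, tod)
    ])

    # --- criterion intents ------------------------------------------------
    sepsis = (~minor) & (rng.random(n) < config.sepsis_prevalence)
    crit: dict[str, np.ndarray] = {}
    crit["age_ge_18"] = ~minor
    for name, p in _NONSEPSIS_CRITERION_P.items():
        crit[name] = np.where(sepsis, True, rng.random(n) < p)
    all_six = crit["ed_location"] & crit["age_ge_18"] & crit["cultures_in_window"] \
        & crit["antibiotics_in_window"] & crit["sofa_element"] & crit["required_labs"]
    fixup = all_six & ~sepsis
    crit["sofa_element"] = crit["sofa_element"] & ~fixup

    location = np.where(
        crit["ed_location"], "ED",
        rng.choice(["other_ed", "ward", "urgent_care"], size=n))

    sofa_true = crit["sofa_element"]
    sofa_false = ~sofa_true
    forced_idx = rng.integers(0, len(_SOFA_ELEMENT_NAMES), n)
    forced = {
        name: sofa_true & (forced_idx == i)
        for i, name in enumerate(_SOFA_ELEMENT_NAMES)
    }
    pressor_route = forced["map_or_pressor"] & (rng.random(n) < 0.5)
    hypotension_route = forced["map_or_pressor"] & ~pressor_route

    # --- base clinical values, clamped to respect intents -----------------
    specs = {row[0]: row for row in _VARIABLE_TABLE}
    base: dict[str, np.ndarray] = {
        code: _draw_variable(rng, specs[code], n) for code in CLINICAL_VARIABLES
    }

    m = forced["platelets"]
    base["platelets"][m] = rng.uniform(40.0, 149.0, int(m.sum()))
    base["platelets"][sofa_false] = np.maximum(base["platelets"][sofa_false], 150.0)

    m = forced["bilirubin"]
    base["bilirubin"][m] = rng.uniform(1.3, 6.0, int(m.sum()))
    base["bilirubin"][sofa_false] = np.minimum(base["bilirubin"][sofa_false], 1.2)

    m = forced["creatinine"]
    base["creatinine"][m] = rng.uniform(1.3, 4.0, int(m.sum()))
    base["creatinine"][sofa_false] = np.minimum(base["creatinine"][sofa_false], 1.2)

    base["gcs"] = np.round(base["gcs"], 0)
    m = forced["gcs"]
    base["gcs"][m] = rng.integers(6, 15, int(m.sum())).astype(float)
    base["gcs"][sofa_false] = 15.0

    # P/F: the simulator charts FiO2 0.21 (room air) alongside every PaO2.
    base["fio2"][:] = 0.21
    m = forced["pf_ratio"]
    base["pao2"][m] = rng.uniform(55.0, 80.0, int(m.sum()))  # P/F 262-381
    base["pao2"][sofa_false] = np.maximum(base["pao2"][sofa_false], 85.0)  # P/F > 400

    # blood pressure: MAP = (sbp + 2 dbp) / 3
    m = hypotension_route
    k = int(m.sum())
    map_target = rng.uniform(45.0, 69.0, k)
    pulse = rng.uniform(30.0, 50.0, k)
    base["sbp"][m] = map_target + 2.0 * pulse / 3.0
    base["dbp"][m] = base["sbp"][m] - pulse
    _clamp_map_floor(base, sofa_false)
    base["map"] = (base["sbp"] + 2.0 * base["dbp"]) / 3.0

    # --- presence masks ----------------------------------------------------
    present: dict[str, np.ndarray] = {}
    labs_true = crit["required_labs"]
    req_drop = rng.integers(0, 3, n)
    for code in CLINICAL_VARIABLES:
        if code in REQUIRED_LAB_CODES:
            i = REQUIRED_LAB_CODES.index(code)
            keep = labs_true | ((req_drop != i) & (rng.random(n) < 0.85))
            present[code] = keep
        else:
            present[code] = rng.random(n) >= config.missingness[code]
    # paired arterial gas: one mask for PaO2+FiO2
    present["fio2"] = present["pao2"].copy()
    # protect forced-element evidence from missingness
    present["platelets"] |= forced["platelets"]
    present["bilirubin"] |= forced["bilirubin"]
    present["creatinine"] |= forced["creatinine"]
    present["gcs"] |= forced["gcs"]
    for code in ("pao2", "fio2"):
        present[code] |= forced["pf_ratio"]
    for code in ("sbp", "dbp"):
        present[code] |= hypotension_route

    # --- event assembly ----------------------------------------------------
    frames: list[pd.DataFrame] = []
    vital_reps = max(1, int(round(config.event_rate_params.get("vital", 3.0))))

    bp_t0 = rng.integers(0, 60, n)
    for code in CLINICAL_VARIABLES:
        spec = specs[code]
        kind = "vital" if spec[1] == "vital" else "lab"
        dec = spec[6]
        unit = spec[7]
        mask = present[code]
        if code in ("sbp", "dbp", "map"):
            t0 = bp_t0  # paired timestamps so MAP is derivable
        elif kind == "vital":
            t0 = rng.integers(0, 60, n)
        else:
            t0 = rng.integers(20, 300, n)
        frames.append(_event_frame(enc_ids, t0, kind, code, base[code], unit, dec, mask))
        if kind == "vital" and code not in ("map", "sbp", "dbp") and vital_reps > 1:
            for _ in range(vital_reps - 1):
                jit = base[code] * (1.0 + rng.normal(0.0, 0.04, n))
                jit = _reclamp_extra(code, jit, base[code], sofa_false, spec)
                t_extra = rng.integers(60, 360, n)
                frames.append(_event_frame(enc_ids, t_extra, kind, code, jit, unit, dec, mask))
    # repeated blood-pressure extras must preserve the MAP clamp jointly
    if vital_reps > 1:
        for _ in range(vital_reps - 1):
            sbp_j = base["sbp"] * (1.0 + rng.normal(0.0, 0.04, n))
            dbp_j = base["dbp"] * (1.0 + rng.normal(0.0, 0.04, n))
            bp = {"sbp": sbp_j, "dbp": dbp_j}
            _clamp_map_floor(bp, sofa_false)
            t_extra = rng.integers(60, 360, n)
            mask_bp = present["sbp"] & present["dbp"]
            frames.append(_event_frame(enc_ids, t_extra, "vital", "sbp", bp["sbp"], "mmHg", 0, mask_bp))
            frames.append(_event_frame(enc_ids, t_extra, "vital", "dbp", bp["dbp"], "mmHg", 0, mask_bp))

    # suspected-infection events
    frames.append(_binary_events(
        rng, enc_ids, crit["cultures_in_window"], "culture_order", "blood_culture",
        in_lo=0, in_hi=300, out_lo=361, out_hi=720, out_frac=0.5))
    abx_code = rng.choice(np.array(ANTIBIOTIC_CODES), size=n)
    frames.append(_binary_events(
        rng, enc_ids, crit["antibiotics_in_window"], "med_admin", abx_code,
        in_lo=0, in_hi=340, out_lo=361, out_hi=720, out_frac=0.5))

    # vasopressors (qualify the cardiovascular element on their own)
    k = int(pressor_route.sum())
    if k:
        frames.append(pd.DataFrame({
            "encounter_id": enc_ids[pressor_route],
            "t_minutes": rng.integers(0, 340, k),
            "kind": "med_admin",
            "code": rng.choice(np.array(VASOPRESSOR_CODES), size=k),
            "value": 1.0,
            "unit": "dose",
        }))

    # --- specimens ----------------------------------------------------------
    specimens = _generate_specimens(rng, config, enc_ids, n)
    if len(specimens):
        frames.append(pd.DataFrame({
            "encounter_id": specimens["encounter_id"],
            "t_minutes": specimens["t_minutes"],
            "kind": "specimen_collect",
            "code": specimens["tube_type"],
            "value": specimens["remnant_volume_ul"],
            "unit": "uL",
        }))

    events = pd.concat(frames, ignore_index=True)
    events["t_minutes"] = events["t_minutes"].astype(int)
    events = events.sort_values(
        ["encounter_id", "t_minutes", "kind", "code"], kind="mergesort"
    ).reset_index(drop=True)

    encounters = pd.DataFrame({
        "encounter_id": enc_ids,
        "patient_id": pat_ids,
        "age_years": age,
        "sex": sex,
        "race": race,
        "arrival_datetime": arrival,
        "location": location,
        "elixhauser_count": comorbid,
    })

    truth = pd.DataFrame({
        "encounter_id": enc_ids,
        "true_sepsis": sepsis,
        "ed_location": crit["ed_location"],
        "age_ge_18": crit["age_ge_18"],
        "cultures_in_window": crit["cultures_in_window"],
        "antibiotics_in_window": crit["antibiotics_in_window"],
        "sofa_element": crit["sofa_element"],
        "required_labs": crit["required_labs"],
    })

    return CohortData(encounters, events, specimens, truth)


def _clamp_map_floor(values: Mapping[str, np.ndarray], rows: np.ndarray,
                     floor: float = 70.5) -> None:
    """Scale sbp/dbp up in-place so derived MAP >= floor on ``rows``."""
    map_v = (values["sbp"] + 2.0 * values["dbp"]) / 3.0
    bad = rows & (map_v < floor)
    if bad.any():
        factor = floor / map_v[bad]
        values["sbp"][bad] *= factor
        values["dbp"][bad] *= factor


def _reclamp_extra(code: str, jittered: np.ndarray, base: np.ndarray,
                   sofa_false: np.ndarray, spec: tuple) -> np.ndarray:
    """Keep repeated vital measurements inside intent-safe ranges."""
    lo, hi = spec[4], spec[5]
    out = np.clip(jittered, lo, hi)
    if code == "gcs":
        out = base.copy()  # GCS is stable within the window by construction
    elif code == "spo2":
        out = np.minimum(out, 100.0)
    return out


def _event_frame(enc_ids: np.ndarray, t: np.ndarray, kind: str, code: str,
                 values: np.ndarray, unit: str, decimals: int,
                 mask: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "encounter_id": enc_ids[mask],
        "t_minutes": np.asarray(t)[mask],
        "kind": kind,
        "code": code,
        "value": np.round(values[mask], decimals),
        "unit": unit,
    })


def _binary_events(rng: np.random.Generator, enc_ids: np.ndarray,
                   intent_true: np.ndarray, kind: str, code,
                   in_lo: int, in_hi: int, out_lo: int, out_hi: int,
                   out_frac: float) -> pd.DataFrame:
    """Events that must exist in-window iff intent is true; a false intent
    yields either no event or one strictly outside the window."""
    n = len(enc_ids)
    t = np.where(intent_true,
                 rng.integers(in_lo, in_hi, n),
                 rng.integers(out_lo, out_hi, n))
    late = (~intent_true) & (rng.random(n) < out_frac)
    emit = intent_true | late
    codes = code if isinstance(code, str) else code
    frame = pd.DataFrame({
        "encounter_id": enc_ids,
        "t_minutes": t,
        "kind": kind,
        "code": codes,
        "value": 1.0,
        "unit": "",
    })
    return frame[emit].reset_index(drop=True)


def _generate_specimens(rng: np.random.Generator, config: GeneratorConfig,
                        enc_ids: np.ndarray, n: int) -> pd.DataFrame:
    """Clinical specimens accrue repeatedly over the stay: each present tube
    type yields 1 + Poisson(rate) draws, so most patients end up with several
    remnants per type. An out-of-window encounter has all collections after
    the 6-hour screening window."""
    rows = []
    late_enc = rng.random(n) < config.specimen_out_of_window_fraction
    extra_rate = config.event_rate_params.get("specimens_per_tube_extra", 1.8)
    for tube in TUBE_TYPES:
        params = config.tube_volume_params[tube]
        present = rng.random(n) < params.presence
        counts = (1 + rng.poisson(extra_rate, n)) * present
        total = int(counts.sum())
        enc_rep = np.repeat(enc_ids, counts)
        late_rep = np.repeat(late_enc, counts)
        vol = _truncated_normal(rng, params.loc, params.scale, 10.0,
                                params.loc + 6 * max(params.scale, 1.0), total)
        t_in = rng.integers(15, 330, total)
        t_out = rng.integers(360, 1440, total)
        t = np.where(late_rep, t_out, t_in)
        done = t + rng.integers(60, 300, total)
        rows.append(pd.DataFrame({
            "encounter_id": enc_rep,
            "t_minutes": t,
            "tube_type": tube,
            "remnant_volume_ul": np.round(vol, 0),
            "clinical_testing_complete_minutes": done,
        }))
    specimens = pd.concat(rows, ignore_index=True)
    return specimens.sort_values(
        ["encounter_id", "t_minutes", "tube_type"], kind="mergesort"
    ).reset_index(drop=True)


def _empty_cohort() -> CohortData:
    encounters = pd.DataFrame(columns=[
        "encounter_id", "patient_id", "age_years", "sex", "race",
        "arrival_datetime", "location", "elixhauser_count"])
    events = pd.DataFrame(columns=[
        "encounter_id", "t_minutes", "kind", "code", "value", "unit"])
    specimens = pd.DataFrame(columns=[
        "encounter_id", "t_minutes", "tube_type", "remnant_volume_ul",
        "clinical_testing_complete_minutes"])
    truth = pd.DataFrame(columns=[
        "encounter_id", "true_sepsis", "ed_location", "age_ge_18",
        "cultures_in_window", "antibiotics_in_window", "sofa_element",
        "required_labs"])
    return CohortData(encounters, events, specimens, truth)


# --------------------------------------------------------------------------
# Biomarker panel
# --------------------------------------------------------------------------


def generate_biomarker_panel(config: GeneratorConfig, enrolled_ids,
                             markers: tuple[str, ...] = BIOMARKER_NAMES) -> pd.DataFrame:
    """Per-patient remnant-specimen biomarker panel.

    One row per enrolled patient, one column per marker, strictly positive
    concentrations drawn from the configured log-normal marginals. Cells are
    set missing (NaN) at the configured rate to emulate markers that could
    not be measured on a given remnant (white cells in the heat map).
    """
    ids = list(enrolled_ids)
    if not ids:
        raise ValueError("enrolled_ids must be non-empty")
    for m in markers:
        if m not in config.biomarker_params:
            raise ValueError(f"unknown marker name {m!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_002_001]))
    out = {}
    for m in markers:
        p = config.biomarker_params[m]
        vals = p.median * np.exp(rng.normal(0.0, 1.0, len(ids)) * p.sigma) \
            if p.sigma > 0 else np.full(len(ids), p.median)
        if config.biomarker_missingness > 0:
            miss = rng.random(len(ids)) < config.biomarker_missingness
            vals = np.where(miss, np.nan, vals)
        out[m] = vals
    return pd.DataFrame(out, index=pd.Index(ids, name="study_id"))


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.encounters.to_csv(out / "encounters.csv", index=False)
    cohort.events.to_csv(out / "events.csv", index=False)
    cohort.specimens.to_csv(out / "specimens.csv", index=False)
    cohort.truth_labels.to_csv(out / "truth_labels.csv", index=False)


def load_cohort(in_dir: str | Path) -> CohortData:
    p = Path(in_dir)
    truth_path = p / "truth_labels.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else _empty_cohort().truth_labels
    return CohortData(
        pd.read_csv(p / "encounters.csv"),
        pd.read_csv(p / "events.csv"),
        pd.read_csv(p / "specimens.csv"),
        truth,
    )
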
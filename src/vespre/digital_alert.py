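"""EHR-embedded digital sepsis screening alert.

Implements the six-criterion digital flag used to screen ED arrivals for
sepsis-3 within the first 6 hours of presentation:

1. location in the enrolling emergency department,
2. age 18 years or older,
3. blood cultures obtained in the window,
4. antibiotics administered in the window,
5. at least 1 of 6 modified SOFA elements — PaO2/FiO2 < 400 mmHg, GCS < 15,
   MAP < 70 mmHg or vasopressors administered, total bilirubin > 1.2 mg/dL,
   platelets < 150 x10^3/uL, creatinine > 1.2 mg/dL — and
6. hemoglobin, plasma lactate and sodium results obtained (a proxy ensuring
   the proper remnant tube types exist).

All inequalities are strict exactly as printed (platelets 150 does not
trigger). Each element is evaluated on the worst value observed in the
half-open window [0, window) minutes from arrival: minimum for P/F, GCS, MAP
and platelets; maximum for bilirubin and creatinine. An element with no
measurement of its kind is false. The six-criterion conjunction is cumulative
within the window: the flag time is the earliest minute by which every
criterion has been satisfied at least once.

A full-SOFA adjudication oracle scores all six organ systems 0-4 on the
standard Sepsis-3 grid (shipped as ``data/sofa_grid.json``) against
worst-in-window values, mirroring the manual chart review used to validate
the alert. Cardiovascular sub-scores above 2 require vasopressor dose rates
the event model does not carry, so any vasopressor administration scores a
floor of 2; organs without data score 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .synthetic_ehr import ANTIBIOTIC_CODES, REQUIRED_LAB_CODES, VASOPRESSOR_CODES

__all__ = [
    "RecordValidationError",
    "ElementResult",
    "SofaElementAssessment",
    "AlertFlag",
    "evaluate_sofa_elements",
    "detect_suspected_infection",
    "check_required_labs",
    "generate_alert",
    "adjudicate_full_sofa",
    "screen_cohort",
    "WINDOW_MINUTES",
    "CRITERION_NAMES",
]

WINDOW_MINUTES = 360

CRITERION_NAMES = (
    "ed_location",
    "age_ge_18",
    "cultures_in_window",
    "antibiotics_in_window",
    "sofa_element",
    "required_labs",
)

ELEMENT_NAMES = ("pf_ratio", "gcs", "map_or_pressor", "bilirubin", "platelets", "creatinine")

ENROLLING_LOCATION = "ED"


class RecordValidationError(ValueError):
    """A clinical event record failed validation (e.g. non-numeric value)."""


@dataclass
class ElementResult:
    triggered: bool
    evidence_value: float | None = None
    evidence_time: int | None = None
    first_qualifying_time: int | None = None


@dataclass
class SofaElementAssessment:
    """Per-organ evidence for the modified SOFA criterion of one encounter."""

    encounter_id: str | None
    elements: dict[str, ElementResult] = field(default_factory=dict)

    @property
    def n_elements_triggered(self) -> int:
        return sum(1 for e in self.elements.values() if e.triggered)

    @property
    def any_triggered(self) -> bool:
        return self.n_elements_triggered > 0


@dataclass
class AlertFlag:
    """A digital screening flag: exists only when all six criteria hold."""

    encounter_id: str
    flag_time: int
    criteria: dict[str, bool]


def _load_sofa_grid() -> dict:
    with resources.files("vespre").joinpath("data/sofa_grid.json").open() as fh:
        return json.load(fh)


_SOFA_GRID = _load_sofa_grid()["organs"]


# --------------------------------------------------------------------------
# Event-stream access
# --------------------------------------------------------------------------


def _arrays(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(t, kind, code, value) arrays with record-level numeric validation."""
    if len(events) == 0:
        z = np.array([])
        return z.astype(int), z.astype(str), z.astype(str), z
    t = np.asarray(events["t_minutes"], dtype=float).astype(int)
    kind = np.asarray(events["kind"], dtype=str)
    code = np.asarray(events["code"], dtype=str)
    raw = events["value"]
    value = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(value) & raw.notna().to_numpy()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise RecordValidationError(
            f"non-numeric value {raw.iloc[i]!r} for code {code[i]!r} at t={t[i]}")
    return t, kind, code, value


def _series(t, code, value, name, win):
    m = (code == name) & win & ~np.isnan(value)
    return t[m], value[m]


def _pf_series(t, kind, code, value, win):
    """PaO2/FiO2 ratios paired in time. Each PaO2 uses the latest FiO2 charted
    at or before it (else the earliest after); if no FiO2 is charted but a
    room-air oxygen-device event exists, FiO2 0.21 is imputed."""
    tp, vp = _series(t, code, value, "pao2", win)
    tf, vf = _series(t, code, value, "fio2", win)
    if len(tp) == 0:
        return tp, vp
    if len(tf) == 0:
        room_air = ((code == "o2_device") & win).any() or ((code == "room_air") & win).any()
        if not room_air:
            return np.array([], dtype=int), np.array([])
        ratios = vp / 0.21
        return tp, ratios
    order = np.argsort(tf, kind="stable")
    tf, vf = tf[order], vf[order]
    idx = np.searchsorted(tf, tp, side="right") - 1
    idx = np.maximum(idx, 0)
    return tp, vp / vf[idx]


def _map_series(t, kind, code, value, win):
    """Candidate MAP values: directly charted MAP, plus (sbp + 2 dbp)/3
    derived at timestamps where systolic and diastolic coincide and no direct
    MAP was charted (direct readings take precedence)."""
    td, vd = _series(t, code, value, "map", win)
    ts, vs = _series(t, code, value, "sbp", win)
    tb, vb = _series(t, code, value, "dbp", win)
    common, is_, ib = np.intersect1d(ts, tb, return_indices=True)
    derived_t, derived_v = common, (vs[is_] + 2.0 * vb[ib]) / 3.0
    if len(td):
        keep = ~np.isin(derived_t, td)
        derived_t, derived_v = derived_t[keep], derived_v[keep]
    return np.concatenate([td, derived_t]), np.concatenate([vd, derived_v])


def _worst(times, values, side):
    if len(values) == 0:
        return None, None
    i = int(np.argmin(values)) if side == "low" else int(np.argmax(values))
    return float(values[i]), int(times[i])


def _first_qualifying(times, values, qualifies) -> int | None:
    m = qualifies(values)
    return int(times[m].min()) if m.any() else None


# --------------------------------------------------------------------------
# Criterion evaluation
# --------------------------------------------------------------------------


def _assess_elements(t, kind, code, value, window) -> SofaElementAssessment:
    win = (t >= 0) & (t < window)
    out = SofaElementAssessment(encounter_id=None)

    tpf, vpf = _pf_series(t, kind, code, value, win)
    out.elements["pf_ratio"] = _threshold_element(tpf, vpf, lambda v: v < 400.0, "low")

    tg, vg = _series(t, code, value, "gcs", win)
    out.elements["gcs"] = _threshold_element(tg, vg, lambda v: v < 15.0, "low")

    tm, vm = _map_series(t, kind, code, value, win)
    map_el = _threshold_element(tm, vm, lambda v: v < 70.0, "low")
    pressor_t = t[(kind == "med_admin") & np.isin(code, VASOPRESSOR_CODES) & win]
    if len(pressor_t):
        first_p = int(pressor_t.min())
        if not map_el.triggered:
            map_el = ElementResult(True, None, first_p, first_p)
        else:
            map_el.first_qualifying_time = min(map_el.first_qualifying_time, first_p)
    out.elements["map_or_pressor"] = map_el

    tb, vb = _series(t, code, value, "bilirubin", win)
    out.elements["bilirubin"] = _threshold_element(tb, vb, lambda v: v > 1.2, "high")

    tp, vp = _series(t, code, value, "platelets", win)
    out.elements["platelets"] = _threshold_element(tp, vp, lambda v: v < 150.0, "low")

    tc, vc = _series(t, code, value, "creatinine", win)
    out.elements["creatinine"] = _threshold_element(tc, vc, lambda v: v > 1.2, "high")
    return out


def _threshold_element(times, values, qualifies, side) -> ElementResult:
    wv, wt = _worst(times, values, side)
    if wv is None:
        return ElementResult(False)
    trig = bool(qualifies(np.array([wv]))[0]) if callable(qualifies) else False
    fq = _first_qualifying(times, values, qualifies) if trig else None
    return ElementResult(trig, wv, wt, fq)


def evaluate_sofa_elements(events: pd.DataFrame,
                           window_minutes: int = WINDOW_MINUTES) -> SofaElementAssessment:
    """Evaluate the six modified SOFA elements for a single encounter.

    Each element uses the worst value observed in [0, window): minimum for
    P/F, GCS, MAP, platelets; maximum for bilirubin, creatinine. An element
    with no measurement is false.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    assessment = _assess_elements(*_arrays(events), window_minutes)
    if len(events):
        assessment.encounter_id = str(events["encounter_id"].iloc[0])
    return assessment


def detect_suspected_infection(events: pd.DataFrame,
                               window_minutes: int = WINDOW_MINUTES) -> bool:
    """True iff >=1 blood-culture order AND >=1 antibiotic administration both
    fall inside [0, window). An empty stream is False."""
    t, kind, code, _ = _arrays(events)
    win = (t >= 0) & (t < window_minutes)
    culture = ((kind == "culture_order") & win).any()
    abx = ((kind == "med_admin") & np.isin(code, ANTIBIOTIC_CODES) & win).any()
    return bool(culture and abx)


def check_required_labs(events: pd.DataFrame,
                        window_minutes: int = WINDOW_MINUTES) -> bool:
    """True iff hemoglobin, lactate and sodium each have >=1 in-window result."""
    t, _kind, code, value = _arrays(events)
    win = (t >= 0) & (t < window_minutes)
    return all(
        ((code == lab) & win & ~np.isnan(value)).any()
        for lab in REQUIRED_LAB_CODES
    )


def _evaluate_criteria(age: float, location: str, t, kind, code, value,
                       window_minutes: int):
    """All six criteria + cumulative flag time + element assessment."""
    win = (t >= 0) & (t < window_minutes)
    criteria: dict[str, bool] = {}
    times: list[int] = [0]
    criteria["ed_location"] = str(location) == ENROLLING_LOCATION
    criteria["age_ge_18"] = float(age) >= 18.0

    ct = t[(kind == "culture_order") & win]
    criteria["cultures_in_window"] = len(ct) > 0
    if len(ct):
        times.append(int(ct.min()))

    at = t[(kind == "med_admin") & np.isin(code, ANTIBIOTIC_CODES) & win]
    criteria["antibiotics_in_window"] = len(at) > 0
    if len(at):
        times.append(int(at.min()))

    assessment = _assess_elements(t, kind, code, value, window_minutes)
    criteria["sofa_element"] = assessment.any_triggered
    if assessment.any_triggered:
        times.append(min(
            e.first_qualifying_time for e in assessment.elements.values()
            if e.triggered and e.first_qualifying_time is not None))

    lab_firsts = []
    for lab in REQUIRED_LAB_CODES:
        lt = t[(code == lab) & win & ~np.isnan(value)]
        if len(lt):
            lab_firsts.append(int(lt.min()))
    criteria["required_labs"] = len(lab_firsts) == len(REQUIRED_LAB_CODES)
    if criteria["required_labs"]:
        times.append(max(lab_firsts))

    flag_time = max(times) if all(criteria.values()) else None
    return criteria, flag_time, assessment


def generate_alert(encounter, events: pd.DataFrame,
                   window_minutes: int = WINDOW_MINUTES) -> AlertFlag | None:
    """Evaluate all six criteria for one encounter; return an
    :class:`AlertFlag` iff every criterion holds.

    ``encounter`` must carry ``age_years`` and ``location``. The flag time is
    the earliest minute at which all criteria are simultaneously satisfied
    (the max over criteria of their first satisfaction times); location and
    age count from arrival (minute 0).
    """
    age = encounter["age_years"] if "age_years" in encounter else None
    if age is None or (isinstance(age, float) and np.isnan(age)):
        raise RecordValidationError("encounter is missing age_years")
    t, kind, code, value = _arrays(events)
    criteria, flag_time, _ = _evaluate_criteria(
        age, encounter["location"], t, kind, code, value, window_minutes)
    if flag_time is None:
        return None
    enc_id = str(encounter["encounter_id"]) if "encounter_id" in encounter else (
        str(events["encounter_id"].iloc[0]) if len(events) else "")
    return AlertFlag(encounter_id=enc_id, flag_time=flag_time, criteria=criteria)


# --------------------------------------------------------------------------
# Full-SOFA adjudication oracle
# --------------------------------------------------------------------------


def _grid_score(organ: str, worst: float | None, vasopressor: bool = False) -> int:
    grid = _SOFA_GRID[organ]
    score = 0
    if worst is not None:
        for band in grid["bands"]:
            if grid["direction"] == "low":
                if worst < band["below"]:
                    score = band["score"]
                    break
            else:
                if worst >= band["at_least"]:
                    score = band["score"]
                    break
    if vasopressor and organ == "cardiovascular":
        score = max(score, grid.get("vasopressor_floor", 2))
    return score


def adjudicate_full_sofa(events: pd.DataFrame,
                         window_minutes: int = WINDOW_MINUTES) -> int:
    """Full SOFA score 0-24 on worst-in-window values, standard Sepsis-3 grid.

    Organs with no data score 0, mirroring chart adjudication of an early ED
    window where unmeasured organ systems are presumed intact.
    """
    return _adjudicate_arrays(*_arrays(events), window_minutes)


def _adjudicate_arrays(t, kind, code, value, window_minutes: int) -> int:
    win = (t >= 0) & (t < window_minutes)

    tpf, vpf = _pf_series(t, kind, code, value, win)
    pf_worst = float(vpf.min()) if len(vpf) else None
    tp, vp = _series(t, code, value, "platelets", win)
    plt_worst = float(vp.min()) if len(vp) else None
    tb, vb = _series(t, code, value, "bilirubin", win)
    bili_worst = float(vb.max()) if len(vb) else None
    tm, vm = _map_series(t, kind, code, value, win)
    map_worst = float(vm.min()) if len(vm) else None
    tg, vg = _series(t, code, value, "gcs", win)
    gcs_worst = float(vg.min()) if len(vg) else None
    tc, vc = _series(t, code, value, "creatinine", win)
    creat_worst = float(vc.max()) if len(vc) else None
    pressor = bool(((kind == "med_admin") & np.isin(code, VASOPRESSOR_CODES) & win).any())

    return (
        _grid_score("respiration", pf_worst)
        + _grid_score("coagulation", plt_worst)
        + _grid_score("liver", bili_worst)
        + _grid_score("cardiovascular", map_worst, vasopressor=pressor)
        + _grid_score("cns", gcs_worst)
        + _grid_score("renal", creat_worst)
    )


# --------------------------------------------------------------------------
# Cohort screening
# --------------------------------------------------------------------------


def screen_cohort(encounters: pd.DataFrame, events: pd.DataFrame,
                  window_minutes: int = WINDOW_MINUTES,
                  adjudicate: bool = True) -> pd.DataFrame:
    """Run the alert over a whole cohort.

    Returns one row per encounter with the six criterion booleans, the flag
    indicator and time, the triggered-element count, the adjudicated full
    SOFA score, and the arrival day (for the daily enrollment cap).
    """
    t, kind, code, value = _arrays(events)
    enc_col = np.asarray(events["encounter_id"], dtype=str) if len(events) else np.array([], dtype=str)
    order = np.argsort(enc_col, kind="stable")
    t, kind, code, value, enc_col = t[order], kind[order], code[order], value[order], enc_col[order]
    bounds = np.searchsorted(enc_col, np.asarray(encounters["encounter_id"], dtype=str), side="left")
    bounds_hi = np.searchsorted(enc_col, np.asarray(encounters["encounter_id"], dtype=str), side="right")

    enc_ids = np.asarray(encounters["encounter_id"], dtype=str)
    ages = np.asarray(encounters["age_years"], dtype=float)
    locations = np.asarray(encounters["location"], dtype=str)
    arrivals = (np.asarray(encounters["arrival_datetime"], dtype=str)
                if "arrival_datetime" in encounters else np.full(len(encounters), ""))

    rows = []
    for i in range(len(encounters)):
        if np.isnan(ages[i]):
            raise RecordValidationError(
                f"encounter {enc_ids[i]} is missing age_years")
        sl = slice(bounds[i], bounds_hi[i])
        criteria, flag_time, assessment = _evaluate_criteria(
            ages[i], locations[i], t[sl], kind[sl], code[sl], value[sl],
            window_minutes)
        row = {
            "encounter_id": enc_ids[i],
            "arrival_datetime": arrivals[i],
            "flagged": flag_time is not None,
            "flag_time_minutes": flag_time if flag_time is not None else np.nan,
            "n_elements_triggered": assessment.n_elements_triggered,
        }
        row.update(criteria)
        if adjudicate:
            row["adjudicated_sofa"] = _adjudicate_arrays(
                t[sl], kind[sl], code[sl], value[sl], window_minutes)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["day"] = pd.to_datetime(out["arrival_datetime"]).dt.date.astype(str)
    else:
        out = pd.DataFrame(columns=[
            "encounter_id", "arrival_datetime", "flagged", "flag_time_minutes",
            "n_elements_triggered", *CRITERION_NAMES, "adjudicated_sofa", "day"])
    return out
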
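"""Remnant-specimen eligibility and aliquot accounting.

The biorepository is "virtually enabled": no dedicated research draws exist,
only leftover clinical specimens identified by the digital alert. A remnant
specimen is eligible when

* its tube type is known (heparin, EDTA, sodium fluoride, citrate, urine),
* its remaining volume meets the tube-type minimum — strictly greater than
  550 uL for heparin; at least 450 uL for EDTA, 225 uL for sodium fluoride,
  125 uL for urine; citrate (whose minimum was never printed) defaults to
  the EDTA-like 450 uL and is configurable,
* it is retrieved from the clinical laboratory within 48 hours (2880 min)
  of acquisition, and
* retrieval happens only after clinical testing is complete.

Eligibility is monotone: more volume or a shorter retrieval delay can never
flip an eligible specimen to rejected. Aliquot accounting follows the
specimens-meeting-minimum convention — a patient "has >=2 aliquots" of a
tube type when >=2 eligible specimens of that type exist — with an
``aliquot_count`` per specimen derived from a fixed 125 uL aliquot size for
the total-inventory counter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VOLUME_MINIMA",
    "ALIQUOT_SIZE_UL",
    "MAX_PICKUP_DELAY_MINUTES",
    "BiorepositoryReport",
    "assess_remnant_eligibility",
    "aliquot_accounting",
]

#: tube type -> (minimum remnant volume uL, strict inequality?)
VOLUME_MINIMA: dict[str, tuple[float, bool]] = {
    "heparin": (550.0, True),
    "edta": (450.0, False),
    "sodium_fluoride": (225.0, False),
    "citrate": (450.0, False),  # unreported; EDTA-like default, configurable
    "urine": (125.0, False),
}

ALIQUOT_SIZE_UL = 125.0
MAX_PICKUP_DELAY_MINUTES = 48 * 60

BLOOD_TUBES = ("heparin", "edta", "sodium_fluoride", "citrate")


def assess_remnant_eligibility(
    specimens: pd.DataFrame,
    volume_minima: dict[str, tuple[float, bool]] | None = None,
    max_pickup_delay: int = MAX_PICKUP_DELAY_MINUTES,
    aliquot_size_ul: float = ALIQUOT_SIZE_UL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split specimens into (eligible samples, rejects with reasons).

    ``specimens`` must carry ``tube_type``, ``remnant_volume_ul``,
    ``t_minutes`` (acquisition) and ``clinical_testing_complete_minutes``.
    An optional ``collected_from_lab_minutes`` column gives the research
    retrieval time; when absent, retrieval is assumed to happen as soon as
    clinical testing completes. Reject reasons: ``unknown_tube``,
    ``below_volume_minimum``, ``window_48h``, ``before_testing_complete``.
    Eligible rows gain an ``aliquot_count`` column (volume // aliquot size).
    """
    minima = volume_minima or VOLUME_MINIMA
    spec = specimens.copy()
    if "collected_from_lab_minutes" not in spec:
        spec["collected_from_lab_minutes"] = spec["clinical_testing_complete_minutes"]

    reason = np.full(len(spec), "", dtype=object)
    tube = spec["tube_type"].astype(str).to_numpy()
    vol = spec["remnant_volume_ul"].to_numpy(dtype=float)
    acquired = spec["t_minutes"].to_numpy(dtype=float)
    testing_done = spec["clinical_testing_complete_minutes"].to_numpy(dtype=float)
    pickup = spec["collected_from_lab_minutes"].to_numpy(dtype=float)

    unknown = ~np.isin(tube, list(minima))
    reason[unknown] = "unknown_tube"

    vol_ok = np.zeros(len(spec), dtype=bool)
    for t, (vmin, strict) in minima.items():
        m = tube == t
        vol_ok[m] = vol[m] > vmin if strict else vol[m] >= vmin
    m = ~unknown & ~vol_ok
    reason[m] = "below_volume_minimum"

    late = pickup - acquired > max_pickup_delay
    m = ~unknown & vol_ok & late
    reason[m] = "window_48h"

    premature = pickup < testing_done
    m = ~unknown & vol_ok & ~late & premature
    reason[m] = "before_testing_complete"

    eligible = spec[reason == ""].copy()
    eligible["aliquot_count"] = (
        eligible["remnant_volume_ul"].to_numpy(dtype=float) // aliquot_size_ul
    ).astype(int)
    rejects = spec[reason != ""].copy()
    rejects["reject_reason"] = reason[reason != ""]
    return eligible.reset_index(drop=True), rejects.reset_index(drop=True)


@dataclass
class BiorepositoryReport:
    """Aliquot availability over the enrolled denominator."""

    n_enrolled: int
    n_ge2_any: int
    pct_ge2_any: int
    per_tube_ge2: dict[str, int]
    per_tube_pct: dict[str, int]
    n_ge2_urine: int
    pct_ge2_urine: int
    total_aliquots: int
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for k, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {k} outside [0, 1]: {f}")


def _round_pct(numerator: int, denominator: int) -> int:
    if denominator <= 0:
        return 0
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def aliquot_accounting(samples: pd.DataFrame, n_enrolled: int) -> BiorepositoryReport:
    """Summarize eligible remnant samples into availability fractions.

    ``samples`` must carry ``study_id`` (or ``encounter_id``) and
    ``tube_type`` and should already be restricted to eligible remnants of
    enrolled patients. Percentages are integer-rounded over the enrolled
    denominator, which is recorded alongside every fraction.
    """
    if n_enrolled < 0:
        raise ValueError("n_enrolled must be >= 0")
    key = "study_id" if "study_id" in samples else "encounter_id"
    counts = (samples.groupby([key, "tube_type"]).size().unstack(fill_value=0)
              if len(samples) else pd.DataFrame())

    per_tube_ge2: dict[str, int] = {}
    for tube in BLOOD_TUBES:
        n = int((counts[tube] >= 2).sum()) if tube in counts.columns else 0
        per_tube_ge2[tube] = n
    n_ge2_any = int((counts.sum(axis=1) >= 2).sum()) if len(counts) else 0
    n_ge2_urine = (int((counts["urine"] >= 2).sum())
                   if "urine" in counts.columns else 0)
    total_aliquots = int(samples["aliquot_count"].sum()) if "aliquot_count" in samples else len(samples)

    fractions = {"ge2_any": n_ge2_any / n_enrolled if n_enrolled else 0.0,
                 "ge2_urine": n_ge2_urine / n_enrolled if n_enrolled else 0.0}
    for tube, n in per_tube_ge2.items():
        fractions[f"ge2_{tube}"] = n / n_enrolled if n_enrolled else 0.0

    return BiorepositoryReport(
        n_enrolled=n_enrolled,
        n_ge2_any=n_ge2_any,
        pct_ge2_any=_round_pct(n_ge2_any, n_enrolled),
        per_tube_ge2=per_tube_ge2,
        per_tube_pct={t: _round_pct(n, n_enrolled) for t, n in per_tube_ge2.items()},
        n_ge2_urine=n_ge2_urine,
        pct_ge2_urine=_round_pct(n_ge2_urine, n_enrolled),
        total_aliquots=total_aliquots,
        fractions=fractions,
    )
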
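"""Line-item study-cost accounting with cent-exact arithmetic.

Compares the incremental cost of the EHR-embedded design against
coordinator-led alternatives. Currency is held as integer cents end to end —
line items are parsed from dollars-and-cents strings through
:class:`decimal.Decimal`, category totals sum to design totals exactly, and
per-patient values are rounded half-up to whole cents. (The original report
mixed truncation and rounding in its per-patient figures; this module
standardizes on round-half-up, which reproduces every printed figure except
the two truncation artifacts $14.48 and $125.88, documented in the methods
note.)

Three fixture designs ship in ``data/designs.yaml``: the VESPRE
infrastructure itself (n=1027), a prehospital coordinator cohort (n=787) and
a hypothetical coordinator-led cohort performing the same activities for the
same patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CATEGORIES",
    "LineItem",
    "CostDesign",
    "CostReport",
    "parse_amount",
    "format_cents",
    "total_cost",
    "per_patient_cost",
    "compare_designs",
    "load_designs",
    "builtin_designs",
]

CATEGORIES = ("project_management", "laboratory", "data_management")


def parse_amount(amount) -> int:
    """Parse a currency amount into integer cents, exactly."""
    cents = (Decimal(str(amount)) * 100).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    if Decimal(str(amount)) * 100 != cents:
        raise ValueError(f"amount {amount!r} has sub-cent precision")
    return int(cents)


def format_cents(cents: int) -> str:
    sign = "-" if cents < 0 else ""
    cents = abs(cents)
    return f"{sign}{cents // 100}.{cents % 100:02d}"


@dataclass(frozen=True)
class LineItem:
    label: str
    category: str
    amount_cents: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        if self.amount_cents < 0:
            raise ValueError(f"negative amount for line item {self.label!r}")


@dataclass(frozen=True)
class CostDesign:
    name: str
    n_patients: int
    items: tuple[LineItem, ...]

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.items:
            raise ValueError("a cost design needs at least one line item")


def total_cost(design: CostDesign) -> int:
    """Exact cent-level sum of all line items."""
    return sum(item.amount_cents for item in design.items)


def category_totals(design: CostDesign) -> dict[str, int]:
    out = {c: 0 for c in CATEGORIES}
    for item in design.items:
        out[item.category] += item.amount_cents
    return out


def per_patient_cost(design: CostDesign, cents: int | None = None) -> int:
    """Total (or a given subtotal) divided by n_patients, rounded half-up to
    whole cents."""
    if design.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cents = total_cost(design) if cents is None else cents
    q = (Decimal(cents) / Decimal(design.n_patients)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP)
    return int(q)


@dataclass
class CostReport:
    """Totals, per-category splits, per-patient values and pairwise ratios
    for a set of designs. All amounts are integer cents; ratios are the
    per-patient cost of each design over that of the cheapest design."""

    totals: dict[str, int]
    category: dict[str, dict[str, int]]
    per_patient: dict[str, int]
    per_patient_by_category: dict[str, dict[str, int]]
    ratio_to_cheapest: dict[str, float]

    def formatted(self) -> dict:
        return {
            "totals": {k: format_cents(v) for k, v in self.totals.items()},
            "category": {k: {c: format_cents(v) for c, v in d.items()}
                         for k, d in self.category.items()},
            "per_patient": {k: format_cents(v) for k, v in self.per_patient.items()},
            "per_patient_by_category": {
                k: {c: format_cents(v) for c, v in d.items()}
                for k, d in self.per_patient_by_category.items()},
            "ratio_to_cheapest": {k: round(v, 3) for k, v in self.ratio_to_cheapest.items()},
        }


def compare_designs(designs: list[CostDesign]) -> CostReport:
    """Build the comparison report across >=2 uniquely named designs."""
    if len(designs) < 2:
        raise ValueError("need at least two designs to compare")
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate design names")
    totals = {d.name: total_cost(d) for d in designs}
    category = {d.name: category_totals(d) for d in designs}
    for name in names:  # conservation, cent-exact
        assert sum(category[name].values()) == totals[name]
    per_patient = {d.name: per_patient_cost(d) for d in designs}
    per_patient_by_category = {
        d.name: {c: per_patient_cost(d, v) for c, v in category[d.name].items()}
        for d in designs}
    cheapest = min(per_patient.values())
    ratios = {k: v / cheapest if cheapest else float("inf")
              for k, v in per_patient.items()}
    return CostReport(totals, category, per_patient, per_patient_by_category, ratios)


def _designs_from_mapping(data: dict) -> list[CostDesign]:
    designs = []
    for d in data["designs"]:
        items = tuple(
            LineItem(label=i["label"], category=i["category"],
                     amount_cents=parse_amount(i["amount"]))
            for i in d["items"])
        designs.append(CostDesign(name=d["name"], n_patients=int(d["n_patients"]),
                                  items=items))
    return designs


def load_designs(path: str | Path) -> list[CostDesign]:
    """Load cost designs from a YAML file (see data/designs.yaml schema)."""
    with open(path) as fh:
        return _designs_from_mapping(yaml.safe_load(fh))


def builtin_designs() -> list[CostDesign]:
    """The three shipped study-design fixtures."""
    with resources.files("vespre").joinpath("data/designs.yaml").open() as fh:
        return _designs_from_mapping(yaml.safe_load(fh))
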
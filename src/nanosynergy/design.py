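"""Full-factorial drug-combination designs and plate layouts.

A screen is described by a list of drugs, each with an ordered ladder of
dose levels whose first entry is always 0 (drug absent).  The full factorial
over those ladders yields every condition of the screen: the all-zero
*control*, the *single*-drug conditions, and the *mixture* conditions.  A
four-drug, three-level screen therefore has 3**4 = 81 conditions: 1 control,
8 singles and 72 mixtures.

Condition ordering is deterministic — lexicographic over the drug list
order, then ascending level index — so identical inputs always produce
identical condition ids, which downstream stages and file formats rely on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import CapacityError, DesignError

__all__ = [
    "DrugSpec",
    "Condition",
    "ConditionSet",
    "DesignSummary",
    "PlateMap",
    "build_factorial_design",
    "summarize_design",
    "assign_plate_positions",
    "coefficient_of_variation",
    "miniaturization_factor",
]


@dataclass(frozen=True)
class DrugSpec:
    """A drug and its tested concentration ladder.

    ``dose_levels`` must be strictly increasing and start at exactly 0
    (the drug-absent level); concentrations are in ``units`` (default
    μg/ml).
    """

    name: str
    dose_levels: tuple[float, ...]
    units: str = "ug/ml"

    def __post_init__(self):
        levels = tuple(float(x) for x in self.dose_levels)
        object.__setattr__(self, "dose_levels", levels)
        if not self.name:
            raise DesignError("drug name must be non-empty")
        if len(levels) < 1:
            raise DesignError(f"{self.name}: at least one dose level required")
        if levels[0] != 0.0:
            raise DesignError(f"{self.name}: first dose level must be 0, got {levels[0]}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise DesignError(f"{self.name}: dose levels must be strictly increasing")


@dataclass(frozen=True)
class Condition:
    """One well of the factorial design: a dose per drug plus its role."""

    id: str
    doses: dict[str, float]
    role: str  # control | single | mixture

    @staticmethod
    def role_for(doses: dict[str, float]) -> str:
        n_active = sum(1 for d in doses.values() if d > 0)
        if n_active == 0:
            return "control"
        if n_active == 1:
            return "single"
        return "mixture"


@dataclass
class ConditionSet:
    """A complete factorial design: the drugs and every condition."""

    drugs: list[DrugSpec]
    conditions: list[Condition]

    @property
    def drug_names(self) -> list[str]:
        return [d.name for d in self.drugs]

    def condition(self, condition_id: str) -> Condition:
        try:
            return self._by_id[condition_id]
        except AttributeError:
            self._by_id = {c.id: c for c in self.conditions}
            return self._by_id[condition_id]

    def max_levels(self) -> dict[str, float]:
        """Per-drug maximum tested dose (used for [0,1] standardization)."""
        return {d.name: max(d.dose_levels) for d in self.drugs}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition_id": c.id, "role": c.role, **{n: c.doses[n] for n in self.drug_names}}
            for c in self.conditions
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionSet":
        drug_cols = [c for c in df.columns if c not in ("condition_id", "role")]
        drugs = [
            DrugSpec(name=c, dose_levels=tuple(sorted(df[c].unique())))
            for c in drug_cols
        ]
        conditions = [
            Condition(
                id=str(r["condition_id"]),
                doses={c: float(r[c]) for c in drug_cols},
                role=str(r["role"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(drugs=drugs, conditions=conditions)


@dataclass
class DesignSummary:
    n_control: int
    n_single: int
    n_mixture: int

    @property
    def total(self) -> int:
        return self.n_control + self.n_single + self.n_mixture


@dataclass
class PlateMap:
    """Row-major assignment of conditions onto a rows × cols grid."""

    rows: int
    cols: int
    assignment: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"row": r, "col": c, "condition_id": cid}
            for (r, c), cid in sorted(self.assignment.items())
        ]
        return pd.DataFrame(recs)


def build_factorial_design(drugs: list[DrugSpec]) -> ConditionSet:
    """Full Cartesian product of each drug's dose levels.

    Conditions are ordered lexicographically: drug-list order, ascending
    level index, with the last drug varying fastest.  Ids are ``C001``,
    ``C002``, ... zero-padded to the design size.
    """
    if not drugs:
        raise DesignError("at least one drug required")
    names = [d.name for d in drugs]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate drug names: {names}")

    level_lists = [d.dose_levels for d in drugs]
    n_total = math.prod(len(lv) for lv in level_lists)
    width = max(3, len(str(n_total)))
    conditions = []
    for i, combo in enumerate(itertools.product(*level_lists), start=1):
        doses = dict(zip(names, combo))
        conditions.append(
            Condition(id=f"C{i:0{width}d}", doses=doses, role=Condition.role_for(doses))
        )
    return ConditionSet(drugs=list(drugs), conditions=conditions)


def summarize_design(cs: ConditionSet) -> DesignSummary:
    """Count control / single / mixture conditions; always sums to the total."""
    counts = {"control": 0, "single": 0, "mixture": 0}
    for c in cs.conditions:
        counts[c.role] += 1
    return DesignSummary(counts["control"], counts["single"], counts["mixture"])


def assign_plate_positions(cs: ConditionSet, rows: int, cols: int) -> PlateMap:
    """Assign conditions row-major onto the first N cells of the grid."""
    n = len(cs.conditions)
    if n > rows * cols:
        raise CapacityError(f"{n} conditions exceed {rows}x{cols} = {rows * cols} positions")
    assignment = {}
    for i, cond in enumerate(cs.conditions):
        assignment[(i // cols, i % cols)] = cond.id
    return PlateMap(rows=rows, cols=cols, assignment=assignment)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent, 100·sd/mean — e.g. well-diameter uniformity QC."""
    if mean <= 0:
        raise DesignError("mean must be positive for a CV")
    if sd < 0:
        raise DesignError("sd must be nonnegative")
    return 100.0 * sd / mean


def miniaturization_factor(reference_volume: float, droplet_volume: float) -> float:
    """Volume ratio of a conventional assay to one droplet (same units)."""
    if reference_volume <= 0 or droplet_volume <= 0:
        raise DesignError("volumes must be positive")
    return reference_volume / droplet_volume
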
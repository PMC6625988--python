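"""In vitro → in vivo dose translation via the average dose-reduction index.

A combination that achieves its effect at doses DRI-fold below the
single-agent requirements can spread an MTD-anchored total over the course
of treatment:

    D_invivo = (MTD / DRI_ave) × n

per administration, where n is the number of administrations and DRI_ave is
the arithmetic mean of the per-drug dose-reduction indices — the mean runs
over the m drugs of the cocktail, e.g. (45.4 + 34.4 + 5.3)/3 = 28.4.
DRI_ave is kept at full precision inside the arithmetic; report values are
rounded half-away-from-zero to one decimal.  A translated dose must not
exceed the drug's own MTD upper bound (inclusive); the flag records this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import ConfigError

__all__ = [
    "MTDRange",
    "TranslatedRange",
    "TranslationResult",
    "average_dose_reduction_index",
    "translate_dose",
    "check_mtd_constraint",
    "translate_combination",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MTDRange:
    """Literature maximum-tolerated-dose range for one drug (mg/kg per assay)."""

    drug: str
    lower: float
    upper: float
    source: str = ""

    def __post_init__(self):
        if not 0 < self.lower <= self.upper:
            raise ConfigError(
                f"{self.drug}: need 0 < lower <= upper, got {self.lower}-{self.upper}"
            )


@dataclass
class TranslatedRange:
    drug: str
    lower_raw: float
    upper_raw: float
    lower: float  # rounded to 1 decimal
    upper: float
    within_mtd: bool


@dataclass
class TranslationResult:
    dri_ave: float
    n_administrations: int
    ranges: dict[str, TranslatedRange] = field(default_factory=dict)
    missing_mtd: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "dri_ave": self.dri_ave,
            "dri_ave_rounded": round_half_away(self.dri_ave, 1),
            "n_administrations": self.n_administrations,
            "per_drug": {
                d: {
                    "lower_raw": r.lower_raw,
                    "upper_raw": r.upper_raw,
                    "lower_mg_per_kg": r.lower,
                    "upper_mg_per_kg": r.upper,
                    "within_mtd": r.within_mtd,
                }
                for d, r in self.ranges.items()
            },
        }


def average_dose_reduction_index(dri_values) -> float:
    """Arithmetic mean of the per-drug DRIs (mean over the drugs supplied)."""
    vals = [float(v) for v in dri_values]
    if not vals:
        raise ValueError("at least one DRI value required")
    if any(v <= 0 for v in vals):
        raise ValueError(f"DRI values must be positive, got {vals}")
    return sum(vals) / len(vals)


def translate_dose(mtd: MTDRange, dri_ave: float, n_administrations: int) -> TranslatedRange:
    """Per-administration in vivo dose range (MTD/DRI_ave)·n for one drug."""
    if dri_ave <= 0:
        raise ValueError(f"dri_ave must be positive, got {dri_ave}")
    if n_administrations < 1:
        raise ValueError(f"n_administrations must be >= 1, got {n_administrations}")
    lo = mtd.lower / dri_ave * n_administrations
    hi = mtd.upper / dri_ave * n_administrations
    return TranslatedRange(
        drug=mtd.drug,
        lower_raw=lo,
        upper_raw=hi,
        lower=round_half_away(lo, 1),
        upper=round_half_away(hi, 1),
        within_mtd=check_mtd_constraint(hi, mtd),
    )


def check_mtd_constraint(dose: float, mtd: MTDRange) -> bool:
    """True iff the dose does not exceed the MTD upper bound (inclusive)."""
    return dose <= mtd.upper


def translate_combination(
    dris: dict[str, float],
    mtds: dict[str, MTDRange],
    n_administrations: int,
    on_missing: str = "error",
) -> TranslationResult:
    """Translate a whole cocktail: one DRI_ave over its drugs, then per-drug ranges.

    DRI_ave always averages over every drug of the cocktail.  A drug without
    an MTD range aborts with :class:`ConfigError` by default; with
    ``on_missing='skip'`` its dose range is omitted and the drug listed in
    ``missing_mtd`` (no MTD, no translatable range — the constraint cannot
    be checked).
    """
    missing = [d for d in dris if d not in mtds]
    if missing and on_missing != "skip":
        raise ConfigError(f"missing MTD range for drug(s): {missing}")
    dri_ave = average_dose_reduction_index(dris.values())
    ranges = {
        d: translate_dose(mtds[d], dri_ave, n_administrations) for d in dris if d in mtds
    }
    return TranslationResult(
        dri_ave=dri_ave,
        n_administrations=n_administrations,
        ranges=ranges,
        missing_mtd=missing,
    )
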
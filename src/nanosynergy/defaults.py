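"""Built-in demo screen: the four-drug prostate-cancer panel.

The default design is the 4-drug × 3-level (including zero) factorial used
throughout the examples and smoke runs: cisplatin (0/5/10 μg/ml),
paclitaxel (0/0.6/1.2), 5-fluorouracil (0/500/1000) and doxorubicin
(0/10/20) — 81 conditions.  Ground-truth median-effect parameters place
each drug's Dm at its published single-agent IC50 on PC-3 cells (62.9, 8.0,
8324.2 and 13.4 μg/ml) with sigmoidicity slopes in the usual 1.3–2 range;
at the tested doses 5-FU then has a near-null effect while doxorubicin is
the strongest effector, which is the structure the two-stage screening is
meant to resolve.  MTD ranges are the literature values for nude mice:
cisplatin 4.0–6.6, paclitaxel 15–36, doxorubicin 2–10 mg/kg per assay.
"""

from __future__ import annotations

from .design import ConditionSet, DrugSpec, build_factorial_design
from .simulate import TrueDrugParams
from .translation import MTDRange

CISPLATIN = "cisplatin"
PACLITAXEL = "paclitaxel"
FLUOROURACIL = "5-FU"
DOXORUBICIN = "doxorubicin"


def default_drugs() -> list[DrugSpec]:
    return [
        DrugSpec(CISPLATIN, (0.0, 5.0, 10.0)),
        DrugSpec(PACLITAXEL, (0.0, 0.6, 1.2)),
        DrugSpec(FLUOROURACIL, (0.0, 500.0, 1000.0)),
        DrugSpec(DOXORUBICIN, (0.0, 10.0, 20.0)),
    ]


def default_design() -> ConditionSet:
    return build_factorial_design(default_drugs())


def default_true_params() -> list[TrueDrugParams]:
    return [
        TrueDrugParams(CISPLATIN, m_slope=1.5, dm=62.9),
        TrueDrugParams(PACLITAXEL, m_slope=1.3, dm=8.0),
        TrueDrugParams(FLUOROURACIL, m_slope=2.0, dm=8324.2),
        TrueDrugParams(DOXORUBICIN, m_slope=1.8, dm=13.4),
    ]


def default_mtds() -> dict[str, MTDRange]:
    return {
        CISPLATIN: MTDRange(CISPLATIN, 4.0, 6.6, source="nude-mouse literature range"),
        PACLITAXEL: MTDRange(PACLITAXEL, 15.0, 36.0, source="nude-mouse literature range"),
        DOXORUBICIN: MTDRange(DOXORUBICIN, 2.0, 10.0, source="nude-mouse literature range"),
    }
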
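"""Translate an in vitro cocktail's dose-reduction indices into mouse dose ranges.

The combination screen showed that, at the optimum's effect level, cisplatin,
paclitaxel and doxorubicin could be dosed 45.4-, 34.4- and 5.3-fold below
their single-agent requirements.  Spreading each drug's maximum tolerated
dose (MTD) over n = 7 administrations, discounted by the average dose
reduction, gives the in vivo range per injection:

    D_invivo = (MTD / DRI_ave) x n
"""

import nanosynergy as ns
from nanosynergy.defaults import default_mtds

dris = {"cisplatin": 45.4, "paclitaxel": 34.4, "doxorubicin": 5.3}
result = ns.translate_combination(dris, default_mtds(), n_administrations=7)

print(f"DRI_ave = {result.dri_ave:.4f} (reported as {round(result.dri_ave, 1)})")
for drug, rng in result.ranges.items():
    flag = "within MTD" if rng.within_mtd else "EXCEEDS MTD"
    print(f"  {drug:12s} {rng.lower:5.1f}-{rng.upper:5.1f} mg/kg  [{flag}]")

# Each range is the per-injection dose window that exhausts the drug's MTD
# over the 7-injection course after the in vitro dose reduction; a range
# exceeding the MTD would be flagged and must not be administered.
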
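"""Build the 4-drug x 3-level factorial combination design and lay it out on a chip.

Four chemotherapeutics, each at zero plus two concentrations, give 3^4 = 81
conditions: one untreated control, eight single-drug conditions and 72
mixtures, mapped row-major onto a 9 x 9 array.
"""

import nanosynergy as ns
from nanosynergy.defaults import default_drugs

design = ns.build_factorial_design(default_drugs())
summary = ns.summarize_design(design)
print(f"{summary.total} conditions: {summary.n_control} control, "
      f"{summary.n_single} single-drug, {summary.n_mixture} mixtures")

plate = ns.assign_plate_positions(design, rows=9, cols=9)
first = design.conditions[1]
print(f"condition {first.id} ({first.role}): {first.doses}")
print(f"plate cell (0, 1) holds {plate.assignment[(0, 1)]}")

# The counts are the design arithmetic of the screen: every possible
# combination of the tested dose levels is present exactly once.
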
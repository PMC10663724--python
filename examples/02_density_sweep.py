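"""Sweep cell density and watch the selectivity window collapse.

Reproduces the locked-density (C_B = C_H) curve family: MIC and MHC both
rise linearly with density, so their ratio decays from MHC0/MIC0 = 5
toward its high-density plateau, for both measurement protocols.
"""

import numpy as np

from ampselect import SweepSpec, melittin_cell, sweep

spec = SweepSpec(
    preset=melittin_cell(n_trapped=5e7),
    vary="both",  # C_B = C_H locked together
    grid=np.logspace(3, 10, 8).tolist(),
)
table = sweep(spec)

wide = table.pivot(index="density", columns="protocol", values="selectivity")
print("MHC/MIC vs cell density (C_B = C_H), N_p = 5e7:\n")
print(wide.round(2).to_string())
print(
    "\nSelectivity decreases monotonically with density under either "
    "protocol;\nat high density the competitive protocol retains more of "
    "the window."
)
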
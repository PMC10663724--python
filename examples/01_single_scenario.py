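"""Compute MIC, MHC and selectivity for one bacteria + host-cell scenario.

A melittin-like peptide among 10^8 E. coli-like cells/mL and a trace of
red-blood-cell-like host cells, with 5e7 peptides trapped per dead cell.
The competitive numbers come from the actual mixture; the noncompetitive
ones combine two separate single-population measurements.
"""

from ampselect import melittin_cell, run_protocol

preset = melittin_cell(n_trapped=5e7)

for protocol in ("competitive", "noncompetitive"):
    res = run_protocol(preset, c_b=1e8, c_h=1e3, protocol=protocol)
    print(
        f"{protocol:>15}: MIC = {res.mic * 1e6:6.2f} uM, "
        f"MHC = {res.mhc * 1e6:6.2f} uM, MHC/MIC = {res.selectivity:6.2f}"
    )

print(
    "\nAt this bacterial density the MIC is ~9x its zero-density value "
    "(1 uM):\npeptide consumed by binding to and getting trapped in dead "
    "bacteria must be\npaid for before the free concentration reaches the "
    "rupture threshold."
)
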
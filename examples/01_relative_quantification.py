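"""Relative quantification: from raw Ct values to 2^-ddCt expression.

Builds a tiny cycle-threshold table for three genes and two samples,
normalizes against a housekeeping gene and a calibrator reference, and
prints the resulting relative expression values.
"""

import pandas as pd

from sigselect import CtTable, compute_relative_expression

ct = pd.DataFrame(
    {
        # sample "cal" is the calibrator; "pt1" a patient sample
        "cal": [25.0, 28.0, 31.0, 20.0],
        "pt1": [24.0, 30.0, 31.0, 20.0],
    },
    index=["NANOG", "SOX2", "HOXB4", "GUSB"],
)
table = CtTable(ct=ct, housekeeping_gene="GUSB", calibrator="cal")
em = compute_relative_expression(table)
print(em.values.round(3))
# Each value is 2^-ddCt: 1.0 means expression equal to the calibrator
# (after housekeeping normalization), 2.0 means one PCR cycle earlier,
# i.e. roughly twice the transcript abundance. Here NANOG is 2-fold up in
# pt1, SOX2 4-fold down, HOXB4 unchanged.
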
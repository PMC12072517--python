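"""Closed-form assay computations: ALT kinetics, clearance, ELISA, doses.

Every number here is a direct application of the printed assay formulas.
"""

import numpy as np

from oxprofile import (
    AltAssayConfig,
    Curve4PL,
    alt_activity,
    creatinine_clearance,
    diet_to_dose,
    evaluate_4pl,
    fit_4pl,
    fold_change,
    human_equivalent_dose,
    invert_4pl,
)
from oxprofile.assays import AbsorbanceSeries, ClearanceInputs

# --- kinetic ALT activity: NADH consumption at 340 nm ----------------------
series = AbsorbanceSeries(times=tuple(range(11)), a340=tuple(0.9 - 0.02 * t for t in range(11)))
alt = alt_activity(series)
print(f"ALT activity: {alt:.4f} U/mL  (1 U = 1 umol pyruvate/min at 37 C)")

# --- creatinine clearance ---------------------------------------------------
cl = creatinine_clearance(ClearanceInputs(urine_creatinine=15.0, urine_volume=1440.0,
                                          plasma_creatinine=0.5))
print(f"Creatinine clearance: {cl:.1f} uL/min over a 24 h collection")

# --- 4PL immunoassay calibration -------------------------------------------
truth = Curve4PL(a=0.05, b=1.3, c=120.0, d=2.1)
doses = np.geomspace(5, 3000, 9)
curve = fit_4pl(doses, evaluate_4pl(truth, doses))
unknown_abs = 1.0
conc = invert_4pl(curve, unknown_abs)
print(f"4PL fit: EC50 = {curve.c:.1f}; a sample reading {unknown_abs} maps to "
      f"{conc:.1f} concentration units")

# --- fold changes and dose conversions from published group means -----------
fc = fold_change(0.3, 0.1)
print(f"Brain 4-HNE, disease vs reference: {fc.fold:.1f}-fold {fc.direction}")
daily = diet_to_dose(600.0, 10 / 3, 20.0)
print(f"600 mg/kg-diet at 3.3 g/day for a 20 g mouse = {daily:.0f} mg/kg/day;"
      f" human equivalent {human_equivalent_dose(daily):.1f} mg/kg/day")
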
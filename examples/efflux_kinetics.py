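"""Fit first-order leakage rate constants to simulated capillary traces.

Seven noisy luminal-fluorescence traces per condition are generated at the
published rate presets (WT 0.08, disease 0.26, treated 0.18, mannitol control
0.58 min^-1) and refitted; group means should recover the presets, and the
disease/WT ratio reproduces the published ~3.2-fold leakage increase.
"""

import numpy as np

from oxprofile import TRACE_PRESETS, TraceModel, fit_first_order, generate_trace, group_rate_table

rng = np.random.default_rng(0)
fits = []
for group, k_true in TRACE_PRESETS.items():
    model = TraceModel(k_true=k_true, noise_sd=5.0)
    for ci in range(7):
        trace = generate_trace(model, seed=int(rng.integers(2**31)),
                               capillary_id=f"{group}-{ci}", group=group)
        fits.append(fit_first_order(trace, plateau_mode="fixed_zero"))

table = group_rate_table(fits, reference="WT")
print(table.round(4).to_string())
print("\nk_mean is the fitted first-order efflux rate (min^-1), averaged over"
      "\n7 capillaries; k_ratio compares each condition with the WT reference.")
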
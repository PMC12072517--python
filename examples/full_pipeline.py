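"""Run the whole study pipeline end to end and render the report.

Simulation -> replicate aggregation -> per-endpoint statistics -> efflux
kinetics -> Y-maze scoring -> correlation profiling, all under one seed; the
markdown report mirrors the study's summary tables.
"""

from oxprofile import RunConfig, render_report, run_pipeline

report = run_pipeline(RunConfig(seed=1))
print(render_report(report, "markdown"))
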
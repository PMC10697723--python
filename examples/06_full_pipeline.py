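"""Run every stage end-to-end and render the Markdown report.

Writes traces, masks, fits, rate tables, ensemble fluxes and a manifest into
./pipeline_demo/, then summarizes them in pipeline_demo/report.md. Re-running
with the same seed reproduces all stochastic outputs bit-for-bit.
"""
from vesselflux import demo_config, make_report, run_pipeline

out = run_pipeline(demo_config(seed=7), "pipeline_demo")
report = make_report(out)
print(f"outputs in {out}/ :")
for path in sorted(out.iterdir()):
    print(f"  {path.name}")
print()
print(report.read_text())
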
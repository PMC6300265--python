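"""Run the whole screening study end to end on a reduced population.

One call executes every stage — simulation, index scoring, training-set
construction, feature selection, model fitting, validation and bootstrap,
population screening, combination table, TAN comparison — and writes all
artifacts plus a manifest into the output directory.
"""

import json

from mps2screen import PipelineConfig, run_full_study

config = PipelineConfig(
    seed=7,
    out_dir="scratch/example_run",
    n_total=50_000,       # reduced from the ~5e5 full-scale default
    bootstrap_B=200,      # reduced from 1000 for a quick demonstration
)
manifest = run_full_study(config)

print(json.dumps(manifest.summary, indent=1, default=str))
print("artifacts:")
for key, path in sorted(manifest.outputs.items()):
    print(f"  {key}: {path}")
# summary["screen_recall_injected"] is the fraction of the injected positive
# patients the screen recovered; prevalence_percent is the flagged share.
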
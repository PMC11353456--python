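"""Run every stage end to end on a simulated dataset and write TSV reports.

The same thing is available from the shell as:
    riverpopgen pipeline --simulate-seed 1 --out-dir riverpopgen_out
"""

from riverpopgen import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/example_pipeline",
    master_seed=1,
    simulation=SimulationConfig(seed=1, history=[(300.0, 0.01), (8000.0, 1.0)]),
    perms=500,
    coalescent_reps=500,
    gw_reps=1000,
)
tables = run_pipeline(cfg)
for name, df in sorted(tables.items()):
    print(f"{name}: {len(df)} rows")
print(f"\nreports written to {cfg.out_dir}/")
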
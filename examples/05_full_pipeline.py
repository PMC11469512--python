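"""Run the whole analysis end to end into a results directory.

simulate -> cross-correlogram -> Kalman fits -> population statistics,
with every stage's table written as CSV/JSON plus a manifest for
reproducibility.  Identical config + seed gives byte-identical outputs.
"""

from headtrack import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_participants=6, master_seed=1, bootstrap_n_reps=100,
                     out_dir="scratch/pipeline_demo")
report = run_pipeline(cfg)

print(f"outputs in {report['out_dir']}:")
for name in report["manifest"]["outputs"]:
    print(f"  {name}")

lag = report["stats"]["summary_lmm"]["lag_of_least_error_s"]
print(f"\nlag model intercept (SLOW-SPARSE mean): {lag['intercept']:.2f} s")
for term, c in lag["contrasts"].items():
    print(f"  {term}: {c['estimate']:+.3f} s")

fits = report["kalman_fits"]
print("\nmean fitted sensory-noise SD (deg) per condition:")
print(fits.groupby(["speed", "density"]).R_hat_sd_deg.mean().round(1))
# FAST/DENSE cells show shorter lags and smaller fitted sensory noise than
# SLOW/SPARSE, mirroring the ground truth the simulator injected.
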
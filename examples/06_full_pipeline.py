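"""End-to-end run: cohort -> behaviour -> physiology -> model -> statistics.

Uses a reduced cohort so the demo finishes in about a minute; the default
configuration reproduces the full 19-participant study conditions.
"""

from histbias.pipeline import RunConfig, run_all
from histbias.synth import TaskDesign

config = RunConfig(
    seed=3,
    n_participants=6,
    design=TaskDesign(n_blocks_per_session=2),
    ddm_starts=2,
    n_perm=2000,
    n_boot=2000,
    out_dir="pipeline_output",
)
report = run_all(config)

print("stimulus repetition probability (by design ~0.5):",
      round(report["stimulus_repetition_probability"], 3))
s = report["stats"]
print("drug effect on abs history bias: t = "
      f"{s['abs_bias_paired_t']['statistic']:.2f}, p = {s['abs_bias_paired_t']['p']:.3f}")
print("drug effect on drift-bias history shift: t = "
      f"{s['vbias_shift_paired_t']['statistic']:.2f}, p = {s['vbias_shift_paired_t']['p']:.3f}")
print("drug effect on starting-point history shift: t = "
      f"{s['z_shift_paired_t']['statistic']:.2f}, p = {s['z_shift_paired_t']['p']:.3f}")
lmm = s["pupil_bin_lmm_repeat"]
print("pupil-bin model selected:", lmm["selected"], "beta1 =", round(lmm["beta1"], 4))
print("\nfull report written to pipeline_output/report.json")
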
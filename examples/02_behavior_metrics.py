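"""Trial exclusions, choice repetition probability and signal-detection metrics.

P(repeat) is the side-bias-free mean of P(left | prev left) and
P(right | prev right); values above 0.5 mean the observer tends to repeat
its previous choice even though stimuli are uncorrelated across trials.
"""

from histbias import behavior
from histbias.synth import TaskDesign, generate_cohort

cohort = generate_cohort(4, design=TaskDesign(n_blocks_per_session=2), seed=7)

filtered, report = behavior.apply_exclusions(cohort.trials)
print("exclusion report:", report)

summary = behavior.summarize(cohort.trials)
print("\nper participant x drug condition:")
print(summary[["participant_id", "drug", "p_repeat", "abs_bias",
               "accuracy", "mean_rt", "dprime", "criterion"]].round(3))

# the drug shrinks the history bias toward indifference (abs_bias -> 0)
print("\ngroup abs_bias by drug (mean +/- sem):")
print(behavior.group_summary(summary, "abs_bias").round(4))
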
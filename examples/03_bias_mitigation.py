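"""Apply the post-processing mitigations and compare error-rate gaps.

Runs the audit with directed balanced probability adjustment (BPA),
equalised-odds scaling, and reweighting, then prints the combined
|TPR gap| + |FPR gap| before and after each.
"""

from fairdx import CohortSpec, RunConfig, run_audit

config = RunConfig(
    cohort=CohortSpec(
        n_subjects=10_000,
        outcome_rate_by_group={1: 0.42, 2: 0.58},
        seed=0,
    ),
    mitigations=("reweight", "bpa", "eq_odds"),
    seed=0,
)
bundle = run_audit(config)

base = bundle.baseline
print(f"baseline:  TPR gap {base.delta_tpr:.3f}  FPR gap {base.delta_fpr:.3f}  "
      f"combined {base.delta_tpr + base.delta_fpr:.3f}")
for name, rep in bundle.mitigated.items():
    print(f"{name:9s}  TPR gap {rep.delta_tpr:.3f}  FPR gap {rep.delta_fpr:.3f}  "
          f"combined {rep.delta_tpr + rep.delta_fpr:.3f}  "
          f"(bal. accuracy {rep.balanced_accuracy:.3f})")

# Each mitigation shrinks the combined error-rate gap relative to baseline;
# the balanced accuracy column shows the fairness/performance trade-off.
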
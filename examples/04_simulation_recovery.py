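"""How well does the index recover a planted credibility state?

Generates cohorts at three non-credible effect sizes with common
random numbers and reports the index's AUC against the latent truth —
the generator's own validity check.
"""

from erdodi import SimulationParams, recovery_report, simulate_cohort

for shift in (0.5, 1.0, 2.0):
    params = SimulationParams(n=3000, noncredible_shift=shift, seed=5)
    report = recovery_report(simulate_cohort(params))
    auc = report["auc_vs_truth"]
    print(
        f"shift {shift:.1f} SD: AUC vs truth = {auc.auc:.3f} "
        f"[{auc.ci_low:.3f}, {auc.ci_high:.3f}], "
        f"sens/spec at >= {report['fail_cutoff']} = "
        f"{report['sensitivity_vs_truth']:.2f}/{report['specificity_vs_truth']:.2f}"
    )

print(
    "\nAUC grows with the planted effect size; at a 2 SD shift the\n"
    "summed index separates non-credible from credible responders\n"
    "almost perfectly, despite each single indicator being noisy."
)
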
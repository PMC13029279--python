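"""Case-level logistic regression of seriousness on polypharmacy burden.

One row per deduplicated case; the per-active odds ratio quantifies how each
additional co-reported drug raises the odds of a regulatory-serious outcome,
and compounding shows the cumulative effect over realistic regimen
differences.
"""

from vigimech import SynthConfig, generate_cohort
from vigimech.seriousness import compound_or, fit_seriousness, sensitivity_restrict

cases, truth = generate_cohort(SynthConfig(n_cases=1938, seed=1))

fit = fit_seriousness(cases)
print(f"per-active OR: {fit.or_per_active:.3f} "
      f"(95% CI {fit.ci_lo:.3f}-{fit.ci_hi:.3f}, p={fit.p:.2e}, n={fit.n})")
print(f"true generator OR: {truth.true_per_active_or:.3f}")

robust = fit_seriousness(cases, robust_se=True)
print(f"HC1-robust CI:  {robust.ci_lo:.3f}-{robust.ci_hi:.3f}")

subset, restricted, retained = sensitivity_restrict(cases)
print(f"restricted to female, non-follow-up, non-literature: "
      f"{len(subset)} cases ({retained:.1%}), OR {restricted.or_per_active:.3f}")

for k in (5, 10):
    c = compound_or(1.03, k)
    print(f"OR 1.03 compounded over {k:2d} drugs -> {c.rounded:.2f}")

# With a 3% per-drug increase, five extra co-administered actives raise the
# odds of a serious report by ~16% and ten by ~34%.
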
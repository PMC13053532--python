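"""A-priori sample-size design and its Monte-Carlo verification.

For a two-sided two-sample t test at alpha = 0.05 targeting 80% power to
detect a large standardized volume difference (Cohen's d = 0.90), the
noncentral-t search gives the minimum group size; simulation confirms the
design is realized.
"""

from panotex import PowerSpec, empirical_power, power_two_sample_t, sample_size_two_group_t

spec = PowerSpec(effect_d=0.90, alpha=0.05, target_power=0.80)
n = sample_size_two_group_t(spec)
print(f"designed sample size: {n} per group ({2 * n} total)")
print(f"exact power at n={n}: {power_two_sample_t(spec.effect_d, n):.4f}")
print(f"exact power at n={n - 1}: {power_two_sample_t(spec.effect_d, n - 1):.4f}"
      " (below target, hence the minimum)")

rate = empirical_power(spec.effect_d, n, alpha=spec.alpha, reps=10_000, seed=1)
print(f"Monte-Carlo rejection rate (10,000 reps): {rate:.4f}")
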
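"""Sample size for a treatment trial using fat fraction as the endpoint.

A natural-history 6-month change of 4% (SD 3%) compared against an
expected 0.5% change under effective treatment, at 90% power and a
two-sided 5% significance level, requires 16 subjects per arm -- far
fewer than function-based endpoints typically need.
"""

from musclefat import PowerSpec, sample_size_two_group

spec = PowerSpec(delta_control=4.0, delta_treated=0.5, sd=3.0,
                 power=0.90, alpha=0.05, two_sided=True)
n = sample_size_two_group(spec)
print(f"observed change (natural history): {spec.delta_control}% +/- {spec.sd}%")
print(f"expected change (treated arm)    : {spec.delta_treated}%")
print(f"power {spec.power:.0%}, two-sided alpha {spec.alpha}")
print(f"-> minimum {n} subjects per group")

print()
print("sensitivity to the treated-arm effect:")
for treated in (0.0, 0.5, 1.0, 2.0):
    s = PowerSpec(delta_control=4.0, delta_treated=treated, sd=3.0)
    print(f"  treated change {treated:.1f}% -> n = {sample_size_two_group(s)} per group")
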
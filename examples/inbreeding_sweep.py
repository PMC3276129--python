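"""Sweep the inbreeding coefficient of a selfing population with pure imprinting.

With k1 = -k2 the heterozygote mean sits midway between the homozygotes (no
dominance), so the total variance rises *linearly* in f; the sex-specific
additive-by-dominance covariances are nonzero under inbreeding and of
opposite sign whenever imprinting acts.
"""

from imprintqg import ImprintingLocus, PopulationState, inbred_variance_components

locus = ImprintingLocus(a=0.5, k1=0.5, k2=-0.5)

print(f"locus: a={locus.a}, k1={locus.k1}, k2={locus.k2}; p1=0.5 (selfing sweep)")
print(f"{'f':>5} {'s2_G':>8} {'s2_A_f':>8} {'s2_A_m':>8} {'s2_D_f':>8} {'s2_D_m':>8} {'s_AD_f':>8} {'s_AD_m':>8}")
for f in [0.0, 0.25, 0.5, 0.75, 1.0]:
    c = inbred_variance_components(locus, PopulationState(p1=0.5, f=f))
    print(
        f"{f:5.2f} {c.sigma2_G:8.4f} {c.sigma2_A_f:8.4f} {c.sigma2_A_m:8.4f} "
        f"{c.sigma2_D_f:8.4f} {c.sigma2_D_m:8.4f} {c.sigma_AD_f:8.4f} {c.sigma_AD_m:8.4f}"
    )
print(
    "\nThe total climbs linearly 0.16 -> 0.25 (0.20 at f=1/2, 0.18 at f=1/4,"
    " 0.23 at f=3/4): imprinting inflates a selfer's variance, and the effect"
    " fades as f -> 1 where only homozygotes remain."
)
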
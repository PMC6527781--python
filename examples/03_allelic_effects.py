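"""Decompose a SNP's fitted genotypic values into allelic effects.

Given class means (g11, g12, g22) and genotype frequencies, the
decomposition yields the allelic means, allelic effects, the average effect
of gene substitution alpha, the dominance effect delta, and the qualitative
labels (allelic pattern, dominance mode).
"""

import numpy as np

import aglsgwas as ag

# a SNP under Hardy-Weinberg equilibrium with allele-1 frequency 0.6
p1 = 0.6
freq = ag.SnpFrequencies(10_000, p1 * p1, 2 * p1 * (1 - p1), (1 - p1) ** 2)
g = np.array([10.0, 8.0, 2.0])  # trait units, e.g. kg

eff = ag.allelic_decomposition(g, freq, mu_all=7.0)
delta = ag.dominance_effect(g)
print(f"allelic means        mu1 = {eff.mu1:.2f}, mu2 = {eff.mu2:.2f}  (mu = {eff.mu:.2f})")
print(f"allelic effects      a1 = {eff.a1:+.2f}, a2 = {eff.a2:+.2f}  (p1*a1 + p2*a2 = {p1*eff.a1 + (1-p1)*eff.a2:.1e})")
print(f"gene substitution    alpha = {eff.alpha:+.2f}  (= mu1 - mu2 = s_a . g)")
print(f"comparable effects   a1* = {eff.a1_comparable:+.2f}, a2* = {eff.a2_comparable:+.2f}  (anchored at mu_all = 7.0)")
print(f"dominance            delta = {delta:+.2f}, mode = {ag.classify_dominance_mode(g, delta)}")
print(f"allelic pattern      {ag.classify_allelic_pattern(eff.a1_comparable, eff.a2_comparable)}")
# alpha is the distance between the two allelic means: the additive effect
# the t-test targets.  The comparable effects re-anchor each allele at the
# across-SNP mean genotypic value so alleles can be compared across SNPs.
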
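"""Unpaired-nucleotide-frequency profile and its link to substitution rates.

Computes the per-position UNF across the 5' matures of a generated cohort,
then builds a substitution-rate table in which structurally constrained
(mostly paired) positions mutate slowly and loop-rich positions mutate
fast — the relation observed for structural RNAs — and shows that the
UNF/rate rank correlation is positive and stepwise: strong between the two
groups, absent within them.
"""

import numpy as np

from mirfoot import rank_correlation, correlate_unf_substitution, unf_profile
from mirfoot.simulate import CohortSpec, generate_hairpin_set

records, _ = generate_hairpin_set(
    CohortSpec(n=500, internal_loop_prob=0.6, seed=3)
)
profile = unf_profile(records, "five_prime", flank_width=3)
frame = profile.to_frame()
print(frame.to_string(index=False, max_rows=14))

# rates follow structure: two groups split at the median UNF, jitter within
rng = np.random.default_rng(12)
positions = [p for p in profile.positions() if p >= 1]
median_unf = float(np.median([profile.frequency[p] for p in positions]))
low_group = [p for p in positions if profile.frequency[p] <= median_unf]
rates = {
    p: float(rng.uniform(0.7, 1.0) if p in low_group else rng.uniform(1.5, 2.1))
    for p in positions
}

overall, _ = correlate_unf_substitution(profile, rates)
within = rank_correlation(
    [profile.frequency[p] for p in low_group], [rates[p] for p in low_group]
)
print(f"\noverall rho(UNF, rate) = {overall.rho:.3f}  (p = {overall.p_value:.2g})")
print(f"within the paired group rho = {within.rho:.3f}  (p = {within.p_value:.2g})")
print()
print("UNF(p) is the fraction of hairpins whose nucleotide at mature")
print("position p is single-stranded (denominator = hairpins possessing p).")
print("The overall correlation is strong while the within-group one is not:")
print("the dependence is stepwise, driven by the paired/unpaired division,")
print("not linear in the rate.")
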
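"""Overhang statistics: joint distribution, independence null, coherence.

Generates two cohorts of synthetic pre-miRNA hairpins — one with
independently drawn Drosha-side and Dicer-side overhang lengths, one with a
20% perfectly coherent component — computes the overhangs from structure,
and contrasts the fitted independence model on both.
"""

import numpy as np

from mirfoot import (
    compute_overhangs,
    fit_independence_model,
    joint_overhang_table,
    restrict_near_canonical,
)
from mirfoot.overhang_stats import overhang_correlation
from mirfoot.simulate import (
    CohortSpec,
    coherent_mixture,
    generate_hairpin_set,
    independent_joint,
)

for label, joint in [
    ("independent", independent_joint(0.2, 0.1)),
    ("20% coherent", coherent_mixture(0.2, 0.1, 0.2)),
]:
    records, _ = generate_hairpin_set(
        CohortSpec(n=4000, overhang_joint=joint, seed=42)
    )
    pairs = [compute_overhangs(r) for r in records]
    near, fraction = restrict_near_canonical(pairs)
    fit = fit_independence_model(joint_overhang_table(near))
    corr = overhang_correlation(near)
    print(f"--- {label} cohort (n={len(pairs)}) ---")
    print(f"near-canonical fraction: {fraction:.3f}")
    print(f"fitted marginal: p_short={fit.p_short:.3f} "
          f"p_canonical={fit.p_canonical:.3f} p_long={fit.p_long:.3f}")
    print("obs/exp table (rows basal 1,2,3 nt; cols apical 1,2,3 nt):")
    print(np.round(fit.obs_over_exp, 2))
    print(f"Spearman rho(basal, apical) = {corr.rho:.3f}  p = {corr.p_value:.2g}")
    print()

print("The coherent cohort shows the same marginals but enriched 1nt/1nt and")
print("3nt/3nt cells (obs/exp > 1) and a positive rank correlation: the")
print("signature of coupled cleavage-site imprecision.")
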
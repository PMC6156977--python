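"""Per-CpG MZ twin correlations before and after cell-composition adjustment.

Twin resemblance at a CpG mixes a genuine familial component with shared
cell composition.  Residualizing on the estimated cell fractions removes
the second source; the drop in the mean correlation quantifies it.
"""

from twinmeth import SimConfig, generate_twin_cohort
from twinmeth.twin import compare_probe_sets, twin_correlations, within_pair_differences
from twinmeth.workflows import adjust_for_cell_composition, estimate_cell_fractions

cohort = generate_twin_cohort(
    SimConfig(n_pairs=60, n_cpgs=500, n_snps=50, n_mqtl_cpgs=0,
              familial_corr=0.21, seed=5)
)
before = twin_correlations(cohort.beta.values, cohort.sheet)
fractions = estimate_cell_fractions(cohort.beta, cohort.reference)
resid = adjust_for_cell_composition(cohort.beta, fractions)
after = twin_correlations(resid, cohort.sheet)

print(f"mean twin r before cell adjustment: {before['r'].mean():.3f}")
print(f"mean twin r after  cell adjustment: {after['r'].mean():.3f}")

cpgs = after.index
res = compare_probe_sets(after, cpgs[: len(cpgs) // 2], cpgs[len(cpgs) // 2 :])
print(f"probe-set rank test (random halves): p = {res.p_value:.3f}")

diffs = within_pair_differences(cohort.beta, cohort.sheet, threshold=0.3)
counts = [d.n_large for d in diffs.values()]
print(f"large within-pair differences (|Δβ| > 0.3) per pair: "
      f"median {int(sorted(counts)[len(counts)//2])}, max {max(counts)}")
# The adjusted mean reflects the familial component alone (generator
# value 0.21, slightly attenuated by fraction-estimation error and
# boundary clipping); the unadjusted value sits higher because co-twins
# also share cell composition.  Random probe-set halves are correctly
# indistinct, and at the default noise level no within-pair difference
# reaches the 0.3 threshold — large discordances are rare events.
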
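"""Genome-wide profile similarity between samples, by pair category.

Raw β correlations are inflated (even unrelated people exceed r = 0.98
because most CpGs sit near 0 or 1); per-CpG standardized correlations
separate replicates, MZ twins and unrelated pairs.
"""

from twinmeth import SimConfig, generate_twin_cohort
from twinmeth.similarity import (
    build_pair_catalog,
    pair_correlations,
    standardize_betas,
    summarize_by_category,
)

cohort = generate_twin_cohort(
    SimConfig(n_pairs=40, n_cpgs=600, n_snps=50, n_mqtl_cpgs=0,
              n_replicate_pairs=10, seed=4)
)
z = standardize_betas(cohort.beta)
catalog = build_pair_catalog(cohort.sheet)
table = pair_correlations(cohort.beta, z, catalog, min_shared=300)
summary = summarize_by_category(table)

for cat in ("replicate", "mz_twin", "unrelated"):
    raw = summary.loc[cat, ("pearson_r", "mean")]
    std = summary.loc[cat, ("pearson_r_standardized", "mean")]
    n = summary.loc[cat, "n_pairs"].iloc[0]
    print(f"{cat:>10}: raw r = {raw:.4f}   standardized r = {std:+.4f}   ({n} pairs)")
# Raw correlations crowd near 1 for every category; the standardized
# metric orders the categories by actual relatedness, with unrelated
# pairs near zero.
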
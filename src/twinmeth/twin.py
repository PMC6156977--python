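"""Twin-resemblance analyses of per-CpG methylation.

Covers covariate residualization (removing cell-composition and other
nuisance signal CpG by CpG), per-CpG Pearson correlations between
co-twins across monozygotic pairs, rank-sum comparison of correlation
distributions between probe sets, counting of large within-pair β
differences (|Δβ| > 0.3), and the reproducibility of those differences
across technical replicates.

The twin correlation is "single entry": twin 1 and twin 2 are taken from
the sample sheet's role column, giving one observation per pair.  Because
that assignment is arbitrary, a double-entry variant (each pair entered
in both orders) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import BetaMatrix, StructuralError, twin_columns

__all__ = [
    "CollinearityError",
    "residualize",
    "twin_correlations",
    "ProbeSetComparison",
    "compare_probe_sets",
    "WithinPairDiff",
    "within_pair_differences",
    "pair_difference",
    "replicate_pair_differences",
    "ReplicateOverlap",
    "replicate_diff_reproducibility",
    "label_cpgs_by_bed",
]


class CollinearityError(ValueError):
    """The covariate design is rank-deficient."""


def _as_frame(values) -> pd.DataFrame:
    return values.values if isinstance(values, BetaMatrix) else values


def residualize(values, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG OLS residuals of β on covariates (with intercept).

    ``values`` is a CpG × sample frame (or `BetaMatrix`); ``covariates`` a
    sample × covariate frame, complete for every analyzed sample.  Samples
    missing β at a CpG are excluded from that CpG's fit and stay missing
    in the output; CpGs with fewer than (n_covariates + 2) usable samples
    are returned all-missing.
    """
    Y = _as_frame(values)
    missing_cov = pd.Index(Y.columns).difference(covariates.index)
    if len(missing_cov):
        raise StructuralError(
            f"covariates missing for samples {missing_cov[:3].tolist()}"
        )
    C = covariates.loc[Y.columns].to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValueError("covariates must be complete (no missing values)")
    X = np.column_stack([np.ones(len(C)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate design is rank-deficient (collinear columns)")
    mat = Y.to_numpy(dtype=float)
    out = np.full_like(mat, np.nan)
    p = X.shape[1]

    complete = np.isfinite(mat).all(axis=1)
    if complete.any():
        sub = mat[complete]
        coef, *_ = np.linalg.lstsq(X, sub.T, rcond=None)
        out[complete] = sub - (X @ coef).T
    for i in np.nonzero(~complete)[0]:
        row = mat[i]
        mask = np.isfinite(row)
        if mask.sum() < p + 1:  # fewer than n_covariates + 2 usable samples
            continue
        Xi = X[mask]
        if np.linalg.matrix_rank(Xi) < p:
            raise CollinearityError(
                f"covariates collinear over the non-missing samples of CpG "
                f"{Y.index[i]}"
            )
        coef, *_ = np.linalg.lstsq(Xi, row[mask], rcond=None)
        res = row[mask] - Xi @ coef
        out[i, mask] = res
    return pd.DataFrame(out, index=Y.index, columns=Y.columns)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray, min_n: int = 3):
    """Nan-aware Pearson r per row of two aligned matrices."""
    mask = np.isfinite(A) & np.isfinite(B)
    n = mask.sum(axis=1)
    Am = np.where(mask, A, 0.0)
    Bm = np.where(mask, B, 0.0)
    sx = Am.sum(axis=1)
    sy = Bm.sum(axis=1)
    sxx = (Am**2).sum(axis=1)
    syy = (Bm**2).sum(axis=1)
    sxy = (Am * Bm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        r = np.where((n >= min_n) & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return r, n


def twin_correlations(
    values, sheet: pd.DataFrame, double_entry: bool = False, min_pairs: int = 3
) -> pd.DataFrame:
    """Per-CpG Pearson correlation between co-twins across MZ pairs.

    One observation per complete pair (twin 1 vs twin 2 per the sample
    sheet roles, first measurement of each individual); pairs with either
    co-twin missing at a CpG are excluded for that CpG.  CpGs with fewer
    than ``min_pairs`` usable pairs get a missing r and a reason code.

    With ``double_entry=True`` each pair contributes both orderings,
    making the estimate invariant to the arbitrary twin labeling (a
    correlation akin to an intraclass correlation).
    """
    frame = _as_frame(values)
    pairs, t1, t2 = twin_columns(sheet)
    if not pairs:
        raise StructuralError("no complete twin pairs in the sample sheet")
    A = frame[t1].to_numpy(dtype=float)
    B = frame[t2].to_numpy(dtype=float)
    if double_entry:
        A, B = np.hstack([A, B]), np.hstack([B, A])
    r, n = _rowwise_pearson(A, B, min_n=min_pairs)
    n_pairs_used = n if not double_entry else n // 2
    out = pd.DataFrame(
        {
            "r": r,
            "n_pairs_used": n_pairs_used,
            "reason": np.where(
                n >= min_pairs,
                np.where(np.isfinite(r), "", "zero_variance"),
                "too_few_pairs",
            ),
        },
        index=frame.index,
    )
    return out


@dataclass
class ProbeSetComparison:
    """Mann–Whitney comparison of twin-correlation distributions."""

    u_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def compare_probe_sets(table: pd.DataFrame, set_a, set_b) -> ProbeSetComparison:
    """Two-sided Mann–Whitney rank-sum test of per-CpG twin correlations
    between two disjoint probe sets (each with ≥ 10 usable CpGs)."""
    set_a, set_b = pd.Index(set_a), pd.Index(set_b)
    overlap = set_a.intersection(set_b)
    if len(overlap):
        raise ValueError(f"probe sets overlap ({len(overlap)} CpGs in common)")
    ra = table.loc[table.index.intersection(set_a), "r"].dropna()
    rb = table.loc[table.index.intersection(set_b), "r"].dropna()
    if len(ra) < 10 or len(rb) < 10:
        raise ValueError("each probe set needs at least 10 CpGs with a correlation")
    res = mannwhitneyu(ra, rb, alternative="two-sided")
    return ProbeSetComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(ra.mean()),
        mean_b=float(rb.mean()),
        n_a=len(ra),
        n_b=len(rb),
    )


@dataclass
class WithinPairDiff:
    """Co-twin methylation difference for one pair of samples.

    ``delta`` = sample_a − sample_b per CpG (missing where either is);
    ``exceed`` flags |Δβ| strictly above the threshold; ``n_large`` counts
    the flags.
    """

    pair_id: str
    sample_a: str
    sample_b: str
    threshold: float
    delta: pd.Series
    exceed: pd.Series = field(repr=False, default=None)
    n_large: int = 0

    def __post_init__(self) -> None:
        if self.exceed is None:
            self.exceed = self.delta.abs() > self.threshold
            self.exceed = self.exceed.fillna(False).astype(bool)
            self.n_large = int(self.exceed.sum())


def pair_difference(values, sample_a: str, sample_b: str, threshold: float = 0.3,
                    pair_id: str = "") -> WithinPairDiff:
    """Δβ between two specific sample columns (strict |Δβ| > threshold)."""
    frame = _as_frame(values)
    delta = frame[sample_a] - frame[sample_b]
    return WithinPairDiff(
        pair_id=pair_id or f"{sample_a}-{sample_b}",
        sample_a=sample_a,
        sample_b=sample_b,
        threshold=threshold,
        delta=delta,
    )


def within_pair_differences(values, sheet: pd.DataFrame, threshold: float = 0.3) -> dict:
    """Per-pair Δβ = twin1 − twin2 with strict exceedance counts.

    Uses the first measurement of each co-twin; the exceedance rule is a
    strict inequality, so a difference of exactly the threshold does not
    count.
    """
    frame = _as_frame(values)
    pairs, t1, t2 = twin_columns(sheet)
    return {
        pair: pair_difference(frame, a, b, threshold, pair_id=pair)
        for pair, a, b in zip(pairs, t1, t2)
    }


def replicate_pair_differences(
    values, sheet: pd.DataFrame, pair_id: str, threshold: float = 0.3
) -> list:
    """All replicate-combination difference measures for one twin pair.

    With two measurements per co-twin this yields the four measures
    d(a, b) = twin1-replicate-a − twin2-replicate-b.
    """
    frame = _as_frame(values)
    rows = sheet[sheet["pair_id"] == pair_id]
    reps1 = rows[rows["role"] == 1].sort_values("replicate")["sample_id"].tolist()
    reps2 = rows[rows["role"] == 2].sort_values("replicate")["sample_id"].tolist()
    if not reps1 or not reps2:
        raise StructuralError(f"pair {pair_id} lacks samples for one co-twin")
    return [
        pair_difference(frame, a, b, threshold, pair_id=f"{pair_id}:{a}|{b}")
        for a, b in product(reps1, reps2)
    ]


@dataclass
class ReplicateOverlap:
    """Agreement structure of replicated within-pair difference measures."""

    n_union: int
    n_intersection_all: int
    venn_counts: dict                 # membership pattern ("1010") -> count
    union_cpgs: list
    correlations: pd.DataFrame        # measure × measure Pearson on the union set
    independent_pairs: list           # measure-id pairs sharing no sample
    mean_correlation: float           # mean over all distinct measure pairs


def replicate_diff_reproducibility(diffs: list) -> ReplicateOverlap:
    """Overlap and correlation of ≥ 2 difference measures of the same pair.

    The union set collects CpGs exceeding the threshold in any measure;
    ``venn_counts`` gives the count of union CpGs for every observed
    membership pattern across measures; correlations between Δ vectors are
    computed on the union set only.  Measure pairs sharing no underlying
    sample (e.g. d(rep1, rep1) vs d(rep2, rep2)) are listed as
    ``independent_pairs``.
    """
    if len(diffs) < 2:
        raise ValueError("need at least two difference measures")
    universe = diffs[0].delta.index
    for d in diffs[1:]:
        if not d.delta.index.equals(universe):
            raise StructuralError("difference measures cover different CpG universes")
    exceed = pd.DataFrame({d.pair_id: d.exceed for d in diffs})
    union_mask = exceed.any(axis=1)
    union_cpgs = list(universe[union_mask])
    patterns = exceed.loc[union_mask]
    venn = {}
    for _, row in patterns.iterrows():
        key = "".join("1" if v else "0" for v in row)
        venn[key] = venn.get(key, 0) + 1
    n_all = int(exceed.loc[union_mask].all(axis=1).sum())

    deltas = pd.DataFrame({d.pair_id: d.delta for d in diffs}).loc[union_cpgs]
    corr = deltas.corr(method="pearson")
    ids = [d.pair_id for d in diffs]
    independent = [
        (di.pair_id, dj.pair_id)
        for di, dj in combinations(diffs, 2)
        if {di.sample_a, di.sample_b}.isdisjoint({dj.sample_a, dj.sample_b})
    ]
    offdiag = [corr.loc[a, b] for a, b in combinations(ids, 2)]
    offdiag = [v for v in offdiag if np.isfinite(v)]
    return ReplicateOverlap(
        n_union=len(union_cpgs),
        n_intersection_all=n_all,
        venn_counts=venn,
        union_cpgs=union_cpgs,
        correlations=corr,
        independent_pairs=independent,
        mean_correlation=float(np.nanmean(offdiag)) if offdiag else np.nan,
    )


def label_cpgs_by_bed(coords: pd.DataFrame, bed_path) -> pd.Series:
    """Flag CpGs overlapping intervals of a BED file.

    BED intervals are 0-based half-open; the CpG's 1-based position is
    converted to the 0-based point [pos − 1, pos) before the overlap test.
    """
    from intervaltree import IntervalTree

    trees: dict = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    flags = []
    for cpg, row in coords.iterrows():
        tree = trees.get(str(row["chrom"]))
        flags.append(bool(tree is not None and tree.overlaps_point(int(row["pos"]) - 1)))
    return pd.Series(flags, index=coords.index, name="in_bed")
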
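"""Between-sample genome-wide methylation profile similarity.

Raw β-value correlations between any two samples are dominated by the
many CpGs sitting near 0 or 1, so even unrelated people correlate above
0.98.  Standardizing each CpG row to zero mean and unit variance across
samples removes that shared bimodal shape; Pearson correlation on the
standardized matrix is then an informative profile-similarity measure
(near zero for unrelated pairs, highest for technical replicates).

Note the direction of standardization: z-scoring *within a sample* is an
affine transform of that sample's values and cannot change any Pearson
correlation between samples; only per-CpG (across-sample) standardization
alters the metric.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import BetaMatrix, StructuralError, first_measurements

__all__ = [
    "PAIR_CATEGORIES",
    "standardize_betas",
    "build_pair_catalog",
    "enumerate_unrelated_pairs",
    "pair_correlations",
    "summarize_by_category",
]

PAIR_CATEGORIES = ("replicate", "mz_twin", "platform_match", "unrelated")

#: Pairs sharing fewer non-missing CpGs than this are flagged unreliable.
MIN_SHARED_CPGS = 1000


def standardize_betas(beta: BetaMatrix) -> pd.DataFrame:
    """Per-CpG z-scores across samples.

    Each row is centered and scaled to unit variance (ddof = 1) using its
    non-missing entries; rows with zero variance are flagged missing
    (all-NaN).  Requires at least two samples.
    """
    if beta.n_samples < 2:
        raise StructuralError("standardization needs at least 2 samples")
    vals = beta.values.to_numpy(dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    z = (vals - mean) / np.where(sd > 0, sd, np.nan)
    return pd.DataFrame(z, index=beta.values.index, columns=beta.values.columns)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    # average ranks for ties
    return _pearson(rankdata(x), rankdata(y))


def build_pair_catalog(sheet: pd.DataFrame) -> pd.DataFrame:
    """Enumerate (sample_a, sample_b, category) pairs from a sample sheet.

    * ``replicate``: two measurements of the same individual;
    * ``platform_match``: same individual measured on two platforms;
    * ``mz_twin``: first measurements of the two co-twins of a pair;
    * ``unrelated``: first measurements of individuals from different pairs.
    """
    rows = []
    for _, grp in sheet.groupby("individual_id"):
        for a, b in combinations(grp.itertuples(), 2):
            cat = "replicate" if a.platform == b.platform else "platform_match"
            rows.append((a.sample_id, b.sample_id, cat))
    first = first_measurements(sheet)
    for _, grp in first.groupby("pair_id"):
        if len(grp) == 2:
            a, b = grp["sample_id"].tolist()
            rows.append((a, b, "mz_twin"))
    rows.extend(
        enumerate_unrelated_pairs(sheet).itertuples(index=False, name=None)
    )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "category"])


def enumerate_unrelated_pairs(sheet: pd.DataFrame) -> pd.DataFrame:
    """All cross-individual pairs excluding co-twins (one sample per
    individual, the first measurement), as catalog rows."""
    first = first_measurements(sheet)
    rows = [
        (a.sample_id, b.sample_id, "unrelated")
        for a, b in combinations(first.itertuples(), 2)
        if a.pair_id != b.pair_id
    ]
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "category"])


def pair_correlations(
    beta: BetaMatrix,
    z: pd.DataFrame,
    catalog: pd.DataFrame,
    min_shared: int = MIN_SHARED_CPGS,
) -> pd.DataFrame:
    """Per-pair Pearson, Spearman and standardized-β Pearson correlations.

    For each catalogued pair, raw-β Pearson and Spearman are computed over
    the CpGs non-missing in both samples; the standardized correlation is
    Pearson over the rows of ``z`` shared by both.  Pairs with fewer than
    ``min_shared`` shared CpGs are flagged ``unreliable``.
    """
    absent = (
        pd.Index(catalog["sample_a"]).union(pd.Index(catalog["sample_b"]))
    ).difference(beta.values.columns)
    if len(absent):
        raise StructuralError(f"catalog samples absent from matrix: {absent[:3].tolist()}")
    raw = beta.values
    records = []
    for row in catalog.itertuples(index=False):
        a = raw[row.sample_a].to_numpy(dtype=float)
        b = raw[row.sample_b].to_numpy(dtype=float)
        shared = np.isfinite(a) & np.isfinite(b)
        za = z[row.sample_a].to_numpy(dtype=float)
        zb = z[row.sample_b].to_numpy(dtype=float)
        zshared = np.isfinite(za) & np.isfinite(zb)
        records.append(
            {
                "sample_a": row.sample_a,
                "sample_b": row.sample_b,
                "category": row.category,
                "pearson_r": _pearson(a[shared], b[shared]) if shared.any() else np.nan,
                "spearman_rho": _spearman(a[shared], b[shared]) if shared.any() else np.nan,
                "pearson_r_standardized": _pearson(za[zshared], zb[zshared])
                if zshared.any()
                else np.nan,
                "n_shared_cpgs": int(shared.sum()),
                "unreliable": bool(shared.sum() < min_shared),
            }
        )
    return pd.DataFrame(records)


def summarize_by_category(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of each correlation metric per pair category."""
    metrics = ["pearson_r", "spearman_rho", "pearson_r_standardized"]
    out = table.groupby("category")[metrics].agg(["mean", "min", "max"])
    out["n_pairs"] = table.groupby("category").size()
    return out
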
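"""cis-mQTL mapping with a twin-pair-preserving permutation FDR.

The scan regresses (residualized, optionally rank-normalized) methylation
on SNP allele dosage for every (CpG, SNP) pair lying within 1 Mb on the
same chromosome — simple linear regression with n − 2 degrees of freedom.
Because both members of each MZ twin pair enter the sample, raw p-values
are anti-conservative; inference is drawn from a permutation-based FDR
whose null preserves the family structure: whole genotype twin-pair
blocks are reassigned to random methylation twin-pair blocks, and the
complete cis scan is repeated for each permutation.  The significance
threshold is the largest observed per-CpG minimum p such that

    mean over permutations of #CpGs significant in permuted data
    ──────────────────────────────────────────────────────────── ≤ FDR.
    #CpGs significant in observed data
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, rankdata
from scipy.stats import t as t_dist

from .containers import BetaMatrix, GenotypeTable, StructuralError, twin_columns

__all__ = [
    "DegenerateRankError",
    "filter_snps",
    "inverse_normal_transform",
    "inverse_normal_transform_matrix",
    "cis_scan",
    "cis_min_logp",
    "PairPermutation",
    "permute_pairs",
    "FDRResult",
    "permutation_fdr",
    "MQTLSummary",
    "summarize_mqtl",
    "genotype_pcs",
]

P_FLOOR = 1e-300
SNP_FILTER_RULES = ("maf", "hwe_p", "mac", "imp_r2")


class DegenerateRankError(ValueError):
    """All values equal: ranks carry no information."""


def _hwe_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) HWE p per SNP from rounded dosages."""
    g = np.clip(np.round(dosages), 0, 2)
    n = g.shape[1]
    n2 = (g == 2).sum(axis=1)
    n1 = (g == 1).sum(axis=1)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        obs = np.stack([n0, n1, n2])
        stat = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    out = chi2.sf(stat, df=1)
    out[(p == 0) | (p == 1)] = 1.0
    return out


def filter_snps(
    geno: GenotypeTable,
    maf: float = 0.01,
    hwe_p: float = 1e-4,
    mac: float = 10,
    imp_r2: float = 0.8,
    recompute_hwe: bool = False,
) -> tuple[GenotypeTable, dict]:
    """Retain SNPs strictly exceeding all four quality thresholds.

    All comparisons are strict (``>``), so a SNP sitting exactly at a
    threshold is removed.  Returns the filtered table and per-criterion
    removal counts (each removed SNP attributed to the first criterion it
    violates, in the order MAF → HWE → MAC → imputation r²).

    With ``recompute_hwe=True`` the HWE p-value is recomputed by
    chi-square on rounded dosages over the provided columns instead of
    trusting the metadata (note: with co-twins present the test is on
    non-independent units).
    """
    meta = geno.meta
    missing = set(SNP_FILTER_RULES) - set(meta.columns)
    if missing:
        raise StructuralError(f"SNP metadata lacks columns {sorted(missing)}")
    hwe_vals = (
        _hwe_from_dosages(geno.dosages.to_numpy(dtype=float))
        if recompute_hwe
        else meta["hwe_p"].to_numpy(dtype=float)
    )
    masks = {
        "maf": meta["maf"].to_numpy(dtype=float) > maf,
        "hwe_p": hwe_vals > hwe_p,
        "mac": meta["mac"].to_numpy(dtype=float) > mac,
        "imp_r2": meta["imp_r2"].to_numpy(dtype=float) > imp_r2,
    }
    keep = np.ones(len(meta), dtype=bool)
    removed = {}
    for rule in SNP_FILTER_RULES:
        hit = ~masks[rule] & keep
        removed[rule] = int(hit.sum())
        keep &= masks[rule]
    return geno.subset_snps(meta.index[keep]), removed


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps the i-th smallest of n values to Φ⁻¹((rank − 3/8)/(n + 1/4)),
    averaging ranks for ties; missing values are preserved.  Requires at
    least 10 non-missing values and at least two distinct values.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"inverse normal transform needs ≥ 10 values, got {n}")
    sub = x[mask]
    if np.all(sub == sub[0]):
        raise DegenerateRankError("all values equal: ranks are degenerate")
    ranks = rankdata(sub, method="average")
    out = np.full_like(x, np.nan)
    out[mask] = ndtri((ranks - 0.375) / (n + 0.25))
    return out


def inverse_normal_transform_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise inverse normal transform; unusable rows become all-missing."""
    out = np.full(values.shape, np.nan)
    mat = values.to_numpy(dtype=float)
    for i in range(mat.shape[0]):
        try:
            out[i] = inverse_normal_transform(mat[i])
        except (ValueError, DegenerateRankError):
            pass
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _aligned_dosages(meth: pd.DataFrame, geno: GenotypeTable, individual_of=None):
    """Dosage matrix with one column per methylation sample column."""
    if individual_of is None:
        individual_of = {s: s for s in meth.columns}
    try:
        cols = [individual_of[s] for s in meth.columns]
    except KeyError as exc:
        raise StructuralError(f"no individual mapping for sample {exc}") from exc
    absent = set(cols) - set(geno.dosages.columns)
    if absent:
        raise StructuralError(
            f"samples without genotypes: {sorted(absent)[:3]}"
        )
    G = geno.dosages[cols].to_numpy(dtype=float)
    if np.isnan(G).any():
        raise StructuralError("dosage matrix must be complete")
    return G


def _cis_ranges(cpg_coords: pd.DataFrame, snp_meta: pd.DataFrame, window: int):
    """Per-CpG [lo, hi) slices into position-sorted SNPs, per chromosome.

    The window is strict: |pos_snp − pos_cpg| < window.
    """
    order = np.argsort(snp_meta["pos"].to_numpy(), kind="stable")
    snp_sorted = snp_meta.iloc[order]
    ranges = {}
    for chrom, sub in snp_sorted.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = np.arange(len(snp_sorted))[
            (snp_sorted["chrom"] == chrom).to_numpy()
        ]
        ranges[chrom] = (pos, idx)
    lo = np.zeros(len(cpg_coords), dtype=int)
    hi = np.zeros(len(cpg_coords), dtype=int)
    snp_row = []
    for i, (_, row) in enumerate(cpg_coords.iterrows()):
        entry = ranges.get(row["chrom"])
        if entry is None:
            lo[i] = hi[i] = 0
            snp_row.append(np.empty(0, dtype=int))
            continue
        pos, idx = entry
        a = np.searchsorted(pos, row["pos"] - window, side="right")
        b = np.searchsorted(pos, row["pos"] + window, side="left")
        lo[i], hi[i] = a, b
        snp_row.append(idx[a:b])
    return snp_sorted, snp_row


def _logp_from_t(t_abs: np.ndarray, df: np.ndarray | int) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.log(2.0) + t_dist.logsf(t_abs, df)


def cis_scan(
    meth,
    geno: GenotypeTable,
    cpg_coords: pd.DataFrame | None = None,
    window: int = 1_000_000,
    individual_of: dict | None = None,
) -> pd.DataFrame:
    """Simple-regression scan of every (CpG, SNP) pair within the window.

    For each pair on the same chromosome with |pos_snp − pos_cpg| <
    ``window`` (strict), fits methylation ~ dosage by ordinary least
    squares and reports the slope, the t statistic (n − 2 df) and the
    two-sided p-value (floored at 1e-300; the natural-log p is reported
    alongside).  SNPs with zero dosage variance over a CpG's usable
    samples are skipped.

    ``meth`` columns are sample ids; ``individual_of`` maps them to
    genotype columns (identity by default).
    """
    frame = meth.values if isinstance(meth, BetaMatrix) else meth
    if cpg_coords is None:
        if not isinstance(meth, BetaMatrix):
            raise StructuralError("cpg_coords required when meth is a plain frame")
        cpg_coords = meth.coords
    cpg_coords = cpg_coords.loc[frame.index]
    G_all = _aligned_dosages(frame, geno, individual_of)
    snp_sorted, snp_rows = _cis_ranges(cpg_coords, geno.meta, window)
    order_index = snp_sorted.index
    G_sorted = G_all[geno.meta.index.get_indexer(order_index)]
    snp_pos_sorted = snp_sorted["pos"].to_numpy()

    M = frame.to_numpy(dtype=float)
    cpg_pos = cpg_coords["pos"].to_numpy()
    records = []
    for i in range(M.shape[0]):
        rows = snp_rows[i]
        if rows.size == 0:
            continue
        y = M[i]
        mask = np.isfinite(y)
        n = int(mask.sum())
        if n < 3:
            continue
        yv = y[mask]
        yc = yv - yv.mean()
        ssy = float((yc**2).sum())
        G = G_sorted[rows][:, mask]
        Gc = G - G.mean(axis=1, keepdims=True)
        ssx = (Gc**2).sum(axis=1)
        ok = ssx > 0
        if ssy == 0 or not ok.any():
            continue
        sxy = Gc @ yc
        beta = np.full(rows.size, np.nan)
        beta[ok] = sxy[ok] / ssx[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(ok, sxy / np.sqrt(np.where(ok, ssx, 1.0) * ssy), np.nan)
            r = np.clip(r, -1.0, 1.0)
            tt = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        logp = _logp_from_t(np.abs(tt[ok]), n - 2)
        # numerically perfect fits: report the underflow floor
        logp[r[ok] ** 2 >= 1.0 - 1e-12] = -np.inf
        pvals = np.maximum(np.exp(logp), P_FLOOR)
        sel = np.nonzero(ok)[0]
        snp_ids = order_index.to_numpy()[rows[sel]]
        positions = snp_pos_sorted[rows[sel]]
        rec = pd.DataFrame(
            {
                "cpg_id": frame.index[i],
                "snp_id": snp_ids,
                "chrom": cpg_coords["chrom"].iloc[i],
                "pos_cpg": cpg_pos[i],
                "pos_snp": positions,
                "distance": np.abs(positions - cpg_pos[i]),
                "n": n,
                "beta": beta[sel],
                "t_stat": tt[sel],
                "p_value": pvals,
                "logp": logp,
            }
        )
        records.append(rec)
    if not records:
        return pd.DataFrame(
            columns=[
                "cpg_id", "snp_id", "chrom", "pos_cpg", "pos_snp",
                "distance", "n", "beta", "t_stat", "p_value", "logp",
            ]
        )
    return pd.concat(records, ignore_index=True)


def cis_min_logp(
    meth: pd.DataFrame,
    G_sorted: np.ndarray,
    snp_rows: list,
    col_order: np.ndarray | None = None,
) -> np.ndarray:
    """Per-CpG minimum log-p over its cis SNPs (scan without records).

    ``G_sorted`` and ``snp_rows`` come from the same `_cis_ranges`
    precomputation used by `cis_scan`; ``col_order`` optionally permutes
    the methylation columns (used by the pair-permutation null).  CpGs
    with no testable SNP get +inf.
    """
    M = meth.to_numpy(dtype=float)
    if col_order is not None:
        M = M[:, col_order]
    n_cpgs, n_samples = M.shape
    out = np.full(n_cpgs, np.inf)

    finite = np.isfinite(M)
    complete = finite.all(axis=1)

    # fast path: complete rows via one standardized matrix product
    if complete.any():
        sub = M[complete]
        sub = sub - sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1)
        nz = sd > 0
        Z = np.zeros_like(sub)
        Z[nz] = sub[nz] / sd[nz][:, None]
        Gc = G_sorted - G_sorted.mean(axis=1, keepdims=True)
        gsd = Gc.std(axis=1)
        gnz = gsd > 0
        Zg = np.zeros_like(Gc)
        Zg[gnz] = Gc[gnz] / gsd[gnz][:, None]
        R = (Z @ Zg.T) / n_samples
        comp_idx = np.nonzero(complete)[0]
        for k, i in enumerate(comp_idx):
            rows = snp_rows[i]
            if rows.size == 0 or not nz[k]:
                continue
            usable = rows[gnz[rows]]
            if usable.size == 0:
                continue
            rmax = np.abs(R[k, usable]).max()
            rmax = min(rmax, 1.0)
            if rmax**2 >= 1.0 - 1e-12:
                out[i] = -np.inf
                continue
            tt = rmax * np.sqrt((n_samples - 2) / max(1.0 - rmax**2, 1e-300))
            out[i] = _logp_from_t(np.array([tt]), n_samples - 2)[0]

    for i in np.nonzero(~complete)[0]:
        rows = snp_rows[i]
        if rows.size == 0:
            continue
        y = M[i]
        mask = finite[i]
        n = int(mask.sum())
        if n < 3:
            continue
        yv = y[mask]
        yc = yv - yv.mean()
        ssy = float((yc**2).sum())
        if ssy == 0:
            continue
        G = G_sorted[rows][:, mask]
        Gc = G - G.mean(axis=1, keepdims=True)
        ssx = (Gc**2).sum(axis=1)
        ok = ssx > 0
        if not ok.any():
            continue
        sxy = Gc[ok] @ yc
        r = np.abs(sxy) / np.sqrt(ssx[ok] * ssy)
        rmax = min(float(r.max()), 1.0)
        if rmax**2 >= 1.0 - 1e-12:
            out[i] = -np.inf
            continue
        tt = rmax * np.sqrt((n - 2) / max(1.0 - rmax**2, 1e-300))
        out[i] = _logp_from_t(np.array([tt]), n - 2)[0]
    return out


@dataclass
class PairPermutation:
    """A pair-block permutation: genotype pair i ↦ methylation pair perm[i]."""

    pair_ids: list
    perm: np.ndarray

    def mapping(self) -> dict:
        return {self.pair_ids[i]: self.pair_ids[j] for i, j in enumerate(self.perm)}

    def column_order(self) -> np.ndarray:
        """Column reindex for a methylation matrix ordered pairwise
        [pair1·twin1, pair1·twin2, pair2·twin1, …]."""
        out = np.empty(2 * len(self.pair_ids), dtype=int)
        out[0::2] = 2 * self.perm
        out[1::2] = 2 * self.perm + 1
        return out


def permute_pairs(sheet_or_pairs, rng) -> PairPermutation:
    """Uniformly random permutation of twin-pair labels.

    Both co-twins of genotype pair i are mapped to the two methylation
    samples of the permuted pair, preserving within-pair genotype
    identity.  Derangements are not enforced (the identity assignment of
    a pair is a legitimate draw of the uniform null).
    """
    if isinstance(sheet_or_pairs, pd.DataFrame):
        sheet = sheet_or_pairs
        counts = (
            sheet.groupby("pair_id")["individual_id"].nunique()
        )
        incomplete = counts[counts != 2]
        if len(incomplete):
            raise StructuralError(
                f"incomplete pairs must be dropped before permutation: "
                f"{incomplete.index[:3].tolist()}"
            )
        pair_ids = sorted(counts.index)
    else:
        pair_ids = list(sheet_or_pairs)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(len(pair_ids))
    return PairPermutation(pair_ids=pair_ids, perm=perm)


@dataclass
class FDRResult:
    """Permutation-FDR threshold and significance summary."""

    fdr: float
    n_perm: int
    status: str                      # "ok" or "no_threshold"
    p_threshold: float = np.nan
    logp_threshold: float = np.nan
    n_sig_cpgs: int = 0
    n_sig_associations: int = 0
    n_sig_snps: int = 0
    per_perm_sig_cpg_counts: list = field(default_factory=list)


def permutation_fdr(
    meth,
    geno: GenotypeTable,
    sheet: pd.DataFrame,
    cpg_coords: pd.DataFrame | None = None,
    observed: pd.DataFrame | None = None,
    window: int = 1_000_000,
    n_perm: int = 10,
    fdr: float = 0.05,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    rank_normalize: bool = False,
) -> FDRResult:
    """Twin-pair-preserving permutation FDR for the cis scan.

    Candidate thresholds are the observed per-CpG minimum p-values; the
    selected threshold is the largest candidate t for which the mean
    permuted count of CpGs with min p ≤ t, divided by the observed count,
    stays at or below ``fdr``.  For every permutation the complete cis
    analysis is recomputed on pair-block-permuted data: when
    ``covariates`` are supplied (sample × covariate, indexed like the
    methylation columns), each permuted matrix is re-residualized on them
    — and rank-normalized when ``rank_normalize`` — before its scan, so
    permuted and observed statistics remain exchangeable even though the
    observed methylation was itself covariate-adjusted.  ``meth`` should
    then be the residual matrix before rank normalization (residualizing
    residuals is a no-op, so the observed pass is unaffected).

    ``meth`` columns must be one sample per individual of complete twin
    pairs; genotype columns are located through the sample sheet.
    """
    frame = meth.values if isinstance(meth, BetaMatrix) else meth
    if cpg_coords is None:
        if not isinstance(meth, BetaMatrix):
            raise StructuralError("cpg_coords required when meth is a plain frame")
        cpg_coords = meth.coords
    cpg_coords = cpg_coords.loc[frame.index]

    pairs, t1, t2 = twin_columns(sheet)
    sample_order = [s for ab in zip(t1, t2) for s in ab]
    absent = set(sample_order) - set(frame.columns)
    if absent:
        raise StructuralError(f"methylation lacks samples {sorted(absent)[:3]}")
    extra = set(frame.columns) - set(sample_order)
    if extra:
        raise StructuralError(
            "every analyzed individual must belong to a complete pair; "
            f"unexpected samples {sorted(extra)[:3]}"
        )
    frame = frame[sample_order]
    ind_of = (
        sheet.set_index("sample_id")["individual_id"].to_dict()
    )
    G_all = _aligned_dosages(frame, geno, ind_of)
    snp_sorted, snp_rows = _cis_ranges(cpg_coords, geno.meta, window)
    G_sorted = G_all[geno.meta.index.get_indexer(snp_sorted.index)]

    def _prepare(mat: pd.DataFrame) -> pd.DataFrame:
        out = mat
        if covariates is not None:
            from .twin import residualize

            out = residualize(out, covariates.loc[out.columns])
        if rank_normalize:
            out = inverse_normal_transform_matrix(out)
        return out

    obs_logp = cis_min_logp(_prepare(frame), G_sorted, snp_rows)
    tested = np.isfinite(obs_logp)
    if not tested.any():
        return FDRResult(fdr=fdr, n_perm=n_perm, status="no_threshold")
    obs_sorted = np.sort(obs_logp[tested])

    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    perm_sorted = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        perm = permute_pairs(pairs, rng)
        # reassign pair blocks but keep the column labels in place, so the
        # covariate re-adjustment stays aligned with the genotype side
        permuted = pd.DataFrame(
            frame.to_numpy()[:, perm.column_order()],
            index=frame.index,
            columns=frame.columns,
        )
        lp = cis_min_logp(_prepare(permuted), G_sorted, snp_rows)
        perm_sorted.append(np.sort(lp[np.isfinite(lp)]))

    candidates = np.unique(obs_sorted)
    r_obs = np.searchsorted(obs_sorted, candidates, side="right")
    r_perm = np.zeros(len(candidates))
    for lp in perm_sorted:
        r_perm += np.searchsorted(lp, candidates, side="right")
    r_perm /= n_perm
    ratio = r_perm / r_obs
    passing = np.nonzero(ratio <= fdr)[0]
    if passing.size == 0:
        return FDRResult(fdr=fdr, n_perm=n_perm, status="no_threshold")
    k = passing.max()
    logp_thr = float(candidates[k])
    result = FDRResult(
        fdr=fdr,
        n_perm=n_perm,
        status="ok",
        p_threshold=float(max(np.exp(logp_thr), P_FLOOR)),
        logp_threshold=logp_thr,
        n_sig_cpgs=int(r_obs[k]),
        per_perm_sig_cpg_counts=[
            int(np.searchsorted(lp, logp_thr, side="right")) for lp in perm_sorted
        ],
    )
    if observed is not None and len(observed):
        sig = observed[observed["logp"] <= logp_thr]
        result.n_sig_associations = int(len(sig))
        result.n_sig_snps = int(sig["snp_id"].nunique())
        # recompute CpG count from the records for consistency
        result.n_sig_cpgs = int(sig["cpg_id"].nunique())
    return result


@dataclass
class MQTLSummary:
    """Counts and distance summaries of the significant associations."""

    n_sig_associations: int
    n_sig_cpgs: int
    n_sig_snps: int
    snps_per_cpg: dict
    cpgs_per_snp: dict
    distance_to_top_snp: pd.Series
    median_distance_bp: float


def summarize_mqtl(records: pd.DataFrame, fdr_result: FDRResult) -> MQTLSummary:
    """Summarize the associations below the permutation threshold.

    Each significant CpG is assigned the distance to its minimum-p SNP
    (ties broken toward the smallest distance); the median of those
    distances is reported in base pairs.
    """
    if fdr_result.status != "ok":
        raise ValueError("no significance threshold available")
    sig = records[records["logp"] <= fdr_result.logp_threshold]
    per_cpg = sig.groupby("cpg_id").size()
    per_snp = sig.groupby("snp_id").size()

    def _stats(counts: pd.Series) -> dict:
        if counts.empty:
            return {"min": 0, "median": 0.0, "mean": 0.0, "max": 0}
        return {
            "min": int(counts.min()),
            "median": float(counts.median()),
            "mean": float(counts.mean()),
            "max": int(counts.max()),
        }

    top = (
        sig.sort_values(["cpg_id", "logp", "distance"], kind="stable")
        .groupby("cpg_id", sort=True)
        .first()
    )
    dist = top["distance"].astype(float)
    return MQTLSummary(
        n_sig_associations=int(len(sig)),
        n_sig_cpgs=int(per_cpg.size),
        n_sig_snps=int(per_snp.size),
        snps_per_cpg=_stats(per_cpg),
        cpgs_per_snp=_stats(per_snp),
        distance_to_top_snp=dist,
        median_distance_bp=float(dist.median()) if len(dist) else np.nan,
    )


def genotype_pcs(geno: GenotypeTable, n_pcs: int = 10) -> pd.DataFrame:
    """Principal-component scores of individuals from the dosage matrix.

    Standard eigendecomposition of the individual × individual Gram matrix
    of per-SNP standardized dosages; scores are sign-fixed so the largest
    absolute loading of each PC is positive.
    """
    X = geno.dosages.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    nz = sd > 0
    Z = Xc[nz] / sd[nz][:, None]
    K = (Z.T @ Z) / Z.shape[0]
    w, v = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:n_pcs]
    scores = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=geno.dosages.columns, columns=cols)
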
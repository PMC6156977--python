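"""End-to-end analysis workflows stitching the modules together.

These helpers reproduce the study's analysis order on any cohort (real
files or synthetic): QC → cell-fraction estimation → covariate
residualization → twin correlations / within-pair differences → cis-mQTL
scan with permutation FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GenotypeTable, ReferenceProfiles, twin_columns
from .deconvolution import hepidish_cohort
from .mqtl import (
    FDRResult,
    cis_scan,
    filter_snps,
    genotype_pcs,
    inverse_normal_transform_matrix,
    permutation_fdr,
)
from .twin import residualize, twin_correlations

__all__ = [
    "TWIN_ADJUSTMENT_CELLTYPES",
    "estimate_cell_fractions",
    "cell_covariates",
    "full_rank_covariates",
    "adjust_for_cell_composition",
    "run_twin_correlation_analysis",
    "MQTLAnalysis",
    "run_mqtl_analysis",
]

#: Cell fractions adjusted for in the twin-correlation and mQTL analyses
#: (the types that vary between buccal samples).
TWIN_ADJUSTMENT_CELLTYPES = ("Epi", "Neutro", "B", "NK", "CD4T", "Mono")


def estimate_cell_fractions(beta: BetaMatrix, reference: ReferenceProfiles) -> pd.DataFrame:
    """Hierarchical deconvolution of every sample (rows = samples)."""
    return hepidish_cohort(beta, reference)


def cell_covariates(
    fractions: pd.DataFrame, celltypes=TWIN_ADJUSTMENT_CELLTYPES
) -> pd.DataFrame:
    return fractions[list(celltypes)]


def full_rank_covariates(covariates: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Drop columns that are (numerically) linear combinations of earlier
    ones, plus the intercept.

    Residualizing on a reduced full-rank set yields the same residuals as
    the rank-deficient set would (the projection depends only on the
    column span), so this never changes an analysis — it only makes the
    per-CpG fits well-posed.
    """
    X = np.column_stack([np.ones(len(covariates))])
    kept = []
    for col in covariates.columns:
        v = covariates[col].to_numpy(dtype=float)
        trial = np.column_stack([X, v])
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] > tol * s[0]:
            X = trial
            kept.append(col)
    return covariates[kept]


def adjust_for_cell_composition(values, fractions: pd.DataFrame) -> pd.DataFrame:
    """Residualize β on the varying cell fractions."""
    frame = values.values if isinstance(values, BetaMatrix) else values
    covars = full_rank_covariates(cell_covariates(fractions).loc[frame.columns])
    return residualize(frame, covars)


def run_twin_correlation_analysis(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    fractions: pd.DataFrame | None = None,
    reference: ReferenceProfiles | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-CpG MZ twin correlations, optionally after cell adjustment."""
    if adjust:
        if fractions is None:
            if reference is None:
                raise ValueError("need fractions or reference profiles to adjust")
            fractions = estimate_cell_fractions(beta, reference)
        values = adjust_for_cell_composition(beta, fractions)
    else:
        values = beta.values
    return twin_correlations(values, sheet)


@dataclass
class _ResidualDosages:
    """Covariate-adjusted dosages (may leave [0, 2]) with SNP metadata."""

    dosages: pd.DataFrame
    meta: pd.DataFrame


@dataclass
class MQTLAnalysis:
    records: pd.DataFrame
    fdr_result: FDRResult
    covariates: pd.DataFrame
    snp_filter_report: dict
    samples: list


def run_mqtl_analysis(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    geno: GenotypeTable,
    fractions: pd.DataFrame | None = None,
    reference: ReferenceProfiles | None = None,
    window: int = 1_000_000,
    n_perm: int = 10,
    fdr: float = 0.05,
    seed: int = 0,
    rank_normalize: bool = True,
    n_pcs: int = 10,
    apply_snp_filters: bool = True,
) -> MQTLAnalysis:
    """Full cis-mQTL analysis on complete twin pairs.

    One sample per individual (first measurement); methylation is
    residualized on the varying cell fractions plus sex, age and the
    leading genotype PCs, then rank-normalized (Blom) per CpG; SNPs pass
    the MAF/HWE/MAC/imputation filters; the scan and the
    pair-permutation FDR threshold are computed on the result.

    The same covariates are projected out of the dosages before the scan
    (Frisch–Waugh), so each reported slope equals the SNP coefficient of
    the multiple regression that includes the covariates; test df stays
    n − 2, a negligible difference at these sample sizes.
    """
    pairs, t1, t2 = twin_columns(sheet)
    samples = [s for ab in zip(t1, t2) for s in ab]
    sheet_sub = sheet[sheet["sample_id"].isin(samples)]
    values = beta.values[samples]

    if fractions is None:
        if reference is None:
            raise ValueError("need fractions or reference profiles")
        fractions = estimate_cell_fractions(beta, reference)
    fractions = fractions.loc[samples]

    if apply_snp_filters:
        geno_f, removed = filter_snps(geno)
    else:
        geno_f, removed = geno, {}

    ind_of = sheet_sub.set_index("sample_id")["individual_id"].to_dict()
    n_pcs_eff = min(n_pcs, max(len(samples) - 2, 1))
    pcs = genotype_pcs(geno_f, n_pcs_eff)
    meta = sheet_sub.set_index("sample_id")
    covars = cell_covariates(fractions).copy()
    covars["sex"] = (meta.loc[samples, "sex"] == "M").astype(float).to_numpy()
    covars["age"] = meta.loc[samples, "age"].to_numpy(dtype=float)
    pc_block = pcs.loc[[ind_of[s] for s in samples]].to_numpy()
    for j in range(pc_block.shape[1]):
        covars[f"PC{j + 1}"] = pc_block[:, j]
    covars = full_rank_covariates(covars)

    resid = residualize(values, covars)
    meth = inverse_normal_transform_matrix(resid) if rank_normalize else resid

    # project the covariates out of the dosages as well, so the simple-
    # regression slope equals the covariate-including model's coefficient
    dose_cols = [ind_of[s] for s in samples]
    dose = geno_f.dosages[dose_cols].copy()
    dose.columns = samples
    dose_resid = residualize(dose, covars)
    dose_resid.columns = dose_cols
    geno_scan = _ResidualDosages(dosages=dose_resid, meta=geno_f.meta)

    records = cis_scan(
        meth, geno_scan, cpg_coords=beta.coords, window=window, individual_of=ind_of
    )
    # hand the permutation the pre-rank-normalization residuals plus the
    # covariates: each permuted pass repeats the complete adjustment chain
    fdr_result = permutation_fdr(
        resid,
        geno_scan,
        sheet_sub,
        cpg_coords=beta.coords,
        observed=records,
        window=window,
        n_perm=n_perm,
        fdr=fdr,
        seed=seed,
        covariates=covars,
        rank_normalize=rank_normalize,
    )
    return MQTLAnalysis(
        records=records,
        fdr_result=fdr_result,
        covariates=covars,
        snp_filter_report=removed,
        samples=samples,
    )
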
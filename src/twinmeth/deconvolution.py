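"""Reference-based cell-type deconvolution for epithelial tissues.

Two estimators of cellular composition from a sample's β-value profile:

* a hierarchical two-stage robust-regression estimator: stage 1 regresses
  the sample on epithelial / fibroblast / generic-immune reference
  profiles over a stage-1 signature CpG set; stage 2 resolves the immune
  compartment into seven leukocyte sub-types over a second signature set,
  and the sub-type proportions are scaled by the stage-1 immune total;
* a two-CpG epithelial estimator: a linear combination of the β-values of
  two designated CpGs (cg07380416 and cg20837735), clipped to [0, 1].

The robust fit is iteratively reweighted least squares with Huber
weighting (tuning constant 1.345); an intercept is included and discarded,
negative coefficients are truncated to zero, and the remainder is
renormalized to sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ALL_CELLTYPES, IMMUNE_SUBTYPES, BetaMatrix, ReferenceProfiles
from .simulate import EIPEL_CPGS

__all__ = [
    "CoverageError",
    "SingularityError",
    "MissingInputError",
    "EipelCoefficients",
    "DEFAULT_EIPEL_COEFFICIENTS",
    "rpc_fit",
    "hepidish",
    "hepidish_cohort",
    "eipel_estimate",
    "eipel_cohort",
    "calibrate_eipel",
]

HUBER_T = 1.345
MAX_ITER = 100
CONV_TOL = 1e-8


class CoverageError(ValueError):
    """Too few usable signature CpGs to fit the reference regression."""


class SingularityError(ValueError):
    """Reference profiles are rank-deficient over the usable CpGs."""


class MissingInputError(ValueError):
    """A required CpG measurement is missing."""


def rpc_fit(
    sample_betas: pd.Series,
    reference: pd.DataFrame,
    signature,
) -> pd.Series:
    """Estimate cell-type fractions of one sample by robust regression.

    Regresses the sample's β-values on the reference profile columns over
    the signature CpGs (missing CpGs are dropped from the fit).  The fit
    is Huber-weighted IRLS with an intercept; the intercept is discarded,
    coefficients are truncated below at 0 and renormalized to sum to 1.

    Parameters
    ----------
    sample_betas
        β-values indexed by CpG id.
    reference
        CpG × cell-type mean β-profiles.
    signature
        CpG ids on which to fit; must be present in ``reference``.

    Returns
    -------
    pandas.Series of fractions, one per reference column, summing to 1.
    """
    sig = pd.Index(signature)
    absent = sig.difference(reference.index)
    if len(absent):
        raise CoverageError(
            f"{len(absent)} signature CpGs absent from the reference profiles"
        )
    y = sample_betas.reindex(sig)
    usable = sig[y.notna().to_numpy()]
    n_types = reference.shape[1]
    if len(usable) < max(10, n_types + 1):
        raise CoverageError(
            f"only {len(usable)} usable signature CpGs "
            f"(need at least {max(10, n_types + 1)})"
        )
    X = reference.loc[usable].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(usable)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularityError(
            "reference profiles are rank-deficient over the usable signature CpGs"
        )
    yv = y.loc[usable].to_numpy(dtype=float)

    # Exact fits first: with (near-)zero residuals the robust scale estimate
    # degenerates, and ordinary least squares is already the IRLS fixed point.
    ols_coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
    if np.abs(design @ ols_coef - yv).max() < 1e-8:
        coef = ols_coef[1:]
    else:
        rlm = sm.RLM(yv, design, M=sm.robust.norms.HuberT(t=HUBER_T))
        fit = rlm.fit(maxiter=MAX_ITER, tol=CONV_TOL, conv="coefs")
        coef = np.asarray(fit.params)[1:]

    coef = np.clip(coef, 0.0, None)
    total = coef.sum()
    if total <= 0:
        warnings.warn(
            "all truncated coefficients are zero; returning uniform fractions",
            stacklevel=2,
        )
        coef = np.full(n_types, 1.0 / n_types)
    else:
        coef = coef / total
    return pd.Series(coef, index=reference.columns, name=sample_betas.name)


def hepidish(sample_betas: pd.Series, reference: ReferenceProfiles) -> pd.Series:
    """Two-stage hierarchical deconvolution of one sample.

    Stage 1 estimates (epithelial, fibroblast, immune-total); stage 2
    estimates relative proportions of the 7 leukocyte sub-types; final
    sub-type fractions are stage-2 proportions × immune-total, so the
    output sums to 1 and the sub-types sum to the immune total exactly.
    """
    stage1 = rpc_fit(sample_betas, reference.stage1, reference.signature1)
    stage2 = rpc_fit(sample_betas, reference.stage2, reference.signature2)
    out = pd.Series(0.0, index=list(ALL_CELLTYPES), name=sample_betas.name)
    out["Epi"] = stage1["Epi"]
    out["Fib"] = stage1["Fib"]
    out[list(IMMUNE_SUBTYPES)] = stage2.to_numpy() * stage1["IC"]
    return out


def hepidish_cohort(beta: BetaMatrix, reference: ReferenceProfiles) -> pd.DataFrame:
    """Apply `hepidish` to every sample column; rows = samples."""
    rows = {
        sample: hepidish(beta.values[sample], reference)
        for sample in beta.values.columns
    }
    return pd.DataFrame(rows).T.loc[beta.values.columns]


@dataclass(frozen=True)
class EipelCoefficients:
    """Coefficients of the two-CpG epithelial estimator:
    fraction = clip(intercept + b1·β(cg07380416) + b2·β(cg20837735), 0, 1).
    """

    intercept: float
    b1: float
    b2: float


#: Synthetic stand-in coefficients, calibrated analytically against this
#: package's synthetic reference profiles (in which cg07380416 is an
#: epithelial-high marker and cg20837735 an epithelial-low marker); they do
#: not reproduce the originally published two-CpG formula.
DEFAULT_EIPEL_COEFFICIENTS = EipelCoefficients(
    intercept=0.5, b1=1.0 / 1.8, b2=-1.0 / 1.8
)


def eipel_estimate(
    beta_cg07380416: float,
    beta_cg20837735: float,
    coefficients: EipelCoefficients = DEFAULT_EIPEL_COEFFICIENTS,
) -> float:
    """Epithelial fraction from the two designated CpGs, clipped to [0, 1].

    Raises
    ------
    MissingInputError
        If either β-value is missing — an unavailable estimate is reported
        explicitly, never silently as zero.
    """
    b1, b2 = float(beta_cg07380416), float(beta_cg20837735)
    if not (np.isfinite(b1) and np.isfinite(b2)):
        raise MissingInputError(
            "both cg07380416 and cg20837735 must be measured for the "
            "two-CpG epithelial estimate"
        )
    raw = coefficients.intercept + coefficients.b1 * b1 + coefficients.b2 * b2
    return float(np.clip(raw, 0.0, 1.0))


def eipel_cohort(
    beta: BetaMatrix,
    coefficients: EipelCoefficients = DEFAULT_EIPEL_COEFFICIENTS,
) -> pd.Series:
    """Two-CpG epithelial estimates per sample.

    Samples with either CpG missing (or a matrix lacking the probes
    entirely) get ``NaN``, flagged in the returned series' ``attrs``
    under ``"unavailable"``.
    """
    out = pd.Series(np.nan, index=beta.values.columns, name="eipel_epi")
    unavailable = []
    for sample in beta.values.columns:
        try:
            b1 = beta.values.at[EIPEL_CPGS[0], sample] if EIPEL_CPGS[0] in beta.values.index else np.nan
            b2 = beta.values.at[EIPEL_CPGS[1], sample] if EIPEL_CPGS[1] in beta.values.index else np.nan
            out[sample] = eipel_estimate(b1, b2, coefficients)
        except MissingInputError:
            unavailable.append(sample)
    out.attrs["unavailable"] = unavailable
    return out


def calibrate_eipel(beta: BetaMatrix, epithelial_fractions: pd.Series) -> EipelCoefficients:
    """Least-squares calibration of the two-CpG estimator on known fractions."""
    b1 = beta.values.loc[EIPEL_CPGS[0]]
    b2 = beta.values.loc[EIPEL_CPGS[1]]
    frame = pd.DataFrame({"b1": b1, "b2": b2, "y": epithelial_fractions}).dropna()
    X = np.column_stack([np.ones(len(frame)), frame["b1"], frame["b2"]])
    coef, *_ = np.linalg.lstsq(X, frame["y"].to_numpy(), rcond=None)
    return EipelCoefficients(intercept=coef[0], b1=coef[1], b2=coef[2])
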
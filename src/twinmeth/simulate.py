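"""Synthetic twin-cohort generator with known ground truth.

Emulates the statistical structure of a buccal-swab methylome study of
young monozygotic (MZ) twins measured on a methylation array:

* every sample is a two-level cell mixture — epithelial cells, fibroblasts
  and an immune compartment that is itself a mixture of seven leukocyte
  sub-types — so the β-value of a CpG is the fraction-weighted average of
  cell-type profiles;
* epithelial fractions of co-twins are correlated (default r = 0.51,
  via a Gaussian copula on the logit scale);
* a pair-shared "familial" deviation gives the cell-free signal a tunable
  per-CpG twin correlation;
* a subset of CpGs carries an additive cis genetic effect (β-shift per
  reference allele) from a SNP placed within 1 Mb;
* co-twins carry identical hard genotypes (MZ identity); dosages add
  bounded imputation noise;
* a small rate of (probe, sample) cells is flagged as technical failures
  (detection p > 0.01, bead count < 3, or zero intensity), and a few
  samples are measured twice as technical replicates.

All randomness derives from ``SimConfig.seed``; identical configs produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.special import expit, logit
from scipy.stats import chi2

from .containers import (
    ALL_CELLTYPES,
    IMMUNE_SUBTYPES,
    BetaMatrix,
    DetectionStats,
    GenotypeTable,
    ProbeAnnotation,
    ReferenceProfiles,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TwinCohort",
    "GenotypeSim",
    "SizingError",
    "ParameterizationError",
    "generate_reference_profiles",
    "generate_genotypes",
    "generate_twin_cohort",
    "signature_separation",
    "EIPEL_CPGS",
]

#: The two CpGs used by the two-probe epithelial-fraction estimator.
EIPEL_CPGS = ("cg07380416", "cg20837735")

# Relative leukocyte composition of the immune compartment (neutrophils
# dominant, CD8T/eosinophils near zero), matching microscopy-era reports
# for buccal swabs.
_IMMUNE_BASE_PROPS = np.array([0.158, 0.167, 0.103, 0.005, 0.197, 0.365, 0.005])
_IMMUNE_BASE_PROPS = _IMMUNE_BASE_PROPS / _IMMUNE_BASE_PROPS.sum()


class SizingError(ValueError):
    """The CpG universe is too small to host the requested structure."""


class ParameterizationError(ValueError):
    """The requested correlation/variance combination is infeasible."""


@dataclass
class SimConfig:
    """Parameters of the synthetic twin cohort.

    The defaults describe the emulated study: 49 MZ pairs aged 1–10,
    epithelial-dominated buccal mixtures (mean fraction 0.796) with co-twin
    epithelial correlation 0.51, a residual familial twin correlation of
    0.21 at the typical CpG, and 100 cis-mQTL CpGs with a 0.15 β-shift per
    allele.
    """

    n_pairs: int = 49
    n_cpgs: int = 2000
    n_snps: int = 2000
    n_celltypes_stage1: int = 3
    n_immune_subtypes: int = 7
    epi_fraction_mean: float = 0.796
    #: sd of the epithelial fraction on the logit scale (0 ⇒ constant).
    epi_fraction_logit_sd: float = 0.5
    epi_fraction_twin_corr: float = 0.51
    fib_fraction_mean: float = 0.0
    #: twin correlation of the cell-free signal; scalar or length-n_cpgs vector.
    familial_corr: float | np.ndarray = 0.21
    n_mqtl_cpgs: int = 100
    mqtl_effect_size: float = 0.15
    maf_range: tuple = (0.05, 0.5)
    imp_noise_sd: float = 0.05
    noise_sd: float = 0.03
    fail_rate: float = 0.001
    n_replicate_pairs: int = 2
    #: Dirichlet concentration for per-sample immune sub-type mixes
    #: (None ⇒ every sample uses the fixed base composition).
    immune_dirichlet_conc: float | None = 50.0
    chrom: str = "1"
    chrom_length: int = 20_000_000
    signature_size1: int = 48
    signature_size2: int = 56
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_cpgs", "n_snps", "n_celltypes_stage1",
                     "n_immune_subtypes", "chrom_length",
                     "signature_size1", "signature_size2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_mqtl_cpgs", "n_replicate_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("epi_fraction_mean", "fib_fraction_mean", "fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not -1.0 <= self.epi_fraction_twin_corr <= 1.0:
            raise ValueError("epi_fraction_twin_corr must lie in [-1, 1]")
        if self.n_mqtl_cpgs > self.n_cpgs:
            raise ValueError("n_mqtl_cpgs cannot exceed n_cpgs")
        if self.n_replicate_pairs > 2 * self.n_pairs:
            raise ValueError("cannot replicate more samples than exist")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        fam = np.atleast_1d(np.asarray(self.familial_corr, dtype=float))
        if fam.size not in (1, self.n_cpgs):
            raise ValueError("familial_corr must be scalar or length n_cpgs")
        if (fam < 0).any() or (fam >= 1).any():
            raise ParameterizationError(
                "familial_corr must lie in [0, 1): a pair-shared variance "
                "component cannot induce negative or perfect correlation"
            )
        if (fam > 0).any() and self.noise_sd == 0:
            raise ParameterizationError(
                "familial_corr > 0 with noise_sd = 0 is infeasible: the "
                "familial variance is scaled relative to the noise variance"
            )
        if self.noise_sd < 0 or self.imp_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def familial_corr_vector(self) -> np.ndarray:
        fam = np.atleast_1d(np.asarray(self.familial_corr, dtype=float))
        if fam.size == 1:
            fam = np.full(self.n_cpgs, fam[0])
        return fam


@dataclass
class GroundTruth:
    """Latent quantities of a generated cohort, for recovery tests.

    ``true_fractions``: sample × cell-type fractions (rows sum to 1).
    ``mqtl_map``: one row per planted effect (cpg_id, snp_id, effect).
    ``familial_component``: pair × CpG pair-shared latent deviations.
    """

    true_fractions: pd.DataFrame
    mqtl_map: pd.DataFrame
    familial_component: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.true_fractions.sum(axis=1).to_numpy()
        if np.abs(sums - 1.0).max(initial=0.0) > 1e-9:
            raise ValueError("true cell fractions must sum to 1 per sample")


@dataclass
class GenotypeSim:
    """Genotypes plus the latent per-pair hard calls and pair assignment."""

    table: GenotypeTable
    hard_calls: pd.DataFrame            # SNP × pair_id, values in {0, 1, 2}
    pair_of_individual: dict            # individual_id -> pair_id


@dataclass
class TwinCohort:
    """Everything `generate_twin_cohort` produces."""

    beta: BetaMatrix
    stats: DetectionStats
    genotypes: GenotypeTable
    sheet: pd.DataFrame
    truth: GroundTruth
    reference: ReferenceProfiles
    hard_genotypes: pd.DataFrame        # SNP × pair_id
    annotation: ProbeAnnotation


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _next_pow2(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


def _hadamard_block(n_types: int, size: int) -> np.ndarray:
    """(n_types × size) matrix of well-separated reference values.

    Rows 1..K of a Hadamard matrix (the all-ones row is skipped) are mapped
    to β ∈ {0.1, 0.9} and tiled column-wise.  Any two rows disagree in
    exactly half the positions of each full tile, so the pairwise mean
    |Δβ| over the block is 0.4 ≥ 0.3 by construction.
    """
    m = _next_pow2(n_types + 1)
    H = hadamard(m)
    cols = np.arange(size) % m
    return 0.5 + 0.4 * H[1 : n_types + 1][:, cols]


def signature_separation(profiles: pd.DataFrame, signature) -> float:
    """Minimum over cell-type pairs of the mean |Δβ| across signature CpGs."""
    sub = profiles.loc[list(signature)].to_numpy()
    k = sub.shape[1]
    seps = [
        np.abs(sub[:, i] - sub[:, j]).mean()
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return float(min(seps))


def _cpg_ids(config: SimConfig) -> list:
    ids = [f"cg{10000000 + i:08d}" for i in range(config.n_cpgs)]
    if config.n_celltypes_stage1 == 3:
        s1 = _effective_size(config.signature_size1, 3)
        ids[s1] = EIPEL_CPGS[0]
        ids[s1 + 1] = EIPEL_CPGS[1]
    return ids


def _effective_size(size: int, n_types: int) -> int:
    m = _next_pow2(n_types + 1)
    eff = (size // m) * m
    if eff < m:
        raise SizingError(
            f"signature size {size} cannot host {n_types} cell types "
            f"(needs at least {m} CpGs)"
        )
    return eff


@dataclass
class _ProfileBuild:
    reference: ReferenceProfiles
    full: pd.DataFrame            # CpG × (Epi, Fib, 7 sub-types)
    mqtl_cpgs: list
    mqtl_effects: np.ndarray


def _build_profiles(config: SimConfig) -> _ProfileBuild:
    if config.n_celltypes_stage1 != 3:
        raise ValueError(
            "the cohort model is defined for 3 stage-1 cell types "
            "(epithelial, fibroblast, immune)"
        )
    if config.n_immune_subtypes != len(IMMUNE_SUBTYPES):
        raise ValueError(f"the immune stage models {len(IMMUNE_SUBTYPES)} sub-types")
    rng = _rng(config, 1)
    n = config.n_cpgs
    s1 = _effective_size(config.signature_size1, 3)
    s2 = _effective_size(config.signature_size2, 7)
    n_sig = s1 + 2 + s2                      # +2 for the Eipel CpGs
    if n < n_sig + config.n_mqtl_cpgs:
        raise SizingError(
            f"n_cpgs={n} too small for disjoint signature sets ({n_sig}) "
            f"plus {config.n_mqtl_cpgs} mQTL CpGs"
        )
    ids = _cpg_ids(config)
    sig1 = ids[: s1 + 2]
    sig2 = ids[s1 + 2 : n_sig]

    full = np.empty((n, 9))

    # -- stage-1 signature: Epi/Fib/IC Hadamard-coded; sub-types share IC.
    block1 = _hadamard_block(3, s1)          # rows: Epi, Fib, IC
    full[:s1, 0] = block1[0]
    full[:s1, 1] = block1[1]
    full[:s1, 2:] = block1[2][:, None]
    # Eipel CpGs: one epithelial-high, one epithelial-low marker.
    full[s1, :] = 0.05
    full[s1, 0] = 0.95
    full[s1 + 1, :] = 0.95
    full[s1 + 1, 0] = 0.05

    # -- stage-2 signature: sub-types Hadamard-coded; Epi/Fib neutral at 0.5
    # so the epithelial contribution is absorbed by the fit intercept.
    block2 = _hadamard_block(7, s2)
    lo2, hi2 = s1 + 2, n_sig
    full[lo2:hi2, 0] = 0.5
    full[lo2:hi2, 1] = 0.5
    full[lo2:hi2, 2:] = block2.T

    # -- bulk CpGs: bimodal base level shared across cell types, with a
    # subset carrying epithelial-vs-immune offsets (cell-composition signal).
    n_rest = n - n_sig
    comp = rng.choice(3, size=n_rest, p=[0.3, 0.4, 0.3])
    base = np.where(
        comp == 0,
        rng.uniform(0.03, 0.15, n_rest),
        np.where(
            comp == 1,
            rng.uniform(0.15, 0.85, n_rest),
            rng.uniform(0.85, 0.97, n_rest),
        ),
    )
    rest_idx = np.arange(n_sig, n)
    # mQTL CpGs: mid-range base so the additive allele shift stays in [0,1];
    # excluded from cell-type offsets.
    mqtl_local = rng.choice(n_rest, size=config.n_mqtl_cpgs, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_mqtl_cpgs)
    base[mqtl_local] = np.where(
        signs > 0,
        rng.uniform(0.2, 0.5, config.n_mqtl_cpgs),
        rng.uniform(0.5, 0.8, config.n_mqtl_cpgs),
    )
    dev_mask = rng.random(n_rest) < 0.25
    dev_mask[mqtl_local] = False
    delta_e = np.where(dev_mask, rng.normal(0.0, 0.12, n_rest), 0.0)
    delta_i = np.where(dev_mask, rng.normal(0.0, 0.12, n_rest), 0.0)
    full[rest_idx, 0] = np.clip(base + delta_e, 0.01, 0.99)
    full[rest_idx, 1] = np.clip(base + delta_e, 0.01, 0.99)
    full[rest_idx, 2:] = np.clip(base + delta_i, 0.01, 0.99)[:, None]

    full_df = pd.DataFrame(full, index=ids, columns=list(ALL_CELLTYPES))
    stage2 = full_df[list(IMMUNE_SUBTYPES)].copy()
    stage1 = pd.DataFrame(
        {
            "Epi": full_df["Epi"],
            "Fib": full_df["Fib"],
            "IC": stage2.mean(axis=1),
        }
    )
    reference = ReferenceProfiles(
        stage1=stage1, stage2=stage2, signature1=list(sig1), signature2=list(sig2)
    )
    for frame, sig in ((stage1, sig1), (stage2, sig2)):
        if signature_separation(frame, sig) < 0.3:
            raise SizingError("signature construction failed the 0.3 separation bound")
    mqtl_cpgs = [ids[n_sig + k] for k in mqtl_local]
    return _ProfileBuild(
        reference=reference,
        full=full_df,
        mqtl_cpgs=mqtl_cpgs,
        mqtl_effects=signs * config.mqtl_effect_size,
    )


def generate_reference_profiles(config: SimConfig) -> ReferenceProfiles:
    """Stage-1 (Epi/Fib/IC) and stage-2 (7 leukocyte sub-types) mean-β
    profiles with disjoint signature-CpG sets.

    On signature CpGs any two cell types differ by ≥ 0.3 mean |Δβ| by
    construction; all means lie in [0, 1].
    """
    return _build_profiles(config).reference


def _hwe_pvalues(hard: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) Hardy–Weinberg test per SNP on hard calls.

    ``hard``: SNP × units matrix of genotypes in {0, 1, 2}, one unit per
    twin pair (co-twins are not independent draws).  Monomorphic SNPs
    return p = 1.
    """
    n = hard.shape[1]
    n2 = (hard == 2).sum(axis=1)
    n1 = (hard == 1).sum(axis=1)
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


def generate_genotypes(config: SimConfig, positions: np.ndarray | None = None) -> GenotypeSim:
    """Simulate per-pair genotypes and noisy per-individual dosages.

    For each SNP an allele frequency is drawn uniformly from
    ``config.maf_range`` and one hard genotype per twin pair is drawn under
    Hardy–Weinberg proportions; both co-twins inherit it unchanged (MZ
    identity).  Dosage = hard call + N(0, ``imp_noise_sd``) clipped to
    [0, 2], drawn independently per individual (imputation noise).
    Metadata (position, empirical MAF/MAC, HWE p from hard calls, dosage
    imputation r²) is populated per SNP.
    """
    rng = _rng(config, 2)
    n_snps, n_pairs = config.n_snps, config.n_pairs
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, n_snps)
    hard = rng.binomial(2, freq[:, None], size=(n_snps, n_pairs)).astype(float)

    pair_ids = [f"pair{i + 1:03d}" for i in range(n_pairs)]
    individuals = [f"{p}_{t}" for p in pair_ids for t in (1, 2)]
    dup = np.repeat(hard, 2, axis=1)
    noise = rng.normal(0.0, config.imp_noise_sd, size=dup.shape) if config.imp_noise_sd else 0.0
    dosages = np.clip(dup + noise, 0.0, 2.0)

    if positions is None:
        positions = np.sort(
            rng.integers(1, config.chrom_length - n_snps, n_snps)
        ) + np.arange(n_snps)
    positions = np.asarray(positions)
    order = np.argsort(positions, kind="stable")

    snp_ids = [f"snp{j + 1:07d}" for j in range(n_snps)]
    # empirical allele stats over analysis individuals (co-twins both counted)
    af = dup.mean(axis=1) / 2.0
    maf = np.minimum(af, 1 - af)
    mac = np.minimum(dup.sum(axis=1), 2 * len(individuals) - dup.sum(axis=1))
    hwe = _hwe_pvalues(hard)
    if config.imp_noise_sd:
        hc = dup - dup.mean(axis=1, keepdims=True)
        dc = dosages - dosages.mean(axis=1, keepdims=True)
        denom = np.sqrt((hc**2).sum(axis=1) * (dc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, ((hc * dc).sum(axis=1) / np.where(denom > 0, denom, 1.0)) ** 2, 0.0)
    else:
        r2 = np.ones(n_snps)

    meta = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "hwe_p": hwe,
            "mac": mac.astype(int),
            "imp_r2": r2,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    dosage_df = pd.DataFrame(dosages, index=meta.index, columns=individuals)
    hard_df = pd.DataFrame(hard, index=meta.index, columns=pair_ids)

    # store sorted by genomic position
    meta = meta.iloc[order]
    dosage_df = dosage_df.iloc[order]
    hard_df = hard_df.iloc[order]
    pair_of = {ind: ind.rsplit("_", 1)[0] for ind in individuals}
    return GenotypeSim(
        table=GenotypeTable(dosage_df, meta),
        hard_calls=hard_df,
        pair_of_individual=pair_of,
    )


def _epithelial_fractions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_pairs × 2) epithelial fractions, co-twin correlated.

    Gaussian copula on the logit scale: latent bivariate normal with the
    target correlation, pushed through logistic(mu + sd·z).
    """
    rho = config.epi_fraction_twin_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_pairs, method="svd")
    if config.epi_fraction_logit_sd == 0:
        return np.full((config.n_pairs, 2), config.epi_fraction_mean)
    mu = logit(np.clip(config.epi_fraction_mean, 1e-9, 1 - 1e-9))
    return expit(mu + config.epi_fraction_logit_sd * z)


def generate_twin_cohort(config: SimConfig) -> TwinCohort:
    """Generate a full synthetic twin cohort.

    Per sample, β = Σ_k fraction_k·profile_k + pair-shared familial
    deviation + mQTL allele shift + independent measurement noise, clipped
    to [0, 1].  The familial variance is ρ/(1−ρ)·noise_sd² so the twin
    correlation of the cell-free signal equals ``familial_corr``.
    Technical replicates re-measure the same biological sample with fresh
    noise and fresh detection failures.
    """
    build = _build_profiles(config)
    n, n_pairs = config.n_cpgs, config.n_pairs
    ids = list(build.full.index)

    # -- genomic coordinates -------------------------------------------------
    rng_coord = _rng(config, 3)
    cpg_pos = np.sort(
        rng_coord.integers(1, config.chrom_length - n, n)
    ) + np.arange(n)
    coords = pd.DataFrame({"chrom": config.chrom, "pos": cpg_pos}, index=pd.Index(ids, name="cpg_id"))

    # SNP positions: mQTL SNPs land within the cis window of their CpG
    # (distance log-uniform in [1, 10^6)); the rest are uniform.
    n_mqtl = config.n_mqtl_cpgs
    pos_of = coords["pos"]
    snp_positions = np.sort(
        rng_coord.integers(1, config.chrom_length - config.n_snps, config.n_snps)
    ) + np.arange(config.n_snps)
    snp_positions = snp_positions.astype(np.int64)
    mqtl_snp_rows = rng_coord.choice(config.n_snps, size=n_mqtl, replace=False)
    dist = np.floor(np.exp(rng_coord.uniform(0.0, np.log(1e6), n_mqtl))).astype(np.int64)
    dist = np.clip(dist, 1, 999_999)
    side = rng_coord.choice([-1, 1], size=n_mqtl)
    for k, cpg in enumerate(build.mqtl_cpgs):
        p = int(pos_of[cpg])
        cand = p + side[k] * dist[k]
        if cand < 1 or cand > config.chrom_length:
            cand = p - side[k] * dist[k]
        snp_positions[mqtl_snp_rows[k]] = int(np.clip(cand, 1, config.chrom_length))

    geno_sim = generate_genotypes(config, positions=snp_positions)
    # recover the ids assigned to the mQTL SNPs (generation order j -> snp id)
    mqtl_snp_ids = [f"snp{j + 1:07d}" for j in mqtl_snp_rows]

    # -- cell fractions ------------------------------------------------------
    rng_frac = _rng(config, 4)
    epi = _epithelial_fractions(config, rng_frac)          # pairs × 2
    pair_ids = list(geno_sim.hard_calls.columns)
    individuals = list(geno_sim.table.dosages.columns)
    epi_flat = epi.reshape(-1)                             # individual order
    fib = np.minimum(config.fib_fraction_mean, 1.0 - epi_flat)
    immune_total = 1.0 - epi_flat - fib
    if config.immune_dirichlet_conc is None:
        rel = np.tile(_IMMUNE_BASE_PROPS, (len(individuals), 1))
    else:
        alpha = config.immune_dirichlet_conc * _IMMUNE_BASE_PROPS
        rel = rng_frac.dirichlet(alpha, size=len(individuals))
    fractions = np.column_stack([epi_flat, fib, rel * immune_total[:, None]])
    frac_df = pd.DataFrame(fractions, index=individuals, columns=list(ALL_CELLTYPES))

    # -- latent signal per individual ---------------------------------------
    signal = build.full.to_numpy() @ fractions.T           # CpG × individuals

    rng_fam = _rng(config, 5)
    fam_rho = config.familial_corr_vector()
    fam_sd = np.sqrt(fam_rho / (1.0 - fam_rho)) * config.noise_sd
    familial = rng_fam.normal(0.0, 1.0, size=(n, n_pairs)) * fam_sd[:, None]
    signal = signal + np.repeat(familial, 2, axis=1)

    if n_mqtl:
        hard = geno_sim.hard_calls.loc[mqtl_snp_ids].to_numpy()   # mqtl × pairs
        rows = [ids.index(c) for c in build.mqtl_cpgs]
        shift = build.mqtl_effects[:, None] * hard                # mqtl × pairs
        signal[rows, :] += np.repeat(shift, 2, axis=1)

    # -- measurements (individuals + technical replicates) -------------------
    replicated = individuals[: config.n_replicate_pairs]
    sample_ids = list(individuals) + [f"{s}_rep2" for s in replicated]
    col_of = {s: i for i, s in enumerate(individuals)}
    src = [col_of[s.replace("_rep2", "")] for s in sample_ids]

    rng_noise = _rng(config, 6)
    meas = signal[:, src]
    if config.noise_sd:
        meas = meas + rng_noise.normal(0.0, config.noise_sd, size=meas.shape)
    beta_vals = np.clip(meas, 0.0, 1.0)
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=pd.Index(ids, name="cpg_id"), columns=sample_ids),
        coords,
    )

    # -- detection statistics -------------------------------------------------
    rng_fail = _rng(config, 7)
    shape = beta_vals.shape
    detp = rng_fail.uniform(0.0, 0.005, size=shape)
    beads = rng_fail.integers(5, 26, size=shape)
    zero = np.zeros(shape, dtype=bool)
    fail = rng_fail.random(shape) < config.fail_rate
    mode = rng_fail.integers(0, 3, size=shape)
    detp[fail & (mode == 0)] = rng_fail.uniform(0.011, 1.0, size=int((fail & (mode == 0)).sum()))
    beads[fail & (mode == 1)] = rng_fail.integers(0, 3, size=int((fail & (mode == 1)).sum()))
    zero[fail & (mode == 2)] = True
    idx, cols = beta.values.index, beta.values.columns
    stats = DetectionStats(
        detection_p=pd.DataFrame(detp, index=idx, columns=cols),
        bead_count=pd.DataFrame(beads, index=idx, columns=cols),
        zero_intensity=pd.DataFrame(zero, index=idx, columns=cols),
    )

    # -- sample sheet ----------------------------------------------------------
    rng_sheet = _rng(config, 8)
    age_of_pair = dict(zip(pair_ids, np.round(rng_sheet.uniform(1.0, 10.0, n_pairs), 1)))
    sex_of_pair = dict(
        zip(pair_ids, np.where(rng_sheet.random(n_pairs) < 0.58, "M", "F"))
    )
    rows = []
    for s in sample_ids:
        ind = s.replace("_rep2", "")
        pair, role = ind.rsplit("_", 1)
        rows.append(
            {
                "sample_id": s,
                "individual_id": ind,
                "pair_id": pair,
                "role": int(role),
                "replicate": 2 if s.endswith("_rep2") else 1,
                "age": age_of_pair[pair],
                "sex": sex_of_pair[pair],
                "platform": "EPIC",
            }
        )
    sheet = pd.DataFrame(rows)

    truth = GroundTruth(
        true_fractions=frac_df.loc[[individuals[i] for i in src]].set_axis(sample_ids),
        mqtl_map=pd.DataFrame(
            {"cpg_id": build.mqtl_cpgs, "snp_id": mqtl_snp_ids, "effect": build.mqtl_effects}
        ),
        familial_component=pd.DataFrame(familial.T, index=pair_ids, columns=ids),
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "multi_mapping": False,
                "snp_overlap": False,
                "autosomal": True,
            },
            index=idx,
        )
    )
    return TwinCohort(
        beta=beta,
        stats=stats,
        genotypes=geno_sim.table,
        sheet=sheet,
        truth=truth,
        reference=build.reference,
        hard_genotypes=geno_sim.hard_calls,
        annotation=annotation,
    )
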
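"""SNP filters, inverse normal transform, cis scan, permutations, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import chisquare, kstest, linregress

import twinmeth.mqtl as mqtl_mod
from twinmeth.containers import GenotypeTable, StructuralError
from twinmeth.mqtl import (
    DegenerateRankError,
    cis_scan,
    filter_snps,
    genotype_pcs,
    inverse_normal_transform,
    permutation_fdr,
    permute_pairs,
    summarize_mqtl,
    FDRResult,
)
from twinmeth.simulate import SimConfig, generate_twin_cohort
from twinmeth.workflows import run_mqtl_analysis


def _geno(dosages, pos=None, maf=0.3, hwe=0.5, mac=50, r2=0.99, chrom="1"):
    dosages = pd.DataFrame(
        np.asarray(dosages, dtype=float),
        index=[f"snp{i}" for i in range(len(dosages))],
    )
    dosages.columns = [f"i{j}" for j in range(dosages.shape[1])]
    n = len(dosages)
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else 1000 * (np.arange(n) + 1),
            "maf": maf if np.ndim(maf) else np.full(n, maf),
            "hwe_p": hwe if np.ndim(hwe) else np.full(n, hwe),
            "mac": mac if np.ndim(mac) else np.full(n, mac),
            "imp_r2": r2 if np.ndim(r2) else np.full(n, r2),
        },
        index=dosages.index,
    )
    return GenotypeTable(dosages, meta)


# ------------------------------------------------------------------ filters

def test_snp_filters_are_strict_and_attributed():
    geno = _geno(
        np.ones((6, 20)),
        maf=[0.005, 0.01, 0.3, 0.3, 0.3, 0.3],
        hwe=[0.5, 0.5, 1e-5, 0.5, 0.5, 0.5],
        mac=[50, 50, 50, 10, 50, 50],
        r2=[0.99, 0.99, 0.99, 0.99, 0.8, 0.99],
    )
    kept, removed = filter_snps(geno)
    assert list(kept.snp_ids) == ["snp5"]
    assert removed == {"maf": 2, "hwe_p": 1, "mac": 1, "imp_r2": 1}


def test_snp_filter_fixture_counts():
    rng = np.random.default_rng(0)
    maf = np.full(20, 0.25)
    maf[:3] = 0.005
    mac = np.full(20, 40)
    mac[3] = 5
    r2 = np.full(20, 0.95)
    r2[4] = 0.5
    geno = _geno(rng.uniform(0, 2, (20, 10)), maf=maf, mac=mac, r2=r2)
    kept, removed = filter_snps(geno)
    assert len(kept.snp_ids) == 15
    assert sum(removed.values()) == 5


def test_missing_metadata_column_rejected():
    geno = _geno(np.ones((2, 4)))
    geno.meta.drop(columns=["mac"], inplace=True)
    with pytest.raises(StructuralError):
        filter_snps(geno)


def test_recomputed_hwe_matches_oracle():
    rng = np.random.default_rng(1)
    hard = rng.binomial(2, 0.4, size=(30, 200)).astype(float)
    geno = _geno(hard)
    _, removed_meta = filter_snps(geno, hwe_p=0.9)           # metadata hwe = 0.5
    kept, _ = filter_snps(geno, hwe_p=1e-4, recompute_hwe=True)
    # oracle per SNP
    from scipy.stats import chi2 as chi2_dist

    for j, snp in enumerate(geno.snp_ids):
        g = hard[j]
        counts = np.array([(g == k).sum() for k in (0, 1, 2)], dtype=float)
        p = (2 * counts[2] + counts[1]) / (2 * len(g))
        exp = len(g) * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        stat = ((counts - exp) ** 2 / exp).sum()
        keep = chi2_dist.sf(stat, 1) > 1e-4
        assert (snp in set(kept.snp_ids)) == keep


# -------------------------------------------------- inverse normal transform

def test_int_closed_form_n5_padded():
    """First five order statistics follow the Blom formula exactly."""
    x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
    out = inverse_normal_transform(x)
    n = 10
    expected = ndtri((np.arange(1, 11) - 0.375) / (n + 0.25))
    assert np.allclose(out, expected, atol=1e-12)


def test_int_is_rank_invariant_under_permutation():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    perm = rng.permutation(50)
    out = inverse_normal_transform(x)
    out_perm = inverse_normal_transform(x[perm])
    assert np.allclose(np.sort(out), np.sort(out_perm))
    assert np.allclose(out[perm], out_perm)


def test_int_fixed_point_on_normal_quantiles():
    n = 200
    q = ndtri((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    assert np.allclose(inverse_normal_transform(q), q, atol=1e-6)


def test_int_handles_ties_and_degenerate_input():
    x = np.array([1.0, 1, 1, 2, 2, 3, 4, 5, 6, 7])
    out = inverse_normal_transform(x)
    assert out[0] == out[1] == out[2]
    with pytest.raises(DegenerateRankError):
        inverse_normal_transform(np.ones(12))
    with pytest.raises(ValueError):
        inverse_normal_transform(np.arange(5.0))


# ---------------------------------------------------------------- cis scan

def _random_scan_inputs(n_cpgs=50, n_snps=200, n_samples=86, missing=False, seed=3):
    rng = np.random.default_rng(seed)
    meth = pd.DataFrame(
        rng.normal(size=(n_cpgs, n_samples)),
        index=[f"cg{i:03d}" for i in range(n_cpgs)],
        columns=[f"i{j}" for j in range(n_samples)],
    )
    if missing:
        mask = rng.random(meth.shape) < 0.03
        meth = meth.mask(mask)
    coords = pd.DataFrame(
        {"chrom": "1", "pos": np.sort(rng.choice(10_000_000, n_cpgs, replace=False)) + 1},
        index=meth.index,
    )
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, (n_snps, 1)), (n_snps, n_samples))
    geno = _geno(dos.astype(float), pos=np.sort(rng.choice(10_000_000, n_snps, replace=False)) + 1)
    return meth, coords, geno


@pytest.mark.parametrize("missing", [False, True])
def test_cis_scan_matches_per_pair_regression_oracle(missing):
    meth, coords, geno = _random_scan_inputs(missing=missing)
    records = cis_scan(meth, geno, coords, window=1_000_000)
    assert len(records) > 500
    rng = np.random.default_rng(4)
    sample = records.sample(200, random_state=7)
    for _, row in sample.iterrows():
        y = meth.loc[row["cpg_id"]].to_numpy()
        x = geno.dosages.loc[row["snp_id"]].to_numpy()
        m = np.isfinite(y)
        res = linregress(x[m], y[m])
        assert row["beta"] == pytest.approx(res.slope, abs=1e-10)
        assert row["p_value"] == pytest.approx(res.pvalue, rel=1e-8, abs=1e-12)
        assert row["n"] == m.sum()


def test_cis_window_is_strict_and_monotone():
    meth = pd.DataFrame(
        np.random.default_rng(5).normal(size=(1, 20)),
        index=["cgX"], columns=[f"i{j}" for j in range(20)],
    )
    coords = pd.DataFrame({"chrom": "1", "pos": [2_000_000]}, index=["cgX"])
    pos = np.array([1_000_000, 1_000_001, 2_999_999, 3_000_000])
    geno = _geno(np.random.default_rng(6).binomial(2, 0.4, (4, 20)).astype(float), pos=pos)
    records = cis_scan(meth, geno, coords, window=1_000_000)
    # SNPs at exactly 1 Mb are excluded (strict <)
    assert set(records["snp_id"]) == {"snp1", "snp2"}
    wide = cis_scan(meth, geno, coords, window=2_000_000)
    assert set(records["snp_id"]) <= set(wide["snp_id"])
    assert (records["distance"] < 1_000_000).all()


def test_exact_linear_relation_floors_p():
    dosage = np.array([[0.0, 1, 2, 0, 1, 2, 0, 1, 2, 1, 0, 2]])
    meth = pd.DataFrame([0.1 * dosage[0]], index=["cg0"], columns=[f"i{j}" for j in range(12)])
    coords = pd.DataFrame({"chrom": "1", "pos": [500]}, index=["cg0"])
    geno = _geno(dosage, pos=[600])
    rec = cis_scan(meth, geno, coords)
    assert rec.loc[0, "beta"] == pytest.approx(0.1, abs=1e-12)
    assert rec.loc[0, "p_value"] == 1e-300


def test_zero_variance_dosage_skipped():
    meth = pd.DataFrame(
        np.random.default_rng(7).normal(size=(1, 10)),
        index=["cg0"], columns=[f"i{j}" for j in range(10)],
    )
    coords = pd.DataFrame({"chrom": "1", "pos": [500]}, index=["cg0"])
    geno = _geno(np.vstack([np.ones(10), np.random.default_rng(8).binomial(2, 0.5, 10)]),
                 pos=[600, 700])
    rec = cis_scan(meth, geno, coords)
    assert list(rec["snp_id"]) == ["snp1"]


def test_null_pvalues_uniform_at_scale():
    """With independent unrelated samples, raw scan p-values are uniform."""
    meth, coords, geno = _random_scan_inputs(n_cpgs=100, n_snps=500, n_samples=80, seed=9)
    records = cis_scan(meth, geno, coords, window=10_000_000)
    assert len(records) >= 50_000
    assert kstest(records["p_value"], "uniform").pvalue > 0.01


# ------------------------------------------------------------- permutations

def test_pair_permutation_is_bijective():
    perm = permute_pairs([f"p{i}" for i in range(7)], rng=3)
    order = perm.column_order()
    assert sorted(order) == list(range(14))
    mapping = perm.mapping()
    assert sorted(mapping.values()) == sorted(mapping.keys())


def test_pair_permutation_uniform_over_all_orderings():
    rng = np.random.default_rng(11)
    from math import factorial

    counts = {}
    n_draws = 6000
    for _ in range(n_draws):
        perm = permute_pairs(list("abcde"), rng)
        counts[tuple(perm.perm)] = counts.get(tuple(perm.perm), 0) + 1
    assert len(counts) == factorial(5)
    observed = np.array(list(counts.values()))
    assert chisquare(observed).pvalue > 0.001


def test_incomplete_pairs_rejected():
    sheet = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "individual_id": ["a", "b", "c"],
            "pair_id": ["p1", "p1", "p2"],
            "role": [1, 2, 1],
            "replicate": [1, 1, 1],
            "age": 5.0,
            "sex": "F",
            "platform": "EPIC",
        }
    )
    with pytest.raises(StructuralError):
        permute_pairs(sheet, rng=0)


def test_identity_permutation_reproduces_observed_scan(monkeypatch):
    """If every 'permutation' is the identity, no threshold can be attained."""
    config = SimConfig(n_pairs=20, n_cpgs=200, n_snps=300, n_mqtl_cpgs=20,
                       fail_rate=0.0, n_replicate_pairs=0, seed=31)
    cohort = generate_twin_cohort(config)

    def identity_permutation(pairs, rng):
        pairs = list(pairs)
        return mqtl_mod.PairPermutation(pairs, np.arange(len(pairs)))

    monkeypatch.setattr(mqtl_mod, "permute_pairs", identity_permutation)
    result = permutation_fdr(
        cohort.beta.values, cohort.genotypes, cohort.sheet,
        cpg_coords=cohort.beta.coords, n_perm=3, seed=1,
    )
    assert result.status == "no_threshold"


def test_fdr_threshold_monotone_in_target():
    config = SimConfig(n_pairs=30, n_cpgs=250, n_snps=500, n_mqtl_cpgs=40,
                       fail_rate=0.0, n_replicate_pairs=0, seed=41)
    cohort = generate_twin_cohort(config)
    thresholds = []
    for fdr in (0.10, 0.05, 0.01):
        res = permutation_fdr(
            cohort.beta.values, cohort.genotypes, cohort.sheet,
            cpg_coords=cohort.beta.coords, n_perm=5, fdr=fdr, seed=2,
        )
        assert res.status == "ok"
        thresholds.append(res.logp_threshold)
    assert thresholds[0] >= thresholds[1] >= thresholds[2]


def test_permutation_preserves_within_pair_identity():
    """Under any pair permutation both co-twins keep a common genotype pair."""
    rng = np.random.default_rng(13)
    pairs = [f"p{i}" for i in range(10)]
    for _ in range(50):
        perm = permute_pairs(pairs, rng)
        order = perm.column_order()
        for i in range(10):
            a, b = order[2 * i], order[2 * i + 1]
            assert b == a + 1 and a % 2 == 0  # samples move as intact pair blocks


# ---------------------------------------------------------------- summaries

def _records_fixture():
    rows = [
        # cpg, snp, dist, logp
        ("cgA", "s1", 18_000, np.log(1e-9)),
        ("cgB", "s1", 5_000, np.log(1e-8)),
        ("cgB", "s2", 50_000, np.log(1e-8)),   # tied min p, larger distance
        ("cgB", "s3", 70_000, np.log(1e-5)),   # not significant
        ("cgC", "s4", 200_000, np.log(1e-3)),  # not significant
    ]
    rec = pd.DataFrame(rows, columns=["cpg_id", "snp_id", "distance", "logp"])
    rec["p_value"] = np.exp(rec["logp"])
    rec["chrom"] = "1"
    return rec


def test_summary_counts_and_tie_break():
    rec = _records_fixture()
    fdr = FDRResult(fdr=0.05, n_perm=10, status="ok",
                    p_threshold=1e-6, logp_threshold=np.log(1e-6))
    summary = summarize_mqtl(rec, fdr)
    assert summary.n_sig_associations == 3
    assert summary.n_sig_cpgs == 2
    assert summary.n_sig_snps == 2
    # cgB's two SNPs tie on p: the closer one (5 kb) defines the distance
    assert summary.distance_to_top_snp["cgB"] == 5_000
    assert summary.distance_to_top_snp["cgA"] == 18_000
    assert summary.median_distance_bp == pytest.approx(11_500)
    assert summary.snps_per_cpg["max"] == 2


def test_singleton_summary_median_distance():
    rec = _records_fixture().iloc[:1]
    fdr = FDRResult(fdr=0.05, n_perm=10, status="ok",
                    p_threshold=1e-6, logp_threshold=np.log(1e-6))
    summary = summarize_mqtl(rec, fdr)
    assert summary.median_distance_bp == 18_000


def test_summary_requires_threshold():
    with pytest.raises(ValueError):
        summarize_mqtl(_records_fixture(), FDRResult(fdr=0.05, n_perm=10, status="no_threshold"))


# ------------------------------------------------------------- genotype PCs

def test_genotype_pcs_reconstruct_gram_matrix():
    rng = np.random.default_rng(17)
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, (100, 1)), (100, 12)).astype(float)
    geno = _geno(dos)
    pcs = genotype_pcs(geno, n_pcs=12)
    X = dos - dos.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    Z = X[sd > 0] / sd[sd > 0][:, None]
    K = Z.T @ Z / Z.shape[0]
    assert np.allclose(pcs.to_numpy() @ pcs.to_numpy().T, K, atol=1e-8)
    again = genotype_pcs(geno, n_pcs=12)
    pd.testing.assert_frame_equal(pcs, again)


# ------------------------------------------------------ end-to-end pipeline

def test_pipeline_detects_planted_effects_and_recovers_slopes():
    config = SimConfig(n_pairs=43, n_cpgs=300, n_snps=1500, n_mqtl_cpgs=50, seed=51)
    cohort = generate_twin_cohort(config)
    analysis = run_mqtl_analysis(
        cohort.beta, cohort.sheet, cohort.genotypes,
        reference=cohort.reference, seed=3,
    )
    fr = analysis.fdr_result
    assert fr.status == "ok"
    truth = set(cohort.truth.mqtl_map["cpg_id"])
    sig = set(
        analysis.records.loc[analysis.records["logp"] <= fr.logp_threshold, "cpg_id"]
    )
    assert len(truth & sig) >= 0.9 * len(truth)
    # slope recovery on the β scale (no rank normalization)
    plain = run_mqtl_analysis(
        cohort.beta, cohort.sheet, cohort.genotypes,
        reference=cohort.reference, seed=3, rank_normalize=False, n_perm=2,
    )
    rec = plain.records.merge(cohort.truth.mqtl_map, on=["cpg_id", "snp_id"])
    assert len(rec) >= 45
    assert (rec["beta"] - rec["effect"]).abs().mean() < 0.03
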
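"""Residualization, twin correlations, probe-set tests, within-pair differences."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from twinmeth.containers import StructuralError, twin_columns
from twinmeth.simulate import SimConfig, generate_twin_cohort
from twinmeth.twin import (
    CollinearityError,
    compare_probe_sets,
    label_cpgs_by_bed,
    pair_difference,
    replicate_diff_reproducibility,
    replicate_pair_differences,
    residualize,
    twin_correlations,
    within_pair_differences,
)
from twinmeth.workflows import adjust_for_cell_composition, estimate_cell_fractions

from conftest import make_beta


def _sheet(n_pairs, reps=()):
    rows = []
    for p in range(n_pairs):
        for role in (1, 2):
            ind = f"pair{p:03d}_{role}"
            rows.append(
                dict(sample_id=ind, individual_id=ind, pair_id=f"pair{p:03d}",
                     role=role, replicate=1, age=5.0, sex="F", platform="EPIC")
            )
            if ind in reps:
                rows.append(
                    dict(sample_id=f"{ind}_rep2", individual_id=ind,
                         pair_id=f"pair{p:03d}", role=role, replicate=2,
                         age=5.0, sex="F", platform="EPIC")
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- residualize

def test_residuals_zero_when_beta_is_exact_function_of_covariate():
    rng = np.random.default_rng(0)
    epi = rng.uniform(0.5, 1.0, 30)
    values = pd.DataFrame(
        [0.3 + 0.5 * epi, 0.1 + 0.2 * epi],
        index=["cgA", "cgB"],
        columns=[f"s{i}" for i in range(30)],
    )
    covars = pd.DataFrame({"epi": epi}, index=values.columns)
    resid = residualize(values, covars)
    assert np.abs(resid.to_numpy()).max() < 1e-10


def test_orthogonal_covariate_leaves_centered_values():
    rng = np.random.default_rng(1)
    y = rng.uniform(size=40)
    x = rng.uniform(size=40)
    x = x - x.mean()
    y_perp = y - y.mean()
    y_perp = y_perp - (y_perp @ x) / (x @ x) * x  # orthogonalize to x
    values = pd.DataFrame([y_perp + 0.5], index=["cg"], columns=[f"s{i}" for i in range(40)])
    covars = pd.DataFrame({"x": x}, index=values.columns)
    resid = residualize(values, covars)
    assert np.abs(resid.to_numpy()[0] - y_perp).max() < 1e-10


def test_residualize_matches_normal_equations_oracle():
    rng = np.random.default_rng(2)
    n = 20
    values = pd.DataFrame(
        rng.uniform(size=(15, n)), index=[f"cg{i}" for i in range(15)],
        columns=[f"s{i}" for i in range(n)],
    )
    values.iloc[3, 5] = np.nan
    values.iloc[8, [0, 11]] = np.nan
    covars = pd.DataFrame(
        rng.normal(size=(n, 3)), index=values.columns, columns=list("abc")
    )
    resid = residualize(values, covars)
    for i in range(15):
        row = values.iloc[i].to_numpy()
        mask = np.isfinite(row)
        X = np.column_stack([np.ones(mask.sum()), covars.to_numpy()[mask]])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ row[mask])
        expected = row[mask] - X @ beta_hat
        assert np.abs(resid.iloc[i].to_numpy()[mask] - expected).max() < 1e-10
        assert resid.iloc[i].isna().to_numpy()[~mask].all()


def test_residuals_orthogonal_to_covariates(small_cohort):
    from twinmeth.workflows import cell_covariates, full_rank_covariates

    fractions = estimate_cell_fractions(small_cohort.beta, small_cohort.reference)
    resid = adjust_for_cell_composition(small_cohort.beta, fractions)
    C = full_rank_covariates(cell_covariates(fractions).loc[resid.columns])
    R = resid.to_numpy()
    complete = np.isfinite(R).all(axis=1)
    dots = R[complete] @ (C - C.mean()) / len(C)
    assert np.abs(dots.to_numpy()).max() < 1e-8


def test_collinear_covariates_raise():
    values = pd.DataFrame(
        np.random.default_rng(3).uniform(size=(4, 10)),
        columns=[f"s{i}" for i in range(10)],
    )
    x = np.arange(10.0)
    covars = pd.DataFrame({"a": x, "b": 2 * x + 1}, index=values.columns)
    with pytest.raises(CollinearityError):
        residualize(values, covars)


# ---------------------------------------------------------- twin correlations

def test_identical_cotwins_give_unit_correlation():
    sheet = _sheet(6)
    rng = np.random.default_rng(4)
    per_pair = rng.uniform(size=(10, 6))
    values = pd.DataFrame(
        np.repeat(per_pair, 2, axis=1),
        index=[f"cg{i}" for i in range(10)],
        columns=sheet["sample_id"],
    )
    table = twin_correlations(values, sheet)
    assert np.allclose(table["r"], 1.0)
    assert (table["n_pairs_used"] == 6).all()


def test_too_few_pairs_reported_with_reason():
    sheet = _sheet(4)
    values = pd.DataFrame(
        np.random.default_rng(5).uniform(size=(2, 8)), columns=sheet["sample_id"]
    )
    values.iloc[0, [0, 2, 4]] = np.nan  # only 1 complete pair left at cg 0
    table = twin_correlations(values, sheet)
    assert table.iloc[0]["reason"] == "too_few_pairs"
    assert np.isnan(table.iloc[0]["r"])
    assert table.iloc[1]["reason"] == ""


def test_familial_correlation_recovered_at_moderate_sample_size():
    config = SimConfig(
        n_pairs=100, n_cpgs=200, n_snps=10, n_mqtl_cpgs=0,
        epi_fraction_logit_sd=0.0, immune_dirichlet_conc=None,
        familial_corr=0.6, fail_rate=0.0, n_replicate_pairs=0, seed=19,
    )
    cohort = generate_twin_cohort(config)
    table = twin_correlations(cohort.beta.values, cohort.sheet)
    assert abs(table["r"].mean() - 0.6) < 0.05


def test_cell_composition_confounding_removed_by_residualization():
    """Twin resemblance coming only from shared cell fractions disappears
    after adjustment (the 0.30 → 0.21 mechanism, taken to its null limit)."""
    config = SimConfig(
        n_pairs=200, n_cpgs=300, n_snps=10, n_mqtl_cpgs=0,
        familial_corr=0.0, epi_fraction_twin_corr=0.9,
        fail_rate=0.0, n_replicate_pairs=0, seed=23,
    )
    cohort = generate_twin_cohort(config)
    before = twin_correlations(cohort.beta.values, cohort.sheet)["r"].mean()
    resid = adjust_for_cell_composition(
        cohort.beta, cohort.truth.true_fractions
    )
    after = twin_correlations(resid, cohort.sheet)["r"].mean()
    assert after < before
    assert after <= 0.05


def test_double_entry_is_label_invariant():
    sheet = _sheet(30)
    rng = np.random.default_rng(6)
    values = pd.DataFrame(
        rng.uniform(size=(20, 60)), columns=sheet["sample_id"]
    )
    # swap the arbitrary twin-1/twin-2 labels for a subset of pairs
    swapped = sheet.copy()
    flip = swapped["pair_id"].isin([f"pair{p:03d}" for p in range(0, 30, 2)])
    swapped.loc[flip, "role"] = 3 - swapped.loc[flip, "role"]
    de1 = twin_correlations(values, sheet, double_entry=True)["r"]
    de2 = twin_correlations(values, swapped, double_entry=True)["r"]
    assert np.allclose(de1, de2)
    se1 = twin_correlations(values, sheet)["r"]
    se2 = twin_correlations(values, swapped)["r"]
    assert not np.allclose(se1, se2)  # single entry depends on the labeling


# ------------------------------------------------------------ probe-set test

def test_probe_set_comparison_null_is_calibrated():
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(200):
        r = rng.normal(0.2, 0.1, 100)
        table = pd.DataFrame({"r": r}, index=[f"cg{i}" for i in range(100)])
        res = compare_probe_sets(table, table.index[:50], table.index[50:])
        pvals.append(res.p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_probe_set_comparison_detects_shift():
    rng = np.random.default_rng(8)
    r = np.concatenate([rng.normal(0.2, 0.1, 1000), rng.normal(0.3, 0.1, 1000)])
    table = pd.DataFrame({"r": r}, index=[f"cg{i}" for i in range(2000)])
    res = compare_probe_sets(table, table.index[:1000], table.index[1000:])
    assert res.p_value < 1e-6
    assert res.mean_b - res.mean_a == pytest.approx(0.1, abs=0.02)


def test_probe_set_overlap_rejected():
    table = pd.DataFrame({"r": np.linspace(0, 1, 40)}, index=[f"cg{i}" for i in range(40)])
    with pytest.raises(ValueError, match="overlap"):
        compare_probe_sets(table, table.index[:25], table.index[20:])


# ------------------------------------------------------- within-pair differences

def test_within_pair_count_uses_strict_threshold():
    sheet = _sheet(1)
    t1 = np.array([0.80, 0.70, 0.05, 0.50])
    t2 = t1 - np.array([0.31, 0.30, -0.35, 0.10])
    values = pd.DataFrame(
        np.column_stack([t1, t2]), index=[f"cg{i}" for i in range(4)],
        columns=sheet["sample_id"],
    )
    diffs = within_pair_differences(values, sheet, threshold=0.3)
    d = diffs["pair000"]
    assert d.n_large == 2  # 0.30 is not counted: strict inequality
    assert np.allclose(d.delta, [0.31, 0.30, -0.35, 0.10])


def test_identical_cotwins_have_zero_large_differences():
    sheet = _sheet(2)
    col = np.random.default_rng(9).uniform(size=50)
    values = pd.DataFrame(
        np.column_stack([col, col, col, col]), columns=sheet["sample_id"]
    )
    diffs = within_pair_differences(values, sheet)
    assert all(d.n_large == 0 for d in diffs.values())


def test_planted_discordance_recovered_exactly():
    sheet = _sheet(1)
    rng = np.random.default_rng(10)
    base = rng.uniform(0.3, 0.6, 500)
    other = base.copy()
    planted = rng.choice(500, 50, replace=False)
    other[planted] += 0.35
    values = pd.DataFrame(
        np.column_stack([base, np.clip(other, 0, 1)]), columns=sheet["sample_id"]
    )
    diffs = within_pair_differences(values, sheet)
    assert diffs["pair000"].n_large == 50
    assert set(np.nonzero(diffs["pair000"].exceed.to_numpy())[0]) == set(planted)


def test_count_monotone_in_threshold():
    sheet = _sheet(3)
    rng = np.random.default_rng(11)
    values = pd.DataFrame(rng.uniform(size=(300, 6)), columns=sheet["sample_id"])
    counts = []
    for thr in (0.1, 0.2, 0.3, 0.5):
        diffs = within_pair_differences(values, sheet, threshold=thr)
        counts.append([d.n_large for d in diffs.values()])
    for lo, hi in zip(counts[1:], counts[:-1]):
        assert all(a <= b for a, b in zip(lo, hi))


# ------------------------------------------------------ replicate reproducibility

def test_identical_measures_have_full_overlap():
    delta = pd.Series(
        [0.5, -0.4, 0.0, 0.2], index=[f"cg{i}" for i in range(4)]
    )
    diffs = [
        pair_difference(
            pd.DataFrame({"a": delta + 0.3, "b": pd.Series(0.3, index=delta.index)}),
            "a", "b", pair_id=f"m{i}",
        )
        for i in range(2)
    ]
    # same underlying samples → not independent; force distinct ids
    diffs[1].sample_a, diffs[1].sample_b = "a2", "b2"
    overlap = replicate_diff_reproducibility(diffs)
    assert overlap.n_union == overlap.n_intersection_all == 2
    assert overlap.correlations.iloc[0, 1] == pytest.approx(1.0)


def test_planted_union_and_intersection_structure():
    """Four measures engineered to show 205 union CpGs, 11 in all four."""
    rng = np.random.default_rng(12)
    n = 2000
    idx = pd.Index([f"cg{i:05d}" for i in range(n)])
    base = np.zeros(n)
    always = rng.choice(n, 11, replace=False)
    rest = np.setdiff1d(np.arange(n), always)
    onceers = rng.choice(rest, 194, replace=False)
    deltas = []
    for m in range(4):
        d = base.copy()
        d[always] = 0.6
        d[onceers[m::4]] = 0.5  # each extra CpG exceeds in exactly one measure
        deltas.append(pd.Series(d, index=idx))
    diffs = []
    for m, d in enumerate(deltas):
        wpd = pair_difference(
            pd.DataFrame({"x": d.clip(0, 1), "y": 0.0}, index=idx), "x", "y",
            pair_id=f"m{m}",
        )
        wpd.sample_a, wpd.sample_b = f"a{m}", f"b{m}"
        diffs.append(wpd)
    overlap = replicate_diff_reproducibility(diffs)
    assert overlap.n_union == 205
    assert overlap.n_intersection_all == 11
    assert overlap.venn_counts["1111"] == 11
    assert sum(overlap.venn_counts.values()) == 205


def test_independent_noise_measures_uncorrelated_on_union():
    rng = np.random.default_rng(13)
    idx = pd.Index([f"cg{i}" for i in range(5000)])
    diffs = []
    for m in range(4):
        d = pd.Series(rng.normal(0, 0.15, 5000), index=idx)
        wpd = pair_difference(
            pd.DataFrame({"x": 0.5 + d.clip(-0.5, 0.5), "y": 0.5}, index=idx),
            "x", "y", pair_id=f"m{m}",
        )
        wpd.sample_a, wpd.sample_b = f"a{m}", f"b{m}"
        diffs.append(wpd)
    overlap = replicate_diff_reproducibility(diffs)
    off = [
        overlap.correlations.iloc[i, j]
        for i in range(4) for j in range(i + 1, 4)
    ]
    assert max(abs(np.array(off))) < 0.1
    assert len(overlap.independent_pairs) == 6  # all pairs use distinct samples


def test_replicate_pair_differences_structure(small_cohort):
    sheet = small_cohort.sheet
    diffs = replicate_pair_differences(small_cohort.beta, sheet, "pair001")
    assert len(diffs) == 4  # 2 replicates per co-twin → 2×2 measures
    overlap = replicate_diff_reproducibility(diffs)
    assert len(overlap.independent_pairs) == 2  # d11–d22 and d12–d21
    assert overlap.n_intersection_all <= overlap.n_union


def test_mismatched_universes_rejected():
    a = pair_difference(pd.DataFrame({"x": [0.9, 0.1], "y": [0.1, 0.1]}), "x", "y")
    b = pair_difference(
        pd.DataFrame({"x": [0.9, 0.1, 0.5], "y": [0.1, 0.1, 0.5]}), "x", "y"
    )
    with pytest.raises(StructuralError):
        replicate_diff_reproducibility([a, b])


# -------------------------------------------------------------- BED overlap

def test_bed_overlap_coordinate_convention(tmp_path):
    bed = tmp_path / "regions.bed"
    bed.write_text("1\t10\t20\tregion1\n2\t0\t5\tregion2\n")
    coords = pd.DataFrame(
        {"chrom": ["1", "1", "1", "1", "2"], "pos": [10, 11, 20, 21, 3]},
        index=[f"cg{i}" for i in range(5)],
    )
    flags = label_cpgs_by_bed(coords, bed)
    # BED [10,20) covers 1-based positions 11..20
    assert flags.tolist() == [False, True, True, False, True]
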
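"""Binning, KS test (against brute force), medians, correlations, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_ks
from temir.stratstats import (
    SiteFilter,
    bin_medians,
    correlations,
    ks_two_sample,
    plot_cdf,
    quantile_bins,
    stratified_comparison,
)
from temir.targets import classify_targets


def test_quantile_bins_basic():
    assert list(quantile_bins([1, 2, 3, 4], 4)) == [0, 1, 2, 3]
    assert list(quantile_bins([3, 1, 4, 2], 2)) == [1, 0, 1, 0]


def test_quantile_bins_partition_and_balance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=103)
    for k in (2, 4, 5):
        bins = quantile_bins(x, k)
        sizes = np.bincount(bins, minlength=k)
        assert sizes.sum() == x.size  # every value in exactly one bin
        assert sizes.max() - sizes.min() <= 1


def test_quantile_bins_median_ties_go_low():
    bins = quantile_bins([1.0, 2.0, 2.0, 3.0], 2)
    assert list(bins) == [0, 0, 0, 1]


def test_quantile_bins_errors():
    with pytest.raises(ValueError, match="identical"):
        quantile_bins([5.0, 5.0, 5.0], 2)
    with pytest.raises(ValueError):
        quantile_bins([1.0], 2)


@pytest.mark.parametrize(
    "x,y,expected_d",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2], [3, 4], 1.0),
        ([1, 3], [2, 4], 0.5),
    ],
)
def test_ks_analytic_examples(x, y, expected_d):
    d, p = ks_two_sample(x, y)
    assert d == pytest.approx(expected_d)
    assert 0 <= p <= 1


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


def test_ks_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        nx, ny = rng.integers(1, 51, size=2)
        x = rng.normal(size=nx)
        y = rng.normal(loc=rng.uniform(-1, 1), size=ny)
        if rng.random() < 0.3:  # force ties
            x = np.round(x)
            y = np.round(y)
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(brute_force_ks(x, y))


def test_ks_asymptotic_p_formula():
    from scipy.special import kolmogorov

    rng = np.random.default_rng(1)
    x, y = rng.normal(size=80), rng.normal(0.3, size=120)
    d, p = ks_two_sample(x, y)
    en = 80 * 120 / 200
    assert p == pytest.approx(float(kolmogorov(np.sqrt(en) * d)))


def test_ks_permutation_fallback_close_to_asymptotic():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=25), rng.normal(0.8, size=25)
    d_a, p_a = ks_two_sample(x, y, method="asymp")
    d_p, p_p = ks_two_sample(x, y, method="permutation", n_resamples=2000, seed=0)
    assert d_a == d_p
    assert p_p == pytest.approx(p_a, abs=0.05)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(-5, 5), min_size=1, max_size=30),
    st.lists(st.integers(-5, 5), min_size=1, max_size=30),
)
def test_ks_statistic_properties(xs, ys):
    d, p = ks_two_sample(xs, ys)
    assert 0.0 <= d <= 1.0
    assert 0.0 <= p <= 1.0
    assert d == pytest.approx(brute_force_ks(xs, ys))
    d_sym, _ = ks_two_sample(ys, xs)
    assert d == pytest.approx(d_sym)


def test_bin_medians():
    fc = pd.Series([-1.0, 0.0, 1.0, 2.0], index=list("abcd"))
    med = bin_medians(fc, [0, 0, 0, 1])
    assert med[0] == pytest.approx(0.0)
    med = bin_medians(fc, [0, 0, 1, 1])
    assert med[0] == pytest.approx(-0.5)  # even n: mean of middle two


def test_correlations_basic():
    x = np.arange(1, 11, dtype=float)
    res = correlations(x, 2 * x + 1)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.spearman_rs == pytest.approx(1.0)
    res = correlations(x, x**2)
    assert res.spearman_rs == pytest.approx(1.0)
    assert res.pearson_r < 1.0
    with pytest.raises(ValueError, match="zero-variance"):
        correlations(x, np.ones(10))


def test_correlations_null():
    rng = np.random.default_rng(8)
    res = correlations(rng.normal(size=10000), rng.normal(size=10000))
    assert abs(res.pearson_r) < 0.1


def _toy_records_and_annotation():
    rng = np.random.default_rng(17)
    n = 400
    te = rng.lognormal(0, 1, n)
    is_target = np.arange(n) < 200
    fc = rng.normal(0, 0.1, n) - np.where(is_target, 0.5, 0.0)
    records = pd.DataFrame(
        {"fc_rpf": fc, "fc_rna": fc, "te": te},
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )
    ann = pd.DataFrame(
        {
            "n_8mer": np.where(is_target & (np.arange(n) % 2 == 0), 1, 0),
            "n_7mer-m8": np.where(is_target & (np.arange(n) % 2 == 1), 2, 0),
            "n_7mer-a1": 0,
            "n_6mer": 0,
        },
        index=records.index,
    )
    ann["n_sites"] = ann.sum(axis=1)
    ann["best_type"] = np.where(
        ann["n_8mer"] > 0, "8mer", np.where(ann["n_7mer-m8"] > 0, "7mer-m8", "none")
    )
    return records, ann


def test_stratified_comparison_structure():
    records, ann = _toy_records_and_annotation()
    res = stratified_comparison(records, ann, assay="RPF", binning="quartiles")
    assert [b.label for b in res.bins] == ["Low", "Med.Low", "Med.High", "High"]
    assert sum(b.n for b in res.bins) == res.all_targets.n == 200
    assert res.background.n == 200
    assert len(res.pairwise_ks) == 6 + 1  # all quartile pairs + targets-vs-background
    for (a, b), (d, p) in res.pairwise_ks.items():
        assert 0 <= d <= 1 and 0 <= p <= 1
    # targets are repressed relative to the no-site background
    d, p = res.pairwise_ks[("All targets", "No site")]
    assert p < 1e-6


def test_stratified_site_filter_selects_best_type():
    records, ann = _toy_records_and_annotation()
    res = stratified_comparison(
        records, ann, site_filter=SiteFilter(best_types=["8mer"]), binning="median"
    )
    assert res.all_targets.n == int((ann["best_type"] == "8mer").sum())
    with pytest.raises(ValueError, match="site filter"):
        stratified_comparison(
            records,
            ann,
            site_filter=SiteFilter(best_types=["8mer"], min_sites=5),
        )


def test_stratified_external_te_override():
    records, ann = _toy_records_and_annotation()
    te_true = pd.Series(
        np.linspace(1, 2, len(records)), index=records.index, name="te"
    )
    res = stratified_comparison(records, ann, binning="median", te=te_true)
    # override TE is monotone in index; first 100 targets land in the low bin
    assert res.bins[0].n == res.bins[1].n == 100


def test_plot_cdf_writes_file(tmp_path):
    records, ann = _toy_records_and_annotation()
    res = stratified_comparison(records, ann, binning="median")
    out = tmp_path / "cdf.png"
    plot_cdf(res, out)
    assert out.stat().st_size > 0


def test_stratified_on_simulation_round_trip(small_sim, small_records, mirna):
    """Site-filtered target counts equal the planted composition."""
    tx, truth = small_sim["tx"], small_sim["truth"]
    ann = classify_targets(tx["utr3"].to_dict(), mirna)
    # per-gene detected counts equal planted truth exactly
    planted = truth.sites.groupby("gene_id").size()
    detected = ann.loc[ann["n_sites"] > 0, "n_sites"]
    pd.testing.assert_series_equal(
        planted.sort_index(), detected.sort_index(), check_names=False
    )
    eight_only = SiteFilter(best_types=["8mer"])
    n_8mer_targets = len(
        records_idx := small_records.index.intersection(eight_only.apply(ann))
    )
    res = stratified_comparison(
        small_records, ann, binning="median", site_filter=eight_only
    )
    assert res.all_targets.n == n_8mer_targets
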
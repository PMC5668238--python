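"""Generator contracts: determinism, planted truth, effect model, conservation."""

import numpy as np
import pandas as pd
import pytest

from temir.expression import read_expression_table
from temir.simdata import (
    ParameterError,
    SimParams,
    make_transcriptome,
    plant_sites,
    read_sequences,
    read_truth,
    simulate,
    simulate_experiment,
    write_fixture,
)
from temir.targets import find_seed_sites


def test_determinism_under_fixed_seed(mirna):
    p = SimParams(n_genes=10, seed=1)
    a = make_transcriptome(p)
    b = make_transcriptome(p)
    pd.testing.assert_frame_equal(a, b)
    tx1, t1, tr1 = simulate(p, mirna)
    tx2, t2, tr2 = simulate(p, mirna)
    pd.testing.assert_frame_equal(tx1, tx2)
    for key in t1:
        pd.testing.assert_frame_equal(t1[key].data, t2[key].data)
    pd.testing.assert_frame_equal(tr1.genes, tr2.genes)


def test_cds_structure_and_degenerate_length_range():
    p = SimParams(
        n_genes=30, seed=2, length_params={"utr5": (50, 60), "cds": (300, 300), "utr3": (100, 120)}
    )
    tx = make_transcriptome(p)
    assert (tx["len_cds"] == 300).all()  # degenerate range: exactly 100 codons
    for cds in tx["cds"]:
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        assert cds[-3:] in {"TAA", "TAG", "TGA"}
        internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not (set(internal) & {"TAA", "TAG", "TGA"})
        assert set(cds) <= set("ACGT")


def test_gc_fraction_of_pooled_sequence():
    p = SimParams(n_genes=2000, seed=4, gc=0.5)
    tx = make_transcriptome(p)
    pooled = "".join(tx["utr5"]) + "".join(tx["cds"]) + "".join(tx["utr3"])
    gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
    assert abs(gc - 0.5) < 0.02


def test_invalid_params_rejected():
    with pytest.raises(ParameterError, match="length range"):
        SimParams(length_params={"utr5": (50, 10), "cds": (300, 300), "utr3": (9, 9)}).validate()
    with pytest.raises(ParameterError, match="dispersion"):
        SimParams(dispersion=0.0).validate()
    with pytest.raises(ParameterError, match="sum to 1"):
        SimParams(site_type_mix={"8mer": 0.5}).validate()
    with pytest.raises(ParameterError, match="target_fraction"):
        SimParams(target_fraction=1.5).validate()


def test_plant_sites_zero_fraction(mirna):
    p = SimParams(n_genes=50, target_fraction=0.0, seed=5)
    tx, sites = plant_sites(make_transcriptome(p), mirna, p)
    assert sites.empty
    for utr in tx["utr3"]:
        assert find_seed_sites(utr, mirna) == []


def test_plant_sites_round_trip_exact(mirna, small_sim):
    """Every planted site re-detects at the planted coordinates and type."""
    tx, truth = small_sim["tx"], small_sim["truth"]
    expected = {
        g: sorted(map(tuple, grp[["start", "end", "site_type"]].to_numpy()))
        for g, grp in truth.sites.groupby("gene_id")
    }
    n_with_sites = 0
    for gene, utr in tx["utr3"].items():
        found = sorted((s.start, s.end, s.site_type) for s in find_seed_sites(utr, mirna))
        assert found == expected.get(gene, [])
        n_with_sites += bool(found)
    assert n_with_sites == round(
        small_sim["params"].target_fraction * small_sim["params"].n_genes
    )


def test_plant_sites_degenerate_mix(mirna):
    p = SimParams(
        n_genes=250, target_fraction=0.4, seed=6, site_type_mix={"8mer": 1.0}
    )
    tx, sites = plant_sites(make_transcriptome(p), mirna, p)
    assert (sites["site_type"] == "8mer").all()
    assert sites["gene_id"].nunique() == 100


def test_effect_model_two_site_targets(mirna):
    """beta=0, delta=0.5, forced 2 sites: true RNA log2 fc of targets is -1."""
    p = SimParams(
        n_genes=300, seed=8, delta_decay=0.5, beta_te=0.0, max_sites=2,
        site_type_mix={"8mer": 1.0},
    )
    tx, sites = plant_sites(make_transcriptome(p), mirna, p)
    _, truth = simulate_experiment(tx, sites, p)
    two_site = truth.genes[truth.genes["n_sites"] == 2]
    assert len(two_site) > 10
    assert np.allclose(two_site["rna_log2fc_true"], -1.0)
    assert np.allclose(two_site["rpf_log2fc_true"], -1.0)  # beta=0: no extra channel


def test_truth_invariants(small_sim):
    g = small_sim["truth"].genes
    non_targets = g[~g["is_target"]]
    assert (non_targets[["rna_log2fc_true", "rpf_log2fc_true"]] == 0).all().all()
    targets = g[g["is_target"]]
    assert (targets["rpf_log2fc_true"] <= targets["rna_log2fc_true"] + 1e-12).all()
    # monotone coupling: the translational excess is non-increasing in true TE
    excess = (targets["rpf_log2fc_true"] - targets["rna_log2fc_true"]) / targets["w_site"]
    order = targets["te_true"].argsort()
    assert (np.diff(excess.iloc[order]) <= 1e-12).all()


def test_decay_channel_independent_of_te(mirna):
    """With beta=0 the 95% CI for the slope of true RNA fc on TE covers 0
    at close to its nominal rate across seeds."""
    import statsmodels.api as sm

    covered = 0
    seeds = range(10)
    for seed in seeds:
        p = SimParams(n_genes=1500, seed=seed, beta_te=0.0, delta_decay=0.4)
        _, _, truth = simulate(p, mirna)
        t = truth.genes[truth.genes["is_target"]]
        X = sm.add_constant(np.log(t["te_true"].to_numpy()))
        res = sm.OLS(t["rna_log2fc_true"].to_numpy(), X).fit()
        lo, hi = res.conf_int()[1]
        covered += lo <= 0.0 <= hi
    assert covered >= 8


def test_expected_depth_conservation(small_sim):
    phi = small_sim["params"].dispersion
    for (assay, _), table in small_sim["tables"].items():
        depth = getattr(small_sim["params"], f"depth_{assay.lower()}")
        total = table.data["count"].sum()
        # NB sum: var = sum(m + phi m^2); counts stand in for the means
        sigma = np.sqrt(depth + phi * (table.data["count"].astype(float) ** 2).sum())
        assert abs(total - depth) < 5 * sigma


def test_fixture_round_trip(tmp_path, small_sim):
    paths = write_fixture(tmp_path, small_sim["tx"], small_sim["tables"], small_sim["truth"])
    seqs = read_sequences(paths["sequences"])
    pd.testing.assert_frame_equal(
        seqs[["utr5", "cds", "utr3"]].sort_index(),
        small_sim["tx"][["utr5", "cds", "utr3"]].sort_index(),
    )
    truth_back = read_truth(paths["truth"])
    pd.testing.assert_frame_equal(
        truth_back, small_sim["truth"].genes, check_dtype=False, atol=1e-12
    )
    counts = read_expression_table(paths["counts"], "RPF", "mir")
    pd.testing.assert_frame_equal(
        counts.data.sort_index(),
        small_sim["tables"][("RPF", "mir")].data.sort_index(),
        check_dtype=False,
    )


def test_fixture_empty_gene_set(tmp_path):
    import json

    tx = pd.DataFrame(columns=["utr5", "cds", "utr3"]).rename_axis("gene_id")
    from temir.simdata import SyntheticTruth

    truth = SyntheticTruth(
        params=SimParams(),
        genes=pd.DataFrame().rename_axis("gene_id"),
        sites=pd.DataFrame(columns=["gene_id", "start", "end", "site_type"]),
    )
    paths = write_fixture(tmp_path, tx, {}, truth)
    header = paths["counts"].read_text().splitlines()[0]
    assert header == "gene_id\tassay\tcondition\tcount\tlength"
    assert json.loads(paths["params"].read_text())["n_genes"] == SimParams().n_genes


def test_null_model_targets_indistinguishable(mirna):
    """delta=beta=0: target vs non-target fold changes differ only by noise."""
    from temir.expression import repression_records
    from temir.stratstats import ks_two_sample

    pvals = []
    for seed in range(25):
        p = SimParams(n_genes=300, seed=seed, delta_decay=0.0, beta_te=0.0)
        _, tables, truth = simulate(p, mirna)
        rec = repression_records(
            tables[("RPF", "mock")], tables[("RPF", "mir")],
            tables[("RNA", "mock")], tables[("RNA", "mir")],
        )
        is_t = truth.genes.loc[rec.index, "is_target"]
        _, pv = ks_two_sample(rec.loc[is_t, "fc_rpf"], rec.loc[~is_t, "fc_rpf"])
        pvals.append(pv)
    # no systematic separation: p-values not concentrated near 0
    assert np.mean(np.array(pvals) < 0.05) <= 0.2
    assert np.median(pvals) > 0.1
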
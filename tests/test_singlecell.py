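"""Single-cell QC, markers, specificity, and the Stouffer meta-analysis."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from otomap._errors import InvalidArgumentError
from otomap.singlecell import (
    _exact_ranksum_p,
    find_markers,
    haircell_meta,
    normalize_and_select,
    qc_filter,
    risk_gene_specificity,
)
from otomap.sim import gen_sc_counts


def make_adata(X, mito=None):
    X = np.asarray(X, dtype=float)
    var = pd.DataFrame(
        {"mito": mito if mito is not None else np.zeros(X.shape[1], bool)},
        index=[f"g{j}" for j in range(X.shape[1])],
    )
    return ad.AnnData(X=X, var=var, obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]))


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------


def test_cell_with_49_umis_removed_and_20000_kept():
    X = np.zeros((3, 2))
    X[0] = [25, 24]  # 49 total -> removed (strict <50)
    X[1] = [10_000, 10_000]  # exactly 20,000 -> kept (strict >20000)
    X[2] = [100, 100]
    filt, report = qc_filter(make_adata(X))
    assert filt.n_obs == 2
    assert report["removed_low_umi"] == 1


def test_high_mito_cell_removed():
    X = np.array([[30.0, 70.0], [10.0, 90.0]])
    mito = np.array([True, False])
    filt, report = qc_filter(make_adata(X, mito), min_umi=10)
    assert filt.n_obs == 1
    assert report["removed_high_mito"] == 1


def test_qc_removes_exactly_planted_violators():
    adata, truth = gen_sc_counts(
        {"A": 200, "B": 200}, 400, depth_mean=2000, seed=30, qc_violator_fraction=0.05
    )
    filt, report = qc_filter(adata)
    kept = set(filt.obs_names)
    planted_bad = set(truth.loc[truth["qc_violation"] != "", "barcode"])
    assert kept == set(truth["barcode"]) - planted_bad


def test_qc_idempotent():
    adata, _ = gen_sc_counts({"A": 100}, 200, depth_mean=1500, seed=31,
                             qc_violator_fraction=0.1)
    once, _ = qc_filter(adata)
    twice, rep = qc_filter(once)
    assert twice.n_obs == once.n_obs


def test_qc_all_removed_errors():
    X = np.full((3, 2), 1.0)  # all cells at 2 UMIs
    with pytest.raises(InvalidArgumentError):
        qc_filter(make_adata(X))


# --------------------------------------------------------------------------
# normalization / variable genes
# --------------------------------------------------------------------------


def test_doubling_counts_of_one_cell_leaves_profile_unchanged():
    adata, _ = gen_sc_counts({"A": 50}, 300, depth_mean=1500, seed=32)
    filt, _ = qc_filter(adata)
    doubled = filt.copy()
    doubled.X = doubled.X.copy()
    doubled.X[0] *= 2
    n1, _ = normalize_and_select(filt)
    n2, _ = normalize_and_select(doubled)
    assert np.allclose(np.asarray(n1.X)[0], np.asarray(n2.X)[0], atol=1e-10)


def test_planted_variable_markers_selected():
    hits = 0
    for seed in range(10):
        markers = {"A": {f"Gene{j}": 8.0 for j in range(10, 30)}}
        adata, _ = gen_sc_counts({"A": 150, "B": 150}, 1000, markers, depth_mean=2000, seed=seed)
        filt, _ = qc_filter(adata)
        _, hvg = normalize_and_select(filt)
        found = sum(1 for j in range(10, 30) if f"Gene{j}" in hvg)
        hits += found / 20
    assert hits / 10 >= 0.95


def test_zero_count_cell_rejected():
    X = np.array([[0.0, 0.0], [5.0, 5.0]])
    with pytest.raises(InvalidArgumentError):
        normalize_and_select(make_adata(X))


# --------------------------------------------------------------------------
# Wilcoxon markers
# --------------------------------------------------------------------------


def oracle_exact_p(values, in_mask):
    """Enumeration over all group assignments of the same size."""
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values)
    n = len(values)
    n1 = int(in_mask.sum())
    w_obs = ranks[in_mask].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / total


@pytest.mark.parametrize("seed", range(6))
def test_exact_wilcoxon_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 7), rng.integers(2, 9)
    values = np.round(rng.uniform(0, 4, n1 + n2), 1)  # rounded -> ties likely
    mask = np.zeros(n1 + n2, bool)
    mask[:n1] = True
    assert _exact_ranksum_p(values, mask) == pytest.approx(
        oracle_exact_p(values, mask), abs=1e-12
    )


def test_three_vs_three_exact_distribution():
    values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    mask = np.array([True, True, True, False, False, False])
    # W_in = 6 (minimum): exact two-sided p = 2 * 1/20 = 0.1
    assert _exact_ranksum_p(values, mask) == pytest.approx(0.1)


def test_null_markers_mostly_nonsignificant():
    adata, _ = gen_sc_counts({"A": 60, "B": 60}, 150, depth_mean=1500, seed=33)
    filt, _ = qc_filter(adata)
    norm_a, _ = normalize_and_select(filt)
    labels = np.array(["x"] * 60 + ["y"] * 60)[: filt.n_obs]
    markers = find_markers(norm_a, labels)
    assert (markers["p_adjusted"] >= 0.05).mean() >= 0.95


def test_planted_marker_minimal_p_in_own_cluster():
    markers_spec = {"A": {"Gene10": 10.0}}
    adata, truth = gen_sc_counts({"A": 100, "B": 100}, 200, markers_spec,
                                 depth_mean=2000, seed=34)
    filt, _ = qc_filter(adata)
    norm_a, _ = normalize_and_select(filt)
    labels = truth.set_index("barcode").loc[norm_a.obs_names, "celltype"].to_numpy()
    mk = find_markers(norm_a, labels)
    row = mk[(mk["gene"] == "Gene10")].sort_values("p")
    best = row.iloc[0]
    assert best["cluster"] == "A"
    assert best["log_fold_change"] > 0


def test_singleton_cluster_skipped_with_warning():
    adata, _ = gen_sc_counts({"A": 30}, 50, depth_mean=1000, seed=35)
    filt, _ = qc_filter(adata)
    norm_a, _ = normalize_and_select(filt)
    labels = np.array(["a"] * (filt.n_obs - 1) + ["b"])
    with pytest.warns(UserWarning):
        mk = find_markers(norm_a, labels)
    assert set(mk["cluster"]) == {"a"}


# --------------------------------------------------------------------------
# specificity
# --------------------------------------------------------------------------


def test_absent_gene_reported_not_expressed():
    mk = pd.DataFrame(
        {"gene": ["g1"], "cluster": ["c0"], "p": [0.01], "p_adjusted": [0.1],
         "pct_in": [0.5], "pct_out": [0.1], "log_fold_change": [1.0]}
    )
    out = risk_gene_specificity(mk, ["g1", "missing"])
    assert not out.loc[out["gene"] == "missing", "expressed"].iloc[0]


def test_tie_in_p_broken_by_fold_change_then_cluster():
    mk = pd.DataFrame(
        {
            "gene": ["g1"] * 3,
            "cluster": ["c2", "c0", "c1"],
            "p": [0.01, 0.01, 0.01],
            "p_adjusted": [0.1] * 3,
            "pct_in": [0.5] * 3,
            "pct_out": [0.1] * 3,
            "log_fold_change": [2.0, 2.0, 3.0],
        }
    )
    out = risk_gene_specificity(mk, ["g1"])
    assert list(out["cluster"]) == ["c1", "c0", "c2"]


# --------------------------------------------------------------------------
# Stouffer meta-analysis
# --------------------------------------------------------------------------


def _dataset(rng, genes, n_hair=10, n_other=10, fold=None):
    fold = fold or {}
    cols = n_hair + n_other
    hair = np.array([True] * n_hair + [False] * n_other)
    expr = pd.DataFrame(
        rng.normal(2.0, 0.5, size=(len(genes), cols)), index=genes
    )
    for g, f in fold.items():
        expr.loc[g, hair] += np.log(f)
    age = rng.uniform(0, 5, cols)
    return expr, hair, age


def test_identical_z_scale_with_sqrt_k():
    # k datasets each giving z ~= 2 -> combined Z ~= 2*sqrt(k)
    rng = np.random.default_rng(36)
    genes = ["g1"]
    datasets = []
    expr, hair, age = _dataset(rng, genes)
    for _ in range(4):
        datasets.append((expr.copy(), hair.copy(), age.copy()))
    out = haircell_meta(datasets, genes)
    from otomap.singlecell import _signed_z

    z1 = _signed_z(expr.loc["g1"].to_numpy(), hair, age)
    assert out["combined_z"].iloc[0] == pytest.approx(4 * z1 / np.sqrt(4), abs=1e-9)


def test_opposite_z_cancel():
    genes = ["g1"]
    rng = np.random.default_rng(37)
    e1, h, a = _dataset(rng, genes, fold={"g1": 3.0})
    e2 = e1.copy()
    e2.loc["g1"] = e1.loc["g1"].to_numpy()[::-1]  # reverse: flips the contrast
    out = haircell_meta([(e1, h, a[::-1]), (e2, h, a)], genes)
    assert abs(out["combined_z"].iloc[0]) < 1e-6
    assert out["p"].iloc[0] == pytest.approx(0.5, abs=1e-6)


def test_gene_missing_from_one_dataset_combined_over_rest():
    rng = np.random.default_rng(38)
    genes = ["g1", "g2"]
    e1, h1, a1 = _dataset(rng, genes)
    e2, h2, a2 = _dataset(rng, ["g1"])
    out = haircell_meta([(e1, h1, a1), (e2, h2, a2)], genes).set_index("gene")
    assert out.loc["g1", "k"] == 2
    assert out.loc["g2", "k"] == 1


def test_fewer_than_two_datasets_errors():
    rng = np.random.default_rng(39)
    e, h, a = _dataset(rng, ["g1"])
    with pytest.raises(InvalidArgumentError):
        haircell_meta([(e, h, a)], ["g1"])


def test_bh_fdr_matches_bruteforce_step_up():
    rng = np.random.default_rng(40)
    p = np.concatenate([rng.uniform(0, 1e-4, 10), rng.uniform(0, 1, 90)])
    # brute-force BH step-up at q=0.1
    m = len(p)
    order = np.argsort(p)
    passed = np.zeros(m, bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= 0.1 * rank / m:
            kmax = rank
    passed[order[:kmax]] = True
    got = multipletests(p, alpha=0.1, method="fdr_bh")[0]
    assert np.array_equal(got, passed)
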
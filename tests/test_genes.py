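"""Gene-level association, set/property tests, quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import kstest, norm

from otomap._errors import InvalidArgumentError
from otomap.genes import (
    gene_property_test,
    gene_set_test,
    gene_test,
    map_snps_to_genes,
    normalize_expression,
    weighted_chi2_sf,
)


class MatrixLD:
    """LD provider backed by a fixed correlation matrix over known ids."""

    def __init__(self, ids, R):
        self.idx = {s: i for i, s in enumerate(ids)}
        self.R = np.asarray(R)

    def corr_matrix(self, ids):
        sel = [self.idx[s] for s in ids]
        return self.R[np.ix_(sel, sel)]


def make_sumstats(z, ids=None, chrom="1", pos=None):
    z = np.asarray(z, dtype=float)
    n = len(z)
    ids = ids or [f"s{i}" for i in range(n)]
    pos = pos if pos is not None else (np.arange(n) + 1) * 100
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": ids,
            "beta": z * 0.01,
            "se": 0.01,
            "p": chi2_dist.sf(z**2, 1),
            "n": 10_000,
        }
    )


# --------------------------------------------------------------------------
# SNP-to-gene mapping
# --------------------------------------------------------------------------


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])


def test_snp_at_gene_start_included():
    ss = make_sumstats([1.0], pos=[500])
    genes = make_genes([("G1", "GENE1", "1", 500, 600, "+")])
    assert map_snps_to_genes(ss, genes) == {"G1": ["s0"]}


def test_snp_in_exclusion_region_dropped():
    ss = make_sumstats([1.0], pos=[550])
    genes = make_genes([("G1", "GENE1", "1", 500, 600, "+")])
    assert map_snps_to_genes(ss, genes, [("1", 540, 560)]) == {}


def test_mapping_matches_bruteforce_join():
    rng = np.random.default_rng(8)
    n_snps, n_genes = 500, 50
    pos = rng.integers(1, 1_000_000, size=n_snps)
    ss = make_sumstats(rng.standard_normal(n_snps), pos=pos)
    rows = []
    for i in range(n_genes):
        s = int(rng.integers(1, 990_000))
        rows.append((f"G{i}", f"GENE{i}", "1", s, s + int(rng.integers(1000, 50_000)), "+"))
    genes = make_genes(rows)
    got = map_snps_to_genes(ss, genes)
    want = {}
    for g in genes.itertuples(index=False):
        hits = [
            ss["id"].iloc[j]
            for j in range(n_snps)
            if g.start <= pos[j] <= g.end
        ]
        if hits:
            want[g.gene_id] = hits
    assert got == want


# --------------------------------------------------------------------------
# gene test
# --------------------------------------------------------------------------


def test_single_snp_gene_p_equals_snp_p():
    ss = make_sumstats([2.3])
    res = gene_test({"G": ["s0"]}, ss, MatrixLD(["s0"], np.eye(1)))
    assert res["p"].iloc[0] == pytest.approx(float(ss["p"].iloc[0]), rel=1e-10)


def test_independent_snps_null_is_scaled_chi2k():
    # k independent SNPs: mean chi2 ~ chi2_k / k; p matches the closed form
    z = np.array([1.0, -0.5, 2.0, 0.3])
    ss = make_sumstats(z)
    res = gene_test({"G": list(ss["id"])}, ss, MatrixLD(list(ss["id"]), np.eye(4)))
    q = float((z**2).sum())
    assert res["p"].iloc[0] == pytest.approx(chi2_dist.sf(q, 4), rel=1e-6)


def test_correlated_ld_p_matches_monte_carlo():
    R = np.array(
        [
            [1.0, 0.8, 0.5, 0.2, 0.1],
            [0.8, 1.0, 0.6, 0.3, 0.1],
            [0.5, 0.6, 1.0, 0.4, 0.2],
            [0.2, 0.3, 0.4, 1.0, 0.5],
            [0.1, 0.1, 0.2, 0.5, 1.0],
        ]
    )
    lam = np.linalg.eigvalsh(R)
    rng = np.random.default_rng(9)
    q = 11.0
    draws = (lam * rng.standard_normal((1_000_000, 5)) ** 2).sum(axis=1)
    mc = (draws > q).mean()
    p = weighted_chi2_sf(q, lam)
    assert p == pytest.approx(mc, rel=0.01)


def test_gene_z_is_probit_of_p():
    ss = make_sumstats([1.5, -0.7])
    res = gene_test({"G": list(ss["id"])}, ss, MatrixLD(list(ss["id"]), np.eye(2)))
    assert res["z"].iloc[0] == pytest.approx(norm.isf(res["p"].iloc[0]), abs=1e-10)


def test_empty_gene_skipped():
    ss = make_sumstats([1.0])
    res = gene_test({"G": ["absent"]}, ss, MatrixLD(["s0"], np.eye(1)))
    assert len(res) == 0


# --------------------------------------------------------------------------
# gene set test
# --------------------------------------------------------------------------


def _null_gene_results(rng, n=200):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "n_snps": 5,
            "stat": 1.0,
            "p": 0.5,
            "z": rng.standard_normal(n),
            "log_length": rng.uniform(7, 12, n),
            "log_n_snps": rng.uniform(0, 3, n),
            "ld_density": rng.uniform(0, 0.5, n),
        }
    )


def test_gene_set_null_p_uniform():
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(200):
        gr = _null_gene_results(rng)
        members = set(rng.choice(gr["gene_id"], 40, replace=False))
        _, _, p = gene_set_test(gr, members)
        ps.append(p)
    assert kstest(ps, "uniform").pvalue > 0.01


def test_gene_set_shifted_z_detected():
    rng = np.random.default_rng(11)
    gr = _null_gene_results(rng)
    members = set(gr["gene_id"].iloc[:100])
    gr.loc[gr["gene_id"].isin(members), "z"] += 1.0
    _, _, p = gene_set_test(gr, members)
    assert p < 1e-4


def test_gene_set_degenerate_membership_errors():
    rng = np.random.default_rng(12)
    gr = _null_gene_results(rng, 10)
    with pytest.raises(InvalidArgumentError):
        gene_set_test(gr, set())
    with pytest.raises(InvalidArgumentError):
        gene_set_test(gr, set(gr["gene_id"]))


# --------------------------------------------------------------------------
# expression normalization
# --------------------------------------------------------------------------


def test_identical_columns_preserved():
    tpm = pd.DataFrame({"a": [0.0, 1, 5, 10], "b": [0.0, 1, 5, 10]})
    nrm, _ = normalize_expression(tpm)
    assert np.allclose(nrm["a"], nrm["b"])
    assert (np.diff(nrm["a"]) > 0).all()  # monotone relabeling


def test_two_column_toy_equals_hand_computed_mapping():
    tpm = pd.DataFrame({"a": [0.0, 1.0, 3.0], "b": [0.0, 7.0, 1.0]})
    la = np.log1p([0.0, 1.0, 3.0])
    lb = np.log1p([0.0, 7.0, 1.0])
    ref = (np.sort(la) + np.sort(lb)) / 2
    nrm, avg = normalize_expression(tpm)
    # ranks: a -> (0,1,2); b -> (0,2,1)
    assert np.allclose(nrm["a"], ref)
    assert np.allclose(nrm["b"], ref[[0, 2, 1]])
    assert np.allclose(avg, (nrm["a"] + nrm["b"]) / 2)


def test_all_zero_gene_stays_zero():
    tpm = pd.DataFrame({"a": [0.0, 1, 5], "b": [0.0, 2, 8]})
    nrm, _ = normalize_expression(tpm)
    assert nrm.iloc[0].eq(0).all()


def test_negative_values_rejected():
    with pytest.raises(InvalidArgumentError):
        normalize_expression(pd.DataFrame({"a": [-1.0, 2.0]}))


# --------------------------------------------------------------------------
# gene property test
# --------------------------------------------------------------------------


def test_property_collinear_with_average_dropped():
    rng = np.random.default_rng(13)
    gr = _null_gene_results(rng, 100)
    expr = pd.DataFrame(
        {f"T{i}": rng.uniform(0, 5, 100) for i in range(4)},
        index=gr["gene_id"],
    )
    expr["same"] = expr.mean(axis=1)
    with pytest.warns(UserWarning):
        res = gene_property_test(gr, expr, "same", average=expr.drop(columns="same").mean(axis=1))
    # the column equals the conditioning average: no specific signal
    assert res.flagged is not None
    assert res.p == pytest.approx(0.5)


def test_property_zero_variance_flagged():
    rng = np.random.default_rng(14)
    gr = _null_gene_results(rng, 50)
    expr = pd.DataFrame({"T0": np.ones(50), "T1": rng.uniform(0, 5, 50)}, index=gr["gene_id"])
    res = gene_property_test(gr, expr, "T0")
    assert res.flagged == "zero-variance expression"


def test_property_permuted_labels_null_uniform():
    rng = np.random.default_rng(15)
    ps = []
    for _ in range(200):
        gr = _null_gene_results(rng, 150)
        expr = pd.DataFrame(
            {f"T{i}": rng.uniform(0, 5, 150) for i in range(5)}, index=gr["gene_id"]
        )
        res = gene_property_test(gr, expr, "T0")
        ps.append(res.p)
    assert kstest(ps, "uniform").pvalue > 0.01


def test_property_planted_celltype_signal_detected():
    rng = np.random.default_rng(16)
    hits = 0
    for rep in range(20):
        n = 200
        gr = _null_gene_results(rng, n)
        expr = pd.DataFrame(
            {f"T{i}": rng.uniform(0, 5, n) for i in range(5)}, index=gr["gene_id"]
        )
        # genes highly expressed in T0 get elevated z
        gr["z"] += 0.5 * (expr["T0"].to_numpy() - expr.mean(axis=1).to_numpy())
        ps = [gene_property_test(gr, expr, f"T{i}").p for i in range(5)]
        hits += int(np.argmin(ps) == 0)
    assert hits >= 18
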
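"""Minimal droplet single-cell RNA-seq pipeline.

Counts live in an :class:`anndata.AnnData` (cells x genes) with a boolean
``var['mito']`` column. QC, normalization, variable-gene selection,
covariate regression, PCA, neighbor graph and modularity clustering go
through scanpy; Wilcoxon marker detection is computed in-package with an
exact tie-aware rank-sum distribution for small groups, since marker
p-values feed downstream specificity ranking and the hair-cell
meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from ._errors import InvalidArgumentError


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------


def qc_filter(
    counts: ad.AnnData,
    min_umi: int = 50,
    max_umi: int = 20_000,
    max_mito: float = 0.20,
) -> tuple[ad.AnnData, dict]:
    """Remove cells with <min_umi or >max_umi total UMIs or mito share >max_mito.

    Thresholds are strict on both UMI bounds (a cell at exactly ``max_umi``
    is retained). Returns the filtered matrix and per-reason removal counts.
    """
    if "mito" not in counts.var:
        raise InvalidArgumentError("var['mito'] flags are required")
    X = np.asarray(counts.X)
    total = X.sum(axis=1)
    mito_frac = np.divide(
        X[:, counts.var["mito"].to_numpy(bool)].sum(axis=1),
        total,
        out=np.zeros_like(total, dtype=float),
        where=total > 0,
    )
    low = total < min_umi
    high = total > max_umi
    mito = mito_frac > max_mito
    keep = ~(low | high | mito)
    if not keep.any():
        raise InvalidArgumentError("QC removed every cell")
    report = {
        "n_input": int(counts.n_obs),
        "n_kept": int(keep.sum()),
        "removed_low_umi": int(low.sum()),
        "removed_high_umi": int(high.sum()),
        "removed_high_mito": int((mito & ~low & ~high).sum()),
    }
    out = counts[keep].copy()
    out.obs["total_umi"] = total[keep]
    out.obs["mito_frac"] = mito_frac[keep]
    return out, report


# --------------------------------------------------------------------------
# normalization and variable genes
# --------------------------------------------------------------------------


def normalize_and_select(
    counts: ad.AnnData,
    scale_factor: int = 10_000,
    mean_min: float = 0.0123,
    mean_max: float = 3.0,
    dispersion_cutoff: float = 0.5,
) -> tuple[ad.AnnData, list[str]]:
    """Library-size normalize, log1p, and select variable genes.

    Variable genes have binned mean expression in [mean_min, mean_max] and
    standardized log variance-to-mean dispersion above
    ``dispersion_cutoff`` — the Seurat FindVariableGenes convention
    (x.low.cutoff, x.high.cutoff, y.cutoff with LogVMR dispersion). A
    dispersion ceiling would discard exactly the strongest markers, so none
    is applied.
    """
    X = np.asarray(counts.X)
    if (X.sum(axis=1) == 0).any():
        raise InvalidArgumentError("zero-count cell present; run qc_filter first")
    adata = counts.copy()
    adata.layers["counts"] = X.copy()
    sc.pp.normalize_total(adata, target_sum=scale_factor)
    sc.pp.log1p(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata,
            flavor="seurat",
            min_mean=mean_min,
            max_mean=mean_max,
            min_disp=dispersion_cutoff,
        )
    variable = adata.var_names[adata.var["highly_variable"]].tolist()
    return adata, variable


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------


def cluster_cells(
    normalized: ad.AnnData,
    covariates: tuple[str, ...] = ("cell_cycle", "mito_frac", "total_umi"),
    n_components: int = 10,
    resolution: float = 0.6,
    k_neighbors: int = 20,
    seed: int = 0,
    variable_genes: list[str] | None = None,
) -> np.ndarray:
    """Covariate regression, PCA, SNN graph and modularity clustering.

    Deterministic given ``seed``. Covariates named in ``covariates`` are
    regressed out of scaled expression when present in ``obs``.
    """
    if normalized.n_obs < k_neighbors:
        raise InvalidArgumentError("fewer cells than k_neighbors")
    adata = normalized.copy()
    if variable_genes:
        adata = adata[:, variable_genes].copy()
    present = [c for c in covariates if c in adata.obs.columns]
    if present:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.regress_out(adata, present)
    sc.pp.scale(adata, max_value=10)
    n_comps = min(n_components, adata.n_vars - 1, adata.n_obs - 1)
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=k_neighbors, n_pcs=n_comps, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return adata.obs["leiden"].to_numpy()


# --------------------------------------------------------------------------
# Wilcoxon rank-sum markers
# --------------------------------------------------------------------------


def _exact_ranksum_p(values: np.ndarray, in_mask: np.ndarray) -> float:
    """Two-sided exact tie-aware rank-sum p by DP over the midrank multiset."""
    ranks = rankdata(values)  # midranks; ties averaged
    r2 = np.round(2 * ranks).astype(int)  # doubled to keep integers
    n = len(values)
    n1 = int(in_mask.sum())
    w_obs = int(r2[in_mask].sum())
    # DP: ways[k][s] = #subsets of size k with doubled-rank sum s
    max_s = int(r2.sum())
    ways = np.zeros((n1 + 1, max_s + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in r2:
        for k in range(min(n1, 1_000_000), 0, -1):
            ways[k, r:] += ways[k - 1, : max_s + 1 - r]
    dist = ways[n1]
    total = dist.sum()
    mu = n1 * (n + 1)  # doubled-scale mean
    dev = abs(w_obs - mu)
    s_vals = np.arange(max_s + 1)
    p = dist[np.abs(s_vals - mu) >= dev].sum() / total
    return float(min(p, 1.0))


def _asymptotic_ranksum_p(X: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p per gene (columns)."""
    n, _ = X.shape
    n1 = int(in_mask.sum())
    n2 = n - n1
    ranks = np.apply_along_axis(rankdata, 0, X)
    W = ranks[in_mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction per gene
    ties = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, cnt = np.unique(X[:, j], return_counts=True)
        ties[j] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (W - mu) / sigma
    return 2.0 * norm.sf(np.abs(z))


@dataclass
class MarkerTable:
    df: pd.DataFrame  # gene, cluster, p, p_adjusted, pct_in, pct_out, log_fold_change


def find_markers(
    normalized: ad.AnnData,
    labels: np.ndarray,
    exact_max_group: int = 8,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of each cluster vs all other cells.

    Exact tie-aware p for groups where min(n_in, n_out) <= ``exact_max_group``,
    normal approximation with tie correction otherwise. p_adjusted is
    Bonferroni across genes within a cluster. pct_in/pct_out are fractions
    of cells with nonzero counts; log fold change compares expm1 means.
    """
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels), key=str)
    if len(clusters) < 2:
        raise InvalidArgumentError("need at least two clusters")
    X = np.asarray(normalized.X)
    raw = normalized.layers["counts"] if "counts" in normalized.layers else X
    raw = np.asarray(raw)
    genes = normalized.var_names.to_numpy()
    n_genes = X.shape[1]
    rows = []
    for cl in clusters:
        in_mask = labels == cl
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 2:
            warnings.warn(f"cluster {cl!r} is (near-)singleton; skipped")
            continue
        if min(n_in, n_out) <= exact_max_group:
            p = np.array([_exact_ranksum_p(X[:, j], in_mask) for j in range(n_genes)])
        else:
            p = _asymptotic_ranksum_p(X, in_mask)
        pct_in = (raw[in_mask] > 0).mean(axis=0)
        pct_out = (raw[~in_mask] > 0).mean(axis=0)
        mean_in = np.expm1(X[in_mask]).mean(axis=0)
        mean_out = np.expm1(X[~in_mask]).mean(axis=0)
        lfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        p_adj = np.minimum(p * n_genes, 1.0)
        for j in range(n_genes):
            rows.append(
                {
                    "gene": genes[j],
                    "cluster": cl,
                    "p": float(p[j]),
                    "p_adjusted": float(p_adj[j]),
                    "pct_in": float(pct_in[j]),
                    "pct_out": float(pct_out[j]),
                    "log_fold_change": float(lfc[j]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster", "p", "p_adjusted", "pct_in", "pct_out", "log_fold_change"],
    )


# --------------------------------------------------------------------------
# risk-gene specificity
# --------------------------------------------------------------------------


def risk_gene_specificity(
    markers: pd.DataFrame,
    risk_genes: list[str],
    top_k: int = 3,
    detection_floor: float = 0.05,
) -> pd.DataFrame:
    """Top clusters per risk gene, ranked by marker significance.

    Ranking: p ascending, then |log fold change| descending, then cluster
    label — deterministic. Genes absent from the matrix or with maximum
    in-cluster detection below ``detection_floor`` are reported
    not-expressed.
    """
    rows = []
    for gene in risk_genes:
        sub = markers[markers["gene"] == gene]
        if len(sub) == 0 or sub["pct_in"].max() < detection_floor:
            rows.append({"gene": gene, "rank": np.nan, "cluster": "", "p": np.nan,
                         "log_fold_change": np.nan, "expressed": False})
            continue
        ordered = sub.assign(_abs_lfc=sub["log_fold_change"].abs()).sort_values(
            ["p", "_abs_lfc", "cluster"],
            ascending=[True, False, True],
            kind="stable",
        )
        for rank, r in enumerate(ordered.head(top_k).itertuples(index=False), start=1):
            rows.append({"gene": gene, "rank": rank, "cluster": r.cluster, "p": r.p,
                         "log_fold_change": r.log_fold_change, "expressed": True})
    return pd.DataFrame(
        rows, columns=["gene", "rank", "cluster", "p", "log_fold_change", "expressed"]
    )


# --------------------------------------------------------------------------
# hair-cell meta-analysis (Stouffer)
# --------------------------------------------------------------------------


def _signed_z(y: np.ndarray, group: np.ndarray, age: np.ndarray | None):
    """One-sided z toward higher expression in the hair-cell group (OLS)."""
    cols = [np.ones_like(y), group.astype(float)]
    if age is not None and np.std(age) > 0:
        cols.append(age.astype(float))
    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - rank
    sigma2 = float(resid @ resid) / max(dof, 1)
    se = np.sqrt(sigma2 * np.linalg.pinv(X.T @ X)[1, 1])
    if se == 0:
        return 0.0
    from scipy.stats import t as t_dist

    p_one = float(t_dist.sf(coef[1] / se, dof))
    p_one = min(max(p_one, 1e-300), 1 - 1e-16)
    return float(norm.isf(p_one))


def haircell_meta(
    datasets: list[tuple[pd.DataFrame, np.ndarray, np.ndarray | None]],
    genes: list[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Stouffer equal-weight combination of hair-vs-other expression tests.

    Each dataset is (log-expression genes x samples, boolean hair labels,
    age covariate or None). Per gene: combined Z = sum(z_i)/sqrt(k) over the
    datasets that measured it; one-sided p; Benjamini-Hochberg across genes;
    flag = FDR < ``fdr``.
    """
    if len(datasets) < 2:
        raise InvalidArgumentError("need at least two datasets")
    per_gene: dict[str, list[float]] = {g: [] for g in genes}
    for expr, hair, age in datasets:
        hair = np.asarray(hair, dtype=bool)
        for g in genes:
            if g not in expr.index:
                continue
            y = expr.loc[g].to_numpy(dtype=float)
            per_gene[g].append(_signed_z(y, hair, age))
    rows = []
    for g in genes:
        zs = per_gene[g]
        k = len(zs)
        if k == 0:
            rows.append({"gene": g, "k": 0, "combined_z": np.nan, "p": np.nan})
            continue
        Z = float(np.sum(zs) / np.sqrt(k))
        rows.append({"gene": g, "k": k, "combined_z": Z, "p": float(norm.sf(Z))})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr_q"] = np.nan
    if ok.any():
        out.loc[ok, "fdr_q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["flag"] = out["fdr_q"] < fdr
    return out
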
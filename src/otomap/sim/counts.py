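"""Cell-type-structured negative-binomial UMI counts.

Emulates droplet single-cell RNA-seq of a heterogeneous tissue: per-gene
baseline expression weights shared across cell types, marker genes with
planted fold-changes in their type, a designated mitochondrial gene subset
contributing a target fraction of UMIs, lognormal sequencing depth, and a
configurable fraction of cells that violate QC bounds to exercise
filtering.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from .._errors import InvalidArgumentError
from .panel import stage_seed


def gen_sc_counts(
    celltype_sizes: dict[str, int],
    n_genes: int,
    marker_spec: dict[str, dict[str, float]] | None = None,
    depth_mean: float = 2000.0,
    dispersion: float = 0.3,
    mito_fraction: float = 0.05,
    seed: int = 0,
    n_mito_genes: int | None = None,
    qc_violator_fraction: float = 0.0,
    depth_sigma: float = 0.35,
    marker_base_weight: float | None = 0.5,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a UMI count matrix with planted cell types.

    Returns (AnnData cells x genes with var['mito'], truth table with the
    planted cell type and QC-violation reason per cell). Counts are
    negative binomial: var = mu + dispersion * mu^2.
    """
    if depth_mean <= 0:
        raise InvalidArgumentError("depth_mean must be positive")
    if dispersion <= 0:
        raise InvalidArgumentError("dispersion must be positive")
    if not celltype_sizes:
        raise InvalidArgumentError("need at least one cell type")
    marker_spec = marker_spec or {}

    rng = np.random.default_rng(stage_seed(seed, "sc_counts"))
    if n_mito_genes is None:
        n_mito_genes = max(3, n_genes // 50)
    gene_names = [f"Mt{i + 1}" for i in range(n_mito_genes)] + [
        f"Gene{i + 1}" for i in range(n_genes - n_mito_genes)
    ]
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    mito = np.zeros(n_genes, dtype=bool)
    mito[:n_mito_genes] = True

    # contradictory marker folds for the same gene are a user error
    fold_of_gene: dict[str, tuple[str, float]] = {}
    for ct, spec in marker_spec.items():
        for g, fold in spec.items():
            if g not in name_to_idx:
                raise InvalidArgumentError(f"marker gene {g!r} not in the gene universe")
            if g in fold_of_gene and fold_of_gene[g][1] != fold and fold_of_gene[g][0] != ct:
                raise InvalidArgumentError(f"contradictory folds for marker {g!r}")
            fold_of_gene[g] = (ct, float(fold))

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    if marker_base_weight is not None:
        # planted markers start from a controlled baseline so their fold
        # change, not a random lognormal draw, sets their expression level
        for spec in marker_spec.values():
            for g in spec:
                base[name_to_idx[g]] = marker_base_weight
    # mito genes contribute ~mito_fraction of UMIs
    base_mito = base[mito].sum()
    base_rest = base[~mito].sum()
    if base_mito > 0 and mito_fraction > 0:
        base[mito] *= (mito_fraction / (1 - mito_fraction)) * base_rest / base_mito

    celltypes = list(celltype_sizes)
    profiles = {}
    for ct in celltypes:
        w = base.copy()
        for g, fold in (marker_spec.get(ct) or {}).items():
            w[name_to_idx[g]] *= float(fold)
        profiles[ct] = w / w.sum()

    n_cells = sum(celltype_sizes.values())
    labels = np.concatenate([[ct] * n for ct, n in celltype_sizes.items()])
    order = rng.permutation(n_cells)
    labels = labels[order]

    depth = rng.lognormal(np.log(depth_mean), depth_sigma, size=n_cells)
    violation = np.array([""] * n_cells, dtype=object)
    if qc_violator_fraction > 0:
        n_bad = int(round(qc_violator_fraction * n_cells))
        bad = rng.choice(n_cells, n_bad, replace=False)
        kinds = rng.integers(0, 3, size=n_bad)
        for i, kind in zip(bad, kinds):
            if kind == 0:
                depth[i] = rng.uniform(5, 30)  # below the 50-UMI floor
                violation[i] = "low_umi"
            elif kind == 1:
                depth[i] = rng.uniform(25_000, 40_000)  # above the 20k ceiling
                violation[i] = "high_umi"
            else:
                violation[i] = "high_mito"

    X = np.empty((n_cells, n_genes), dtype=np.int64)
    r = 1.0 / dispersion  # NB size parameter
    for i in range(n_cells):
        w = profiles[labels[i]].copy()
        if violation[i] == "high_mito":
            target = rng.uniform(0.35, 0.6)
            w = w.copy()
            w[mito] *= (target / max(w[mito].sum(), 1e-12)) * (1 - w[mito].sum()) / (1 - target)
            w /= w.sum()
        mu = depth[i] * w
        lam = rng.gamma(shape=r, scale=mu / r)
        X[i] = rng.poisson(lam)

    barcodes = [f"cell{i + 1:05d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=X.astype(float),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame({"mito": mito}, index=gene_names),
    )
    truth = pd.DataFrame(
        {"barcode": barcodes, "celltype": labels, "qc_violation": violation}
    )
    return adata, truth
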
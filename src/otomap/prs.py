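"""Polygenic risk scoring and evaluation in a target cohort.

Multi-frequency hearing thresholds are summarized by PCA (PC1 is the
overall hearing measure); the cohort is QC'd plink-style (individual and
SNP missingness, MAF, Hardy-Weinberg exact test); scores are weighted sums
of effect-allele dosages over discovery SNPs passing each p-value
threshold; variance explained is the incremental R^2 of the score over
covariates, with an F-test p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from ._errors import InvalidArgumentError

PRS_THRESHOLDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# --------------------------------------------------------------------------
# phenotype PCA
# --------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    scores: pd.DataFrame  # individuals x PCs
    loadings: pd.DataFrame  # frequencies x PCs
    explained_variance_ratio: np.ndarray
    imputed: bool = False


def phenotype_pca(thresholds: pd.DataFrame) -> PhenotypeTable:
    """Column-centered PCA of per-frequency thresholds.

    PC signs are fixed so PC1 correlates positively with the mean threshold
    (an overall hearing-loss measure); remaining PCs get their largest
    loading positive. Constant columns are dropped with a warning; missing
    values are mean-imputed and flagged.
    """
    df = thresholds.copy()
    if df.shape[1] < 2:
        raise InvalidArgumentError("PCA needs at least two frequencies")
    const = df.std(axis=0, ddof=0) == 0
    if const.any():
        warnings.warn(f"dropping constant columns: {list(df.columns[const])}")
        df = df.loc[:, ~const]
    imputed = bool(df.isna().any().any())
    if imputed:
        df = df.fillna(df.mean())
    X = df.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    evr = s**2 / (s**2).sum()
    # sign conventions
    row_mean = X.mean(axis=1)
    for k in range(scores.shape[1]):
        if k == 0:
            flip = np.corrcoef(scores[:, 0], row_mean)[0, 1] < 0
        else:
            flip = Vt[k, np.argmax(np.abs(Vt[k]))] < 0
        if flip:
            scores[:, k] *= -1
            Vt[k] *= -1
    pc_names = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PhenotypeTable(
        scores=pd.DataFrame(scores, index=thresholds.index, columns=pc_names),
        loadings=pd.DataFrame(Vt.T, index=df.columns, columns=pc_names),
        explained_variance_ratio=evr,
        imputed=imputed,
    )


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test
# --------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p: sum of genotype-configuration probabilities
    no more likely than the observed one (Wigginton-style recurrence)."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure the rarer allele
        n_minor = 2 * n - n_minor
    if n == 0:
        return 1.0
    het_probs = np.zeros(n_minor + 1)
    mid = int(n_minor * (2 * n - n_minor) / (2 * n))
    if mid % 2 != n_minor % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward from mid
    het, hom_r = mid, (n_minor - mid) // 2
    hom_c = n - het - hom_r
    h, hr, hc = het, hom_r, hom_c
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h -= 2
        hr += 1
        hc += 1
    h, hr, hc = mid, (n_minor - mid) // 2, n - mid - (n_minor - mid) // 2
    while h <= n_minor - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        h += 2
        hr -= 1
        hc -= 1
    het_probs /= het_probs.sum()
    obs = n_het if n_het <= n_minor else n_minor
    p = het_probs[het_probs <= het_probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# --------------------------------------------------------------------------
# cohort QC
# --------------------------------------------------------------------------


def qc_cohort(
    genotypes: pd.DataFrame,
    miss_ind: float = 0.10,
    miss_snp: float = 0.10,
    maf_min: float = 0.05,
    hwe_p: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Plink-style cohort QC in the stated order.

    1. drop individuals with missingness > miss_ind;
    2. drop SNPs with missingness > miss_snp;
    3. drop SNPs with MAF < maf_min;
    4. drop SNPs failing the Hardy-Weinberg exact test at p < hwe_p.
    """
    g = genotypes.copy()
    report = {"n_individuals_in": g.shape[0], "n_snps_in": g.shape[1]}

    ind_miss = g.isna().mean(axis=1)
    bad_ind = ind_miss > miss_ind
    g = g.loc[~bad_ind]
    report["removed_individuals"] = int(bad_ind.sum())

    snp_miss = g.isna().mean(axis=0)
    bad_missing = snp_miss > miss_snp
    g = g.loc[:, ~bad_missing]
    report["removed_snp_missingness"] = int(bad_missing.sum())

    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    bad_maf = maf < maf_min
    g = g.loc[:, ~bad_maf]
    report["removed_maf"] = int(bad_maf.sum())

    # cheap chi-square prefilter: the exact test is only evaluated where the
    # asymptotic test is anywhere near the threshold
    from scipy.stats import chi2 as chi2_dist

    arr = g.to_numpy()
    n_het = np.nansum(arr == 1, axis=0).astype(int)
    n_hom1 = np.nansum(arr == 2, axis=0).astype(int)
    n_hom0 = np.nansum(arr == 0, axis=0).astype(int)
    n_tot = n_het + n_hom1 + n_hom0
    p_minor = (2 * n_hom1 + n_het) / np.maximum(2 * n_tot, 1)
    exp_het = 2 * p_minor * (1 - p_minor) * n_tot
    exp_hom1 = p_minor**2 * n_tot
    exp_hom0 = (1 - p_minor) ** 2 * n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_stat = (
            np.nan_to_num((n_het - exp_het) ** 2 / exp_het)
            + np.nan_to_num((n_hom1 - exp_hom1) ** 2 / exp_hom1)
            + np.nan_to_num((n_hom0 - exp_hom0) ** 2 / exp_hom0)
        )
    approx_p = chi2_dist.sf(chi2_stat, 1)
    bad_hwe = []
    for j, snp in enumerate(g.columns):
        if approx_p[j] > max(1e3 * hwe_p, 1e-3):
            continue
        if hwe_exact_p(n_het[j], n_hom1[j], n_hom0[j]) < hwe_p:
            bad_hwe.append(snp)
    g = g.drop(columns=bad_hwe)
    report["removed_hwe"] = len(bad_hwe)
    report["n_individuals_out"] = g.shape[0]
    report["n_snps_out"] = g.shape[1]
    if g.shape[0] == 0 or g.shape[1] == 0:
        raise InvalidArgumentError("QC removed all individuals or all SNPs")
    return g, report


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------


@dataclass
class PRSResult:
    p_threshold: float
    n_snps_used: int
    scores: pd.Series
    r2: float | None = None
    p: float | None = None


def _harmonized_weights(
    discovery: pd.DataFrame, target_variants: pd.DataFrame
) -> pd.DataFrame:
    """Align discovery betas to target effect alleles; drop ambiguous SNPs."""
    t = target_variants.rename(
        columns={"allele_effect": "effect_allele", "allele_other": "other_allele"}
    )
    m = discovery.merge(
        t[["id", "effect_allele", "other_allele"]], on="id", suffixes=("", "_t")
    )
    ambiguous = [
        frozenset((a, b)) in AMBIGUOUS_PAIRS
        for a, b in zip(m["effect_allele"], m["other_allele"])
    ]
    m = m[~np.array(ambiguous)]
    same = (m["effect_allele"] == m["effect_allele_t"]) & (
        m["other_allele"] == m["other_allele_t"]
    )
    flipped = (m["effect_allele"] == m["other_allele_t"]) & (
        m["other_allele"] == m["effect_allele_t"]
    )
    m = m[same | flipped].copy()
    m["beta_aligned"] = np.where(same[same | flipped], m["beta"], -m["beta"])
    return m


def compute_prs(
    genotypes: pd.DataFrame,
    target_variants: pd.DataFrame,
    discovery: pd.DataFrame,
    thresholds: tuple[float, ...] = PRS_THRESHOLDS,
    ld=None,
    clump_r2: float = 0.1,
    clump_kb: int = 250,
) -> list[PRSResult]:
    """Threshold-based polygenic scores.

    score_i = sum_j beta_j * dosage_ij over harmonized SNPs with discovery
    p <= threshold. Missing dosages are mean-imputed per SNP. If an LD
    provider is given, discovery SNPs are clumped first (greedy by p,
    r2 >= clump_r2 within clump_kb absorbs).
    """
    weights = _harmonized_weights(discovery, target_variants)
    weights = weights[weights["id"].isin(genotypes.columns)]
    if ld is not None:
        from .loci import clump_lead_snps

        old_window = getattr(ld, "window_bp", None)
        if old_window is not None:
            ld.window_bp = clump_kb * 1000
        try:
            kept = clump_lead_snps(weights, ld, p_threshold=1.1, r2_independence=clump_r2)
        finally:
            if old_window is not None:
                ld.window_bp = old_window
        weights = weights[weights["id"].isin(kept)]

    results = []
    for thr in thresholds:
        sel = weights[weights["p"] <= thr]
        if len(sel) == 0:
            results.append(
                PRSResult(thr, 0, pd.Series(np.nan, index=genotypes.index))
            )
            continue
        dos = genotypes[sel["id"]].to_numpy(dtype=float)
        col_mean = np.nanmean(dos, axis=0)
        nan_mask = np.isnan(dos)
        dos[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        score = dos @ sel["beta_aligned"].to_numpy()
        results.append(PRSResult(thr, len(sel), pd.Series(score, index=genotypes.index)))
    return results


def evaluate_prs(
    scores: pd.Series,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Incremental R^2 of the score over covariates and its F-test p-value."""
    idx = scores.index.intersection(phenotype.index)
    if len(idx) < 30:
        warnings.warn("fewer than 30 individuals; estimates will be unstable")
    y = phenotype.loc[idx].to_numpy(dtype=float)
    s = scores.loc[idx].to_numpy(dtype=float)
    n = len(idx)
    cols = [np.ones(n)]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates.loc[idx, c].to_numpy(dtype=float))
    X0 = np.column_stack(cols)
    X1 = np.column_stack(cols + [s])

    def _rss(X):
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    tss = float(((y - y.mean()) ** 2).sum())
    rss0, rss1 = _rss(X0), _rss(X1)
    r2_inc = (rss0 - rss1) / tss
    dof = n - X1.shape[1]
    F = (rss0 - rss1) / (rss1 / dof)
    p = float(f_dist.sf(F, 1, dof)) if rss1 > 0 else 0.0
    return float(r2_inc), p


def evaluate_thresholds(
    results: list[PRSResult],
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """R^2 and p per threshold; the best threshold maximizes R^2."""
    rows = []
    for res in results:
        if res.n_snps_used == 0 or res.scores.isna().all():
            rows.append({"threshold": res.p_threshold, "n_snps": 0, "r2": np.nan, "p": np.nan})
            continue
        r2, p = evaluate_prs(res.scores, phenotype, covariates)
        res.r2, res.p = r2, p
        rows.append({"threshold": res.p_threshold, "n_snps": res.n_snps_used, "r2": r2, "p": p})
    df = pd.DataFrame(rows)
    df["best"] = df["r2"] == df["r2"].max()
    return df
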
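"""Desk-scale (stratified) LD score regression.

Implements the regression of GWAS chi-square statistics on LD scores to
estimate SNP heritability (h2), the confounding intercept, per-annotation
enrichment, and cross-trait genetic correlation (rg), with uncertainty by
delete-one block jackknife over contiguous SNP blocks.

Model:  E[chi2_j] = intercept + N * sum_c tau_c * l_{j,c}

where l_{j,c} is the LD score of SNP j with members of category c, tau_c
the per-SNP heritability contributed by membership in c, and the intercept
captures confounding (population stratification, cryptic relatedness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import InvalidArgumentError
from .annotations import BASE_CATEGORY, AnnotationMatrix
from .sim.panel import ReferencePanel


# --------------------------------------------------------------------------
# LD scores
# --------------------------------------------------------------------------


@dataclass
class LDScoreTable:
    """Per-variant, per-category LD scores l_{j,c} = sum_k r2_{jk} a_{kc}."""

    categories: list[str]
    scores: np.ndarray  # (n_variants, n_categories)
    ids: np.ndarray

    @property
    def base(self) -> np.ndarray:
        return self.scores[:, self.categories.index(BASE_CATEGORY)]

    def column(self, category: str) -> np.ndarray:
        return self.scores[:, self.categories.index(category)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.categories)
        df.insert(0, "id", self.ids)
        return df


def compute_ld_scores(
    panel: ReferencePanel,
    annotations: AnnotationMatrix | None = None,
    window_bp: int = 1_000_000,
    chunk: int = 512,
) -> LDScoreTable:
    """LD scores from panel genotypes with the unbiased r2 estimator.

    Off-diagonal r2 estimates use r_hat^2 - (1 - r_hat^2)/(n - 2), clipped at
    zero so scores stay interpretable (l_base >= 1, with the self term
    included as exactly 1). Pairs beyond ``window_bp`` contribute zero.
    """
    n, M = panel.genotypes.shape
    if annotations is None:
        annotations = AnnotationMatrix.base_only(M)
    annotations.check_aligned(M)
    span = panel.block_length * np.median(np.diff(panel.variants["pos"].to_numpy()[: panel.block_length]))
    if window_bp < span:
        warnings.warn("window smaller than the LD block span; scores will be truncated")

    X = panel.standardized() / np.sqrt(n)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    A = annotations.membership.astype(float)
    out = np.zeros((M, len(annotations.categories)))

    for i0 in range(0, M, chunk):
        i1 = min(i0 + chunk, M)
        # union window for the chunk, then mask per pair
        lo = np.searchsorted(pos, pos[i0] - window_bp) if chrom[i0] == chrom[i1 - 1] else 0
        lo = 0 if chrom[0] != chrom[i0] else lo  # conservative across chromosomes
        w0, w1 = 0, M
        # restrict to the widest plausible window for speed when single-sorted
        w0 = np.searchsorted(pos, pos[i0] - window_bp)
        w1 = np.searchsorted(pos, pos[i1 - 1] + window_bp, side="right")
        r = X[:, w0:w1].T @ X[:, i0:i1]
        r2 = r * r
        adj = r2 - (1.0 - r2) / max(n - 2, 1)
        np.clip(adj, 0.0, None, out=adj)
        rows = np.arange(w0, w1)
        cols = np.arange(i0, i1)
        in_window = (
            np.abs(pos[rows, None] - pos[None, cols]) <= window_bp
        ) & (chrom[rows, None] == chrom[None, cols])
        adj *= in_window
        adj[cols - w0, np.arange(i1 - i0)] = 1.0  # self term, exact
        out[i0:i1] = adj.T @ A[w0:w1]

    return LDScoreTable(
        categories=list(annotations.categories),
        scores=out,
        ids=panel.variants["id"].to_numpy(),
    )


def block_ld_scores(
    panel: ReferencePanel, annotations: AnnotationMatrix | None = None
) -> LDScoreTable:
    """Exact LD scores from the panel's block correlation structure.

    For simulated panels the empirical block R is the generating (population)
    LD, so summing its squares gives the exact l_{j,c} with no estimation
    noise; this is the right regressor when the panel itself generated the
    summary statistics. For external data use :func:`compute_ld_scores`.
    """
    M = panel.n_variants
    if annotations is None:
        annotations = AnnotationMatrix.base_only(M)
    annotations.check_aligned(M)
    A = annotations.membership.astype(float)
    out = np.zeros((M, len(annotations.categories)))
    for b, sl in enumerate(panel.block_slices()):
        r2 = panel.block_correlations()[b] ** 2
        out[sl] = r2 @ A[sl]
    return LDScoreTable(
        categories=list(annotations.categories),
        scores=out,
        ids=panel.variants["id"].to_numpy(),
    )


# --------------------------------------------------------------------------
# weighted regression with block jackknife
# --------------------------------------------------------------------------


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_jackknife(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """WLS coefficients plus delete-one-block jackknife replicates."""
    m, k = X.shape
    bounds = _block_bounds(m, n_blocks)
    Xw = X * w[:, None]
    A_blocks = np.empty((n_blocks, k, k))
    c_blocks = np.empty((n_blocks, k))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        A_blocks[b] = Xw[sl].T @ X[sl]
        c_blocks[b] = Xw[sl].T @ y[sl]
    A = A_blocks.sum(axis=0)
    c = c_blocks.sum(axis=0)
    coef = np.linalg.solve(A, c)
    reps = np.empty((n_blocks, k))
    for b in range(n_blocks):
        reps[b] = np.linalg.solve(A - A_blocks[b], c - c_blocks[b])
    return coef, reps


def _jackknife_se(reps: np.ndarray) -> np.ndarray:
    B = reps.shape[0]
    return np.sqrt((B - 1) / B * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))


def _chi2_from(sumstats: pd.DataFrame) -> np.ndarray:
    return (sumstats["beta"].to_numpy() / sumstats["se"].to_numpy()) ** 2


def _ldsc_weights(ell: np.ndarray, N: int, M: int, h2: float, intercept: float) -> np.ndarray:
    ell = np.maximum(ell, 1.0)
    var_term = 2.0 * (N * ell * max(h2, 0.0) / M + intercept) ** 2
    return 1.0 / (ell * var_term)


# --------------------------------------------------------------------------
# fits
# --------------------------------------------------------------------------


@dataclass
class HeritabilityFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    attribution: float | None  # share of inflation ascribed to polygenicity
    per_category: pd.DataFrame | None = None
    tau: np.ndarray | None = None
    dropped_categories: list[str] = field(default_factory=list)
    h2_reps: np.ndarray | None = field(default=None, repr=False)
    intercept_reps: np.ndarray | None = field(default=None, repr=False)

    def h2_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return self.h2 - z * self.h2_se, self.h2 + z * self.h2_se


def _two_pass_weights(
    chi2: np.ndarray, ell: np.ndarray, n: int, M: int, block_count: int
) -> np.ndarray:
    """Standard LDSC weights from a rough unweighted first pass."""
    X = np.column_stack([np.ones_like(ell), ell])
    coef0, _ = _wls_jackknife(X, chi2, np.ones_like(ell), block_count)
    h2_0 = float(np.clip(coef0[1] * M / n, 0.0, 1.0))
    return _ldsc_weights(ell, n, M, h2_0, max(coef0[0], 1.0))


def _cap_chi2(chi2: np.ndarray, N: int, chi2_cap: float | None) -> np.ndarray:
    cap = max(80.0, 0.001 * N) if chi2_cap is None else chi2_cap
    return np.minimum(chi2, cap)


def fit_ldsc(
    sumstats: pd.DataFrame,
    ldscores: np.ndarray | LDScoreTable,
    n: int,
    block_count: int = 200,
    m: int | None = None,
    chi2_cap: float | None = None,
) -> HeritabilityFit:
    """Univariate LD score regression of chi2 on the base LD score.

    h2 = slope * M / N; the attribution of mean-chi2 inflation to
    polygenicity is (mean chi2 - intercept) / (mean chi2 - 1), reported only
    when mean chi2 > 1.
    """
    ell = ldscores.base if isinstance(ldscores, LDScoreTable) else np.asarray(ldscores, float)
    chi2 = _chi2_from(sumstats)
    if len(chi2) != len(ell):
        raise InvalidArgumentError("sumstats and LD scores are not aligned")
    if len(chi2) < block_count:
        raise InvalidArgumentError("need at least block_count SNPs")
    M = m if m is not None else len(ell)
    chi2 = _cap_chi2(chi2, n, chi2_cap)

    X = np.column_stack([np.ones_like(ell), ell])
    w = _two_pass_weights(chi2, ell, n, M, block_count)
    coef, reps = _wls_jackknife(X, chi2, w, block_count)

    h2 = coef[1] * M / n
    h2_reps = reps[:, 1] * M / n
    se = _jackknife_se(np.column_stack([reps[:, 0], h2_reps]))
    mean_chi2 = float(chi2.mean())
    attribution = None
    if mean_chi2 > 1.0:
        attribution = float((mean_chi2 - coef[0]) / (mean_chi2 - 1.0))
    return HeritabilityFit(
        h2=float(h2),
        h2_se=float(se[1]),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        mean_chi2=mean_chi2,
        attribution=attribution,
        h2_reps=h2_reps,
        intercept_reps=reps[:, 0],
    )


def fit_stratified_ldsc(
    sumstats: pd.DataFrame,
    ldscores: LDScoreTable,
    annotations: AnnotationMatrix,
    n: int,
    block_count: int = 200,
    chi2_cap: float | None = None,
) -> HeritabilityFit:
    """Stratified LD score regression across (possibly overlapping) categories.

    Reports per-category tau, prop_h2, prop_snps, enrichment and a jackknife
    z-test p-value on (prop_h2 - prop_snps). Collinear categories are dropped
    with a warning.
    """
    chi2 = _chi2_from(sumstats)
    M = annotations.n_variants
    if len(chi2) != M or ldscores.scores.shape[0] != M:
        raise InvalidArgumentError("sumstats, LD scores, annotations not aligned")
    chi2 = _cap_chi2(chi2, n, chi2_cap)

    cats = list(ldscores.categories)
    S = ldscores.scores.copy()
    # drop collinear categories (keep base)
    keep = list(range(len(cats)))
    dropped: list[str] = []
    X_full = np.column_stack([np.ones(M), S])
    rank = np.linalg.matrix_rank(X_full)
    while rank < X_full.shape[1] and len(keep) > 1:
        for idx in reversed(keep):
            if cats[idx] == BASE_CATEGORY:
                continue
            trial = [i for i in keep if i != idx]
            Xt = np.column_stack([np.ones(M), S[:, trial]])
            if np.linalg.matrix_rank(Xt) == Xt.shape[1]:
                dropped.append(cats[idx])
                keep = trial
                X_full = Xt
                rank = Xt.shape[1]
                break
        else:
            break
    if dropped:
        warnings.warn(f"dropped collinear categories: {dropped}")
    cats_kept = [cats[i] for i in keep]
    S = S[:, keep]
    A = annotations.membership[:, [annotations.categories.index(c) for c in cats_kept]].astype(float)

    ell_base = ldscores.base
    w = _two_pass_weights(chi2, ell_base, n, M, block_count)

    X = np.column_stack([np.ones(M), S])
    coef, reps = _wls_jackknife(X, chi2, w, block_count)
    tau = coef[1:] / n
    tau_reps = reps[:, 1:] / n

    m_c = A.sum(axis=0)
    h2_j = A @ tau  # per-SNP heritability under the tau model
    h2_total = float(h2_j.sum())
    h2_c = (A * h2_j[:, None]).sum(axis=0)
    prop_snps = m_c / M

    def _props(tau_vec: np.ndarray) -> tuple[float, np.ndarray]:
        hj = A @ tau_vec
        tot = hj.sum()
        return tot, (A * hj[:, None]).sum(axis=0) / tot

    prop_h2 = h2_c / h2_total if h2_total != 0 else np.full_like(h2_c, np.nan)
    enrichment = prop_h2 / prop_snps

    B = reps.shape[0]
    diff_reps = np.empty((B, len(cats_kept)))
    h2_reps = np.empty(B)
    for b in range(B):
        tot_b, prop_b = _props(tau_reps[b])
        diff_reps[b] = prop_b - prop_snps
        h2_reps[b] = tot_b
    diff_se = _jackknife_se(diff_reps)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (prop_h2 - prop_snps) / diff_se
    enrichment_p = 2.0 * norm.sf(np.abs(z))

    per_category = pd.DataFrame(
        {
            "category": cats_kept,
            "tau": tau,
            "prop_snps": prop_snps,
            "prop_h2": prop_h2,
            "enrichment": enrichment,
            "enrichment_p": enrichment_p,
        }
    )
    se_all = _jackknife_se(np.column_stack([reps[:, 0], h2_reps]))
    mean_chi2 = float(chi2.mean())
    attribution = None
    if mean_chi2 > 1.0:
        attribution = float((mean_chi2 - coef[0]) / (mean_chi2 - 1.0))
    return HeritabilityFit(
        h2=h2_total,
        h2_se=float(se_all[1]),
        intercept=float(coef[0]),
        intercept_se=float(se_all[0]),
        mean_chi2=mean_chi2,
        attribution=attribution,
        per_category=per_category,
        tau=tau,
        dropped_categories=dropped,
        h2_reps=h2_reps,
        intercept_reps=reps[:, 0],
    )


# --------------------------------------------------------------------------
# genetic correlation
# --------------------------------------------------------------------------


@dataclass
class GeneticCorrelation:
    rg: float | None
    se: float | None
    p: float | None
    gencov: float
    h2_a: float
    h2_b: float
    cross_intercept: float
    flagged: str | None = None


def harmonize(sumstats_a: pd.DataFrame, sumstats_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two tables on id, flipping beta_b where alleles are swapped."""
    m = sumstats_a.merge(sumstats_b, on="id", suffixes=("_a", "_b"))
    same = (m["effect_allele_a"] == m["effect_allele_b"]) & (
        m["other_allele_a"] == m["other_allele_b"]
    )
    flipped = (m["effect_allele_a"] == m["other_allele_b"]) & (
        m["other_allele_a"] == m["effect_allele_b"]
    )
    m = m[same | flipped].copy()
    sign = np.where(same[same | flipped], 1.0, -1.0)
    m["beta_b"] = m["beta_b"] * sign
    return m


def fit_genetic_correlation(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    ldscores: np.ndarray | LDScoreTable,
    n_a: int,
    n_b: int,
    n_overlap: int = 0,
    block_count: int = 200,
    m: int | None = None,
) -> GeneticCorrelation:
    """Cross-trait LD score regression.

    rg = gencov / sqrt(h2_a * h2_b); sample overlap is absorbed by the free
    cross-trait intercept. SE and p by delete-one block jackknife of the
    whole pipeline.
    """
    ell = ldscores.base if isinstance(ldscores, LDScoreTable) else np.asarray(ldscores, float)
    merged = harmonize(sumstats_a, sumstats_b)
    if len(merged) != len(ell):
        # align scores to the merged set by id when a table is provided
        if isinstance(ldscores, LDScoreTable):
            lut = pd.Series(ell, index=ldscores.ids)
            ell = lut.loc[merged["id"]].to_numpy()
        else:
            raise InvalidArgumentError("LD scores not aligned to the harmonized SNP set")
    M = m if m is not None else len(ell)
    z_a = merged["beta_a"].to_numpy() / merged["se_a"].to_numpy()
    z_b = merged["beta_b"].to_numpy() / merged["se_b"].to_numpy()

    X = np.column_stack([np.ones_like(ell), ell])

    def _full(zA, zB):
        wA = np.ones_like(ell)
        cA, _ = _wls_jackknife(X, zA**2, wA, block_count)
        cB, _ = _wls_jackknife(X, zB**2, wA, block_count)
        h2a0 = np.clip(cA[1] * M / n_a, 0, 1)
        h2b0 = np.clip(cB[1] * M / n_b, 0, 1)
        wa = _ldsc_weights(ell, n_a, M, h2a0, max(cA[0], 1.0))
        wb = _ldsc_weights(ell, n_b, M, h2b0, max(cB[0], 1.0))
        w = np.sqrt(wa * wb)
        return w, wa, wb

    w, wa, wb = _full(z_a, z_b)
    coef_a, reps_a = _wls_jackknife(X, z_a**2, wa, block_count)
    coef_b, reps_b = _wls_jackknife(X, z_b**2, wb, block_count)
    coef_x, reps_x = _wls_jackknife(X, z_a * z_b, w, block_count)

    h2_a = coef_a[1] * M / n_a
    h2_b = coef_b[1] * M / n_b
    gencov = coef_x[1] * M / np.sqrt(n_a * n_b)
    if h2_a <= 0 or h2_b <= 0:
        return GeneticCorrelation(
            rg=None, se=None, p=None, gencov=float(gencov),
            h2_a=float(h2_a), h2_b=float(h2_b),
            cross_intercept=float(coef_x[0]),
            flagged="non-positive heritability estimate; rg undefined",
        )
    rg = gencov / np.sqrt(h2_a * h2_b)

    B = reps_x.shape[0]
    rg_reps = np.empty(B)
    for b in range(B):
        ha = reps_a[b, 1] * M / n_a
        hb = reps_b[b, 1] * M / n_b
        gc = reps_x[b, 1] * M / np.sqrt(n_a * n_b)
        rg_reps[b] = gc / np.sqrt(ha * hb) if ha > 0 and hb > 0 else rg
    se = float(_jackknife_se(rg_reps[:, None])[0])
    p = float(2.0 * norm.sf(abs(rg / se))) if se > 0 else 0.0
    return GeneticCorrelation(
        rg=float(rg),
        se=se,
        p=p,
        gencov=float(gencov),
        h2_a=float(h2_a),
        h2_b=float(h2_b),
        cross_intercept=float(coef_x[0]),
    )
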
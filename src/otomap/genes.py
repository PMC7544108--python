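"""Gene-level association and expression-based enrichment.

The gene statistic is the mean chi-square of the SNPs in the gene body.
Under the null the member z-scores are multivariate normal with the local
LD correlation R, so the statistic is distributed as a weighted sum of
1-df chi-squares with weights the eigenvalues of R; the tail is evaluated
by Imhof-type numeric integration (Monte-Carlo fallback). The gene z-score
is the probit transform of the resulting p-value.

Competitive gene-set and gene-property tests regress gene z on membership
(or a cell type's expression profile), controlling for gene length, SNP
count and LD density — the standard confounders of competitive tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm, rankdata, t as t_dist

from ._errors import InvalidArgumentError

MHC_DEFAULT = ("6", 25_000_000, 34_000_000)  # extended-LD region excluded by convention


# --------------------------------------------------------------------------
# SNP-to-gene mapping
# --------------------------------------------------------------------------


def map_snps_to_genes(
    sumstats: pd.DataFrame,
    genes: pd.DataFrame,
    exclusion_regions: list[tuple[str, int, int]] | None = None,
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose body contains it (closed interval).

    SNPs inside any exclusion region (chrom, start, end; 1-based closed) are
    dropped from all genes.
    """
    excluded = np.zeros(len(sumstats), dtype=bool)
    chrom = sumstats["chrom"].astype(str).to_numpy()
    pos = sumstats["pos"].to_numpy()
    for c, s, e in exclusion_regions or []:
        excluded |= (chrom == str(c)) & (pos >= s) & (pos <= e)
    mapping: dict[str, list[str]] = {}
    for gene_id, gchrom, start, end in genes[["gene_id", "chrom", "start", "end"]].itertuples(
        index=False
    ):
        hit = (~excluded) & (chrom == str(gchrom)) & (pos >= start) & (pos <= end)
        ids = sumstats.loc[hit, "id"].tolist()
        if ids:
            mapping[gene_id] = ids
    return mapping


# --------------------------------------------------------------------------
# weighted chi-square tail
# --------------------------------------------------------------------------


def weighted_chi2_sf(q: float, lam: np.ndarray, tol: float = 1e-8, mc_draws: int = 1_000_000,
                     rng: np.random.Generator | None = None) -> float:
    """P(sum_i lam_i * chi2_1 > q) by Imhof integration, Monte-Carlo fallback."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    if q <= 0:
        return 1.0
    if np.ptp(lam) <= 1e-10 * lam.max():  # all weights equal: exact chi-square
        from scipy.stats import chi2 as chi2_dist

        return float(chi2_dist.sf(q / lam[0], df=lam.size))

    def rho(u):
        return np.exp(0.25 * np.sum(np.log1p(np.square(lam[:, None] * u)), axis=0))

    # truncation point: beyond U the integral over whole oscillation periods
    # is bounded by ~ (4/q) * envelope(U) (integration by parts)
    target = tol * 0.1
    U = 1.0
    while (4.0 / max(q, 1e-2)) / (U * rho(np.array([U]))[0]) > target and U < 4e6:
        U *= 2.0
    omega = 0.5 * (lam.sum() + q)  # max oscillation frequency of the integrand
    n_pts = int(min(max(4000, 16 * U * omega / (2 * np.pi)), 4_000_000))
    if n_pts < 4_000_000:
        u = np.linspace(0.0, U, n_pts + 1)
        theta = 0.5 * np.sum(np.arctan(lam[:, None] * u[1:]), axis=0) - 0.5 * q * u[1:]
        f = np.empty(n_pts + 1)
        f[0] = 0.5 * (lam.sum() - q)  # limit of sin(theta)/ (u rho) at u -> 0
        f[1:] = np.sin(theta) / (u[1:] * rho(u[1:]))
        val = integrate.simpson(f, x=u)
        p = 0.5 + val / np.pi
        if -1e-5 <= p <= 1 + 1e-5:
            return float(min(max(p, 0.0), 1.0))
    rng = rng or np.random.default_rng(0)
    draws = (lam[None, :] * rng.standard_normal((mc_draws, lam.size)) ** 2).sum(axis=1)
    return float((1 + (draws > q).sum()) / (mc_draws + 1))


# --------------------------------------------------------------------------
# gene test
# --------------------------------------------------------------------------


def gene_test(
    gene_snp_map: dict[str, list[str]],
    sumstats: pd.DataFrame,
    ld,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean-chi-square gene test against the weighted-chi-square null.

    Returns one row per gene: n_snps, statistic, p, z (= probit of 1-p) and
    the competitive-test covariates (log gene length if ``genes`` given,
    log n_snps, LD density = mean off-diagonal r2 among member SNPs).
    """
    stats = sumstats.set_index("id")
    chi2_by_id = (stats["beta"] / stats["se"]) ** 2
    lengths = (
        genes.set_index("gene_id").eval("end - start + 1") if genes is not None else None
    )
    rows = []
    for gene_id, snp_ids in gene_snp_map.items():
        snp_ids = [s for s in snp_ids if s in chi2_by_id.index]
        k = len(snp_ids)
        if k == 0:
            continue  # gene skipped
        chi2 = chi2_by_id[snp_ids].to_numpy()
        stat = float(chi2.mean())
        R = ld.corr_matrix(snp_ids)
        lam = np.linalg.eigvalsh(R)
        p = weighted_chi2_sf(k * stat, lam)
        p = min(max(p, 1e-300), 1.0)
        off = R[~np.eye(k, dtype=bool)] ** 2 if k > 1 else np.array([0.0])
        rows.append(
            {
                "gene_id": gene_id,
                "n_snps": k,
                "stat": stat,
                "p": p,
                "z": float(norm.isf(p)),
                "log_length": float(np.log(lengths[gene_id])) if lengths is not None else 0.0,
                "log_n_snps": float(np.log(k)),
                "ld_density": float(off.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_snps", "stat", "p", "z", "log_length", "log_n_snps", "ld_density"],
    )


COVARIATE_COLUMNS = ["log_length", "log_n_snps", "ld_density"]


def _design(gene_results: pd.DataFrame, predictor: np.ndarray, covariates: list[str]):
    cols = [np.ones(len(gene_results)), predictor]
    for c in covariates:
        v = gene_results[c].to_numpy(dtype=float)
        if np.std(v) > 0:
            cols.append(v)
    return np.column_stack(cols)


def _ols_one_sided(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS; returns (beta, se, one-sided p for beta > 0) of column 1."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - rank
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    tstat = coef[1] / se
    return float(coef[1]), se, float(t_dist.sf(tstat, dof))


def gene_set_test(
    gene_results: pd.DataFrame,
    set_membership: dict[str, bool] | set,
    covariates: list[str] = COVARIATE_COLUMNS,
) -> tuple[float, float, float]:
    """Competitive gene-set test: z ~ membership + covariates, one-sided."""
    if isinstance(set_membership, (set, frozenset, list)):
        member = gene_results["gene_id"].isin(set_membership).to_numpy()
    else:
        member = gene_results["gene_id"].map(set_membership).fillna(False).to_numpy(bool)
    n_in = int(member.sum())
    if n_in < 2 or len(member) - n_in < 2:
        raise InvalidArgumentError("need at least two genes inside and outside the set")
    X = _design(gene_results, member.astype(float), covariates)
    return _ols_one_sided(X, gene_results["z"].to_numpy())


@dataclass
class GenePropertyResult:
    celltype: str
    beta: float
    se: float
    p: float
    flagged: str | None = None


def gene_property_test(
    gene_results: pd.DataFrame,
    expression: pd.DataFrame,
    celltype: str,
    covariates: list[str] = COVARIATE_COLUMNS,
    average: pd.Series | None = None,
    center: str = "mean",
) -> GenePropertyResult:
    """Gene-property test: z ~ expression[celltype] + across-type average + covariates.

    One-sided for a positive coefficient; conditioning on the per-gene
    across-type average (``center='median'`` switches to the row median)
    removes overall-expression effects, isolating cell-type specificity.
    """
    shared = gene_results["gene_id"][gene_results["gene_id"].isin(expression.index)]
    gr = gene_results.set_index("gene_id").loc[shared]
    x = expression.loc[shared, celltype].to_numpy(dtype=float)
    if np.std(x) == 0:
        return GenePropertyResult(celltype, np.nan, np.nan, np.nan, "zero-variance expression")
    if average is None:
        average = expression.mean(axis=1) if center == "mean" else expression.median(axis=1)
    avg = average.loc[shared].to_numpy(dtype=float)

    resid_x = x - np.poly1d(np.polyfit(avg, x, 1))(avg) if np.std(avg) > 0 else x
    if np.std(resid_x) < 1e-12:
        warnings.warn(f"{celltype}: expression collinear with the average; dropped")
        return GenePropertyResult(celltype, 0.0, np.nan, 0.5, "collinear with average")

    gr2 = gr.reset_index()
    cols = [np.ones(len(gr2)), x, avg]
    for c in covariates:
        v = gr2[c].to_numpy(dtype=float)
        if np.std(v) > 0:
            cols.append(v)
    X = np.column_stack(cols)
    beta, se, p = _ols_one_sided(X, gr2["z"].to_numpy())
    return GenePropertyResult(celltype, beta, se, p)


# --------------------------------------------------------------------------
# expression normalization
# --------------------------------------------------------------------------


def normalize_expression(tpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log(TPM+1), then quantile-normalize columns to the mean sorted profile.

    Ties within a column receive the mean of the reference values at the
    tied ranks. Returns the normalized matrix and the per-gene row mean.
    """
    if (tpm.to_numpy() < 0).any():
        raise InvalidArgumentError("TPM values must be nonnegative")
    logged = np.log1p(tpm.to_numpy(dtype=float))
    ref = np.sort(logged, axis=0).mean(axis=1)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        ranks = rankdata(logged[:, j], method="average") - 1  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    norm_df = pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return norm_df, norm_df.mean(axis=1)
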
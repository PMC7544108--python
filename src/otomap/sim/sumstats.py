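"""Generative twin of the LD score regression model.

Marginal z-scores are drawn blockwise as

    z = sqrt(N) * R @ beta + sqrt(intercept) * chol(R) @ eta

with R the panel's empirical block LD correlation and beta the planted
standardized causal effects, so that E[z z'] = intercept * R + N R D R.
Cross-trait noise correlation absorbs sample overlap
(N_overlap * pheno_corr / sqrt(N_a N_b)); cross-trait effect correlation is
the planted genetic correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .._errors import InvalidArgumentError
from ..annotations import AnnotationMatrix
from .panel import ReferencePanel, stage_seed
from .truth import SimulationTruth, check_truth_aligned

SUMSTAT_COLUMNS = [
    "chrom",
    "pos",
    "id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p",
    "n",
]


def gen_sumstats(
    panel: ReferencePanel,
    annotations: AnnotationMatrix,
    truth: SimulationTruth,
    sample_size: int,
    n_traits: int | None = None,
    confounding_intercept: float = 1.0,
    seed: int = 0,
    n_overlap: int | None = None,
    pheno_corr: np.ndarray | None = None,
    tested_fraction: float = 1.0,
) -> list[pd.DataFrame]:
    """Simulate one summary-statistics table per trait ("z-only" mode).

    ``tested_fraction`` < 1 reports only a random subset of panel variants,
    emulating variants present in the reference panel but untested in the
    GWAS.
    """
    if sample_size <= 0:
        raise InvalidArgumentError("sample_size must be positive")
    if confounding_intercept < 1.0:
        raise InvalidArgumentError("confounding_intercept must be >= 1")
    annotations.check_aligned(panel.n_variants)
    check_truth_aligned(truth, panel)
    if n_traits is None:
        n_traits = truth.n_traits
    if n_traits > truth.n_traits:
        raise InvalidArgumentError("truth does not carry effects for that many traits")

    N = int(sample_size)
    if n_overlap is None:
        n_overlap = N  # full overlap: one cohort answering several questions
    if pheno_corr is None:
        pheno_corr = truth.rg[:n_traits, :n_traits]
    noise_corr = np.asarray(pheno_corr, dtype=float) * (n_overlap / N)
    np.fill_diagonal(noise_corr, 1.0)
    Lt = np.linalg.cholesky(noise_corr + 1e-12 * np.eye(n_traits))

    rng = np.random.default_rng(stage_seed(seed, "sumstats"))
    blocks = panel.block_slices()
    R = panel.block_correlations()
    C = panel.block_cholesky()
    beta = truth.causal_effects[:n_traits]

    z = np.empty((n_traits, panel.n_variants))
    for b, sl in enumerate(blocks):
        mean = np.sqrt(N) * beta[:, sl] @ R[b].T
        eta = Lt @ rng.standard_normal((n_traits, sl.stop - sl.start))
        noise = np.sqrt(confounding_intercept) * eta @ C[b].T
        z[:, sl] = mean + noise

    p_allele = panel.eaf
    scale = 1.0 / np.sqrt(2.0 * p_allele * (1.0 - p_allele))
    se = scale / np.sqrt(N)

    keep = np.ones(panel.n_variants, dtype=bool)
    if tested_fraction < 1.0:
        keep = rng.random(panel.n_variants) < tested_fraction

    tables = []
    for t in range(n_traits):
        df = panel.variants.rename(
            columns={"allele_effect": "effect_allele", "allele_other": "other_allele"}
        ).copy()
        df["beta"] = z[t] * se
        df["se"] = se
        df["p"] = chi2_dist.sf(z[t] ** 2, df=1)
        df["n"] = N
        tables.append(df.loc[keep, SUMSTAT_COLUMNS].reset_index(drop=True))
    return tables
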
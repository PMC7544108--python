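"""Target cohorts with multi-frequency hearing thresholds.

Each individual carries genotypes drawn from the panel's generative latent
process and per-frequency thresholds sharing one latent factor, so that
the first principal component of the thresholds captures the genetic
signal. The variance of that shared factor explained by the polygenic
score built from ``score_weights`` is planted exactly at ``score_r2``.
QC-violating variants (missingness, low MAF, Hardy-Weinberg failures) are
injected at configurable rates to exercise cohort filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._errors import InvalidArgumentError
from .panel import ReferencePanel, stage_seed
from .truth import SimulationTruth, check_truth_aligned


@dataclass
class TargetCohort:
    dosages: pd.DataFrame  # individuals x SNP ids; NaN = missing
    variants: pd.DataFrame  # id, chrom, pos, allele_effect, allele_other
    phenotypes: pd.DataFrame  # individuals x frequency thresholds (dB)
    injected: dict


def gen_target_cohort(
    n_individuals: int,
    panel: ReferencePanel,
    truth: SimulationTruth,
    n_frequencies: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
    score_weights: np.ndarray | None = None,
    score_r2: float = 0.05,
    missing_rate: float = 0.01,
    n_low_maf: int = 0,
    n_hwe_violations: int = 0,
) -> TargetCohort:
    """Simulate genotypes plus per-frequency hearing thresholds.

    threshold_f = 25 + 10 * (shared factor + noise_sd * eps_f), where the
    shared factor mixes the standardized polygenic score (weight
    sqrt(score_r2)) with independent variation. ``score_weights`` are
    per-allele effects aligned to panel variants (default: the truth's
    causal effects).
    """
    if n_frequencies < 2:
        raise InvalidArgumentError("need at least two frequencies (PCA undefined)")
    check_truth_aligned(truth, panel)
    if not (0.0 <= score_r2 <= 1.0):
        raise InvalidArgumentError("score_r2 must be in [0, 1]")
    rng = np.random.default_rng(stage_seed(seed, "target_cohort"))

    geno = panel.sample_genotypes(n_individuals, rng).astype(float)
    if score_weights is None:
        score_weights = truth.per_allele_effects(panel)
    score_weights = np.asarray(score_weights, dtype=float)
    if score_weights.shape != (panel.n_variants,):
        raise InvalidArgumentError("score_weights must align to panel variants")

    g = geno @ score_weights
    g_sd = g.std()
    g_std = (g - g.mean()) / g_sd if g_sd > 0 else np.zeros_like(g)
    shared = np.sqrt(score_r2) * g_std + np.sqrt(1.0 - score_r2) * rng.standard_normal(
        n_individuals
    )
    thresholds = 25.0 + 10.0 * (
        shared[:, None] + noise_sd * rng.standard_normal((n_individuals, n_frequencies))
    )

    ids = panel.variants["id"].tolist()
    injected = {"missing": [], "low_maf": [], "hwe": []}
    # missingness
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = np.nan
        injected["missing"] = [ids[j] for j in np.flatnonzero(mask.any(axis=0))]
    # low-MAF variants: overwrite with rare dosages
    cols = rng.choice(panel.n_variants, size=n_low_maf + n_hwe_violations, replace=False)
    for j in cols[:n_low_maf]:
        geno[:, j] = (rng.random(n_individuals) < 0.01).astype(float) + (
            rng.random(n_individuals) < 0.01
        ).astype(float)
        injected["low_maf"].append(ids[j])
    # HWE violations: all heterozygotes (exact-test p ~ 0 at common MAF)
    for j in cols[n_low_maf:]:
        geno[:, j] = 1.0
        injected["hwe"].append(ids[j])

    individuals = [f"ind{i + 1:05d}" for i in range(n_individuals)]
    dosages = pd.DataFrame(geno, index=individuals, columns=ids)
    phen = pd.DataFrame(
        thresholds,
        index=individuals,
        columns=[f"freq_{k + 1}" for k in range(n_frequencies)],
    )
    return TargetCohort(
        dosages=dosages,
        variants=panel.variants.copy(),
        phenotypes=phen,
        injected=injected,
    )
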
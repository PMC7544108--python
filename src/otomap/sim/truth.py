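"""Planted genetic architectures for simulation.

A ``SimulationTruth`` holds realized per-variant causal effects on the
standardized-genotype scale, rescaled exactly so that (a) the summed
per-variant heritability contributions equal ``h2_total`` and (b) each
annotation category's share of h2 over its share of SNPs equals the
requested enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._errors import AlignmentError, InvalidArgumentError
from ..annotations import BASE_CATEGORY, AnnotationMatrix
from .panel import ReferencePanel, stage_seed


@dataclass
class SimulationTruth:
    h2_total: float
    per_annotation_enrichment: dict[str, float]
    causal_effects: np.ndarray  # (n_traits, n_variants), standardized scale
    rg: np.ndarray  # (n_traits, n_traits) planted genetic correlation
    seed: int
    category_of_variant: np.ndarray = field(repr=False, default=None)

    @property
    def n_traits(self) -> int:
        return self.causal_effects.shape[0]

    @property
    def n_variants(self) -> int:
        return self.causal_effects.shape[1]

    def h2_per_variant(self, trait: int = 0) -> np.ndarray:
        """Realized heritability contribution of each variant."""
        return self.causal_effects[trait] ** 2

    def per_allele_effects(self, panel: ReferencePanel, trait: int = 0) -> np.ndarray:
        """Effects per copy of the effect allele."""
        p = panel.eaf
        return self.causal_effects[trait] / np.sqrt(2.0 * p * (1.0 - p))

    def realized_enrichment(self, annotations: AnnotationMatrix, category: str, trait: int = 0) -> float:
        h2j = self.h2_per_variant(trait)
        a = annotations.column(category).astype(bool)
        prop_h2 = h2j[a].sum() / h2j.sum()
        prop_snps = a.mean()
        return float(prop_h2 / prop_snps)


def plant_truth(
    annotations: AnnotationMatrix,
    h2_total: float,
    enrichment: dict[str, float] | None = None,
    rg: float | np.ndarray = 1.0,
    n_traits: int = 1,
    seed: int = 0,
) -> SimulationTruth:
    """Draw realized causal effects with exact planted h2 and enrichment.

    Non-base enrichment categories must be disjoint; variants outside them
    form an implicit complement whose enrichment is the mirror value implied
    by conservation of total h2.
    """
    if not (0.0 <= h2_total <= 1.0):
        raise InvalidArgumentError("h2_total must be in [0, 1]")
    enrichment = dict(enrichment or {})
    enrichment.pop(BASE_CATEGORY, None)
    M = annotations.n_variants
    cats = list(enrichment)
    if cats:
        cols = np.column_stack([annotations.column(c) for c in cats])
        if (cols.sum(axis=1) > 1).any():
            raise InvalidArgumentError("enrichment categories must be disjoint")
    else:
        cols = np.zeros((M, 0))

    # per-variant relative weight = enrichment ratio of its category (1 outside)
    weight = np.ones(M)
    cat_index = np.full(M, -1)
    for k, c in enumerate(cats):
        in_c = cols[:, k].astype(bool)
        if enrichment[c] <= 0:
            raise InvalidArgumentError("enrichment ratios must be positive")
        weight[in_c] = enrichment[c]
        cat_index[in_c] = k

    rg = np.atleast_2d(np.asarray(rg, dtype=float))
    if rg.shape == (1, 1) and n_traits > 1:
        rg = np.full((n_traits, n_traits), float(rg[0, 0]))
    np.fill_diagonal(rg, 1.0)
    if rg.shape != (n_traits, n_traits):
        raise InvalidArgumentError("rg must be scalar or (n_traits, n_traits)")

    rng = np.random.default_rng(stage_seed(seed, "truth"))
    # cross-trait correlated standard normal effects
    L = np.linalg.cholesky(rg + 1e-12 * np.eye(n_traits))
    u = L @ rng.standard_normal((n_traits, M))
    beta = u * np.sqrt(weight)

    if h2_total == 0.0:
        beta = np.zeros_like(beta)
    else:
        # exact per-category h2 shares: share_c = enrichment_c * prop_snps_c,
        # with the complement absorbing the remainder
        shares = {}
        used = 0.0
        for k, c in enumerate(cats):
            prop = float((cat_index == k).mean())
            shares[k] = enrichment[c] * prop
            used += shares[k]
        if used > 1.0 + 1e-12:
            raise InvalidArgumentError(
                "requested enrichments claim more than 100% of heritability"
            )
        shares[-1] = 1.0 - used
        for t in range(n_traits):
            for k in range(-1, len(cats)):
                in_k = cat_index == k
                if not in_k.any():
                    continue
                target = h2_total * shares[k]
                realized = float((beta[t, in_k] ** 2).sum())
                if realized == 0.0:
                    raise InvalidArgumentError("degenerate category draw; change seed")
                beta[t, in_k] *= np.sqrt(target / realized)

    return SimulationTruth(
        h2_total=float(h2_total),
        per_annotation_enrichment=enrichment,
        causal_effects=beta,
        rg=rg,
        seed=int(seed),
        category_of_variant=cat_index,
    )


def check_truth_aligned(truth: SimulationTruth, panel: ReferencePanel) -> None:
    if truth.n_variants != panel.n_variants:
        raise AlignmentError("truth effects not aligned to panel variants")
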
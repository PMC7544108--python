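"""LD-blocked reference genotype panels.

Genotypes are simulated from AR(1) latent Gaussians thresholded to per-
haplotype allele indicators; dosage = sum of two independent haplotypes.
Thresholding a bivariate normal attenuates correlation, so the latent step
correlation within each block is calibrated (via Owen's T) such that the
*dosage* correlation between adjacent variants equals ``within_block_corr``.
Variants in different blocks are independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri, owens_t
from scipy.stats import norm

from .._errors import InvalidArgumentError

_BASES = np.array(list("ACGT"))


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage child seed from one master seed.

    The splitting rule is ``SeedSequence([master, crc32(stage)])``; it is
    recorded in generated file headers so outputs are reproducible per stage.
    """
    return np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])


def _bvn_cdf_equal(h: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 <= h, Z2 <= h) for standard bivariate normals with correlation rho."""
    h = np.asarray(h, dtype=float)
    rho = np.asarray(rho, dtype=float)
    # Owen's T identity for equal thresholds; guard rho -> 1.
    rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    return norm.cdf(h) - 2.0 * owens_t(h, a)


def _calibrate_latent_step(p: np.ndarray, target_corr: float, iters: int = 60) -> np.ndarray:
    """Latent AR(1) step correlation giving dosage correlation ``target_corr``.

    Solves, per block MAF ``p``, the monotone equation
    ``(P11(s) - p^2) / (p (1 - p)) = target_corr`` by bisection.
    """
    p = np.asarray(p, dtype=float)
    if target_corr <= 0.0:
        return np.zeros_like(p)
    h = ndtri(p)
    lo = np.zeros_like(p)
    hi = np.full_like(p, 1.0 - 1e-10)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        corr = (_bvn_cdf_equal(h, mid) - p**2) / (p * (1.0 - p))
        too_low = corr < target_corr
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


@dataclass
class ReferencePanel:
    """Genotype reference panel with block LD structure.

    Attributes
    ----------
    variants : DataFrame with columns chrom, pos, id, allele_effect, allele_other.
    genotypes : (individuals, variants) int8 matrix of effect-allele dosages.
    maf : per-variant minor allele frequency computed from ``genotypes``.
    block_length : number of variants per independent LD block.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    maf: np.ndarray
    block_length: int
    seed: int | None = None
    block_maf: np.ndarray | None = field(default=None, repr=False)
    block_step: np.ndarray | None = field(default=None, repr=False)
    _block_corr: list[np.ndarray] | None = field(default=None, repr=False)

    def sample_genotypes(self, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
        """Draw new individuals from the panel's generative latent process."""
        if self.block_maf is None or self.block_step is None:
            raise ValueError("panel does not carry its latent block parameters")
        thresh = ndtri(self.block_maf)
        n_hap = 2 * n_individuals
        L = self.block_length
        out = np.empty((n_individuals, self.n_variants), dtype=np.int8)
        for b in range(self.n_blocks):
            s = self.block_step[b]
            z = np.empty((n_hap, L))
            z[:, 0] = rng.standard_normal(n_hap)
            if L > 1:
                eps = rng.standard_normal((n_hap, L - 1))
                scale = np.sqrt(1.0 - s * s)
                for k in range(1, L):
                    z[:, k] = s * z[:, k - 1] + scale * eps[:, k - 1]
            alleles = (z < thresh[b]).astype(np.int8)
            out[:, b * L : (b + 1) * L] = alleles[:n_individuals] + alleles[n_individuals:]
        return out

    @property
    def individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.n_variants // self.block_length

    @property
    def eaf(self) -> np.ndarray:
        """Effect-allele frequency per variant."""
        return self.genotypes.mean(axis=0) / 2.0

    def block_slices(self) -> list[slice]:
        L = self.block_length
        return [slice(b * L, (b + 1) * L) for b in range(self.n_blocks)]

    def block_correlations(self) -> list[np.ndarray]:
        """Empirical genotype correlation matrix per LD block (cached)."""
        if self._block_corr is None:
            out = []
            for sl in self.block_slices():
                g = self.genotypes[:, sl].astype(float)
                r = np.corrcoef(g, rowvar=False)
                out.append(np.atleast_2d(r))
            self._block_corr = out
        return self._block_corr

    def block_cholesky(self) -> list[np.ndarray]:
        """Cholesky factors of the per-block correlation matrices (cached)."""
        if not hasattr(self, "_block_chol") or self._block_chol is None:
            self._block_chol = [
                np.linalg.cholesky(r + 1e-10 * np.eye(r.shape[0]))
                for r in self.block_correlations()
            ]
        return self._block_chol

    def standardized(self) -> np.ndarray:
        """Genotypes standardized to zero mean, unit variance per variant."""
        g = self.genotypes.astype(float)
        g -= g.mean(axis=0)
        sd = g.std(axis=0)
        return g / sd

    def r2_pair(self, i: int, j: int) -> float:
        gi = self.genotypes[:, i].astype(float)
        gj = self.genotypes[:, j].astype(float)
        r = np.corrcoef(gi, gj)[0, 1]
        return float(r * r)


def gen_reference_panel(
    n_individuals: int,
    n_variants: int,
    block_length: int,
    within_block_corr: float | tuple[float, float],
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chromosomes: int = 1,
    spacing_bp: int = 1000,
) -> ReferencePanel:
    """Simulate an LD-blocked reference genotype panel.

    Adjacent variants within a block have expected pairwise dosage
    correlation ``within_block_corr``, decaying approximately geometrically
    with distance; variants in different blocks are independent. Passing an
    interval ``(lo, hi)`` draws the adjacent correlation per block uniformly,
    which spreads LD scores across blocks the way real genomes do. MAF is
    drawn per block (shared within a block) so the target correlation is
    always attainable after thresholding.
    """
    if n_individuals <= 0 or n_variants <= 0 or block_length <= 0:
        raise InvalidArgumentError("panel dimensions must be positive")
    if n_variants % block_length != 0:
        raise InvalidArgumentError("n_variants must be divisible by block_length")
    corr_lo, corr_hi = (
        (within_block_corr, within_block_corr)
        if np.isscalar(within_block_corr)
        else within_block_corr
    )
    if not (0.0 <= corr_lo <= corr_hi < 1.0):
        raise InvalidArgumentError("within_block_corr must be in [0, 1)")
    lo, hi = maf_range
    if not (0.01 < lo <= hi <= 0.5):
        raise InvalidArgumentError("maf_range must lie within (0.01, 0.5]")

    rng = np.random.default_rng(stage_seed(seed, "reference_panel"))
    n_blocks = n_variants // block_length
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    block_corr = rng.uniform(corr_lo, corr_hi, size=n_blocks)
    step = np.empty(n_blocks)
    for b in range(n_blocks):
        step[b] = _calibrate_latent_step(block_maf[b : b + 1], block_corr[b])[0]
    thresh = ndtri(block_maf)

    n_hap = 2 * n_individuals
    genotypes = np.empty((n_individuals, n_variants), dtype=np.int8)
    for b in range(n_blocks):
        s = step[b]
        z = np.empty((n_hap, block_length))
        z[:, 0] = rng.standard_normal(n_hap)
        if block_length > 1:
            eps = rng.standard_normal((n_hap, block_length - 1))
            scale = np.sqrt(1.0 - s * s)
            for k in range(1, block_length):
                z[:, k] = s * z[:, k - 1] + scale * eps[:, k - 1]
        alleles = (z < thresh[b]).astype(np.int8)
        genotypes[:, b * block_length : (b + 1) * block_length] = (
            alleles[:n_individuals] + alleles[n_individuals:]
        )

    # no monomorphic variants: flip one genotype to a heterozygote
    freq = genotypes.mean(axis=0) / 2.0
    mono = np.flatnonzero((freq == 0.0) | (freq == 1.0))
    for j in mono:
        genotypes[rng.integers(n_individuals), j] = 1

    eaf = genotypes.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)

    # variant table: blocks assigned to chromosomes contiguously
    blocks_per_chrom = int(np.ceil(n_blocks / n_chromosomes))
    chrom_of_block = np.minimum(np.arange(n_blocks) // blocks_per_chrom, n_chromosomes - 1)
    chrom = np.repeat(chrom_of_block + 1, block_length).astype(str)
    pos = np.empty(n_variants, dtype=np.int64)
    for c in range(1, n_chromosomes + 1):
        mask = chrom == str(c)
        pos[mask] = (np.arange(mask.sum()) + 1) * spacing_bp
    allele_idx = rng.integers(0, 4, size=n_variants)
    other_idx = (allele_idx + rng.integers(1, 4, size=n_variants)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"rs{i + 1}" for i in range(n_variants)],
            "allele_effect": _BASES[allele_idx],
            "allele_other": _BASES[other_idx],
        }
    )
    return ReferencePanel(
        variants=variants,
        genotypes=genotypes,
        maf=maf,
        block_length=block_length,
        seed=seed,
        block_maf=block_maf,
        block_step=step,
    )
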
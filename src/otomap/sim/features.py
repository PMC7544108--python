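"""Synthetic genome geometries: genes, ATAC peaks, blacklist, chain maps,
chromatin loops, enhancers, and chromatin-state segmentations.

Counts are Poisson in the requested densities; intervals are 0-based
half-open, sorted, and within chromosome bounds. Replicate peak sets share
a jittered common core (>= 60% of peaks) the way biological ATAC
replicates do. Chain maps cover a configurable fraction of the source
genome with identity and shifted aligned blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._errors import InvalidArgumentError
from ..chromatin import Chain, ChainMap, PeakSet
from .panel import stage_seed


@dataclass
class GenomeFeatures:
    genes: pd.DataFrame
    peaks: dict[str, tuple[PeakSet, PeakSet]]  # cell class -> replicate pair
    blacklist: PeakSet
    chain: ChainMap
    loops: pd.DataFrame
    enhancers: PeakSet
    segmentation: PeakSet


def _poisson_intervals(rng, chrom_lengths, per_mb, width_lo, width_hi):
    rows = []
    for chrom, length in chrom_lengths.items():
        n = rng.poisson(per_mb * length / 1e6)
        if n == 0:
            continue
        widths = rng.integers(width_lo, width_hi + 1, size=n)
        starts = rng.integers(0, np.maximum(length - widths, 1))
        for s, w in zip(starts, widths):
            rows.append((str(chrom), int(s), int(min(s + w, length))))
    return rows


def gen_genome_features(
    chrom_lengths: dict[str, int],
    n_genes: int,
    peak_density: float,
    loop_density: float,
    state_labels: list[str] | None = None,
    seed: int = 0,
    cell_classes: tuple[str, ...] = ("epithelial", "non_epithelial"),
    bin_size: int = 40_000,
    chain_coverage: float = 0.8,
    blacklist_density: float = 0.2,
    enhancer_density: float = 0.3,
    target_prefix: str = "h",
) -> GenomeFeatures:
    """Simulate all interval-shaped inputs of the pipeline."""
    if any(l <= 0 for l in chrom_lengths.values()):
        raise InvalidArgumentError("chromosome lengths must be positive")
    state_labels = state_labels or [f"state_{i + 1}" for i in range(5)]
    rng = np.random.default_rng(stage_seed(seed, "genome_features"))

    # --- gene models -------------------------------------------------------
    total = sum(chrom_lengths.values())
    gene_rows = []
    for i in range(n_genes):
        chrom = str(rng.choice(list(chrom_lengths), p=[l / total for l in chrom_lengths.values()]))
        length = int(np.clip(rng.lognormal(np.log(20_000), 0.8), 1_000, 500_000))
        start = int(rng.integers(1, max(chrom_lengths[chrom] - length, 2)))
        gene_rows.append(
            {
                "gene_id": f"G{i + 1:04d}",
                "symbol": f"GENE{i + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    genes = (
        pd.DataFrame(gene_rows)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )

    # --- replicate ATAC peaks per cell class -------------------------------
    peaks = {}
    for cls in cell_classes:
        core = _poisson_intervals(rng, chrom_lengths, peak_density * 0.7, 200, 1000)
        if peak_density == 0 or not core:
            if peak_density > 0 and not core:
                warnings.warn(f"peak density produced no peaks for {cls}")
            peaks[cls] = (PeakSet.empty(), PeakSet.empty())
            continue
        reps = []
        for _ in range(2):
            jitter = rng.integers(-50, 51, size=(len(core), 2))
            rows = [
                (c, max(int(s + j0), 0), max(int(e + j1), int(s + j0) + 1))
                for (c, s, e), (j0, j1) in zip(core, jitter)
            ]
            rows += _poisson_intervals(rng, chrom_lengths, peak_density * 0.3, 200, 1000)
            reps.append(PeakSet.from_intervals(rows))
        peaks[cls] = tuple(reps)

    # --- blacklist, enhancers ----------------------------------------------
    bl = _poisson_intervals(rng, chrom_lengths, blacklist_density, 1_000, 10_000)
    blacklist = PeakSet.from_intervals(bl) if bl else PeakSet.empty()
    en = _poisson_intervals(rng, chrom_lengths, enhancer_density, 500, 2_000)
    enhancers = PeakSet.from_intervals(en) if en else PeakSet.empty()

    # --- chain map ----------------------------------------------------------
    chains = []
    for chrom, length in chrom_lengths.items():
        t = 0
        t_blocks = []
        while t < length:
            span = int(rng.integers(30_000, 80_000))
            if rng.random() < chain_coverage:
                t_blocks.append((t, min(t + span, length)))
            t += span
        if not t_blocks:
            continue
        offset = int(rng.integers(0, 1_000_000))
        c = Chain(
            score=float(rng.integers(1_000, 100_000)),
            t_name=str(chrom),
            t_size=int(length),
            t_start=t_blocks[0][0],
            t_end=t_blocks[-1][1],
            q_name=f"{target_prefix}{chrom}",
            q_size=int(length + 2_000_000),
            q_start=t_blocks[0][0] + offset,
            q_end=0,  # fixed below
        )
        q = c.q_start
        for i, (s, e) in enumerate(t_blocks):
            size = e - s
            if i + 1 < len(t_blocks):
                dt = t_blocks[i + 1][0] - e
                dq = dt + int(rng.integers(-200, 201))  # small indel shifts
                dq = max(dq, 0)
            else:
                dt = dq = 0
            c.blocks.append((size, dt, dq))
            q += size + dq
        c.q_end = q
        chains.append(c)
    chain = ChainMap(chains)

    # --- chromatin loops ----------------------------------------------------
    loop_rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = length // bin_size
        n_loops = rng.poisson(loop_density * length / 1e6)
        for _ in range(n_loops):
            if n_bins < 2:
                break
            a = int(rng.integers(0, n_bins - 1))
            max_span = min(n_bins - a - 1, 3_000_000 // bin_size)
            if max_span < 1:
                continue
            b = a + int(rng.integers(1, max_span + 1))
            logp = rng.uniform(-35, -5)
            loop_rows.append(
                {
                    "chromA": str(chrom),
                    "startA": a * bin_size,
                    "chromB": str(chrom),
                    "startB": b * bin_size,
                    "bin_size": bin_size,
                    "p": 10.0**logp,
                }
            )
    loops = pd.DataFrame(
        loop_rows, columns=["chromA", "startA", "chromB", "startB", "bin_size", "p"]
    )
    if loop_density > 0 and len(loops) == 0:
        warnings.warn("loop density produced no loops")

    # --- chromatin-state segmentation (partition) ---------------------------
    seg_rows = []
    state_w = rng.dirichlet(np.ones(len(state_labels)) * 2)
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            span = int(np.clip(rng.exponential(50_000), 5_000, 500_000))
            end = min(pos + span, length)
            label = str(rng.choice(state_labels, p=state_w))
            seg_rows.append({"chrom": str(chrom), "start": pos, "end": end, "name": label})
            pos = end
    segmentation = PeakSet(pd.DataFrame(seg_rows))

    return GenomeFeatures(
        genes=genes,
        peaks=peaks,
        blacklist=blacklist,
        chain=chain,
        loops=loops,
        enhancers=enhancers,
        segmentation=segmentation,
    )
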
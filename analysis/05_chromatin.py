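"""ATAC peak processing, cross-species mapping, and overlap enrichments.

Merges replicate peak calls per cell class (intersect semantics), removes
blacklist-overlapping peaks, projects the surviving peaks through a chain
map to the "human" assembly requiring 50% of bases to map, then tests
(i) permutation overlap enrichment against a validated-enhancer set
constructed to overlap epithelial peaks, and (ii) fold enrichment across a
chromatin-state segmentation.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from otomap.chromatin import (
    PeakSet,
    map_intervals,
    merge_replicate_peaks,
    permutation_enrichment,
    state_enrichment,
    subtract_blacklist,
)
from otomap.sim import gen_genome_features

CHROMS = {"1": 60_000_000, "2": 40_000_000}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    feats = gen_genome_features(CHROMS, 200, peak_density=5, loop_density=2, seed=args.seed + 50)
    rng = np.random.default_rng(args.seed + 51)

    rows = []
    merged_sets = {}
    for cls, (rep1, rep2) in feats.peaks.items():
        merged = merge_replicate_peaks(rep1, rep2)
        clean = subtract_blacklist(merged, feats.blacklist)
        merged_sets[cls] = clean
        print(f"{cls}: {len(rep1)}/{len(rep2)} replicate peaks -> {len(merged)} merged "
              f"-> {len(clean)} after blacklist")

    workspace = PeakSet.from_intervals([(c, 0, l) for c, l in CHROMS.items()])
    # enhancer set built to overlap epithelial peaks (a positive control)
    epi = merged_sets["epithelial"].df
    picked = epi.sample(n=min(30, len(epi)), random_state=args.seed)
    enhancers = PeakSet.from_intervals(
        [
            (r.chrom, max(r.start - 200, 0), r.end + 200)
            for r in picked.itertuples(index=False)
        ]
    )

    for cls, clean in merged_sets.items():
        mapped, report = map_intervals(feats.chain, clean)
        frac = 100 * report["accepted"].mean()
        print(f"{cls}: {frac:.1f}% of peaks map to the target assembly (50%-bases rule)")
        fold, p, _ = permutation_enrichment(
            clean, enhancers, workspace, n_permutations=2000, seed=args.seed
        )
        rows.append({"cell_class": cls, "mapped_pct": frac, "enhancer_fold": fold, "enhancer_p": p})
        print(f"{cls}: enhancer overlap fold = {fold:.2f}, empirical p = {p:.4g}")

    states = state_enrichment(merged_sets["epithelial"], feats.segmentation)
    states.to_csv(args.out / "state_enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(args.out / "chromatin_enrichment.tsv", sep="\t", index=False)
    print(f"wrote {args.out}/chromatin_enrichment.tsv and state_enrichment.tsv")


if __name__ == "__main__":
    main()
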
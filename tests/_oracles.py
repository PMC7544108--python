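"""Brute-force oracles and random-instance generators shared across tests."""

import numpy as np
import pandas as pd

from otomap.ld import TableLD


def random_ld_instance(rng, n_snps=None):
    """Random sumstats + full pairwise r2 table with grouped LD structure."""
    n = n_snps or int(rng.integers(10, 101))
    n_groups = max(1, n // int(rng.integers(3, 10)))
    groups = rng.integers(0, n_groups, size=n)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n, replace=False))
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"v{i}" for i in range(n)],
            "allele_effect": "A",
            "allele_other": "G",
        }
    )
    R2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if groups[i] == groups[j]:
                R2[i, j] = R2[j, i] = rng.uniform(0.5, 1.0)
            else:
                R2[i, j] = R2[j, i] = rng.uniform(0.0, 0.3)
    np.fill_diagonal(R2, 1.0)
    p = 10.0 ** rng.uniform(-12, 0, size=n)
    ss = variants.rename(
        columns={"allele_effect": "effect_allele", "allele_other": "other_allele"}
    ).copy()
    z = np.sqrt(np.maximum(-2 * np.log(np.maximum(p, 1e-300)), 1e-9))  # monotone in p
    ss["se"] = 0.01
    ss["beta"] = z * 0.01
    ss["p"] = p
    ss["n"] = 10_000
    pairs = pd.DataFrame(
        [
            {"idA": f"v{i}", "idB": f"v{j}", "r2": R2[i, j]}
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    ld = TableLD(pairs, variants)
    return ss, ld, R2, variants


def oracle_clump(ss, R2, p_threshold, r2_ind):
    idx = np.flatnonzero(ss["p"].to_numpy() < p_threshold)
    order = sorted(idx, key=lambda i: (ss["p"].iloc[i], ss["pos"].iloc[i]))
    leads = []
    for i in order:
        if all(R2[i, j] < r2_ind for j in leads):
            leads.append(i)
    return [ss["id"].iloc[i] for i in leads]


def oracle_loci(leads, ss, R2, variants, r2_member, merge_bp):
    """Union-find over lead blocks, merging blocks within merge_bp."""
    ids = variants["id"].tolist()
    pos = variants["pos"].to_numpy()
    lead_idx = [ids.index(l) for l in leads]
    blocks = []
    for li in lead_idx:
        members = set(np.flatnonzero(R2[li] > r2_member)) | {li}
        blocks.append((min(pos[m] for m in members), max(pos[m] for m in members), members, li))
    blocks.sort()
    parent = list(range(len(blocks)))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            lo = max(blocks[i][0], blocks[j][0])
            hi = min(blocks[i][1], blocks[j][1])
            gap = lo - hi if lo > hi else 0
            if gap <= merge_bp:
                parent[find(j)] = find(i)
    clusters = {}
    for i in range(len(blocks)):
        clusters.setdefault(find(i), set()).update(blocks[i][2])
    return sorted(frozenset(c) for c in clusters.values())


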
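"""Open-chromatin interval analysis.

ATAC replicate merging (intersect semantics), blacklist subtraction
(whole-peak removal), chain-based cross-assembly interval projection with
the 50%-of-bases acceptance rule, GAT-style permutation overlap enrichment
within a genomic workspace, and chromatin-state fold enrichment.

All intervals are 0-based half-open and strand-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass
class PeakSet:
    """Sorted, deduplicated set of genomic intervals (BED-like)."""

    df: pd.DataFrame  # columns chrom, start, end [, name]

    def __post_init__(self) -> None:
        df = self.df.copy()
        df["chrom"] = df["chrom"].astype(str)
        if (df["end"] < df["start"]).any():
            raise InvalidArgumentError("negative-length interval")
        key = BED_COLUMNS + (["name"] if "name" in df.columns else [])
        df = df.drop_duplicates(subset=BED_COLUMNS).sort_values(
            ["chrom", "start", "end"], kind="stable"
        )
        self.df = df[key].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def by_chrom(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, grp in self.df.groupby("chrom", sort=True):
            out[str(chrom)] = grp[["start", "end"]].to_numpy()
        return out

    @classmethod
    def from_intervals(cls, intervals, names=None) -> "PeakSet":
        df = pd.DataFrame(intervals, columns=BED_COLUMNS)
        if names is not None:
            df["name"] = list(names)
        return cls(df)

    @classmethod
    def empty(cls) -> "PeakSet":
        return cls(pd.DataFrame(columns=BED_COLUMNS))


def _merge_runs(arr: np.ndarray) -> np.ndarray:
    """Collapse overlapping/adjacent sorted intervals into disjoint runs."""
    if len(arr) == 0:
        return arr
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Intersection segments between sorted interval arrays (two-pointer)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return out


def merge_replicate_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Regions common to both replicates (>=1bp overlap, intersect semantics).

    Overlapping intervals within a replicate are union-merged first, so the
    result is a disjoint interval set.
    """
    rows = []
    b_by = rep2.by_chrom()
    for chrom, a in rep1.by_chrom().items():
        if chrom not in b_by:
            continue
        for s, e in _intersect_arrays(_merge_runs(a), _merge_runs(b_by[chrom])):
            rows.append((chrom, s, e))
    if not rows:
        return PeakSet.empty()
    return PeakSet.from_intervals(rows)


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Remove any peak with >=1bp blacklist overlap (whole-peak removal)."""
    bl = {c: _merge_runs(a) for c, a in blacklist.by_chrom().items()}
    keep = []
    for row in peaks.df.itertuples(index=False):
        arr = bl.get(str(row.chrom))
        if arr is None:
            keep.append(True)
            continue
        i = np.searchsorted(arr[:, 0], row.end)  # first blacklist start >= end
        hit = i > 0 and arr[i - 1, 1] > row.start
        keep.append(not hit)
    return PeakSet(peaks.df[np.array(keep, bool)]) if len(peaks) else PeakSet.empty()


def overlap_bases(a: PeakSet, b: PeakSet) -> int:
    """Total base-pair overlap between two interval sets."""
    total = 0
    b_by = {c: _merge_runs(arr) for c, arr in b.by_chrom().items()}
    for chrom, arr in a.by_chrom().items():
        if chrom in b_by:
            total += sum(e - s for s, e in _intersect_arrays(_merge_runs(arr), b_by[chrom]))
    return int(total)


def overlap_count(a: PeakSet, b: PeakSet) -> int:
    """Number of intervals of ``a`` overlapping ``b`` by >=1bp."""
    count = 0
    b_by = {c: _merge_runs(arr) for c, arr in b.by_chrom().items()}
    for chrom, arr in a.by_chrom().items():
        runs = b_by.get(chrom)
        if runs is None:
            continue
        for s, e in arr:
            i = np.searchsorted(runs[:, 0], e)
            if i > 0 and runs[i - 1, 1] > s:
                count += 1
    return count


# --------------------------------------------------------------------------
# chain maps
# --------------------------------------------------------------------------


@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)  # (size, dt, dq)

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """(t_block_start, q_block_start, size) triples in genome coordinates."""
        out = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            out.append((t, q, size))
            t += size + dt
            q += size + dq
        return out


@dataclass
class ChainMap:
    chains: list[Chain]

    def for_chrom(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.t_name == str(chrom)]


def read_chain(path) -> ChainMap:
    """Parse a UCSC chain file ('+' strands only)."""
    chains = []
    cur: Chain | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                f = line.split()
                if f[4] != "+" or f[9] != "+":
                    raise InvalidArgumentError("only '+' strand chains are supported")
                cur = Chain(
                    score=float(f[1]),
                    t_name=f[2], t_size=int(f[3]), t_start=int(f[5]), t_end=int(f[6]),
                    q_name=f[7], q_size=int(f[8]), q_start=int(f[10]), q_end=int(f[11]),
                )
                chains.append(cur)
            else:
                f = [int(x) for x in line.split()]
                if len(f) == 1:
                    cur.blocks.append((f[0], 0, 0))
                else:
                    cur.blocks.append((f[0], f[1], f[2]))
    return ChainMap(chains)


def write_chain(chain_map: ChainMap, path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(chain_map.chains):
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} + {c.q_start} {c.q_end} {i + 1}\n"
            )
            for j, (size, dt, dq) in enumerate(c.blocks):
                if j == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def map_intervals(
    chain_map: ChainMap, peaks: PeakSet, min_match: float = 0.5
) -> tuple[PeakSet, pd.DataFrame]:
    """Project intervals through chain alignment blocks.

    A peak is accepted iff the fraction of its bases inside aligned blocks of
    its best-scoring overlapping chain is >= ``min_match``; the output
    interval spans the projected bases on the target assembly. Returns the
    mapped set and a per-peak report (mapped fraction, accepted, reason).
    """
    rows = []
    report = []
    for idx, row in enumerate(peaks.df.itertuples(index=False)):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        length = end - start
        cands = [
            c for c in chain_map.for_chrom(chrom) if c.t_start < end and start < c.t_end
        ]
        multi = len(cands) > 1
        if not cands:
            report.append((idx, chrom, start, end, 0.0, False, "no chain"))
            continue
        chain = max(cands, key=lambda c: c.score)
        mapped = 0
        q_lo, q_hi = None, None
        for t0, q0, size in chain.aligned_blocks():
            s = max(start, t0)
            e = min(end, t0 + size)
            if s < e:
                mapped += e - s
                lo = q0 + (s - t0)
                hi = q0 + (e - t0)
                q_lo = lo if q_lo is None else min(q_lo, lo)
                q_hi = hi if q_hi is None else max(q_hi, hi)
        frac = mapped / length if length else 0.0
        accepted = frac >= min_match and mapped > 0
        reason = "multiple chains; best used" if multi else ""
        if accepted:
            rows.append((chain.q_name, q_lo, q_hi))
        report.append((idx, chrom, start, end, frac, accepted, reason))
    mapped_set = PeakSet.from_intervals(rows) if rows else PeakSet.empty()
    rep = pd.DataFrame(
        report,
        columns=["peak_index", "chrom", "start", "end", "mapped_fraction", "accepted", "note"],
    )
    return mapped_set, rep


# --------------------------------------------------------------------------
# permutation enrichment
# --------------------------------------------------------------------------


def _flatten(workspace: PeakSet):
    """Concatenated workspace coordinates: per-segment offsets."""
    segs = []
    for chrom, arr in workspace.by_chrom().items():
        for s, e in _merge_runs(arr):
            segs.append((chrom, int(s), int(e)))
    lengths = np.array([e - s for _, s, e in segs])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return segs, offsets


def permutation_enrichment(
    query: PeakSet,
    reference: PeakSet,
    workspace: PeakSet,
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: str = "bases",
) -> tuple[float, float, dict]:
    """Overlap enrichment of query vs reference by workspace permutation.

    The observed statistic is the base-pair overlap (``mode='bases'``; or
    interval count with ``mode='count'``). The null re-places each query
    interval, lengths preserved, uniformly in flattened workspace
    coordinates. fold = observed / mean(null);
    empirical p = (1 + #{null >= observed}) / (n_permutations + 1).
    """
    segs, offsets = _flatten(workspace)
    W = int(offsets[-1])
    q_lengths = (query.df["end"] - query.df["start"]).to_numpy()
    if q_lengths.sum() > W:
        raise InvalidArgumentError("workspace smaller than total query length")

    # reference in flattened coordinates -> cumulative coverage C(x),
    # piecewise linear with slope 1 inside reference segments
    ref_by = {c: _merge_runs(a) for c, a in reference.by_chrom().items()}
    seg_flat = []
    for (chrom, s, e), off in zip(segs, offsets[:-1]):
        arr = ref_by.get(chrom)
        if arr is None:
            continue
        for rs, re_ in _intersect_arrays(np.array([[s, e]]), arr):
            seg_flat.append((off + rs - s, off + re_ - s))
    seg_flat.sort()
    xs = [0]
    ys = [0]
    acc = 0
    for a, b in seg_flat:
        xs += [a, b]
        ys += [acc, acc + (b - a)]
        acc += b - a
    xs.append(W)
    ys.append(acc)
    xs = np.array(xs, dtype=float)
    ys = np.array(ys, dtype=float)

    if mode == "bases":
        observed = float(overlap_bases(query, reference))
    elif mode == "count":
        observed = float(overlap_count(query, reference))
    else:
        raise InvalidArgumentError("mode must be 'bases' or 'count'")

    rng = np.random.default_rng(seed)
    nq = len(q_lengths)
    starts = rng.random((n_permutations, nq)) * (W - q_lengths)[None, :]
    ends = starts + q_lengths[None, :]
    if mode == "bases":
        ov = np.interp(ends, xs, ys) - np.interp(starts, xs, ys)
        null = ov.sum(axis=1)
    else:
        c_start = np.interp(ends, xs, ys) - np.interp(starts, xs, ys)
        null = (c_start > 0).sum(axis=1).astype(float)

    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    p = float((1 + (null >= observed).sum()) / (n_permutations + 1))
    extras = {"observed": observed, "null_mean": mean_null, "null_sd": float(null.std())}
    return fold, p, extras


# --------------------------------------------------------------------------
# chromatin-state enrichment
# --------------------------------------------------------------------------


def state_enrichment(query: PeakSet, segmentation: PeakSet) -> pd.DataFrame:
    """Per-state fold enrichment of query bases vs workspace composition.

    fold_s = (fraction of query bases in state s) / (fraction of workspace
    in s); the SE is taken across chromosomes. States absent from the
    workspace are flagged with undefined fold.
    """
    if "name" not in segmentation.df.columns:
        raise InvalidArgumentError("segmentation needs a 'name' (state) column")
    states = sorted(segmentation.df["name"].unique())
    chroms = sorted(set(query.df["chrom"]) | set(segmentation.df["chrom"]))
    q_total = query.total_bases
    w_total = segmentation.total_bases
    rows = []
    for state in states:
        seg_s = PeakSet(segmentation.df[segmentation.df["name"] == state][BED_COLUMNS])
        w_frac = seg_s.total_bases / w_total
        if w_frac == 0:
            rows.append({"state": state, "fold": np.nan, "se": np.nan, "flag": "absent"})
            continue
        q_in = overlap_bases(query, seg_s)
        fold = (q_in / q_total) / w_frac if q_total else np.nan
        per_chrom = []
        for chrom in chroms:
            qc = PeakSet(query.df[query.df["chrom"] == chrom]) if len(query) else None
            if qc is None or len(qc) == 0 or qc.total_bases == 0:
                continue
            sc = PeakSet(segmentation.df[segmentation.df["chrom"] == chrom][BED_COLUMNS])
            wc = PeakSet(seg_s.df[seg_s.df["chrom"] == chrom]) if len(seg_s) else None
            denom = (wc.total_bases / sc.total_bases) if wc is not None and sc.total_bases else 0
            if denom == 0:
                continue
            per_chrom.append((overlap_bases(qc, seg_s) / qc.total_bases) / denom)
        se = float(np.std(per_chrom, ddof=1) / np.sqrt(len(per_chrom))) if len(per_chrom) > 1 else np.nan
        rows.append({"state": state, "fold": float(fold), "se": se, "flag": ""})
    return pd.DataFrame(rows, columns=["state", "fold", "se", "flag"])
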
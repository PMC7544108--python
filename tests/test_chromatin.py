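"""Interval algebra, chain projection, permutation and state enrichment.

bedtools (on PATH) serves as the independent oracle for the intersect and
subtract semantics on small random fixtures.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from otomap._errors import InvalidArgumentError
from otomap.chromatin import (
    Chain,
    ChainMap,
    PeakSet,
    map_intervals,
    merge_replicate_peaks,
    overlap_bases,
    permutation_enrichment,
    read_chain,
    state_enrichment,
    subtract_blacklist,
    write_chain,
)

HAVE_BEDTOOLS = shutil.which("bedtools") is not None


def ps(*iv, names=None):
    return PeakSet.from_intervals(list(iv), names=names)


# --------------------------------------------------------------------------
# replicate merging / blacklist
# --------------------------------------------------------------------------


def test_identical_sets_merge_to_themselves():
    a = ps(("1", 10, 50), ("1", 100, 200), ("2", 0, 30))
    assert merge_replicate_peaks(a, a).df.equals(a.df)


def test_disjoint_sets_merge_empty():
    a = ps(("1", 10, 50))
    b = ps(("1", 60, 90))
    assert len(merge_replicate_peaks(a, b)) == 0


def test_six_interval_toy_intersection():
    a = ps(("1", 0, 100), ("1", 200, 300), ("1", 400, 500))
    b = ps(("1", 50, 250), ("1", 450, 460), ("1", 600, 700))
    got = merge_replicate_peaks(a, b)
    want = ps(("1", 50, 100), ("1", 200, 250), ("1", 450, 460))
    assert got.df.equals(want.df)


def test_empty_blacklist_is_identity():
    a = ps(("1", 10, 50), ("2", 5, 9))
    assert subtract_blacklist(a, PeakSet.empty()).df.equals(a.df)


def test_blacklist_covering_everything_empties():
    a = ps(("1", 10, 50), ("1", 100, 150))
    bl = ps(("1", 0, 1000))
    assert len(subtract_blacklist(a, bl)) == 0


def test_partial_overlap_removes_whole_peak():
    a = ps(("1", 10, 50))
    bl = ps(("1", 49, 60))  # clips only the last base
    assert len(subtract_blacklist(a, bl)) == 0  # whole-peak removal, not trimming


@pytest.mark.skipif(not HAVE_BEDTOOLS, reason="bedtools not on PATH")
def test_merge_matches_bedtools_intersect(tmp_path):
    rng = np.random.default_rng(17)
    for rep in range(5):
        def rand_set():
            starts = np.arange(30) * 400 + rng.integers(0, 180, size=30)  # disjoint
            return ps(*[("1", int(s), int(s + rng.integers(10, 200))) for s in starts])

        a, b = rand_set(), rand_set()
        fa, fb = tmp_path / f"a{rep}.bed", tmp_path / f"b{rep}.bed"
        a.df.to_csv(fa, sep="\t", header=False, index=False)
        b.df.to_csv(fb, sep="\t", header=False, index=False)
        out = subprocess.run(
            ["bedtools", "intersect", "-a", fa, "-b", fb],
            capture_output=True, text=True, check=True,
        ).stdout
        rows = [l.split("\t") for l in out.strip().split("\n") if l]
        want = PeakSet.from_intervals([(r[0], int(r[1]), int(r[2])) for r in rows]) if rows else PeakSet.empty()
        got = merge_replicate_peaks(a, b)
        assert got.df.equals(want.df)


def test_base_conservation():
    rng = np.random.default_rng(18)
    a = ps(*[("1", int(s), int(s) + 50) for s in rng.choice(5000, 20, replace=False)])
    b = ps(*[("1", int(s), int(s) + 50) for s in rng.choice(5000, 20, replace=False)])
    # inputs may overlap internally; the result is a disjoint set
    merged = merge_replicate_peaks(a, b)
    assert overlap_bases(merged, a) == merged.total_bases
    assert overlap_bases(merged, b) == merged.total_bases


# --------------------------------------------------------------------------
# chain mapping
# --------------------------------------------------------------------------


def identity_chain(chrom="1", size=1_000_000, q_name=None):
    c = Chain(
        score=1000, t_name=chrom, t_size=size, t_start=0, t_end=size,
        q_name=q_name or chrom, q_size=size, q_start=0, q_end=size,
    )
    c.blocks = [(size, 0, 0)]
    return ChainMap([c])


def test_identity_chain_maps_exactly():
    peaks = ps(("1", 100, 500), ("1", 10_000, 10_100))
    mapped, rep = map_intervals(identity_chain(), peaks)
    assert mapped.df[["start", "end"]].equals(peaks.df[["start", "end"]])
    assert (rep["mapped_fraction"] == 1.0).all()


def test_low_coverage_peak_rejected_at_half_rule():
    # chain covers 40 of 100 peak bases -> rejected at min_match=0.5
    c = Chain(score=10, t_name="1", t_size=10_000, t_start=100, t_end=140,
              q_name="h1", q_size=10_000, q_start=500, q_end=540)
    c.blocks = [(40, 0, 0)]
    peaks = ps(("1", 100, 200))
    mapped, rep = map_intervals(ChainMap([c]), peaks)
    assert len(mapped) == 0
    assert rep["mapped_fraction"].iloc[0] == pytest.approx(0.4)


def test_gap_inside_peak_fraction_and_target_span():
    # 100bp peak; chain aligns 0-50 and 60-100 (10bp gap), target shifted +1000
    # with an extra 5bp insertion on the target side at the gap
    c = Chain(score=10, t_name="1", t_size=10_000, t_start=200, t_end=300,
              q_name="h1", q_size=20_000, q_start=1200, q_end=1305)
    c.blocks = [(50, 10, 15), (40, 0, 0)]
    peaks = ps(("1", 200, 300))
    mapped, rep = map_intervals(ChainMap([c]), peaks)
    assert rep["mapped_fraction"].iloc[0] == pytest.approx(0.9)
    # block arithmetic: first block -> [1200,1250); second -> [1265,1305)
    assert mapped.df.iloc[0]["start"] == 1200
    assert mapped.df.iloc[0]["end"] == 1305


def test_chain_round_trip(tmp_path):
    cm = identity_chain()
    cm.chains[0].blocks = [(100, 5, 7), (200, 0, 0)]
    path = tmp_path / "test.chain"
    write_chain(cm, path)
    back = read_chain(path)
    a, b = cm.chains[0], back.chains[0]
    assert (a.t_name, a.t_start, a.t_end, a.q_name, a.q_start) == (
        b.t_name, b.t_start, b.t_end, b.q_name, b.q_start
    )
    assert a.blocks == b.blocks


def test_mapping_idempotent_on_identity_chain():
    peaks = ps(("1", 100, 500))
    once, _ = map_intervals(identity_chain(), peaks)
    twice, _ = map_intervals(identity_chain(), once)
    assert once.df.equals(twice.df)


# --------------------------------------------------------------------------
# permutation enrichment
# --------------------------------------------------------------------------


def test_reference_equal_workspace_gives_fold_one():
    ws = ps(("1", 0, 100_000))
    query = ps(("1", 100, 600), ("1", 5_000, 5_400))
    fold, p, _ = permutation_enrichment(query, ws, ws, n_permutations=200, seed=1)
    assert fold == pytest.approx(1.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=0.02)


def test_query_inside_sparse_reference_enriched():
    ws = ps(("1", 0, 1_000_000))
    ref = ps(("1", 0, 100_000))  # 10% of workspace
    rng = np.random.default_rng(19)
    starts = np.arange(40) * 2400 + rng.integers(0, 1800, size=40)  # disjoint
    query = ps(*[("1", int(s), int(s + 500)) for s in starts])
    fold, p, _ = permutation_enrichment(query, ref, ws, n_permutations=999, seed=2)
    assert fold == pytest.approx(10.0, rel=0.1)
    assert p == pytest.approx(1.0 / 1000.0)


def test_random_query_fold_near_one():
    ws = ps(("1", 0, 1_000_000))
    ref = ps(("1", 0, 100_000))
    rng = np.random.default_rng(20)
    starts = rng.choice(999_000, 60, replace=False)
    query = ps(*[("1", int(s), int(s + 300)) for s in starts])
    fold, p, ex = permutation_enrichment(query, ref, ws, n_permutations=999, seed=3)
    assert abs(ex["observed"] - ex["null_mean"]) < 2 * ex["null_sd"]


def test_workspace_too_small_errors():
    ws = ps(("1", 0, 100))
    query = ps(("1", 0, 90), ("1", 0, 50))
    with pytest.raises(InvalidArgumentError):
        permutation_enrichment(query, ws, ws, n_permutations=10, seed=0)


# --------------------------------------------------------------------------
# state enrichment
# --------------------------------------------------------------------------


def seg_3state():
    rows = []
    for chrom in ("1", "2"):
        rows += [
            (chrom, 0, 500, "s1"),
            (chrom, 500, 800, "s2"),
            (chrom, 800, 1000, "s3"),
        ]
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def test_state_enrichment_toy_hand_computed():
    seg = seg_3state()
    query = ps(("1", 0, 100), ("2", 600, 700))  # 100bp in s1, 100bp in s2
    res = state_enrichment(query, seg).set_index("state")
    # workspace: s1 50%, s2 30%, s3 20%; query: 50% in s1, 50% in s2
    assert res.loc["s1", "fold"] == pytest.approx(0.5 / 0.5)
    assert res.loc["s2", "fold"] == pytest.approx(0.5 / 0.3)
    assert res.loc["s3", "fold"] == pytest.approx(0.0)


def test_state_query_all_in_one_state():
    seg = seg_3state()
    query = ps(("1", 800, 1000), ("2", 800, 1000))  # all of s3
    res = state_enrichment(query, seg).set_index("state")
    assert res.loc["s3", "fold"] == pytest.approx(1.0 / 0.2)
    assert res.loc["s1", "fold"] == pytest.approx(0.0)


def test_state_absent_from_workspace_flagged():
    seg = seg_3state()
    seg2 = PeakSet(
        pd.concat([seg.df, pd.DataFrame([("3", 0, 0, "s4")], columns=seg.df.columns)])
    )
    query = ps(("1", 0, 100))
    res = state_enrichment(query, seg2).set_index("state")
    assert res.loc["s4", "flag"] == "absent"
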
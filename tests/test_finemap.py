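"""Coding/regulatory annotation and the three-tier prioritization rule."""

import numpy as np
import pandas as pd
import pytest

from otomap.chromatin import PeakSet
from otomap.finemap import (
    assign_distal,
    assign_proximal,
    classify_coding,
    prioritize,
    prioritize_all,
    regulatory_candidates,
)


def cand(rows):
    return pd.DataFrame(rows, columns=["id", "locus_id", "chrom", "pos"])


def eff(rows):
    return pd.DataFrame(rows, columns=["id", "consequence", "gene_id", "aa_change", "cadd_phred"])


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])


# --------------------------------------------------------------------------
# coding classification
# --------------------------------------------------------------------------


def test_deleterious_missense_retained():
    # a KLHDC7B-like missense variant with CADD 16.21 passes the >=10 rule
    c = cand([("rs_a", 31, "22", 50_988_105)])
    e = eff([("rs_a", "missense", "KLHDC7B_like", "Val504Met", 16.21)])
    out = classify_coding(c, e)
    assert list(out["id"]) == ["rs_a"]
    assert out["gene_id"].iloc[0] == "KLHDC7B_like"


def test_missense_below_cadd_threshold_excluded():
    c = cand([("rs_a", 1, "1", 100)])
    e = eff([("rs_a", "missense", "G1", None, 9.9)])
    assert len(classify_coding(c, e)) == 0


def test_synonymous_high_cadd_excluded():
    c = cand([("rs_a", 1, "1", 100)])
    e = eff([("rs_a", "synonymous", "G1", None, 30.0)])
    assert len(classify_coding(c, e)) == 0


def test_unannotated_candidate_defaults_to_noncoding():
    c = cand([("rs_a", 1, "1", 100)])
    assert len(classify_coding(c, eff([]))) == 0


def test_cadd_exactly_at_threshold_retained():
    c = cand([("rs_a", 1, "1", 100)])
    e = eff([("rs_a", "stopgain", "G1", None, 10.0)])
    assert len(classify_coding(c, e)) == 1


# --------------------------------------------------------------------------
# regulatory candidates (OCR flank)
# --------------------------------------------------------------------------


def test_snp_exactly_500bp_left_of_ocr_retained():
    ocr = PeakSet.from_intervals([("1", 10_000, 10_500)], names=["epithelial"])
    # SNP 0-based position 9500 == start - 500: inclusive boundary
    c = cand([("rs_a", 1, "1", 9501)])
    out = regulatory_candidates(c, ocr, flank_bp=500)
    assert list(out["id"]) == ["rs_a"]
    assert out["cell_class"].iloc[0] == "epithelial"


def test_snp_501bp_away_excluded():
    ocr = PeakSet.from_intervals([("1", 10_000, 10_500)])
    c = cand([("rs_a", 1, "1", 9500)])  # 0-based 9499 = start - 501
    assert len(regulatory_candidates(c, ocr, flank_bp=500)) == 0


def test_regulatory_matches_bruteforce_distance_check():
    rng = np.random.default_rng(21)
    ocr_iv = [("1", int(s), int(s) + 400) for s in rng.choice(1_000_000, 50, replace=False)]
    ocr = PeakSet.from_intervals(ocr_iv)
    positions = rng.choice(1_000_000, 300, replace=False) + 1
    c = cand([(f"rs{i}", 1, "1", int(p)) for i, p in enumerate(positions)])
    got = set(regulatory_candidates(c, ocr, flank_bp=500)["id"])
    want = set()
    for i, p in enumerate(positions):
        p0 = p - 1
        for _, s, e in ocr.df.itertuples(index=False):
            if s - 500 <= p0 < e + 500:
                want.add(f"rs{i}")
                break
    assert got == want


# --------------------------------------------------------------------------
# proximal / distal assignment
# --------------------------------------------------------------------------


def reg(rows):
    return pd.DataFrame(rows, columns=["id", "locus_id", "chrom", "pos"])


def test_snp_at_tss_assigned_distance_zero():
    g = genes_df([("G1", "GENE1", "1", 5_000, 9_000, "+")])
    out = assign_proximal(reg([("rs_a", 1, "1", 5_000)]), g)
    assert out["tss_distance"].iloc[0] == 0


def test_two_genes_within_20kb_both_assigned():
    g = genes_df(
        [
            ("G1", "GENE1", "1", 105_000, 120_000, "+"),  # TSS 105k, 5kb away
            ("G2", "GENE2", "1", 50_000, 119_000, "-"),  # TSS 119k, 19kb away
            ("G3", "GENE3", "1", 130_000, 140_000, "+"),  # TSS 130k, 30kb away
        ]
    )
    out = assign_proximal(reg([("rs_a", 1, "1", 100_000)]), g)
    assert sorted(out["gene_id"]) == ["G1", "G2"]


def test_proximal_matches_bruteforce_scan():
    rng = np.random.default_rng(22)
    g = genes_df(
        [
            (f"G{i}", f"GENE{i}", "1", int(s), int(s) + 10_000, "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.choice(2_000_000, 80, replace=False))
        ]
    )
    snps = reg([(f"rs{i}", 1, "1", int(p)) for i, p in enumerate(rng.choice(2_000_000, 100))])
    got = set(map(tuple, assign_proximal(snps, g)[["id", "gene_id"]].to_numpy()))
    want = set()
    for snp in snps.itertuples(index=False):
        for gene in g.itertuples(index=False):
            tss = gene.start if gene.strand == "+" else gene.end
            if abs(tss - snp.pos) <= 20_000:
                want.add((snp.id, gene.gene_id))
    assert got == want


def loops_df(rows):
    return pd.DataFrame(rows, columns=["chromA", "startA", "chromB", "startB", "bin_size", "p"])


def test_weak_loop_excluded_at_threshold():
    g = genes_df([("G1", "GENE1", "1", 800_000, 850_000, "+")])
    lp = loops_df([("1", 40_000, "1", 800_000, 40_000, 1e-20)])
    out = assign_distal(reg([("rs_a", 1, "1", 50_000)]), lp, g, loop_p_max=1e-25)
    assert len(out) == 0


def test_same_bin_snp_tss_not_a_distal_call():
    g = genes_df([("G1", "GENE1", "1", 50_000, 70_000, "+")])  # TSS bin 1
    lp = loops_df([("1", 40_000, "1", 40_000, 40_000, 1e-30)])  # degenerate self-loop
    out = assign_distal(reg([("rs_a", 1, "1", 45_000)]), lp, g)  # SNP bin 1
    assert len(out) == 0


def test_distal_assignment_matches_bin_arithmetic():
    # 3Mb toy: SNP at 130kb (bin 3), strong loop bin3 <-> bin60, gene TSS 2.41Mb (bin 60)
    g = genes_df(
        [
            ("G1", "GENE1", "1", 2_410_000, 2_500_000, "+"),
            ("G2", "GENE2", "1", 2_455_000, 2_500_000, "+"),  # TSS 2.455M: bin 61
        ]
    )
    lp = loops_df(
        [
            ("1", 120_000, "1", 2_400_000, 40_000, 1e-30),
            ("1", 120_000, "1", 2_400_000, 40_000, 1e-28),  # second tissue, weaker
        ]
    )
    out = assign_distal(reg([("rs_a", 1, "1", 130_000)]), lp, g)
    assert list(out["gene_id"]) == ["G1"]
    assert out["loop_p"].iloc[0] == pytest.approx(1e-30)  # min across tissues


# --------------------------------------------------------------------------
# prioritization
# --------------------------------------------------------------------------


def coding_hits(rows):
    return pd.DataFrame(rows, columns=["id", "locus_id", "gene_id", "consequence", "cadd_phred"])


def prox_hits(rows):
    return pd.DataFrame(rows, columns=["id", "locus_id", "gene_id", "tss_distance"])


def dist_hits(rows):
    return pd.DataFrame(rows, columns=["id", "locus_id", "gene_id", "loop_p"])


def test_coding_gene_preempts_distal():
    out = prioritize(
        1,
        coding_hits([("rs_a", 1, "GC", "missense", 20.0)]),
        prox_hits([]),
        dist_hits([("rs_b", 1, "GD1", 1e-30), ("rs_c", 1, "GD2", 1e-28), ("rs_d", 1, "GD3", 1e-30)]),
    )
    assert [g.gene_id for g in out] == ["GC"]
    assert out[0].tier == "coding"


def test_locus_with_no_hits_emits_nothing():
    assert prioritize(5, coding_hits([]), prox_hits([]), dist_hits([])) == []


def test_tier_exclusivity():
    out = prioritize(
        2,
        coding_hits([]),
        prox_hits([("rs_a", 2, "GP", 500)]),
        dist_hits([("rs_b", 2, "GD", 1e-30)]),
    )
    assert {g.tier for g in out} == {"proximal"}


def oracle_prioritize(locus_id, coding, proximal, distal):
    """Independent rule application: dict-based, no shared code."""
    c = {r.gene_id for r in coding.itertuples(index=False) if r.locus_id == locus_id}
    if c:
        return sorted(c), "coding"
    p = {r.gene_id for r in proximal.itertuples(index=False) if r.locus_id == locus_id}
    if p:
        return sorted(p), "proximal"
    d = {r.gene_id for r in distal.itertuples(index=False) if r.locus_id == locus_id}
    if d:
        return sorted(d), "distal"
    return [], None


def random_hits(rng, n_loci=10):
    coding, proximal, distal = [], [], []
    for locus in range(1, n_loci + 1):
        for g in range(rng.integers(0, 3)):
            coding.append((f"rs{locus}_{g}", locus, f"GC{locus}_{g}", "missense", 15.0))
        for g in range(rng.integers(0, 4)):
            proximal.append((f"rp{locus}_{g}", locus, f"GP{locus}_{g}", 1000 * g))
        for g in range(rng.integers(0, 4)):
            distal.append((f"rd{locus}_{g}", locus, f"GD{locus}_{g}", 1e-30))
    return coding_hits(coding), prox_hits(proximal), dist_hits(distal)


def test_randomized_instances_match_rule_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        c, p, d = random_hits(rng)
        table, _ = prioritize_all(list(range(1, 11)), c, p, d)
        for locus in range(1, 11):
            sub = table[table["locus_id"] == locus]
            want_genes, want_tier = oracle_prioritize(locus, c, p, d)
            assert sorted(sub["gene_id"]) == want_genes
            if want_tier:
                assert set(sub["tier"]) == {want_tier}


def test_union_of_evidence_reported_before_tiering():
    c, p, d = (
        coding_hits([("rs1", 1, "GC", "missense", 12.0)]),
        prox_hits([("rs2", 1, "GP", 100)]),
        dist_hits([("rs3", 2, "GD", 1e-30)]),
    )
    _, union = prioritize_all([1, 2], c, p, d)
    assert union == ["GC", "GD", "GP"]


def test_relaxing_loop_threshold_monotone():
    g = genes_df([("G1", "GENE1", "1", 2_410_000, 2_500_000, "+")])
    lp = loops_df([("1", 120_000, "1", 2_400_000, 40_000, 1e-26)])
    snps = reg([("rs_a", 1, "1", 130_000)])
    strict = assign_distal(snps, lp, g, loop_p_max=1e-27)
    relaxed = assign_distal(snps, lp, g, loop_p_max=1e-25)
    assert set(strict["gene_id"]) <= set(relaxed["gene_id"])
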
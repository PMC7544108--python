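"""Functional annotation of candidate SNPs and risk-gene prioritization.

Candidate (r2 > 0.9) SNPs at each risk locus are annotated three ways:

- coding: deleterious protein-altering consequences (CADD Phred >= 10);
- proximal regulatory: within +/-500bp of an open-chromatin region (OCR)
  homologous to cochlear epithelial/non-epithelial ATAC peaks, and within
  20 kb of a transcription start site;
- distal regulatory: OCR-overlapping SNPs connected to a gene's TSS by a
  strong chromatin loop (40 kb bins, p < 1e-25; minimum p across tissues
  per bin pair).

The tier rule then selects per locus: coding genes if any; else proximal
target genes; else distal target genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatin import PeakSet

CODING_CONSEQUENCES = {
    "missense",
    "stopgain",
    "frameshift",
    "nonframeshift_indel",
    "splice_donor",
    "splice_acceptor",
}


@dataclass
class PrioritizedGene:
    locus_id: int
    gene_id: str
    tier: str  # coding | proximal | distal
    evidence_snps: list[tuple[str, str]]  # (snp id, mechanism)


def classify_coding(
    candidates: pd.DataFrame, effects: pd.DataFrame, cadd_min: float = 10.0
) -> pd.DataFrame:
    """Deleterious coding candidates per locus and gene.

    Candidates absent from the effect table default to noncoding. Kept iff
    the consequence is protein-altering and CADD Phred >= ``cadd_min``.
    """
    merged = candidates.merge(effects, on="id", how="left")
    merged["consequence"] = merged["consequence"].fillna("noncoding")
    merged["cadd_phred"] = merged["cadd_phred"].astype(float).fillna(0.0)
    keep = merged["consequence"].isin(CODING_CONSEQUENCES) & (
        merged["cadd_phred"] >= cadd_min
    )
    out = merged.loc[keep, ["id", "locus_id", "gene_id", "consequence", "cadd_phred"]]
    return out.sort_values(["locus_id", "gene_id", "id"], kind="stable").reset_index(drop=True)


def regulatory_candidates(
    candidates: pd.DataFrame, homologous_ocr: PeakSet, flank_bp: int = 500
) -> pd.DataFrame:
    """Candidates within +/-``flank_bp`` of a homologous OCR.

    The window is [start - flank, end + flank) on 0-based coordinates, so a
    SNP exactly ``flank_bp`` left of an OCR start is retained. Cell class is
    taken from the OCR 'name' column when present; one row per (SNP, OCR).
    """
    has_name = "name" in homologous_ocr.df.columns
    rows = []
    by_chrom = {
        str(c): grp.reset_index() for c, grp in homologous_ocr.df.groupby("chrom")
    }
    for cand in candidates.itertuples(index=False):
        grp = by_chrom.get(str(cand.chrom))
        if grp is None:
            continue
        pos0 = int(cand.pos) - 1
        starts = grp["start"].to_numpy() - flank_bp
        ends = grp["end"].to_numpy() + flank_bp
        hits = np.flatnonzero((starts <= pos0) & (pos0 < ends))
        for h in hits:
            rows.append(
                {
                    "id": cand.id,
                    "locus_id": cand.locus_id,
                    "chrom": str(cand.chrom),
                    "pos": int(cand.pos),
                    "ocr_index": int(grp.loc[h, "index"]),
                    "cell_class": str(grp.loc[h, "name"]) if has_name else "",
                }
            )
    return pd.DataFrame(
        rows, columns=["id", "locus_id", "chrom", "pos", "ocr_index", "cell_class"]
    )


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """TSS per gene: start on '+' strand, end on '-'."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["start"], genes["end"]),
        index=genes["gene_id"],
    )


def assign_proximal(
    reg_snps: pd.DataFrame, genes: pd.DataFrame, max_tss_distance: int = 20_000
) -> pd.DataFrame:
    """Every gene whose TSS lies within ``max_tss_distance`` of a regulatory SNP."""
    tss = gene_tss(genes)
    gchrom = genes.set_index("gene_id")["chrom"].astype(str)
    rows = []
    snps = reg_snps.drop_duplicates(subset=["id"])
    for snp in snps.itertuples(index=False):
        same = gchrom == str(snp.chrom)
        dist = (tss[same] - int(snp.pos)).abs()
        for gene_id, d in dist[dist <= max_tss_distance].items():
            rows.append(
                {
                    "id": snp.id,
                    "locus_id": snp.locus_id,
                    "gene_id": gene_id,
                    "tss_distance": int(d),
                }
            )
    return pd.DataFrame(rows, columns=["id", "locus_id", "gene_id", "tss_distance"])


def assign_distal(
    reg_snps: pd.DataFrame,
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    loop_p_max: float = 1e-25,
    bin_size: int = 40_000,
) -> pd.DataFrame:
    """Distal targets through significant chromatin loops between 40kb bins.

    The SNP's bin is floor(pos / bin_size); for each loop with p <
    ``loop_p_max`` touching that bin, every gene whose TSS falls in the
    partner bin is a distal target. Loops from multiple tissues connecting
    the same bin pair contribute their minimum p. Same-bin SNP-TSS pairs are
    never distal calls (loops are strictly inter-bin).
    """
    lp = loops.copy()
    lp["binA"] = lp["startA"] // bin_size
    lp["binB"] = lp["startB"] // bin_size
    lp = lp[lp["p"] < loop_p_max]
    lp = lp[(lp["chromA"].astype(str) != lp["chromB"].astype(str)) | (lp["binA"] != lp["binB"])]
    # minimum chromatin-interaction p per bin pair across tissues
    lp = (
        lp.groupby(["chromA", "binA", "chromB", "binB"], as_index=False)["p"].min()
    )

    tss = gene_tss(genes)
    gchrom = genes.set_index("gene_id")["chrom"].astype(str)
    tss_bin = (tss // bin_size).astype(int)

    rows = []
    snps = reg_snps.drop_duplicates(subset=["id"])
    for snp in snps.itertuples(index=False):
        snp_bin = int(snp.pos) // bin_size
        chrom = str(snp.chrom)
        touching = lp[
            ((lp["chromA"].astype(str) == chrom) & (lp["binA"] == snp_bin))
            | ((lp["chromB"].astype(str) == chrom) & (lp["binB"] == snp_bin))
        ]
        for loop in touching.itertuples(index=False):
            if str(loop.chromA) == chrom and loop.binA == snp_bin:
                partner_chrom, partner_bin = str(loop.chromB), int(loop.binB)
            else:
                partner_chrom, partner_bin = str(loop.chromA), int(loop.binA)
            genes_in = tss_bin[(gchrom == partner_chrom) & (tss_bin == partner_bin)]
            for gene_id in genes_in.index:
                rows.append(
                    {
                        "id": snp.id,
                        "locus_id": snp.locus_id,
                        "gene_id": gene_id,
                        "loop_p": float(loop.p),
                    }
                )
    df = pd.DataFrame(rows, columns=["id", "locus_id", "gene_id", "loop_p"])
    if len(df):
        df = df.sort_values("loop_p").drop_duplicates(subset=["id", "gene_id"]).reset_index(drop=True)
    return df


def prioritize(
    locus_id: int,
    coding_hits: pd.DataFrame,
    proximal_hits: pd.DataFrame,
    distal_hits: pd.DataFrame,
) -> list[PrioritizedGene]:
    """Apply the three-tier rule at one locus.

    Coding genes pre-empt everything; else proximal targets; else distal
    targets. A locus with no hits emits nothing.
    """

    def _at(df):
        return df[df["locus_id"] == locus_id] if len(df) else df

    coding = _at(coding_hits)
    if len(coding):
        out = []
        for gene_id, grp in coding.groupby("gene_id", sort=True):
            ev = [(r.id, f"{r.consequence} (CADD {r.cadd_phred:g})") for r in grp.itertuples(index=False)]
            out.append(PrioritizedGene(locus_id, gene_id, "coding", ev))
        return out
    proximal = _at(proximal_hits)
    if len(proximal):
        out = []
        for gene_id, grp in proximal.groupby("gene_id", sort=True):
            ev = [(r.id, f"OCR overlap; TSS {r.tss_distance}bp") for r in grp.itertuples(index=False)]
            out.append(PrioritizedGene(locus_id, gene_id, "proximal", ev))
        return out
    distal = _at(distal_hits)
    if len(distal):
        out = []
        for gene_id, grp in distal.groupby("gene_id", sort=True):
            ev = [(r.id, f"OCR overlap; loop p={r.loop_p:.2g}") for r in grp.itertuples(index=False)]
            out.append(PrioritizedGene(locus_id, gene_id, "distal", ev))
        return out
    return []


def prioritize_all(
    locus_ids: list[int],
    coding_hits: pd.DataFrame,
    proximal_hits: pd.DataFrame,
    distal_hits: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Tier rule across loci plus the union-of-evidence gene list (pre-tier)."""
    records = []
    union: set[str] = set()
    for df in (coding_hits, proximal_hits, distal_hits):
        if len(df):
            union |= set(df["gene_id"].dropna())
    for locus_id in locus_ids:
        for pg in prioritize(locus_id, coding_hits, proximal_hits, distal_hits):
            records.append(
                {
                    "locus_id": pg.locus_id,
                    "gene_id": pg.gene_id,
                    "tier": pg.tier,
                    "n_evidence_snps": len(pg.evidence_snps),
                    "evidence": "; ".join(f"{s}: {m}" for s, m in pg.evidence_snps),
                }
            )
    table = pd.DataFrame(
        records, columns=["locus_id", "gene_id", "tier", "n_evidence_snps", "evidence"]
    )
    return table, sorted(union)
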
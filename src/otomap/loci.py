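"""Risk-locus definition and fine-mapping candidate expansion.

A locus is built in three steps mirroring standard post-GWAS practice:
greedy LD clumping selects LD-independent lead SNPs (p < 5e-8, mutual
r2 below an independence threshold); each lead's LD block is the set of all
reference-panel variants with r2 above a membership threshold (0.6); blocks
within a merge distance (250 kb) collapse into one locus. The fine-mapping
candidate set extends each locus to every panel variant with r2 > 0.9 to a
lead, including variants never tested in the GWAS (flagged ``tested=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RiskLocus:
    locus_id: int
    chrom: str
    start: int
    end: int
    lead_snps: list[str]
    n_snps: int
    n_gwas_snps: int
    member_ids: list[str] = field(default_factory=list, repr=False)


def clump_lead_snps(
    sumstats: pd.DataFrame,
    ld,
    p_threshold: float = 5e-8,
    r2_independence: float = 0.6,
) -> list[str]:
    """Greedy selection of LD-independent lead SNPs in ascending p.

    A significant SNP is absorbed by an earlier lead iff their r2 is at or
    above ``r2_independence``. Ties at equal p break on smaller genomic
    coordinate. Missing LD raises (no silent independence).
    """
    sig = sumstats.loc[sumstats["p"] < p_threshold]
    sig = sig.sort_values(["p", "chrom", "pos"], kind="stable")
    leads: list[str] = []
    for snp in sig["id"]:
        if any(ld.r2(lead, snp) >= r2_independence for lead in leads):
            continue
        leads.append(snp)
    return leads


def define_risk_loci(
    leads: list[str],
    sumstats: pd.DataFrame,
    ld,
    r2_membership: float = 0.6,
    merge_distance: int = 250_000,
) -> list[RiskLocus]:
    """Union of each lead's LD block, merging blocks within ``merge_distance``.

    Members include reference-panel-only variants (r2 > r2_membership with
    any lead); ``n_gwas_snps`` counts members present in the summary
    statistics. Loci are numbered by genomic order.
    """
    if not leads:
        return []
    lead_p = sumstats.set_index("id")["p"]
    blocks = []
    for lead in leads:
        part = ld.partners(lead, r2_membership)
        blocks.append(
            {
                "lead": lead,
                "chrom": str(part["chrom"].iloc[part["id"].tolist().index(lead)]),
                "start": int(part["pos"].min()),
                "end": int(part["pos"].max()),
                "members": dict(zip(part["id"], part["pos"])),
            }
        )
    blocks.sort(key=lambda b: (b["chrom"], b["start"], b["end"]))

    merged: list[list[dict]] = []
    for b in blocks:
        if (
            merged
            and merged[-1][-1]["chrom"] == b["chrom"]
            and b["start"] - max(x["end"] for x in merged[-1]) <= merge_distance
        ):
            merged[-1].append(b)
        else:
            merged.append([b])

    tested = set(sumstats["id"])
    loci = []
    for i, group in enumerate(
        sorted(merged, key=lambda g: (g[0]["chrom"], min(x["start"] for x in g)))
    ):
        members: dict[str, int] = {}
        for b in group:
            members.update(b["members"])
        group_leads = sorted(
            [b["lead"] for b in group],
            key=lambda s: (lead_p.get(s, np.inf), members.get(s, 0)),
        )
        loci.append(
            RiskLocus(
                locus_id=i + 1,
                chrom=group[0]["chrom"],
                start=min(members.values()),
                end=max(members.values()),
                lead_snps=group_leads,
                n_snps=len(members),
                n_gwas_snps=sum(1 for s in members if s in tested),
                member_ids=sorted(members, key=members.get),
            )
        )
    return loci


def expand_candidates(
    loci: list[RiskLocus],
    ld,
    r2_candidate: float = 0.9,
    sumstats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fine-mapping candidates: panel variants with r2 > r2_candidate to a lead.

    Each candidate records its best lead (highest r2, leads visited in locus
    order) and whether it was tested in the GWAS. Untested candidates carry
    no p-value.
    """
    tested_p = (
        sumstats.set_index("id")["p"] if sumstats is not None else pd.Series(dtype=float)
    )
    rows = []
    for locus in loci:
        best: dict[str, tuple[float, str, str, int]] = {}
        for lead in locus.lead_snps:
            part = ld.partners(lead, r2_candidate)
            for snp, chrom, pos, r2 in part[["id", "chrom", "pos", "r2"]].itertuples(
                index=False
            ):
                if snp not in best or r2 > best[snp][0]:
                    best[snp] = (float(r2), lead, str(chrom), int(pos))
        for snp, (r2, lead, chrom, pos) in sorted(best.items(), key=lambda kv: kv[1][3]):
            is_tested = snp in tested_p.index
            rows.append(
                {
                    "id": snp,
                    "locus_id": locus.locus_id,
                    "chrom": chrom,
                    "pos": pos,
                    "lead_id": lead,
                    "r2_with_lead": r2,
                    "tested": is_tested,
                    "p": float(tested_p[snp]) if is_tested else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["id", "locus_id", "chrom", "pos", "lead_id", "r2_with_lead", "tested", "p"],
    )


def lookup_replication(
    sumstats: pd.DataFrame, snp_ids: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Replication lookups of previously reported SNPs; nominal_flag = p < alpha."""
    p_by_id = sumstats.set_index("id")["p"]
    rows = []
    for snp in snp_ids:
        found = snp in p_by_id.index
        p = float(p_by_id[snp]) if found else np.nan
        rows.append(
            {"id": snp, "found": found, "p": p, "nominal_flag": bool(found and p < alpha)}
        )
    return pd.DataFrame(rows, columns=["id", "found", "p", "nominal_flag"])


def loci_table(loci: list[RiskLocus]) -> pd.DataFrame:
    """Locus summary mirroring the published locus-table columns."""
    return pd.DataFrame(
        [
            {
                "locus": l.locus_id,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "nSNPs": l.n_snps,
                "nGWASSNPs": l.n_gwas_snps,
                "leads": ",".join(l.lead_snps),
            }
            for l in loci
        ]
    )
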
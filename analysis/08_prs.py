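"""Polygenic-score replication in an independent target cohort.

Uses the discovery summary statistics from the simulated GWAS to score an
independent cohort of 1,500 individuals with three-frequency hearing
thresholds (5% of the shared threshold factor explained by the score).
Runs plink-style QC, phenotype PCA, threshold scoring at the standard
p-value cutoffs, and reports incremental R^2 on PC1 per threshold.
"""

import argparse
import importlib.util
from pathlib import Path

HERE = Path(__file__).parent
spec = importlib.util.spec_from_file_location("sim_gwas", HERE / "01_simulate_gwas.py")
sim_gwas = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim_gwas)

from otomap.prs import compute_prs, evaluate_thresholds, phenotype_pca, qc_cohort
from otomap.sim import gen_target_cohort

PLANTED_R2 = 0.05


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel, ann, truth, tables = sim_gwas.simulate(args.seed)
    disc = tables[0]
    # variants untested in the discovery GWAS carry zero scoring weight
    weights = (
        disc.set_index("id")["beta"]
        .reindex(panel.variants["id"])
        .fillna(0.0)
        .to_numpy()
    )

    cohort = gen_target_cohort(
        1500, panel, truth, n_frequencies=3, noise_sd=0.3, seed=args.seed + 80,
        score_weights=weights, score_r2=PLANTED_R2,
        missing_rate=0.01, n_low_maf=10, n_hwe_violations=5,
    )
    geno, report = qc_cohort(cohort.dosages)
    print(f"cohort QC: {report['n_individuals_in']} individuals, "
          f"{report['n_snps_in']} SNPs -> {report['n_snps_out']} SNPs "
          f"(missing {report['removed_snp_missingness']}, MAF {report['removed_maf']}, "
          f"HWE {report['removed_hwe']})")

    pca = phenotype_pca(cohort.phenotypes)
    print(f"phenotype PCA: PC1 explains "
          f"{100 * pca.explained_variance_ratio[0]:.1f}% of threshold variance")

    results = compute_prs(geno, cohort.variants, disc)
    ev = evaluate_thresholds(results, pca.scores["PC1"])
    ev.to_csv(args.out / "prs_thresholds.tsv", sep="\t", index=False)
    best = ev[ev["best"]].iloc[0]
    print(ev[["threshold", "n_snps", "r2", "p"]].to_string(index=False,
                                                           float_format=lambda v: f"{v:.4g}"))
    print(f"best threshold {best['threshold']}: R^2 = {100 * best['r2']:.2f}% "
          f"(planted {100 * PLANTED_R2:.0f}%), p = {best['p']:.2g}")
    print(f"wrote {args.out}/prs_thresholds.tsv")


if __name__ == "__main__":
    main()
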
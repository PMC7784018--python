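#!/usr/bin/env python
"""Selection analyses: polarized spectra, diversity, heterozygosity,
divergent SVs and their location preference.

Computes the outgroup-polarized unfolded SFS for SVs and synonymous SNPs in
landraces and cultivars (projected to 20 alleles, written in the two-line
DFE-input layout), the leftward-shift rank test, theta-pi per group with the
landrace/cultivar ratio, the cultivar heterozygosity excess, and the
Fisher/FDR divergence scan with the per-category location-preference test.
"""

import argparse
from pathlib import Path

import numpy as np

from peachsv import annotate, popgen
from peachsv.cohort import CohortSpec, generate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    study = generate_study(CohortSpec(seed=args.seed))
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    syn_ids = set(study.snp_table.loc[study.snp_table["snp_class"] == "synonymous", "id"])
    for group_name, samples in (("landrace", study.landraces),
                                ("cultivar", study.cultivars)):
        sub_sv = study.sv_genotypes.subset_samples(samples + study.outgroup)
        sv_sites = popgen.polarize(sub_sv, study.outgroup)
        spec = popgen.project_sites(sv_sites, m=20)
        popgen.write_sfs_text(out / f"sfs_sv_{group_name}.txt", spec)
        print(f"{group_name}: {len(sv_sites.derived)} polarized SV sites "
              f"({sv_sites.n_excluded} excluded), projected mass {spec.total_mass:.1f}")

    sv_sites = popgen.polarize(study.sv_genotypes, study.outgroup)
    snp_sites = popgen.polarize(study.snp_genotypes, study.outgroup)
    syn_mask = np.array([m in syn_ids for m in snp_sites.markers])
    p_shift = popgen.sfs_shift_test(sv_sites.frequencies, snp_sites.frequencies[syn_mask])
    print(f"SV-vs-sSNP leftward shift: one-sided Wilcoxon p = {p_shift:.3g}")

    pi_l = popgen.theta_pi(study.sv_genotypes, study.landraces).theta_pi
    pi_c = popgen.theta_pi(study.sv_genotypes, study.cultivars).theta_pi
    print(f"theta-pi (SV): landrace {pi_l:.4f} / cultivar {pi_c:.4f} "
          f"= {popgen.diversity_ratio(pi_l, pi_c):.2f}")

    _, _, p_het = popgen.heterozygosity_ratio(
        study.sv_genotypes, study.cultivars, study.landraces
    )
    print(f"cultivar heterozygosity excess: one-sided Wilcoxon p = {p_het:.3g}")

    div = popgen.divergent_svs(study.sv_genotypes, study.landraces, study.cultivars)
    div.table.to_csv(out / "divergent_svs.tsv", sep="\t", index=False)
    print(f"divergent SVs (FDR < {div.fdr}): {div.n_unfavorable} unfavorable, "
          f"{div.n_favorable} favorable")

    ann = annotate.annotation_table(study.svs, study.genes)
    pref = popgen.location_preference(div, ann)
    pref.to_csv(out / "location_preference.tsv", sep="\t", index=False)
    print("location preference (favorable vs unfavorable):")
    print(pref.to_string(index=False))

    pcs = popgen.genotype_pca(study.sv_genotypes.subset_samples(study.ingroup))
    pcs.to_csv(out / "sv_pca.tsv", sep="\t")
    print(f"-> {out.relative_to(ROOT)}/sfs_sv_*.txt, divergent_svs.tsv, "
          f"location_preference.tsv, sv_pca.tsv")


if __name__ == "__main__":
    main()
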
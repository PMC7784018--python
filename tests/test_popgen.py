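"""Polarized spectra, projection, diversity, divergence, location preference,
and genotype PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peachsv import annotate, popgen
from peachsv.cohort import sample_allele_frequencies
from peachsv.popgen import SpectrumResult
from peachsv.sv_io import MISSING, GenotypeMatrix
from peachsv.annotate import AnnotationResult


def _matrix(dosages, outgroup_dosages):
    d = np.array([list(dosages) + list(outgroup_dosages)], dtype=np.int8)
    n_in, n_out = len(dosages), len(outgroup_dosages)
    return GenotypeMatrix(
        markers=["m1"],
        samples=[f"i{k}" for k in range(n_in)] + [f"o{k}" for k in range(n_out)],
        dosage=d,
    ), [f"o{k}" for k in range(n_out)]


def test_polarize_ancestral_ref():
    m, og = _matrix([0, 1, 2], [0, 0])
    sites = popgen.polarize(m, og)
    assert sites.derived[0] == 3 and sites.n_alleles[0] == 6


def test_polarize_flipped():
    """Outgroup fixed for the alt allele: the ref allele is derived."""
    m, og = _matrix([0, 1, 2], [2, 2])
    sites = popgen.polarize(m, og)
    assert sites.derived[0] == 3  # 6 - 3 ref-allele copies counted as derived


def test_polarize_polymorphic_outgroup_excluded():
    m, og = _matrix([0, 1, 2], [0, 2])
    sites = popgen.polarize(m, og)
    assert len(sites.derived) == 0 and sites.n_excluded == 1


def test_polarize_requires_outgroup():
    m, _ = _matrix([0, 1], [0, 0])
    with pytest.raises(ValueError):
        popgen.polarize(m, [])


def test_polarity_flip_is_exact(rng):
    """Flipping outgroup fixation maps derived counts k -> 2n - k."""
    n_in = 10
    dosages = rng.integers(0, 3, size=n_in)
    m0, og = _matrix(dosages, [0, 0, 0])
    m2, _ = _matrix(dosages, [2, 2, 2])
    s0 = popgen.polarize(m0, og)
    s2 = popgen.polarize(m2, og)
    assert s0.derived[0] + s2.derived[0] == s0.n_alleles[0]


def test_projection_identity_and_combinatorial_case():
    spec = SpectrumResult(n=4, counts=np.array([0.0, 0, 1, 0, 0]))  # one site, i=2
    assert np.allclose(popgen.project_sfs(spec, 4).counts, spec.counts)
    proj = popgen.project_sfs(spec, 2)
    assert np.allclose(proj.counts, [1 / 6, 4 / 6, 1 / 6])


def test_projection_mass_conserved(rng):
    for _ in range(10):
        n = int(rng.integers(5, 40))
        counts = rng.random(n + 1) * 10
        spec = SpectrumResult(n=n, counts=counts)
        m = int(rng.integers(2, n + 1))
        proj = popgen.project_sfs(spec, m)
        assert proj.total_mass == pytest.approx(spec.total_mass)


def test_projection_up_rejected():
    with pytest.raises(ValueError):
        popgen.project_sfs(SpectrumResult(n=4, counts=np.ones(5)), 6)


def test_project_sites_drops_shallow_sites():
    sites = popgen.PolarizedSites(
        markers=["a", "b"], derived=np.array([1, 1]),
        n_alleles=np.array([10, 4]), n_excluded=0,
    )
    proj = popgen.project_sites(sites, m=6)
    assert proj.total_mass == pytest.approx(1.0)  # the n=4 site is dropped
    assert proj.n_excluded == 1


def test_shift_test_identical_and_oracle(rng):
    x = rng.random(200)
    assert popgen.sfs_shift_test(x, x.copy()) == pytest.approx(0.5, abs=0.02)
    # brute-force rank oracle on a tiny input: exact one-sided p by enumeration
    a, b = [0.1, 0.25, 0.3], [0.2, 0.4, 0.5, 0.7]
    u_obs = sum(1 for xa in a for xb in b if xa < xb) + 0.5 * sum(
        1 for xa in a for xb in b if xa == xb
    )
    pooled = a + b
    n_a = len(a)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(1 for xa in ga for xb in gb if xa < xb))
    p_exact = sum(1 for u in us if u >= u_obs) / len(us)
    assert popgen.sfs_shift_test(np.array(a), np.array(b)) == pytest.approx(
        p_exact, abs=1e-9
    )


def test_generated_sv_spectrum_left_of_snps(rng):
    """At the study effect size the SV frequencies sit left of SNP ones."""
    f_sv = sample_allele_frequencies(rng, 1000, sfs_shift=1.0)
    f_snp = sample_allele_frequencies(rng, 3000, sfs_shift=0.0)
    assert popgen.sfs_shift_test(f_sv, f_snp) < 0.05


def test_shift_detection_power(rng):
    """Power >= 0.9 across seeded replicates at study-default sizes."""
    hits = 0
    reps = 40
    for _ in range(reps):
        f_sv = sample_allele_frequencies(rng, 1000, sfs_shift=1.0)
        f_snp = sample_allele_frequencies(rng, 1200, sfs_shift=0.0)
        hits += popgen.sfs_shift_test(f_sv, f_snp) < 0.05
    assert hits / reps >= 0.9


def test_theta_pi_single_site_enumeration():
    # k=2 alt alleles among 4: 6 allele pairs, 4 of them different -> 2/3
    m = GenotypeMatrix(
        markers=["m1"], samples=["a", "b"], dosage=np.array([[1, 1]], dtype=np.int8)
    )
    res = popgen.theta_pi(m)
    assert res.theta_pi == pytest.approx(2 / 3)


def test_theta_pi_monomorphic_zero():
    m = GenotypeMatrix(
        markers=["m1"], samples=["a", "b"], dosage=np.array([[0, 0]], dtype=np.int8)
    )
    assert popgen.theta_pi(m).theta_pi == 0.0


def test_diversity_ratio_printed_values():
    assert popgen.diversity_ratio(0.2359, 0.2035) == pytest.approx(1.16, abs=0.005)


def test_heterozygosity_fractions():
    d = np.array([[1, 1], [1, 0], [1, 0], [1, 0]], dtype=np.int8)
    m = GenotypeMatrix(markers=list("abcd"), samples=["x", "y"], dosage=d)
    ha, hb, _ = popgen.heterozygosity_ratio(m, ["x"], ["y"])
    assert ha[0] == 1.0 and hb[0] == 0.25


def test_cultivar_het_excess(study):
    """The cohort plants a cultivar heterozygosity excess; the rank test
    sees it at P < 0.001."""
    _, _, p = popgen.heterozygosity_ratio(
        study.sv_genotypes, study.cultivars, study.landraces
    )
    assert p < 1e-3


def _bh_oracle(pvals):
    """Brute-force BH step-up."""
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * n / rank)
        q[i] = val
        prev = val
    return q


def test_bh_matches_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    for size in (10, 100, 5000):
        p = rng.random(size)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, _bh_oracle(p))


def test_divergent_extremes_and_direction(study):
    div = popgen.divergent_svs(study.sv_genotypes, study.landraces, study.cultivars)
    t = div.table.set_index("sv")
    for sv_id, direction in study.truth.divergent_ids.items():
        assert t.loc[sv_id, "direction"] == direction
    # equal carrier frequencies -> none
    equal = t[
        (t["carriers_landrace"] / 41).round(1) == (t["carriers_cultivar"] / 108).round(1)
    ]
    assert (equal["direction"] == "none").all()


def test_divergent_group_size_guard(study):
    with pytest.raises(ValueError):
        popgen.divergent_svs(study.sv_genotypes, study.landraces[:1], study.cultivars)


def test_location_preference_planted_upstream():
    """Favorable SVs planted exclusively upstream light up only that row."""
    n = 40
    svs = [f"s{i}" for i in range(2 * n)]
    table = pd.DataFrame(
        {"sv": svs, "direction": ["favorable"] * n + ["unfavorable"] * n}
    )
    div = popgen.DivergenceResult(table=table, fdr=0.01)
    cats = pd.Series(
        ["upstream"] * n + ["intergenic"] * n, index=svs, dtype=object
    )
    ann = AnnotationResult(categories=cats, genes_hit={}, table=None, gene_table=None)
    res = popgen.location_preference(div, ann).set_index("category")
    assert res.loc["upstream", "p"] < 1e-6
    assert res.loc["CDS", "p"] == 1.0
    assert res["prop_favorable"].sum() == pytest.approx(1.0)
    assert res["prop_unfavorable"].sum() == pytest.approx(1.0)


def test_location_preference_empty():
    table = pd.DataFrame({"sv": [], "direction": []})
    div = popgen.DivergenceResult(table=table, fdr=0.01)
    ann = AnnotationResult(
        categories=pd.Series(dtype=object), genes_hit={}, table=None, gene_table=None
    )
    assert popgen.location_preference(div, ann).empty


def test_pca_separates_clusters(rng):
    n_markers, n_a, n_b = 200, 15, 15
    fa, fb = rng.uniform(0.05, 0.3, n_markers), rng.uniform(0.6, 0.95, n_markers)
    d = np.hstack(
        [rng.binomial(2, fa[:, None], (n_markers, n_a)),
         rng.binomial(2, fb[:, None], (n_markers, n_b))]
    ).astype(np.int8)
    m = GenotypeMatrix(
        markers=[f"m{i}" for i in range(n_markers)],
        samples=[f"s{i}" for i in range(n_a + n_b)], dosage=d,
    )
    pcs = popgen.genotype_pca(m)
    pc1 = pcs["PC1"].values
    assert (pc1[:n_a].mean() < pc1[n_a:].mean()) != (pc1[:n_a].min() > pc1[n_a:].max())
    assert np.sign(pc1[:n_a]).std() == 0 and np.sign(pc1[n_a:]).std() == 0


def test_pca_duplicated_sample_identical(rng):
    d = rng.integers(0, 3, (50, 8)).astype(np.int8)
    d[:, 7] = d[:, 0]
    m = GenotypeMatrix(
        markers=[f"m{i}" for i in range(50)], samples=[f"s{i}" for i in range(8)],
        dosage=d,
    )
    pcs = popgen.genotype_pca(m)
    assert np.allclose(pcs.iloc[0], pcs.iloc[7])


def test_pca_snp_sv_concordance(study):
    """SV- and SNP-based PCs order the landrace/cultivar split consistently:
    distances between group centroids correlate across the two marker sets."""
    ing = study.ingroup
    sv_pcs = popgen.genotype_pca(study.sv_genotypes.subset_samples(ing))
    snp_pcs = popgen.genotype_pca(study.snp_genotypes.subset_samples(ing))
    labels = study.samples.set_index("sample").loc[ing, "population"].values
    # both marker sets separate landraces from cultivars on PC1 ...
    for pcs in (sv_pcs, snp_pcs):
        pc1 = pcs["PC1"].values
        p = stats.mannwhitneyu(pc1[labels == "landrace"], pc1[labels == "cultivar"]).pvalue
        assert p < 1e-6
    # ... and the two PC1 orderings agree up to sign
    r = np.corrcoef(sv_pcs["PC1"], snp_pcs["PC1"])[0, 1]
    assert abs(r) > 0.5
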
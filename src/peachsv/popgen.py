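"""Outgroup-polarized site frequency spectra, diversity, divergence scans and
genotype PCA.

Polarization uses an outgroup (here *P. kansuensis*-like samples): the
ancestral allele at a site is the allele fixed among called outgroup samples;
sites with a polymorphic or absent outgroup are excluded.  The unfolded SFS
counts derived alleles per site and can be projected to a smaller sample size
m by hypergeometric downsampling, which doubles as missing-data handling
(sites with fewer than m called alleles are dropped before projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationResult, CATEGORIES
from .sv_io import MISSING, GenotypeMatrix


@dataclass
class PolarizedSites:
    """Per-site derived-allele counts after outgroup polarization."""

    markers: list[str]
    derived: np.ndarray        # derived allele count among called ingroup alleles
    n_alleles: np.ndarray      # called ingroup allele number (2 x called samples)
    n_excluded: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.derived / self.n_alleles


def polarize(
    matrix: GenotypeMatrix,
    outgroup_samples: list[str],
    min_outgroup_called: int = 2,
) -> PolarizedSites:
    """Derived-allele counts for the ingroup, polarized by outgroup fixation."""
    if not outgroup_samples:
        raise ValueError("no outgroup samples given")
    out_idx = matrix.sample_index(outgroup_samples)
    in_idx = np.setdiff1d(np.arange(matrix.n_samples), out_idx)
    markers, derived, n_alleles = [], [], []
    n_excluded = 0
    for i in range(matrix.n_markers):
        og = matrix.dosage[i, out_idx]
        og = og[og != MISSING]
        if len(og) < min_outgroup_called:
            n_excluded += 1
            continue
        if np.all(og == 0):
            ancestral_dosage = 0
        elif np.all(og == 2):
            ancestral_dosage = 2
        else:
            n_excluded += 1
            continue
        ig = matrix.dosage[i, in_idx]
        ig = ig[ig != MISSING]
        if len(ig) == 0:
            n_excluded += 1
            continue
        alt = int(ig.sum())
        n = 2 * len(ig)
        markers.append(matrix.markers[i])
        derived.append(alt if ancestral_dosage == 0 else n - alt)
        n_alleles.append(n)
    return PolarizedSites(
        markers=markers,
        derived=np.array(derived, dtype=int),
        n_alleles=np.array(n_alleles, dtype=int),
        n_excluded=n_excluded,
    )


@dataclass
class SpectrumResult:
    """Unfolded spectrum: ``counts[j]`` is the site mass at derived-allele
    count j out of ``n`` sampled alleles (real-valued after projection)."""

    n: int
    counts: np.ndarray
    n_excluded: int = 0
    projected_to: int | None = None

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


def spectrum_from_sites(sites: PolarizedSites, n: int | None = None) -> SpectrumResult:
    """Integer spectrum from sites with exactly n called alleles (default: the
    maximum observed); sites at other depths are excluded."""
    if len(sites.derived) == 0:
        raise ValueError("no polarized sites")
    if n is None:
        n = int(sites.n_alleles.max())
    use = sites.n_alleles == n
    counts = np.bincount(sites.derived[use], minlength=n + 1).astype(float)
    return SpectrumResult(
        n=n, counts=counts, n_excluded=sites.n_excluded + int(np.sum(~use))
    )


def project_sfs(spectrum: SpectrumResult, m: int = 20) -> SpectrumResult:
    """Hypergeometric projection from n to m alleles.

    A site with i derived of n contributes mass C(i,j) C(n-i, m-j) / C(n,m)
    to projected class j; per-site masses sum to 1, so total mass is conserved.
    """
    n = spectrum.n
    if m > n:
        raise ValueError(f"cannot project up: m={m} > n={n}")
    if m == n:
        return SpectrumResult(n=n, counts=spectrum.counts.copy(),
                              n_excluded=spectrum.n_excluded, projected_to=m)
    i = np.arange(n + 1)[:, None]
    j = np.arange(m + 1)[None, :]
    weights = comb(i, j) * comb(n - i, m - j) / comb(n, m)
    projected = spectrum.counts @ weights
    return SpectrumResult(n=m, counts=projected,
                          n_excluded=spectrum.n_excluded, projected_to=m)


def project_sites(sites: PolarizedSites, m: int = 20) -> SpectrumResult:
    """Project directly from per-site (i, n) data, dropping sites with fewer
    than m called alleles; this is the missing-data-tolerant path."""
    counts = np.zeros(m + 1)
    dropped = 0
    j = np.arange(m + 1)
    for i, n in zip(sites.derived, sites.n_alleles):
        if n < m:
            dropped += 1
            continue
        counts += comb(i, j) * comb(n - i, m - j) / comb(n, m)
    return SpectrumResult(n=m, counts=counts,
                          n_excluded=sites.n_excluded + dropped, projected_to=m)


def sfs_shift_test(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value that the per-site derived-allele
    frequencies ``freq_a`` are stochastically smaller (shifted left) than
    ``freq_b``."""
    if len(freq_a) == 0 or len(freq_b) == 0:
        raise ValueError("empty frequency samples")
    return float(stats.mannwhitneyu(freq_a, freq_b, alternative="less").pvalue)


def write_sfs_text(path, spectrum: SpectrumResult) -> None:
    """Plain two-line spectrum export (header line, then the n+1 masses),
    the input layout expected by DFE-fitting programs."""
    with open(path, "w") as fh:
        fh.write(f"# unfolded SFS, n={spectrum.n}\n")
        fh.write(" ".join(f"{c:.6g}" for c in spectrum.counts) + "\n")


@dataclass
class DiversityResult:
    theta_pi: float            # mean per-site pairwise diversity over variant sites
    per_site: np.ndarray
    n_sites: int


def theta_pi(matrix: GenotypeMatrix, samples: list[str] | None = None) -> DiversityResult:
    """Average pairwise difference probability per variant site.

    Per site with k alt alleles among 2n called alleles,
    pi = 2 k (2n - k) / (2n (2n - 1)); monomorphic sites contribute 0 and the
    mean runs over variant sites only (matching the ~0.2 per-variant-site
    scale of population SV panels, not a per-bp genome-wide rate).
    """
    d = matrix.dosage if samples is None else matrix.dosage[:, matrix.sample_index(samples)]
    called = d != MISSING
    n_called = called.sum(axis=1)
    k = np.where(called, d, 0).sum(axis=1)
    n_al = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * k * (n_al - k) / (n_al * (n_al - 1.0))
    pi = np.where(n_al >= 2, pi, 0.0)
    variant = (k > 0) & (k < n_al)
    mean = float(pi[variant].mean()) if variant.any() else 0.0
    return DiversityResult(theta_pi=mean, per_site=pi, n_sites=int(variant.sum()))


def diversity_ratio(theta_a: float, theta_b: float) -> float:
    return theta_a / theta_b


def heterozygosity_ratio(
    matrix: GenotypeMatrix, group_a: list[str], group_b: list[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-sample heterozygous fraction for two groups plus the one-sided
    rank-sum p that group_a exceeds group_b."""
    def per_sample(names: list[str]) -> np.ndarray:
        d = matrix.dosage[:, matrix.sample_index(names)]
        called = (d != MISSING).sum(axis=0)
        het = (d == 1).sum(axis=0)
        return het / np.maximum(called, 1)

    ha, hb = per_sample(group_a), per_sample(group_b)
    p = float(stats.mannwhitneyu(ha, hb, alternative="greater").pvalue)
    return ha, hb, p


@dataclass
class DivergenceResult:
    """Per-SV carrier-frequency divergence between two groups."""

    table: pd.DataFrame  # sv, carriers/totals per group, p, q, direction
    fdr: float

    @property
    def n_favorable(self) -> int:
        return int((self.table["direction"] == "favorable").sum())

    @property
    def n_unfavorable(self) -> int:
        return int((self.table["direction"] == "unfavorable").sum())


def divergent_svs(
    matrix: GenotypeMatrix,
    landrace_samples: list[str],
    cultivar_samples: list[str],
    fdr: float = 0.01,
) -> DivergenceResult:
    """Fisher exact test of carrier counts (dosage >= 1, missing excluded)
    between landraces and modern cultivars with BH-FDR control.

    Direction: ``favorable`` when the cultivar carrier frequency exceeds the
    landrace carrier frequency at q < fdr (an improvement-selected SV),
    ``unfavorable`` for the reverse, ``none`` otherwise.
    """
    if len(landrace_samples) < 2 or len(cultivar_samples) < 2:
        raise ValueError("each group needs >= 2 samples")
    li = matrix.sample_index(landrace_samples)
    ci = matrix.sample_index(cultivar_samples)
    rows = []
    for i, marker in enumerate(matrix.markers):
        dl, dc = matrix.dosage[i, li], matrix.dosage[i, ci]
        dl, dc = dl[dl != MISSING], dc[dc != MISSING]
        cl, nl = int((dl >= 1).sum()), int((dl == 0).sum())
        cc, nc = int((dc >= 1).sum()), int((dc == 0).sum())
        if (cl + cc == 0) or (nl + nc == 0):
            p = 1.0  # monomorphic across both groups
        else:
            _, p = stats.fisher_exact([[cl, nl], [cc, nc]])
        rows.append((marker, cl, nl, cc, nc, p))
    table = pd.DataFrame(
        rows, columns=["sv", "carriers_landrace", "non_carriers_landrace",
                       "carriers_cultivar", "non_carriers_cultivar", "p"],
    )
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    fl = table["carriers_landrace"] / (table["carriers_landrace"] + table["non_carriers_landrace"]).clip(lower=1)
    fc = table["carriers_cultivar"] / (table["carriers_cultivar"] + table["non_carriers_cultivar"]).clip(lower=1)
    direction = np.where(
        (table["q"] < fdr) & (fc > fl), "favorable",
        np.where((table["q"] < fdr) & (fl > fc), "unfavorable", "none"),
    )
    table["direction"] = direction
    return DivergenceResult(table=table, fdr=fdr)


def location_preference(
    divergence: DivergenceResult, annotation: AnnotationResult
) -> pd.DataFrame:
    """Per-category proportions of favorable vs unfavorable SVs plus a
    two-sided Fisher p per category (favorable/unfavorable x in/out)."""
    t = divergence.table
    fav = set(t.loc[t["direction"] == "favorable", "sv"])
    unfav = set(t.loc[t["direction"] == "unfavorable", "sv"])
    if not fav and not unfav:
        return pd.DataFrame(
            columns=["category", "favorable", "unfavorable",
                     "prop_favorable", "prop_unfavorable", "p"]
        )
    # collapse CDS_full/CDS_partial into CDS for the report
    cat_of = annotation.categories.replace({"CDS_full": "CDS", "CDS_partial": "CDS"})
    cats = ["CDS" if c.startswith("CDS") else c for c in CATEGORIES]
    cats = list(dict.fromkeys(cats))
    rows = []
    n_fav, n_unfav = len(fav), len(unfav)
    for cat in cats:
        in_cat = set(cat_of[cat_of == cat].index)
        a = len(fav & in_cat)
        b = n_fav - a
        c = len(unfav & in_cat)
        d = n_unfav - c
        _, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append(
            (cat, a, c, a / n_fav if n_fav else 0.0, c / n_unfav if n_unfav else 0.0, p)
        )
    return pd.DataFrame(
        rows, columns=["category", "favorable", "unfavorable",
                       "prop_favorable", "prop_unfavorable", "p"],
    )


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Sample PCA of the dosage matrix.

    Markers are mean-centred and scaled by the binomial standard deviation
    sqrt(2 p (1 - p)) of their allele frequency p; constant markers are
    dropped and missing dosages mean-imputed.
    """
    if matrix.n_samples < 2 or matrix.n_markers < 2:
        raise ValueError("need >= 2 samples and >= 2 markers")
    d = matrix.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mean, d)
    p = mean / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd[:, 0] > 0
    z = (d[keep] - mean[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    coords = (vt[:k].T * s[:k]) / np.sqrt(max(z.shape[0] - 1, 1))
    return pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
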
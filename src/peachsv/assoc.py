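"""Mixed-model association, Bonferroni thresholds, LD and segregation checks.

The scan follows the EMMAX approximation: a single random polygenic effect
with covariance proportional to a genotype-derived kinship K, variance
components estimated once under the null by REML over the ratio
delta = sigma2_e / sigma2_g via the spectral decomposition of K, then each
marker tested by generalized least squares with the components held fixed.
With K = I the procedure reduces exactly to ordinary per-marker linear
regression, which is the analytic correctness check used in the tests.

Binary phenotypes (round = 0 / flat = 1) are analysed with the same linear
model, as the reference algorithm does in practice; expression phenotypes
reuse the identical scan (eGWAS).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sv_io import MISSING, GenotypeMatrix, SVRecord

log = logging.getLogger(__name__)


def _impute_standardize(dosage: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Mean-impute missing dosages per marker; optionally scale to unit
    binomial variance.  Constant markers are dropped by the caller."""
    d = dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mean, d)
    if standardize:
        p = np.clip(mean / 2.0, 1e-12, 1 - 1e-12)
        d = (d - mean) / np.sqrt(2.0 * p * (1.0 - p))
    return d


def kinship(matrix: GenotypeMatrix) -> np.ndarray:
    """Standardized-genotype cross-product kinship, scaled by marker count."""
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = matrix.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    var_ok = np.nanvar(d, axis=1) > 0
    if not var_ok.all():
        log.info("kinship: dropping %d constant markers", int((~var_ok).sum()))
    z = _impute_standardize(matrix.dosage[var_ok])
    return (z.T @ z) / z.shape[0]


@dataclass
class LmmFit:
    sigma2_g: float
    sigma2_e: float
    delta: float
    eigenvalues: np.ndarray
    rotation: np.ndarray  # eigenvectors, samples x samples
    null_reml: float


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yr: np.ndarray,
                     xr: np.ndarray) -> float:
    delta = math.exp(log_delta)
    w = 1.0 / (lam + delta)
    xtwx = (xr * w[:, None]).T @ xr
    beta = np.linalg.solve(xtwx, (xr * w[:, None]).T @ yr)
    resid = yr - xr @ beta
    rss = float(resid @ (w * resid))
    n, q = xr.shape
    df = n - q
    sigma2 = max(rss / df, 1e-300)
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(xr.T @ xr)
    ll = -0.5 * (
        df * math.log(2 * math.pi * sigma2) + df
        + float(np.sum(np.log(lam + delta)))
        + logdet_xtwx - logdet_xtx
    )
    return -ll


def fit_null(phenotype: np.ndarray, K: np.ndarray,
             eigen_floor: float = 1e-8) -> LmmFit:
    """REML fit of the null variance components over delta."""
    lam, U = np.linalg.eigh(K)
    if lam.min() < eigen_floor:
        log.info("kinship eigenvalues floored at %g", eigen_floor)
        lam = np.maximum(lam, eigen_floor)
    yr = U.T @ phenotype
    xr = U.T @ np.ones((len(phenotype), 1))
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), args=(lam, yr, xr),
        method="bounded", options={"xatol": 1e-8},
    )
    delta = math.exp(res.x)
    w = 1.0 / (lam + delta)
    xtwx = (xr * w[:, None]).T @ xr
    beta = np.linalg.solve(xtwx, (xr * w[:, None]).T @ yr)
    resid = yr - xr @ beta
    sigma2_g = float(resid @ (w * resid)) / (len(yr) - 1)
    return LmmFit(
        sigma2_g=sigma2_g, sigma2_e=sigma2_g * delta, delta=delta,
        eigenvalues=lam, rotation=U, null_reml=-res.fun,
    )


@dataclass
class AssocResult:
    table: pd.DataFrame  # marker, chrom, pos, effect, se, p, neglog10p
    n_tests: int
    threshold_p: float
    threshold_neglog10: float


def lmm_scan(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray,
    K: np.ndarray | None = None,
    positions: pd.DataFrame | None = None,
    alpha: float = 1.0,
) -> AssocResult:
    """Single-marker mixed-model scan.

    ``positions`` optionally maps markers to (chrom, pos) for Manhattan-ready
    output (SVs use their midpoint).  The significance threshold is the
    reciprocal-test-count Bonferroni rule alpha / n_tests (alpha = 1 by
    convention here).
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotype values not allowed")
    if K is None:
        K = kinship(matrix)
    if np.allclose(y, y[0]):
        # degenerate phenotype: nothing to associate
        thr_p, thr_nl = bonferroni(matrix.n_markers, alpha=alpha)
        table = pd.DataFrame(
            {"marker": matrix.markers, "effect": 0.0, "se": np.nan, "p": 1.0,
             "neglog10p": 0.0, "passes_threshold": False}
        )
        if positions is not None:
            table = table.merge(positions, on="marker", how="left")
        return AssocResult(table=table, n_tests=matrix.n_markers,
                           threshold_p=thr_p, threshold_neglog10=thr_nl)
    fit = fit_null(y, K)
    U, lam = fit.rotation, fit.eigenvalues
    w = 1.0 / (lam + fit.delta)
    yr = U.T @ y
    ones_r = U.T @ np.ones(len(y))
    G = _impute_standardize(matrix.dosage, standardize=False)
    GR = G @ U  # markers x samples, rotated
    n = len(y)
    const_pheno = np.allclose(y, y[0])
    eff = np.zeros(matrix.n_markers)
    se = np.zeros(matrix.n_markers)
    pvals = np.ones(matrix.n_markers)
    for i in range(matrix.n_markers):
        g = GR[i]
        X = np.column_stack([ones_r, g])
        xtwx = (X * w[:, None]).T @ X
        if np.linalg.matrix_rank(xtwx) < 2 or const_pheno:
            eff[i], se[i], pvals[i] = 0.0, np.nan, 1.0
            continue
        beta = np.linalg.solve(xtwx, (X * w[:, None]).T @ yr)
        resid = yr - X @ beta
        rss = float(resid @ (w * resid))
        df = n - 2
        sigma2 = rss / df
        cov = sigma2 * np.linalg.inv(xtwx)
        eff[i] = beta[1]
        se[i] = math.sqrt(max(cov[1, 1], 0.0))
        if se[i] == 0:
            pvals[i] = 0.0
        else:
            t = beta[1] / se[i]
            pvals[i] = 2.0 * stats.t.sf(abs(t), df)
    thr_p, thr_nl = bonferroni(matrix.n_markers, alpha=alpha)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pvals)
    table = pd.DataFrame(
        {"marker": matrix.markers, "effect": eff, "se": se, "p": pvals,
         "neglog10p": neglog, "passes_threshold": pvals < thr_p}
    )
    if positions is not None:
        table = table.merge(positions, on="marker", how="left")
    return AssocResult(
        table=table, n_tests=matrix.n_markers,
        threshold_p=thr_p, threshold_neglog10=thr_nl,
    )


def bonferroni(n_tests: int, alpha: float = 1.0) -> tuple[float, float]:
    """(threshold_p, -log10 threshold rounded to 2 decimals) under the
    reciprocal convention threshold_p = alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return thr, round(-math.log10(thr), 2)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared sample correlation of two dosage vectors, missing values
    pairwise-deleted.  NaN (flagged) when either vector is constant."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_profile(
    focal_dosage: np.ndarray,
    matrix: GenotypeMatrix,
    positions: pd.DataFrame,
    breakpoints: tuple[int, int],
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """r2 of every marker against a focal marker, ordered by position, with
    the distance to the nearest focal breakpoint (0 inside the span)."""
    pos = positions.set_index("marker")
    bp1, bp2 = sorted(breakpoints)
    rows = []
    for i, marker in enumerate(matrix.markers):
        p = int(pos.loc[marker, "pos"])
        if region is not None and not (region[0] <= p <= region[1]):
            continue
        dist = 0 if bp1 <= p <= bp2 else min(abs(p - bp1), abs(p - bp2))
        rows.append((marker, pos.loc[marker, "chrom"], p, dist,
                     ld_r2(focal_dosage, matrix.dosage[i])))
    return (
        pd.DataFrame(rows, columns=["marker", "chrom", "pos", "dist_to_breakpoint", "r2"])
        .sort_values("pos")
        .reset_index(drop=True)
    )


def segregation_check(
    inversion_dosage: np.ndarray, phenotype: np.ndarray
) -> tuple[pd.DataFrame, bool]:
    """Dosage {0,1,2,missing} x phenotype {round,flat} contingency table and
    the perfect-segregation flag: every flat sample heterozygous (dosage 1)
    and every round sample dosage 0.  Homozygous derived flat samples break
    the flag (that genotype aborts fruit and should not occur)."""
    d = np.asarray(inversion_dosage)
    ph = np.asarray(phenotype, dtype=object)
    levels = [0, 1, 2, "missing"]
    table = pd.DataFrame(0, index=levels, columns=["round", "flat"])
    for dos, p in zip(d, ph):
        if p not in ("round", "flat"):
            raise ValueError(f"phenotype must be round/flat, got {p!r}")
        key = "missing" if dos == MISSING else int(dos)
        table.loc[key, p] += 1
    perfect = (
        table.loc[1, "flat"] == (ph == "flat").sum()
        and table.loc[0, "round"] == (ph == "round").sum()
        and table.loc["missing"].sum() == 0
    )
    return table, bool(perfect)


def sv_positions(svs: list[SVRecord]) -> pd.DataFrame:
    """Manhattan-ready marker positions: the SV midpoint."""
    return pd.DataFrame(
        {"marker": [s.id for s in svs],
         "chrom": [s.chrom for s in svs],
         "pos": [s.midpoint0 for s in svs]}
    )
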
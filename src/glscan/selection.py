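"""Selection statistics on the fitted principal components.

Two per-site statistics are computed from the truncated SVD of the
standardized posterior dosages:

* **S1** (per-PC normal statistic): d_jk = v_jk √M, which is standard
  normal under genetic drift because the variant weights form a unit-norm
  eigenvector; d²_jk is tested against χ²₁ separately for each component.

* **S2** (multivariate robust statistic): regression z-scores of each
  site's standardized dosage on the K individual score vectors, obtained
  in closed form from the SVD (β_j = S V_j), followed by a robust
  Mahalanobis distance over the K-dimensional z-scores, referred to χ²_K
  after genomic-inflation correction (λ = median of the observed
  statistics over the null χ² median).

S1 is reported without genomic control; S2 always with it.  Significance
is called against a Bonferroni threshold α / M over the retained sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet

from . import afreq as _afreq
from .afreq import AlleleFreqs, SiteMask
from .io import GenotypeMatrix, GLMatrix, MarkerInfo, genotypes_to_gl
from .pca import FitResult, SVDFactors, fit_individual_afs

__all__ = [
    "S1Result",
    "S2Result",
    "ScanResult",
    "s1_statistic",
    "s2_zscores",
    "robust_mahalanobis",
    "genomic_inflation",
    "pvalues_and_bonferroni",
    "run_scan",
    "SelectionScan",
]

_TINY_P = np.nextafter(0.0, 1.0)


def _safe_sf(stats_arr: np.ndarray, df: int) -> np.ndarray:
    """Upper-tail chi-square p-values; underflow maps to the smallest
    positive float rather than 0 so log-scale reporting stays finite."""
    p = stats.chi2.sf(stats_arr, df=df)
    return np.where(p <= 0.0, _TINY_P, p)


@dataclass
class S1Result:
    """Per-PC selection statistics d_jk = v_jk √M and their χ²₁ p-values."""

    d: np.ndarray
    chi2: np.ndarray
    pvals: np.ndarray


@dataclass
class S2Result:
    """Multivariate statistic: z-scores, robust squared Mahalanobis
    distances, genomic inflation factor and corrected χ²_K p-values."""

    z: np.ndarray
    mahal: np.ndarray
    lambda_gc: float
    mahal_corrected: np.ndarray
    pvals: np.ndarray
    robust: bool
    zero_rss: np.ndarray


@dataclass
class ScanResult:
    """Everything a genome-wide scan reports for the retained sites."""

    markers: list[MarkerInfo]
    maf: np.ndarray
    alpha: float
    bonferroni_threshold: float
    s1: S1Result | None = None
    s2: S2Result | None = None
    s1_significant: np.ndarray | None = None
    s2_significant: np.ndarray | None = None
    site_mask: SiteMask | None = None
    fit: FitResult | None = None
    log: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "chrom": [m.chrom for m in self.markers],
            "pos": [m.pos for m in self.markers],
            "marker": [m.id for m in self.markers],
            "maf": self.maf,
        }
        if self.s1 is not None:
            for k in range(self.s1.d.shape[1]):
                cols[f"s1_d_pc{k + 1}"] = self.s1.d[:, k]
                cols[f"s1_chi2_pc{k + 1}"] = self.s1.chi2[:, k]
                cols[f"s1_pc{k + 1}_pval"] = self.s1.pvals[:, k]
                cols[f"s1_sig_pc{k + 1}"] = self.s1_significant[:, k]
        if self.s2 is not None:
            cols["s2_chi2"] = self.s2.mahal_corrected
            cols["s2_pval"] = self.s2.pvals
            cols["s2_sig"] = self.s2_significant
            cols["s2_zero_rss"] = self.s2.zero_rss
        return pd.DataFrame(cols)


def s1_statistic(factors: SVDFactors) -> S1Result:
    """Per-PC statistic from the variant weights.

    Because each column of V has unit norm, Σ_j d²_jk = M exactly — the
    statistics are calibrated by construction and need no genomic control.
    """
    m = factors.V.shape[0]
    d = factors.V * np.sqrt(m)
    chi2 = d**2
    return S1Result(d, chi2, _safe_sf(chi2, df=1))


def s2_zscores(y: np.ndarray, factors: SVDFactors) -> tuple[np.ndarray, np.ndarray]:
    """Regression z-scores of every site's standardized dosage on U.

    The least-squares coefficients come free from the SVD identity
    β_j = S V_j (U has orthonormal columns, so no refit is needed); the
    shared scalar standard error per site is sqrt(RSS_j / (N − K)) with
    RSS from the rank-K residual y_j − ŷ_j.

    Returns
    -------
    (z, zero_rss) : (M, K) z-scores and a boolean mask of sites whose
        residual vanished (y_j in the span of U); their z rows are set to 0
        and must be special-cased by the caller.
    """
    n, m = y.shape
    k = factors.K
    if n <= k:
        raise ValueError(f"need N > K, got N={n}, K={k}")
    beta = factors.V * factors.S  # (M, K)
    resid = y - factors.reconstruction()
    rss = np.einsum("ij,ij->j", resid, resid)
    zero_rss = rss <= 1e-12 * max(1.0, float(np.median(rss)))
    se = np.sqrt(np.where(zero_rss, 1.0, rss) / (n - k))
    z = beta / se[:, None]
    z[zero_rss] = 0.0
    return z, zero_rss


def robust_mahalanobis(z: np.ndarray, robust: bool = True,
                       support_fraction: float = 0.75,
                       random_state: int = 0) -> np.ndarray:
    """Squared Mahalanobis distances of the rows of ``z``.

    Location and scatter come from the minimum-covariance-determinant
    estimator so that true outliers do not inflate their own yardstick;
    if the robust scatter is singular, falls back to the classical
    mean/covariance with a warning.  ``robust=False`` forces the classical
    estimate directly.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] <= 5 * z.shape[1]:
        raise ValueError("too few rows to estimate a robust scatter matrix")

    def _classical() -> np.ndarray:
        mu = z.mean(axis=0)
        cov = np.cov(z, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if np.linalg.matrix_rank(cov) < cov.shape[0]:
            raise np.linalg.LinAlgError(
                "collinear z-scores: covariance matrix is singular"
            )
        diff = z - mu
        return np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)

    if not robust:
        return _classical()
    try:
        mcd = MinCovDet(support_fraction=support_fraction,
                        random_state=random_state).fit(z)
        cond = np.linalg.cond(np.atleast_2d(mcd.covariance_))
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("robust scatter matrix is singular")
        d2 = mcd.mahalanobis(z)
        if not np.all(np.isfinite(d2)):
            raise np.linalg.LinAlgError("non-finite robust distances")
        return d2
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"robust scatter estimation failed ({exc}); "
            "falling back to classical mean/covariance",
            RuntimeWarning,
        )
        return _classical()


def genomic_inflation(stats_arr: np.ndarray, df: int) -> tuple[float, np.ndarray]:
    """Genomic inflation factor λ and corrected statistics.

    λ is the median observed statistic over the χ²_df median; dividing by
    it restores the null median exactly, a standard guard against residual
    structure inflating a genome-wide test.
    """
    stats_arr = np.asarray(stats_arr, dtype=float)
    med = float(np.median(stats_arr))
    if med <= 0.0:
        raise ValueError("degenerate statistics: median is not positive")
    lam = med / float(stats.chi2.median(df=df))
    return lam, stats_arr / lam


def pvalues_and_bonferroni(stats_arr: np.ndarray, df: int, alpha: float,
                           m_tests: int) -> tuple[np.ndarray, float, np.ndarray]:
    """χ² upper-tail p-values with a Bonferroni family-wise threshold.

    Returns (pvals, threshold, significant) with threshold = alpha / m_tests
    and significant ⇔ p < threshold (strict).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = _safe_sf(np.asarray(stats_arr, dtype=float), df=df)
    threshold = alpha / m_tests
    return p, threshold, p < threshold


def run_scan(gl: GLMatrix | GenotypeMatrix, K: int, which: str = "both",
             alpha: float = 0.05, maf_min: float = 0.05,
             snp_p: float | None = 1e-6, tol: float = 1e-5,
             max_iter: int = 100, seed: int | None = None,
             robust: bool = True) -> ScanResult:
    """End-to-end selection scan.

    Pipeline: EM allele frequencies → variability LRT (skipped when
    ``snp_p`` is None or the input is a hard-genotype matrix of known
    variable sites) → MAF filter → iterative PCA fit → S1 and/or S2
    statistics → Bonferroni calls over the retained sites.
    """
    if which not in ("s1", "s2", "both"):
        raise ValueError("which must be 's1', 's2' or 'both'")
    if isinstance(gl, GenotypeMatrix):
        gl = genotypes_to_gl(gl)
        if snp_p is not None:
            snp_p = None  # known genotypes: sites are taken as called
    n_read = gl.n_sites
    freqs = _afreq.estimate_af_em(gl)
    lrt_p = None
    if snp_p is not None:
        _, lrt_p = _afreq.snp_lrt(gl, freqs)
    mask = _afreq.site_filter(freqs, lrt_p, maf_min=maf_min,
                              snp_p=snp_p if snp_p is not None else 1e-6)
    gl_kept = gl.subset_sites(mask.keep)
    f_kept = AlleleFreqs(freqs.f[mask.keep])
    fit = fit_individual_afs(gl_kept, f_kept, K=K, tol=tol,
                             max_iter=max_iter, seed=seed)
    m_tests = gl_kept.n_sites
    threshold = alpha / m_tests
    maf = np.minimum(f_kept.f, 1.0 - f_kept.f)
    result = ScanResult(
        markers=gl_kept.markers, maf=maf, alpha=alpha,
        bonferroni_threshold=threshold, site_mask=mask, fit=fit,
        log={
            "sites_read": n_read,
            "sites_retained": m_tests,
            "excluded": mask.reason_counts(),
            "n_iter": fit.n_iter,
            "converged": fit.converged,
        },
    )
    if which in ("s1", "both"):
        s1 = s1_statistic(fit.factors)
        sig = s1.pvals < threshold
        result.s1 = s1
        result.s1_significant = sig
    if which in ("s2", "both"):
        z, zero_rss = s2_zscores(fit.y, fit.factors)
        d2 = robust_mahalanobis(z[~zero_rss], robust=robust,
                                random_state=0 if seed is None else seed)
        mahal = np.empty(m_tests)
        mahal[~zero_rss] = d2
        # degenerate sites (residual exactly zero) cannot be scored; give
        # them the largest finite statistic and flag them in the output
        mahal[zero_rss] = d2.max() if d2.size else 0.0
        lam, corrected = genomic_inflation(mahal, df=K)
        pvals, threshold, sig = pvalues_and_bonferroni(
            corrected, df=K, alpha=alpha, m_tests=m_tests)
        result.s2 = S2Result(z, mahal, lam, corrected, pvals,
                             robust=robust, zero_rss=zero_rss)
        result.s2_significant = sig
        result.log["lambda_gc"] = lam
    return result


class SelectionScan(BaseEstimator):
    """PCA-based selection scan for genotype-likelihood data.

    Scikit-learn style front end over the full pipeline: allele-frequency
    estimation, site filtering, the iterative PC fit and the S1/S2
    selection statistics with Bonferroni significance calls.

    Parameters
    ----------
    n_components : int
        Number of principal components K describing the structure.
    statistic : {'s1', 's2', 'both'}
        Which selection statistics to compute.
    maf_min : float
        Strict minor-allele-frequency bound; sites with f̂ ≤ maf_min or
        f̂ ≥ 1 − maf_min are excluded.
    snp_pval : float or None
        Likelihood-ratio-test threshold for calling a site variable; None
        disables the test (known-sites / genotype mode).
    alpha : float
        Family-wise error target for the Bonferroni threshold.
    tol, max_iter : float, int
        Convergence control of the iterative PC fit.
    robust : bool
        Use the minimum-covariance-determinant scatter for the S2
        Mahalanobis distances (classical mean/covariance otherwise).
    random_state : int or None
        Seed for the robust scatter subsampling and SVD backend.

    Attributes
    ----------
    scan_result_ : ScanResult
    results_ : pandas.DataFrame with one row per retained site.
    lambda_gc_ : float, set when S2 is computed.
    bonferroni_threshold_ : float
    """

    def __init__(self, n_components: int = 2, statistic: str = "both",
                 maf_min: float = 0.05, snp_pval: float | None = 1e-6,
                 alpha: float = 0.05, tol: float = 1e-5, max_iter: int = 100,
                 robust: bool = True, random_state: int | None = None):
        self.n_components = n_components
        self.statistic = statistic
        self.maf_min = maf_min
        self.snp_pval = snp_pval
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.robust = robust
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the scan on a GLMatrix, a GenotypeMatrix, or an (N, M, 3)
        likelihood array."""
        if isinstance(X, (GLMatrix, GenotypeMatrix)):
            data = X
        else:
            arr = np.asarray(X, dtype=float)
            markers = [
                MarkerInfo(f"site{j + 1}", "0", "1", f"site{j + 1}", j + 1)
                for j in range(arr.shape[1])
            ]
            data = GLMatrix(arr, markers)
        res = run_scan(
            data, K=self.n_components, which=self.statistic,
            alpha=self.alpha, maf_min=self.maf_min, snp_p=self.snp_pval,
            tol=self.tol, max_iter=self.max_iter, seed=self.random_state,
            robust=self.robust,
        )
        self.scan_result_ = res
        self.results_ = res.to_frame()
        self.bonferroni_threshold_ = res.bonferroni_threshold
        if res.s2 is not None:
            self.lambda_gc_ = res.s2.lambda_gc
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the per-site significance calls: a boolean array
        over retained sites, True where any computed statistic is
        Bonferroni-significant."""
        self.fit(X, y)
        res = self.scan_result_
        sig = np.zeros(res.n_sites, dtype=bool)
        if res.s1_significant is not None:
            sig |= res.s1_significant.any(axis=1)
        if res.s2_significant is not None:
            sig |= res.s2_significant
        return sig
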
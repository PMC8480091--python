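"""Iterative PCA on genotype likelihoods.

The model: genotypes G_ij ~ Binomial(2, π_ij), where the individual allele
frequency π_ij encodes population structure.  With low-coverage sequencing
the genotypes are unobserved; we work with the posterior genotype dosage

    E[G_ij | X_ij, π̂_ij] = Σ_g g · P(X_ij | g) Binom(g; 2, π̂_ij) / Z,

standardize it with the population frequency f̂_j,

    y_ij = (E[G_ij | X_ij, π̂_ij] − 2 f̂_j) / sqrt(2 f̂_j (1 − f̂_j)),

and take the top-K truncated SVD, Ŷ = U S Vᵀ.  The rank-K reconstruction
is mapped back to the frequency scale to update π̂, and the loop repeats
until the individual allele frequencies stabilize.  U carries the
individual coordinates on the principal components, V the per-site variant
weights that the selection statistics test downstream.

Missing observations (equal likelihood triples) contribute their prior
mean 2π̂_ij, i.e. they are imputed from the inferred structure.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .afreq import AlleleFreqs
from .io import GLMatrix

__all__ = [
    "IndAlleleFreqs",
    "SVDFactors",
    "FitResult",
    "genotype_posteriors",
    "posterior_dosage",
    "standardize",
    "truncated_svd",
    "update_ind_afs",
    "fit_individual_afs",
    "GenotypeLikelihoodPCA",
]


@dataclass
class IndAlleleFreqs:
    """N×M individual allele frequencies π̂_ij, clipped inside (0, 1)."""

    pi: np.ndarray


@dataclass
class SVDFactors:
    """Top-K factors of the standardized dosage matrix.

    U: (N, K) orthonormal individual scores; S: (K,) descending singular
    values; V: (M, K) orthonormal variant weights.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    @property
    def K(self) -> int:
        return self.U.shape[1]

    def reconstruction(self) -> np.ndarray:
        """Best rank-K approximation Ŷ = U S Vᵀ."""
        return (self.U * self.S) @ self.V.T


@dataclass
class FitResult:
    """All artifacts of the iterative fit."""

    factors: SVDFactors
    pi: IndAlleleFreqs
    y: np.ndarray
    f: AlleleFreqs
    n_iter: int
    converged: bool
    rmse_trace: list[float]


def genotype_posteriors(gl_triple, pi: float) -> np.ndarray:
    """Posterior genotype probabilities for one observation.

    Bayes rule with a Binomial(2, π) prior: P(g | X, π) ∝ P(X | g) ·
    Binom(g; 2, π).  An uninformative (equal) triple returns the prior; a
    certain triple returns itself.
    """
    gl = np.asarray(gl_triple, dtype=float)
    if np.any(gl < 0) or gl.sum() <= 0:
        raise ValueError("invalid likelihood triple")
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie strictly inside (0, 1)")
    prior = np.array([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2])
    w = gl * prior
    return w / w.sum()


def posterior_dosage(gl: GLMatrix, pi: IndAlleleFreqs | np.ndarray) -> np.ndarray:
    """Expected minor-allele count E[G | X, π̂] for every (individual, site).

    Values lie in [0, 2]; a missing observation yields exactly 2π̂_ij (the
    prior mean), which is how structure-based imputation enters the scan.
    """
    p = pi.pi if isinstance(pi, IndAlleleFreqs) else np.asarray(pi, dtype=float)
    L = gl.likelihoods
    p0 = (1.0 - p) ** 2
    p1 = 2.0 * p * (1.0 - p)
    p2 = p**2
    w1 = L[:, :, 1] * p1
    w2 = L[:, :, 2] * p2
    denom = L[:, :, 0] * p0 + w1 + w2
    return (w1 + 2.0 * w2) / denom


def standardize(dosage: np.ndarray, freqs: AlleleFreqs) -> np.ndarray:
    """Standardize dosages with the population frequency under the Binomial
    variance model: y_ij = (E[G_ij|·] − 2 f̂_j) / sqrt(2 f̂_j (1 − f̂_j))."""
    f = freqs.f if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError(
            "population frequencies must lie strictly in (0, 1); "
            "run site filtering before standardization"
        )
    return (dosage - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|U| entry positive per component
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def truncated_svd(y: np.ndarray, K: int, seed: int | None = None) -> SVDFactors:
    """Top-K singular triplets of the standardized matrix.

    Computed by a dense LAPACK decomposition truncated to K — exact, and
    deterministic regardless of ``seed`` (the argument is accepted for
    interface stability with randomized backends).  A sign convention
    (largest-magnitude U entry positive, ties to the lowest index) fixes
    the orientation across platforms.
    """
    y = np.asarray(y, dtype=float)
    n, m = y.shape
    if not 1 <= K < min(n, m):
        raise ValueError(f"K={K} out of range for a {n}x{m} matrix")
    U, S, Vt = scipy.linalg.svd(y, full_matrices=False)
    U, S, V = U[:, :K], S[:K], Vt[:K].T
    U, V = _apply_sign_convention(U, V)
    return SVDFactors(U, S, V)


def update_ind_afs(factors: SVDFactors, freqs: AlleleFreqs,
                   clip_lo: float = 1e-4) -> IndAlleleFreqs:
    """Map the rank-K reconstruction back to the allele-frequency scale.

    Inverts the standardization: π̂_ij = (Ŷ_ij sqrt(2 f̂_j (1−f̂_j)) + 2 f̂_j)/2,
    clipped into [clip_lo, 1−clip_lo] so downstream Binomial priors stay
    non-degenerate.
    """
    f = freqs.f if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, dtype=float)
    yhat = factors.reconstruction()
    pi = (yhat * np.sqrt(2.0 * f * (1.0 - f)) + 2.0 * f) / 2.0
    return IndAlleleFreqs(np.clip(pi, clip_lo, 1.0 - clip_lo))


def fit_individual_afs(gl: GLMatrix, freqs: AlleleFreqs, K: int,
                       tol: float = 1e-5, max_iter: int = 100,
                       seed: int | None = None,
                       clip_lo: float = 1e-4) -> FitResult:
    """The iterative structure fit.

    Starting from π̂⁰_ij = f̂_j, alternates posterior dosage →
    standardization → truncated SVD → individual-allele-frequency update
    until the RMS change of π̂ between iterations drops below ``tol`` or
    ``max_iter`` is reached, then performs one final dosage/standardize/SVD
    pass with the converged frequencies.
    """
    f = freqs.f if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, dtype=float)
    freqs = AlleleFreqs(f)
    n = gl.n_individuals
    if not 1 <= K < n - 1:
        raise ValueError(f"K={K} must satisfy 1 <= K < N-1 = {n - 1}")
    pi = IndAlleleFreqs(np.broadcast_to(f, (n, gl.n_sites)).copy())
    rmse_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dosage = posterior_dosage(gl, pi)
        y = standardize(dosage, freqs)
        factors = truncated_svd(y, K, seed=seed)
        pi_new = update_ind_afs(factors, freqs, clip_lo=clip_lo)
        rmse = float(np.sqrt(np.mean((pi_new.pi - pi.pi) ** 2)))
        rmse_trace.append(rmse)
        pi = pi_new
        if rmse < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"individual allele frequencies not converged after {max_iter} "
            f"iterations (last RMS change {rmse_trace[-1]:.3g})",
            RuntimeWarning,
        )
    dosage = posterior_dosage(gl, pi)
    y = standardize(dosage, freqs)
    factors = truncated_svd(y, K, seed=seed)
    return FitResult(factors, pi, y, freqs, n_iter, converged, rmse_trace)


class GenotypeLikelihoodPCA(BaseEstimator):
    """Principal-component analysis of genotype likelihoods.

    Scikit-learn style estimator wrapping the iterative individual-allele-
    frequency fit.  ``fit`` consumes a :class:`~glscan.io.GLMatrix` (or a
    raw (N, M, 3) likelihood array) whose sites have already been filtered
    to be polymorphic, together with their population allele frequencies.

    Parameters
    ----------
    n_components : int
        Number of principal components K to retain; must be < N−1.
    tol : float
        Convergence threshold on the RMS change of π̂ between iterations.
    max_iter : int
        Iteration cap; non-convergence warns and returns the last state.
    clip : float
        Lower/upper clipping bound keeping π̂ inside (0, 1).
    random_state : int or None
        Seed forwarded to the SVD backend (the dense backend is
        deterministic; kept for interface stability).

    Attributes
    ----------
    components_ : ndarray of shape (K, M)
        Variant weights (rows of Vᵀ).
    scores_ : ndarray of shape (N, K)
        Individual coordinates (columns of U).
    singular_values_ : ndarray of shape (K,)
    individual_allele_freqs_ : ndarray of shape (N, M)
    standardized_dosages_ : ndarray of shape (N, M)
    allele_freqs_ : ndarray of shape (M,)
    n_iter_ : int
    converged_ : bool
    rmse_trace_ : list of float
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-5,
                 max_iter: int = 100, clip: float = 1e-4,
                 random_state: int | None = None):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.clip = clip
        self.random_state = random_state

    @staticmethod
    def _as_glmatrix(X) -> GLMatrix:
        if isinstance(X, GLMatrix):
            return X
        arr = np.asarray(X, dtype=float)
        from .io import MarkerInfo

        markers = [
            MarkerInfo(f"site{j + 1}", "0", "1", f"site{j + 1}", j + 1)
            for j in range(arr.shape[1])
        ]
        return GLMatrix(arr, markers)

    def fit(self, X, y=None, allele_freqs: AlleleFreqs | np.ndarray | None = None):
        """Fit the iterative PCA to genotype likelihoods.

        When ``allele_freqs`` is omitted they are estimated by EM first
        (the sites must still be polymorphic; fit raises otherwise).
        """
        gl = self._as_glmatrix(X)
        if allele_freqs is None:
            from .afreq import estimate_af_em

            allele_freqs = estimate_af_em(gl)
        f = allele_freqs.f if isinstance(allele_freqs, AlleleFreqs) else np.asarray(allele_freqs)
        res = fit_individual_afs(
            gl, AlleleFreqs(f), K=self.n_components, tol=self.tol,
            max_iter=self.max_iter, seed=self.random_state, clip_lo=self.clip,
        )
        self.components_ = res.factors.V.T
        self.scores_ = res.factors.U
        self.singular_values_ = res.factors.S
        self.individual_allele_freqs_ = res.pi.pi
        self.standardized_dosages_ = res.y
        self.allele_freqs_ = res.f.f
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.rmse_trace_ = res.rmse_trace
        self.fit_result_ = res
        return self

    def fit_transform(self, X, y=None, **fit_params):
        """Fit and return the individual PC coordinates U·S, shape (N, K)."""
        self.fit(X, y, **fit_params)
        return self.scores_ * self.singular_values_

    def transform(self, X=None):
        """Return the fitted individual PC coordinates U·S.

        The fit is transductive (scores exist only for the individuals the
        model was fitted on), so ``X`` must be None or the training data.
        """
        if not hasattr(self, "scores_"):
            raise AttributeError("GenotypeLikelihoodPCA instance is not fitted")
        return self.scores_ * self.singular_values_
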
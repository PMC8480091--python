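"""Population allele frequencies from genotype likelihoods.

Per-site minor-allele frequencies are maximum-likelihood estimates under
Hardy–Weinberg equilibrium, obtained by EM over the unobserved genotypes:
the E-step computes posterior genotype expectations under a Binomial(2, f)
prior and the M-step sets f to half the mean posterior dosage.  A
likelihood-ratio test against the monomorphic null identifies variable
sites, and a minor-allele-frequency filter removes near-fixed sites before
the structure fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GLMatrix

__all__ = [
    "AlleleFreqs",
    "SiteMask",
    "NoSitesRetainedError",
    "estimate_af_em",
    "site_loglik",
    "snp_lrt",
    "site_filter",
]

REASON_MONOMORPHIC = "monomorphic"
REASON_BELOW_MAF = "below-maf"
REASON_FAILED_LRT = "failed-lrt"


class NoSitesRetainedError(RuntimeError):
    """Raised when filtering removes every site."""


@dataclass
class AlleleFreqs:
    """Per-site minor-allele frequencies f̂_j in [0, 1]; NaN marks a site
    with no informative data (all observations missing)."""

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)


@dataclass
class SiteMask:
    """Which sites survive filtering and, for the excluded ones, why."""

    keep: np.ndarray
    reasons: dict[int, str]

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reasons.values():
            counts[r] = counts.get(r, 0) + 1
        return counts


def _binom_prior(f: np.ndarray) -> np.ndarray:
    """Stacked HWE genotype prior [(1-f)^2, 2f(1-f), f^2], shape (3, M)."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])


def _loglik_given(Lnorm: np.ndarray, f: np.ndarray) -> np.ndarray:
    prior = _binom_prior(f)  # (3, M)
    mix = (Lnorm * prior.T[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log(mix).sum(axis=0)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_polish(Lnorm: np.ndarray, f: np.ndarray, half_width: float,
                   n_iter: int = 40) -> np.ndarray:
    """Vectorized golden-section refinement of the per-site maximizer
    inside [f − half_width, f + half_width] ∩ [0, 1]."""
    a = np.clip(f - half_width, 0.0, 1.0)
    b = np.clip(f + half_width, 0.0, 1.0)
    for _ in range(n_iter):
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        keep_left = _loglik_given(Lnorm, c) >= _loglik_given(Lnorm, d)
        a = np.where(keep_left, a, c)
        b = np.where(keep_left, d, b)
    return (a + b) / 2.0


def estimate_af_em(gl: GLMatrix, tol: float = 1e-6,
                   max_iter: int = 200) -> AlleleFreqs:
    """ML estimate of the per-site allele frequency under HWE, by EM.

    Iterates f ← (1/2N) Σ_i E[G_ij | X_ij, f] until the largest per-site
    change drops below ``tol``.  The per-site likelihood in f can be
    multimodal for noisy triples and very flat for small panels, so the
    EM is initialized at the best point of a coarse symmetric grid (which
    selects the right basin) and its fixed point is refined by a bracketed
    golden-section step (which resolves plateaus where the EM increments
    fall below ``tol`` while the maximizer is still away).  Sites where
    every individual is missing carry no frequency information and are
    returned as NaN (they are later masked as monomorphic).
    """
    if gl.n_individuals < 2:
        raise ValueError("allele-frequency estimation needs at least 2 individuals")
    if tol <= 0:
        raise ValueError("tol must be positive")
    L = gl.likelihoods  # (N, M, 3)
    Lnorm = L / L.sum(axis=2, keepdims=True)
    grid = np.linspace(0.0, 1.0, 51)
    ll_grid = np.stack([_loglik_given(Lnorm, np.full(gl.n_sites, g))
                        for g in grid])
    f = np.clip(grid[ll_grid.argmax(axis=0)], 0.005, 0.995)
    for _ in range(max_iter):
        prior = _binom_prior(f)  # (3, M)
        w = L * prior.T[None, :, :]  # (N, M, 3)
        denom = w.sum(axis=2)
        eg = (w[:, :, 1] + 2.0 * w[:, :, 2]) / denom
        f_new = eg.mean(axis=0) / 2.0
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    f = _golden_polish(Lnorm, f, half_width=0.025)
    all_missing = gl.missing_mask().all(axis=0)
    f = np.where(all_missing, np.nan, f)
    return AlleleFreqs(f)


def site_loglik(gl: GLMatrix, f) -> np.ndarray:
    """Per-site log-likelihood ℓ_j(f_j) = Σ_i log Σ_g P(X_ij|g)·Binom(g; 2, f_j).

    ``f`` may be a scalar or a length-M vector.  Likelihood triples are
    normalized per observation first so values are comparable across f
    (differences of ℓ at fixed site are unaffected)."""
    L = gl.likelihoods
    L = L / L.sum(axis=2, keepdims=True)
    f = np.broadcast_to(np.asarray(f, dtype=float), (gl.n_sites,))
    prior = _binom_prior(f)
    mix = (L * prior.T[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log(mix).sum(axis=0)


def snp_lrt(gl: GLMatrix, freqs: AlleleFreqs) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test for a site being variable.

    The null is the better of the two monomorphic models (f = 0 and f = 1);
    LRT_j = 2·[ℓ_j(f̂_j) − max(ℓ_j(0), ℓ_j(1))], clamped at zero, referred
    to the upper tail of χ²₁.

    Returns
    -------
    (lrt, pval) : two length-M arrays.
    """
    f = np.nan_to_num(freqs.f, nan=0.0)
    ll_alt = site_loglik(gl, f)
    ll_null = np.maximum(site_loglik(gl, 0.0), site_loglik(gl, 1.0))
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    pval = stats.chi2.sf(lrt, df=1)
    return lrt, pval


def site_filter(freqs: AlleleFreqs, lrt_p: np.ndarray | None = None,
                maf_min: float = 0.05, snp_p: float = 1e-6) -> SiteMask:
    """Retain sites with maf_min < f̂ < 1 − maf_min (strict) that pass the
    variability test when LRT p-values are supplied.

    Raises
    ------
    NoSitesRetainedError
        If no site survives — a scan over zero sites is meaningless.
    """
    if not (0.0 < maf_min < 1.0 and 0.0 < snp_p < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    f = freqs.f
    reasons: dict[int, str] = {}
    keep = np.ones(f.shape, dtype=bool)
    nanf = np.isnan(f)
    with np.errstate(invalid="ignore"):
        fixed = nanf | (f <= 0.0) | (f >= 1.0)
        below = ~fixed & ((f <= maf_min) | (f >= 1.0 - maf_min))
    for j in np.flatnonzero(fixed):
        reasons[j] = REASON_MONOMORPHIC
    for j in np.flatnonzero(below):
        reasons[j] = REASON_BELOW_MAF
    keep &= ~(fixed | below)
    if lrt_p is not None:
        fail = keep & ~(np.asarray(lrt_p) < snp_p)
        for j in np.flatnonzero(fail):
            reasons[j] = REASON_FAILED_LRT
        keep &= ~fail
    if not keep.any():
        raise NoSitesRetainedError(
            "no sites retained after MAF/variability filtering"
        )
    return SiteMask(keep, reasons)
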
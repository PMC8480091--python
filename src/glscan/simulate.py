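"""Synthetic low-coverage datasets with population structure.

Population allele frequencies follow the Balding–Nichols drift model:
around an ancestral frequency p drawn uniformly from ``maf_range``, each
population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), giving mean p and
variance F·p(1−p).  Individuals carry admixture proportions — discrete
one-hot groups or a two-population cline q_i = i/(N−1) — which mix the
population frequencies into per-individual allele frequencies π_ij.
Genotypes are Binomial(2, π_ij).  Loci under divergent selection are
emulated by elevated drift (``selected_fst``): excess allele-frequency
differentiation along the structure axis is exactly the signal the scan
statistics test for.

Sequencing is emulated at the read level: per (individual, site) the read
count is Poisson(``depth_mean``); each read reports the minor allele with
probability g/2·(1−e) + (1−g/2)·e for true genotype g and per-base error
rate e, and the genotype likelihood of hypothetical genotype g' is the
product of those per-read probabilities evaluated at g'.  Zero reads give
the equal (missing) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GLMatrix, MarkerInfo, write_beagle

__all__ = [
    "SimConfig",
    "SimTruth",
    "sim_population_freqs",
    "sim_admixture",
    "sim_genotypes",
    "sim_gl",
    "make_dataset",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic low-coverage dataset.

    Defaults emulate a small low-coverage panel: 100 individuals at 2000
    diallelic sites on a two-population background with F_ST = 0.05 drift
    and mean sequencing depth 6 with 0.5% per-base error.
    """

    n_individuals: int = 100
    n_sites: int = 2000
    n_populations: int = 2
    fst: float = 0.05
    admixture_mode: str = "discrete"  # or "cline"
    depth_mean: float = 6.0
    error_rate: float = 0.005
    selected_sites: int = 0
    selected_fst: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0 or not 0.0 <= self.selected_fst < 1.0:
            raise ValueError("drift parameters must lie in [0, 1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be nonnegative")
        if self.selected_sites > self.n_sites:
            raise ValueError("selected_sites cannot exceed n_sites")
        if self.admixture_mode not in ("discrete", "cline"):
            raise ValueError("admixture_mode must be 'discrete' or 'cline'")
        if self.admixture_mode == "cline" and self.n_populations != 2:
            raise ValueError("cline mode requires exactly 2 source populations")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray
    admixture: np.ndarray
    true_pi: np.ndarray
    genotypes: np.ndarray
    selected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def sim_population_freqs(config: SimConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ancestral and per-population frequencies under drift.

    Returns (ancestral, pop_freqs, selected_mask) with pop_freqs shaped
    (n_populations, n_sites).  The first ``selected_sites`` sites drift
    with ``selected_fst`` instead of ``fst``; F = 0 degenerates to the
    ancestral frequency exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_sites
    lo, hi = config.maf_range
    anc = rng.uniform(lo, hi, size=m)
    selected = np.zeros(m, dtype=bool)
    selected[: config.selected_sites] = True
    fst_per_site = np.where(selected, config.selected_fst, config.fst)
    pop = np.empty((config.n_populations, m))
    nonzero = fst_per_site > 0
    for p in range(config.n_populations):
        pop[p, ~nonzero] = anc[~nonzero]
        if nonzero.any():
            fz = fst_per_site[nonzero]
            a = anc[nonzero] * (1.0 - fz) / fz
            b = (1.0 - anc[nonzero]) * (1.0 - fz) / fz
            pop[p, nonzero] = rng.beta(a, b)
    return anc, pop, selected


def sim_admixture(config: SimConfig) -> np.ndarray:
    """Admixture proportions, one row per individual, rows summing to 1.

    Discrete mode assigns equal-sized one-hot groups; cline mode places
    individual i at proportion i/(N−1) of population 2, emulating a
    continuous gradient of differentiation.
    """
    n, p = config.n_individuals, config.n_populations
    if config.admixture_mode == "discrete":
        q = np.zeros((n, p))
        bounds = np.linspace(0, n, p + 1).astype(int)
        for k in range(p):
            q[bounds[k]: bounds[k + 1], k] = 1.0
        return q
    frac = np.arange(n) / (n - 1) if n > 1 else np.array([0.5])
    return np.column_stack([1.0 - frac, frac])


def sim_genotypes(truth: SimTruth,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Binomial(2, π_ij) genotypes given the individual allele frequencies."""
    rng = np.random.default_rng() if rng is None else rng
    return rng.binomial(2, truth.true_pi)


def sim_gl(genotypes: np.ndarray, config: SimConfig,
           rng: np.random.Generator | None = None) -> GLMatrix:
    """Read-level genotype likelihoods for a genotype panel.

    With c_ij ~ Poisson(depth_mean) reads of which k_ij carry the minor
    allele, P(X | g) = q_g^k (1−q_g)^(c−k) with q_g = g/2·(1−e)+(1−g/2)·e.
    The triple is scaled to max 1 for numerical comfort; c = 0 gives the
    equal triple that encodes a missing observation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    g = np.asarray(genotypes)
    n, m = g.shape
    e = config.error_rate
    depth = rng.poisson(config.depth_mean, size=(n, m))
    q_true = g / 2.0 * (1.0 - e) + (1.0 - g / 2.0) * e
    k = rng.binomial(depth, q_true)
    gl = np.empty((n, m, 3))
    for gp in (0, 1, 2):
        q = gp / 2.0 * (1.0 - e) + (1.0 - gp / 2.0) * e
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = k * np.log(q) + (depth - k) * np.log1p(-q)
        gl[:, :, gp] = loglik
    # q = 0 or 1 with zero exponent: 0*log(0) = 0 by convention
    gl = np.nan_to_num(gl, nan=0.0, neginf=-np.inf)
    gl = np.exp(gl - gl.max(axis=2, keepdims=True))
    gl[depth == 0] = 1.0  # no reads: uninformative triple
    markers = [
        MarkerInfo(f"chr1_{j + 1}", "0", "1", "chr1", j + 1) for j in range(m)
    ]
    return GLMatrix(gl, markers)


def make_dataset(config: SimConfig,
                 beagle_path=None) -> tuple[GLMatrix, SimTruth]:
    """Compose the full generator, reproducibly from ``config.seed``.

    Optionally writes the likelihoods as a Beagle file to ``beagle_path``.
    """
    rng = np.random.default_rng(config.seed)
    anc, pop, selected = sim_population_freqs(config, rng)
    admix = sim_admixture(config)
    true_pi = admix @ pop
    truth = SimTruth(anc, pop, admix, true_pi, None, selected)
    truth.genotypes = sim_genotypes(truth, rng)
    gl = sim_gl(truth.genotypes, config, rng)
    if beagle_path is not None:
        write_beagle(gl, beagle_path)
    return gl, truth
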
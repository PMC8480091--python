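"""Posterior dosages, standardization and the iterative PC fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from glscan.afreq import AlleleFreqs, estimate_af_em
from glscan.io import GenotypeMatrix, GLMatrix, genotypes_to_gl
from glscan.pca import (
    GenotypeLikelihoodPCA,
    SVDFactors,
    fit_individual_afs,
    genotype_posteriors,
    posterior_dosage,
    standardize,
    truncated_svd,
    update_ind_afs,
)
from glscan.simulate import SimConfig, make_dataset

from conftest import make_markers


class TestGenotypePosteriors:
    def test_uninformative_returns_binomial_prior(self):
        post = genotype_posteriors([1 / 3, 1 / 3, 1 / 3], 0.3)
        np.testing.assert_allclose(post, [0.49, 0.42, 0.09], atol=1e-12)

    def test_bayes_rule_hand_case(self):
        post = genotype_posteriors([0.1, 0.6, 0.3], 0.5)
        np.testing.assert_allclose(post, [0.0625, 0.75, 0.1875], atol=1e-12)

    def test_certain_observation(self):
        np.testing.assert_allclose(genotype_posteriors([1, 0, 0], 0.7),
                                   [1, 0, 0])

    def test_all_zero_triple_rejected(self):
        with pytest.raises(ValueError):
            genotype_posteriors([0, 0, 0], 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        gl=st.tuples(*[st.floats(0, 1) for _ in range(3)]).filter(
            lambda t: sum(t) > 1e-9),
        pi=st.floats(0.01, 0.99),
    )
    def test_sums_to_one(self, gl, pi):
        assert genotype_posteriors(gl, pi).sum() == pytest.approx(1.0, abs=1e-12)


class TestPosteriorDosage:
    def test_missing_gives_prior_mean(self):
        gl = GLMatrix(np.full((1, 1, 3), 1.0), make_markers(1))
        dose = posterior_dosage(gl, np.array([[0.3]]))
        assert dose[0, 0] == pytest.approx(0.6, abs=1e-12)

    def test_hand_case(self):
        gl = GLMatrix(np.array([[[0.1, 0.6, 0.3]]]), make_markers(1))
        dose = posterior_dosage(gl, np.array([[0.5]]))
        assert dose[0, 0] == pytest.approx(1.125, abs=1e-12)

    def test_certain_genotypes_and_range(self, rng):
        geno = rng.integers(0, 3, size=(5, 8))
        gl = genotypes_to_gl(GenotypeMatrix(geno))
        pi = rng.uniform(0.1, 0.9, size=(5, 8))
        dose = posterior_dosage(gl, pi)
        np.testing.assert_allclose(dose, geno, atol=1e-12)
        assert np.all((dose >= 0) & (dose <= 2))


class TestStandardize:
    def test_centered_dosage_is_zero(self):
        f = AlleleFreqs(np.array([0.3]))
        assert standardize(np.array([[0.6]]), f)[0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("dose,f,expected",
                             [(1.125, 0.5, 0.176777), (2.0, 0.05, 6.16441)])
    def test_arithmetic(self, dose, f, expected):
        y = standardize(np.array([[dose]]), AlleleFreqs(np.array([f])))
        assert y[0, 0] == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_degenerate_frequency_is_fatal(self, bad):
        with pytest.raises(ValueError):
            standardize(np.array([[1.0]]), AlleleFreqs(np.array([bad])))


class TestTruncatedSVD:
    def test_exact_rank_one(self, rng):
        y = np.outer(rng.normal(size=12), rng.normal(size=30))
        factors = truncated_svd(y, K=1)
        assert np.linalg.norm(factors.reconstruction() - y) < 1e-8

    def test_matches_dense_oracle(self, rng):
        y = rng.normal(size=(20, 50))
        factors = truncated_svd(y, K=3)
        s_oracle = np.linalg.svd(y, compute_uv=False)[:3]
        np.testing.assert_allclose(factors.S, s_oracle, atol=1e-8)
        assert np.all(np.diff(factors.S) < 0)

    def test_orthonormality_and_sign_convention(self, rng):
        y = rng.normal(size=(15, 40))
        factors = truncated_svd(y, K=4)
        np.testing.assert_allclose(factors.U.T @ factors.U, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(factors.V.T @ factors.V, np.eye(4), atol=1e-8)
        idx = np.abs(factors.U).argmax(axis=0)
        assert np.all(factors.U[idx, np.arange(4)] > 0)

    @pytest.mark.parametrize("k", [0, 10])
    def test_k_out_of_range(self, rng, k):
        with pytest.raises(ValueError):
            truncated_svd(rng.normal(size=(10, 20)), K=k)


class TestUpdateIndAFs:
    def test_no_structure_returns_population_frequency(self):
        factors = SVDFactors(np.zeros((4, 1)), np.zeros(1), np.zeros((6, 1)))
        f = AlleleFreqs(np.full(6, 0.3))
        np.testing.assert_allclose(update_ind_afs(factors, f).pi, 0.3)

    def test_clipping(self):
        factors = SVDFactors(np.array([[-100.0]]), np.array([1.0]),
                             np.array([[1.0]]))
        f = AlleleFreqs(np.array([0.5]))
        pi = update_ind_afs(factors, f, clip_lo=1e-4).pi
        assert pi[0, 0] == pytest.approx(1e-4)


class TestIterativeFit:
    def test_structureless_population_stays_at_population_frequency(self):
        rng = np.random.default_rng(3)
        n, m = 50, 500
        freqs = rng.uniform(0.2, 0.8, m)
        geno = rng.binomial(2, np.broadcast_to(freqs, (n, m)))
        gl = genotypes_to_gl(GenotypeMatrix(geno))
        f = estimate_af_em(gl)
        res = fit_individual_afs(gl, f, K=1)
        assert res.converged
        assert res.n_iter <= 2  # certain genotypes: dosage ignores the prior
        # with no structure the rank-1 factor can only absorb noise; its
        # magnitude is bounded by the largest singular value of an N x M
        # noise matrix, sqrt(M) + sqrt(N), mapped to the frequency scale
        rms = np.sqrt(np.mean((res.pi.pi - f.f) ** 2))
        noise_bound = ((np.sqrt(m) + np.sqrt(n)) / np.sqrt(n * m)
                       * np.max(np.sqrt(2 * f.f * (1 - f.f))) / 2)
        assert rms < noise_bound

    def test_rmse_trace_decreases_after_burn_in(self, two_pop_dataset):
        (gl, truth), _ = two_pop_dataset
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.05) & (f.f < 0.95)
        res = fit_individual_afs(gl.subset_sites(keep),
                                 AlleleFreqs(f.f[keep]), K=1, tol=1e-5)
        # monotone decrease holds while the change is well above the
        # convergence tolerance; at the plateau only numerical jitter remains
        trace = np.array(res.rmse_trace[1:])
        active = trace >= 10 * 1e-5
        assert np.all(np.diff(trace[active]) <= 0)

    def test_pc1_separates_two_populations(self, two_pop_dataset):
        (gl, truth), cfg = two_pop_dataset
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.05) & (f.f < 0.95)
        res = fit_individual_afs(gl.subset_sites(keep),
                                 AlleleFreqs(f.f[keep]), K=1)
        u = res.factors.U[:, 0]
        half = cfg.n_individuals // 2
        signs_a, signs_b = set(np.sign(u[:half])), set(np.sign(u[half:]))
        assert signs_a == {1.0} and signs_b == {-1.0} or (
            signs_a == {-1.0} and signs_b == {1.0})

    def test_recovers_individual_allele_frequencies(self):
        cfg = SimConfig(n_individuals=80, n_sites=1500, fst=0.15,
                        depth_mean=8, error_rate=0.01, seed=21)
        gl, truth = make_dataset(cfg)
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.05) & (f.f < 0.95)
        res = fit_individual_afs(gl.subset_sites(keep),
                                 AlleleFreqs(f.f[keep]), K=1)
        r = np.corrcoef(res.pi.pi.ravel(), truth.true_pi[:, keep].ravel())[0, 1]
        assert r > 0.9

    def test_high_depth_matches_true_genotype_factors(self):
        cfg = SimConfig(n_individuals=60, n_sites=1200, fst=0.1,
                        depth_mean=30, error_rate=0.005, seed=13)
        gl, truth = make_dataset(cfg)
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.05) & (f.f < 0.95)
        res_gl = fit_individual_afs(gl.subset_sites(keep),
                                    AlleleFreqs(f.f[keep]), K=1)
        geno_gl = genotypes_to_gl(GenotypeMatrix(truth.genotypes))
        fg = estimate_af_em(geno_gl)
        res_gt = fit_individual_afs(geno_gl.subset_sites(keep),
                                    AlleleFreqs(fg.f[keep]), K=1)
        for a, b in ((res_gl.factors.U, res_gt.factors.U),
                     (res_gl.factors.V, res_gt.factors.V)):
            r = abs(np.corrcoef(a[:, 0], b[:, 0])[0, 1])
            assert r > 0.99

    def test_allele_relabel_flips_v_row(self, two_pop_dataset):
        (gl, _), _ = two_pop_dataset
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.1) & (f.f < 0.9)
        gl_k = gl.subset_sites(keep)
        f_k = AlleleFreqs(f.f[keep])
        res = fit_individual_afs(gl_k, f_k, K=1, tol=1e-7)
        j = 5
        flipped_lik = gl_k.likelihoods.copy()
        flipped_lik[:, j, :] = flipped_lik[:, j, ::-1]
        gl_flip = GLMatrix(flipped_lik, gl_k.markers)
        f_flip = f_k.f.copy()
        f_flip[j] = 1.0 - f_flip[j]
        res_flip = fit_individual_afs(gl_flip, AlleleFreqs(f_flip), K=1,
                                      tol=1e-7)
        assert res_flip.factors.V[j, 0] == pytest.approx(
            -res.factors.V[j, 0], abs=1e-6)
        np.testing.assert_allclose(res_flip.factors.V[:, 0] ** 2,
                                   res.factors.V[:, 0] ** 2, atol=1e-6)

    def test_k_out_of_range(self, two_pop_dataset):
        (gl, _), _ = two_pop_dataset
        f = estimate_af_em(gl)
        with pytest.raises(ValueError):
            fit_individual_afs(gl, f, K=gl.n_individuals)


class TestEstimator:
    def test_sklearn_protocol(self):
        est = GenotypeLikelihoodPCA(n_components=3, tol=1e-4)
        params = est.get_params()
        assert params["n_components"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(n_components=1)
        assert est.n_components == 1

    def test_fit_attributes(self, two_pop_dataset):
        (gl, _), _ = two_pop_dataset
        f = estimate_af_em(gl)
        keep = ~np.isnan(f.f) & (f.f > 0.05) & (f.f < 0.95)
        est = GenotypeLikelihoodPCA(n_components=2).fit(
            gl.subset_sites(keep), allele_freqs=f.f[keep])
        n, m = gl.n_individuals, int(keep.sum())
        assert est.components_.shape == (2, m)
        assert est.scores_.shape == (n, 2)
        assert est.individual_allele_freqs_.shape == (n, m)
        coords = est.transform()
        np.testing.assert_allclose(coords,
                                   est.scores_ * est.singular_values_)

    def test_unfitted_transform_raises(self):
        with pytest.raises(AttributeError):
            GenotypeLikelihoodPCA().transform()
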
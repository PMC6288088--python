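import numpy as np
import pytest

from coocnet.io_tables import TaxaCountTable, relative_abundances
from coocnet.refine import RefinementConfig, iterative_refinement
from coocnet.sparcc import (
    PosteriorConfig,
    basis_correlations,
    dirichlet_draw,
    permutation_pvalues,
    sparcc_estimate,
    variation_matrix,
)
from coocnet.synthetic import make_truth, simulate_counts


class TestDirichletDraw:
    def test_posterior_mean_matches_closed_form(self):
        # counts (3, 1), alpha=1: posterior mean is (4/6, 2/6)
        t = TaxaCountTable(["a", "b"], ["s1"], np.array([[3], [1]]))
        cfg = PosteriorConfig(n_draws=1, seed=42)
        draws = np.array(
            [dirichlet_draw(t, cfg, d).fractions[:, 0] for d in range(10_000)]
        )
        assert np.allclose(draws.mean(axis=0), [4 / 6, 2 / 6], atol=0.01)

    def test_columns_sum_to_one(self, rng):
        counts = rng.integers(0, 100, size=(10, 5)) + 1
        t = TaxaCountTable([f"t{i}" for i in range(10)], [f"s{j}" for j in range(5)], counts)
        fr = dirichlet_draw(t, PosteriorConfig(seed=0), 3).fractions
        assert np.allclose(fr.sum(axis=0), 1.0, atol=1e-9)
        assert (fr > 0).all()

    def test_deterministic_in_seed_and_draw_index(self, toy_table):
        cfg = PosteriorConfig(seed=5)
        a = dirichlet_draw(toy_table, cfg, 7).fractions
        b = dirichlet_draw(toy_table, cfg, 7).fractions
        c = dirichlet_draw(toy_table, cfg, 8).fractions
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestVariationMatrix:
    def test_duplicated_taxon_has_zero_entry(self):
        f = np.array([[0.2, 0.3, 0.25], [0.2, 0.3, 0.25], [0.6, 0.4, 0.5]])
        t = variation_matrix(f)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_variance(self):
        # two samples with f_i/f_j = (e, e^3): Var[(1, 3)] with n-1 = 2.0
        f = np.array([[np.e / (1 + np.e), np.e**3 / (1 + np.e**3)],
                      [1 / (1 + np.e), 1 / (1 + np.e**3)]])
        f = np.vstack([f, f])  # pad to keep shapes general
        f /= f.sum(axis=0)
        t = variation_matrix(f)
        assert t[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_symmetric_zero_diagonal(self, rng):
        f = rng.dirichlet(np.ones(8), size=6).T
        t = variation_matrix(f)
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 0.0)

    def test_zero_fraction_rejected(self):
        f = np.array([[0.5, 0.0], [0.5, 1.0]])
        with pytest.raises(ValueError, match="dirichlet"):
            variation_matrix(f)


def _oracle_basis_fit(t):
    """Independent dense solve: explicit loops, explicit matrix inverse."""
    K = t.shape[0]
    A = np.zeros((K, K))
    b = np.zeros(K)
    for i in range(K):
        A[i, i] = K - 1
        for j in range(K):
            if j != i:
                A[i, j] = 1.0
                b[i] += t[i, j]
    omega2 = np.linalg.inv(A) @ b
    w = np.sqrt(np.clip(omega2, 1e-10, None))
    rho = np.eye(K)
    for i in range(K):
        for j in range(K):
            if i != j:
                rho[i, j] = np.clip(
                    (omega2[i] + omega2[j] - t[i, j]) / (2 * w[i] * w[j]), -1, 1
                )
    return omega2, rho


class TestBasisCorrelations:
    def test_matches_explicit_inversion_oracle(self, rng):
        z = rng.standard_normal((5, 40))
        f = np.exp(z) / np.exp(z).sum(axis=0)
        t = variation_matrix(f)
        model = basis_correlations(t)
        omega2_o, rho_o = _oracle_basis_fit(t)
        assert np.allclose(model.omega2, omega2_o, atol=1e-8)
        assert np.allclose(model.rho, rho_o, atol=1e-8)

    def test_null_max_correlation_small_at_large_n(self, rng):
        # iid log-normal taxa, K=50, n=500: basis correlations all near zero
        z = rng.standard_normal((50, 500))
        f = np.exp(z) / np.exp(z).sum(axis=0)
        model = basis_correlations(variation_matrix(f))
        off = model.rho[~np.eye(50, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_unit_diagonal_and_symmetry(self, rng):
        z = rng.standard_normal((6, 30))
        f = np.exp(z) / np.exp(z).sum(axis=0)
        model = basis_correlations(variation_matrix(f))
        assert np.array_equal(np.diag(model.rho), np.ones(6))
        assert np.allclose(model.rho, model.rho.T)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="4 taxa"):
            basis_correlations(np.zeros((3, 3)))


class TestSparccEstimate:
    def test_single_draw_equals_manual_pipeline(self, rng):
        truth = make_truth(10, 0, 0, 0.5, seed=3)
        ds = simulate_counts(truth, {"ciliate": 20}, seed=3)
        post = PosteriorConfig(n_draws=1, seed=11)
        refine = RefinementConfig(enabled=False)
        res = sparcc_estimate(ds.table, post, refine)
        fr = dirichlet_draw(ds.table, post, 0)
        model, _, _ = iterative_refinement(variation_matrix(fr), refine)
        assert np.allclose(res.rho_mean, model.rho, atol=1e-12)

    def test_depth_invariance(self):
        # multiplying one sample's counts by 10 barely moves the estimate
        truth = make_truth(15, 0, 0, 0.5, seed=8)
        ds = simulate_counts(truth, {"ciliate": 40}, seed=8)
        post = PosteriorConfig(n_draws=20, seed=2)
        refine = RefinementConfig(enabled=False)
        base = sparcc_estimate(ds.table, post, refine).rho_mean
        scaled_counts = ds.table.counts.copy()
        scaled_counts[:, 0] *= 10
        scaled = TaxaCountTable(ds.table.taxon_ids, ds.table.sample_ids, scaled_counts)
        boosted = sparcc_estimate(scaled, post, refine).rho_mean
        assert np.abs(base - boosted).max() < 0.05

    def test_aggregate_validates(self, toy_table):
        truth = make_truth(10, 0, 0, 0.5, seed=1)
        ds = simulate_counts(truth, {"ciliate": 10}, seed=1)
        with pytest.raises(ValueError):
            sparcc_estimate(ds.table, aggregate="mode")


class TestPermutationPvalues:
    def test_duplicated_taxon_hits_minimum_pseudo_p(self, rng):
        # a taxon duplicated verbatim is perfectly correlated with itself:
        # no permutation can beat it, so p = 1/(n_perm + 1)
        counts = rng.integers(50, 500, size=(8, 30))
        counts[1] = counts[0]
        t = TaxaCountTable([f"t{i}" for i in range(8)], [f"s{j}" for j in range(30)], counts)
        res = sparcc_estimate(t, PosteriorConfig(n_draws=3, seed=4),
                              RefinementConfig(enabled=False))
        n_perm = 50
        p = permutation_pvalues(t, res.rho_mean, n_perm=n_perm, seed=5)
        assert p[0, 1] == pytest.approx(1 / (n_perm + 1))

    def test_pvalues_in_half_open_unit_interval(self, rng):
        counts = rng.integers(1, 200, size=(6, 15))
        t = TaxaCountTable([f"t{i}" for i in range(6)], [f"s{j}" for j in range(15)], counts)
        res = sparcc_estimate(t, PosteriorConfig(n_draws=2, seed=1),
                              RefinementConfig(enabled=False))
        p = permutation_pvalues(t, res.rho_mean, n_perm=20, seed=2)
        assert (p > 0).all() and (p <= 1).all()

    def test_invalid_n_perm_rejected(self, toy_table, rng):
        with pytest.raises(ValueError):
            permutation_pvalues(toy_table, np.eye(3), n_perm=0, seed=0)
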
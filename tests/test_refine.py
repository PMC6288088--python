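import numpy as np
import pytest

from coocnet.refine import (
    RefinementConfig,
    batch_size,
    iterative_refinement,
    pair_covariances,
    total_covariance,
)
from coocnet.sparcc import (
    BasisModel,
    PosteriorConfig,
    basis_correlations,
    dirichlet_draw,
    variation_matrix,
)
from coocnet.synthetic import make_truth, simulate_counts


def _model_from_rho(rho):
    rho = np.asarray(rho, dtype=float)
    K = rho.shape[0]
    return BasisModel(
        omega2=np.ones(K), rho=rho, cov=rho.copy(), floored=np.zeros(K, bool)
    )


class TestPairCovariances:
    def test_hand_sorted_three_taxon_model(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.9
        rho[0, 2] = rho[2, 0] = -0.9
        model = _model_from_rho(rho)
        ordered = pair_covariances(model, [(0, 1), (0, 2), (1, 2)])
        assert [p for p, _ in ordered] == [(0, 1), (1, 2), (0, 2)]

    def test_matches_brute_force_resort(self, rng):
        for _ in range(100):
            K = 6
            m = rng.standard_normal((K, K))
            rho = (m + m.T) / 2
            np.fill_diagonal(rho, 1.0)
            model = _model_from_rho(rho)
            pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
            ordered = pair_covariances(model, pairs)
            oracle = sorted(
                [((i, j), model.cov[i, j]) for i, j in pairs],
                key=lambda kv: (-kv[1], kv[0]),
            )
            assert ordered == oracle

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError):
            pair_covariances(_model_from_rho(np.eye(3)), [])


class TestBatchSize:
    @pytest.mark.parametrize(
        "n_pairs, fraction, expected",
        [
            (36_315, 0.00025, 10),  # 270-taxon table: ceil(9.078)
            (45, 0.00025, 1),       # minimum rule
            (45, 1.0, 45),          # boundary: whole active set
        ],
    )
    def test_examples(self, n_pairs, fraction, expected):
        assert batch_size(n_pairs, fraction) == expected

    def test_invalid_pair_count(self):
        with pytest.raises(ValueError):
            batch_size(0, 0.1)


class TestTotalCovariance:
    def test_identity_model_is_zero(self):
        model = _model_from_rho(np.eye(4))
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        assert total_covariance(model, pairs) == 0.0

    def test_sums_absolute_values(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.3
        rho[0, 2] = rho[2, 0] = -0.2
        model = _model_from_rho(rho)
        assert total_covariance(model, [(0, 1), (0, 2)]) == pytest.approx(0.5)

    def test_removing_largest_pair_never_increases(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.4
        rho[1, 2] = rho[2, 1] = 0.1
        model = _model_from_rho(rho)
        full = total_covariance(model, [(0, 1), (1, 2)])
        assert total_covariance(model, [(1, 2)]) <= full


class TestIterativeRefinement:
    def test_disabled_bypass_is_single_fit(self, rng):
        z = rng.standard_normal((10, 25))
        f = np.exp(z) / np.exp(z).sum(axis=0)
        t = variation_matrix(f)
        model, excluded, trace = iterative_refinement(
            t, RefinementConfig(enabled=False)
        )
        assert excluded == frozenset()
        assert trace.stopped_reason == "disabled"
        assert np.allclose(model.rho, basis_correlations(t).rho)

    def test_planted_strong_pairs_excluded_within_five_iterations(self):
        for seed in (101, 102, 103):
            truth = make_truth(50, 3, 0, 0.8, seed=seed)
            ds = simulate_counts(truth, {"ciliate": 200}, seed=seed)
            fr = dirichlet_draw(ds.table, PosteriorConfig(seed=seed), 0)
            t = variation_matrix(fr)
            _, excluded, _ = iterative_refinement(t, RefinementConfig(max_iter=5))
            planted = {tuple(sorted(p)) for p in truth.pos_pairs}
            assert planted <= set(excluded)

    def test_trace_non_increasing_and_window_termination(self):
        for seed in (0, 1, 2, 3, 4):
            truth = make_truth(40, 0, 0, 0.5, seed=seed)
            ds = simulate_counts(truth, {"ciliate": 34}, seed=seed)
            fr = dirichlet_draw(ds.table, PosteriorConfig(seed=seed), 0)
            t = variation_matrix(fr)
            _, _, trace = iterative_refinement(t, RefinementConfig())
            tc = np.array(trace.total_covariance)
            assert (np.diff(tc) <= 1e-6).all()
            assert trace.stopped_reason == "window_converged"
            assert trace.n_excluded_cumulative == sorted(trace.n_excluded_cumulative)

    def test_fixed_rule_runs_to_exhaustion_on_small_tables(self):
        # the literal fixed-tolerance reading cannot fire at this scale:
        # every iteration removes ~2/1000 of the statistic mechanically
        truth = make_truth(30, 0, 0, 0.5, seed=9)
        ds = simulate_counts(truth, {"ciliate": 30}, seed=9)
        fr = dirichlet_draw(ds.table, PosteriorConfig(seed=9), 0)
        t = variation_matrix(fr)
        _, _, trace = iterative_refinement(
            t, RefinementConfig(stop_rule="fixed", rel_tol=1e-3, max_iter=400)
        )
        assert trace.stopped_reason in ("exhausted", "max_iter")

    def test_refinement_never_flips_planted_sign(self):
        truth = make_truth(50, 3, 0, 0.8, seed=77)
        ds = simulate_counts(truth, {"ciliate": 200}, seed=77)
        fr = dirichlet_draw(ds.table, PosteriorConfig(seed=77), 0)
        t = variation_matrix(fr)
        model, _, _ = iterative_refinement(t, RefinementConfig())
        for i, j in truth.pos_pairs:
            assert model.rho[i, j] > 0

    def test_asymmetric_matrix_rejected(self):
        t = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            iterative_refinement(t, RefinementConfig())
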
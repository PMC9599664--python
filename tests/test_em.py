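import numpy as np
import pytest

from sparsetrack import (
    SourceSinkProblem,
    baseline_em,
    e_step,
    grid_search,
    m_step_alpha,
    m_step_gamma,
    penalized_log_likelihood,
    run_em,
)
from sparsetrack.em import (
    LatentProfiles,
    MixingProportions,
    Responsibilities,
    default_init,
)
from sparsetrack.selection import (
    init_unknown_profile,
    normalize_profiles,
    solve_sparse_qp,
)


def pipeline_init(problem, lam_select=1e-6):
    gamma = normalize_profiles(problem)
    sel = solve_sparse_qp(problem.sink / problem.sink_total, gamma, lam_select)
    unknown = init_unknown_profile(problem, sel)
    return default_init(problem, sel, unknown)


def random_problem(rng, m=None, n=None, depth=2000):
    m = m if m is not None else int(rng.integers(2, 11))
    n = n if n is not None else int(rng.integers(5, 51))
    profiles = rng.dirichlet(np.full(n, 0.5), size=m + 1)
    sources = np.stack([rng.multinomial(depth, p) + 1 for p in profiles[:m]])
    alpha = rng.dirichlet(np.ones(m + 1))
    sink = rng.multinomial(depth, alpha @ profiles)
    if sink.sum() == 0:
        sink[0] = 1
    return SourceSinkProblem(
        sink=sink,
        sources=sources,
        taxon_ids=[f"t{j}" for j in range(n)],
        source_ids=[f"s{i}" for i in range(m)],
    )


class TestEStep:
    def test_disjoint_supports_give_hard_assignment(self):
        alpha = MixingProportions(np.array([0.5, 0.5]))
        gamma = LatentProfiles(np.array([[1.0, 0.0], [0.0, 1.0]]))
        p = e_step(alpha, gamma, np.array([3, 4])).p
        assert p[0, 0] == 1.0 and p[1, 1] == 1.0

    def test_printed_formula_value(self):
        alpha = MixingProportions(np.array([0.6, 0.4]))
        gamma = LatentProfiles(np.array([[0.5, 0.5], [0.25, 0.75]]))
        p = e_step(alpha, gamma, np.array([1, 1])).p
        # p(1|1) = 0.6*0.5 / (0.6*0.5 + 0.4*0.25) = 0.3/0.4
        assert p[0, 0] == pytest.approx(0.75)

    def test_columns_sum_to_one(self, rng):
        for _ in range(5):
            m, n = 4, 12
            alpha = MixingProportions(rng.dirichlet(np.ones(m)))
            gamma = LatentProfiles(rng.dirichlet(np.ones(n), size=m))
            p = e_step(alpha, gamma, rng.integers(0, 5, n)).p
            np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-9)
            assert np.all((p >= 0) & (p <= 1))


class TestMStepGamma:
    def test_update_formula_direct_evaluation(self):
        # y_i=(5,5), x=(10,10), p(i|.)=(1,0):
        # numerators are (10*1+5, 10*0+5) = (15, 5) -> gamma_i = (0.75, 0.25)
        resp = Responsibilities(np.array([[1.0, 0.0], [0.0, 1.0]]))
        Y = np.array([[5.0, 5.0], [5.0, 5.0]])
        gamma = m_step_gamma(resp, np.array([10, 10]), Y).gamma
        np.testing.assert_allclose(gamma[0], [0.75, 0.25])

    def test_zero_responsibility_reduces_to_observed_profile(self):
        resp = Responsibilities(np.array([[0.0, 0.0], [1.0, 1.0]]))
        Y = np.array([[6.0, 2.0], [1.0, 1.0]])
        gamma = m_step_gamma(resp, np.array([4, 4]), Y).gamma
        np.testing.assert_allclose(gamma[0], [0.75, 0.25])

    def test_rows_sum_to_one(self, rng):
        resp = Responsibilities(rng.dirichlet(np.ones(3), size=8).T)
        Y = rng.uniform(0, 10, size=(3, 8))
        gamma = m_step_gamma(resp, rng.integers(0, 9, 8), Y).gamma
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestMStepAlpha:
    def test_lambda_zero_closed_form(self):
        resp = Responsibilities(np.eye(2))
        alpha = m_step_alpha(resp, np.array([3, 1]), lam=0.0).alpha
        np.testing.assert_allclose(alpha, [0.75, 0.25])

    def test_penalized_two_component_value(self):
        # maximize 3 log a1 + 1 log a2 - 1*a1 on the simplex:
        # a1 = 3/(1+nu), a2 = 1/nu with 3/(1+nu) + 1/nu = 1
        # -> nu^2 - 3 nu - 1 = 0 -> nu = (3 + sqrt(13))/2
        nu = (3 + np.sqrt(13)) / 2
        expected = np.array([3 / (1 + nu), 1 / nu])
        resp = Responsibilities(np.eye(2))
        alpha = m_step_alpha(resp, np.array([3, 1]), lam=1.0).alpha
        np.testing.assert_allclose(alpha, expected, atol=1e-10)
        assert alpha[0] == pytest.approx(0.697, abs=2e-3)
        assert alpha[1] == pytest.approx(0.303, abs=2e-3)

    def test_zero_count_source_gets_exact_zero(self):
        resp = Responsibilities(
            np.array([[0.0, 0.0], [0.5, 0.5], [0.5, 0.5]])
        )
        alpha = m_step_alpha(resp, np.array([4, 6]), lam=0.01).alpha
        assert alpha[0] == 0.0
        assert alpha.sum() == pytest.approx(1.0)

    def test_empty_sink_rejected(self):
        resp = Responsibilities(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="empty sink"):
            m_step_alpha(resp, np.zeros(3), lam=0.1)

    def test_huge_lambda_pushes_mass_to_unknown(self):
        # lam much larger than the total sink reads: knowns shrink to c/lam
        resp = Responsibilities(np.array([[1.0, 1.0], [0.0, 0.0]]))
        alpha = m_step_alpha(resp, np.array([5, 5]), lam=100.0).alpha
        assert alpha[-1] == pytest.approx(1.0 - 10 / 100)


class TestPenalizedLogLik:
    def test_matches_independent_summation(self, rng):
        m, n = 3, 6
        alpha = MixingProportions(rng.dirichlet(np.ones(m + 1)))
        gamma = LatentProfiles(rng.dirichlet(np.ones(n), size=m + 1))
        x = rng.integers(0, 8, n)
        Y = rng.integers(0, 9, size=(m + 1, n)).astype(float)
        lam = 0.3
        loglik, pen = penalized_log_likelihood(alpha, gamma, lam, x, Y)
        beta = alpha.alpha @ gamma.gamma
        expected = sum(
            x[j] * np.log(beta[j]) for j in range(n) if x[j] > 0
        ) + sum(
            Y[i, j] * np.log(gamma.gamma[i, j])
            for i in range(m + 1)
            for j in range(n)
            if Y[i, j] > 0
        )
        assert loglik == pytest.approx(expected, rel=1e-12)
        assert pen == pytest.approx(expected - lam * alpha.alpha[:-1].sum(), rel=1e-12)

    def test_plug_in_single_source_value(self, rng):
        n = 5
        x = rng.integers(1, 9, n)
        y = rng.integers(1, 9, (1, n)).astype(float)
        c = x.sum()
        gamma_row = x / c
        alpha = MixingProportions(np.array([1.0, 0.0]))
        gamma = LatentProfiles(np.vstack([gamma_row, np.full(n, 1 / n)]))
        Y = np.vstack([y, np.zeros(n)])
        loglik, _ = penalized_log_likelihood(alpha, gamma, 0.0, x, Y)
        expected = np.sum(x * np.log(x / c)) + np.sum(y[0] * np.log(gamma_row))
        assert loglik == pytest.approx(expected, rel=1e-12)

    def test_gamma_mstep_is_optimal_for_data_term(self, rng):
        # perturbing a gamma row away from its M-step update cannot increase
        # the objective at fixed responsibilities
        problem = random_problem(rng, m=3, n=10)
        init = pipeline_init(problem)
        state = run_em(problem, 1e-6, init, tol=1e-8, max_iter=50)
        x, y_full = problem.sink, np.vstack(
            [problem.sources.astype(float), init[2][-1]]
        )
        resp = e_step(state.alpha, state.gamma, x)
        gamma_opt = m_step_gamma(resp, x, y_full)
        _, base = penalized_log_likelihood(state.alpha, gamma_opt, 1e-6, x, y_full)
        for _ in range(5):
            noise = rng.dirichlet(np.ones(problem.n_taxa))
            perturbed = gamma_opt.gamma.copy()
            perturbed[0] = 0.9 * perturbed[0] + 0.1 * noise
            _, val = penalized_log_likelihood(
                state.alpha, LatentProfiles(perturbed), 1e-6, x, y_full
            )
            assert val <= base + 1e-9


class TestRunEM:
    def test_single_source_recovery(self, rng):
        profiles = rng.dirichlet(np.ones(100), size=1)
        sources = np.stack([rng.multinomial(100_000, profiles[0])])
        sink = rng.multinomial(100_000, sources[0] / sources[0].sum())
        problem = SourceSinkProblem(
            sink=sink, sources=sources,
            taxon_ids=[f"t{j}" for j in range(100)], source_ids=["s0"],
        )
        state = run_em(problem, 1e-6, pipeline_init(problem), tol=1e-10, max_iter=2000)
        assert state.alpha.alpha[0] >= 0.99
        assert state.alpha.alpha[1] <= 0.01

    def test_max_iter_one_flags_unconverged(self, rng):
        problem = random_problem(rng)
        state = run_em(problem, 1e-6, pipeline_init(problem), tol=1e-12, max_iter=1)
        assert state.n_iter == 1
        assert not state.converged

    def test_objective_monotone_on_random_instances(self, rng):
        for _ in range(20):
            problem = random_problem(rng)
            state = run_em(
                problem, 1e-6, pipeline_init(problem),
                tol=1e-9, max_iter=300, trace=True,
            )
            trace = np.array(state.objective_trace)
            slack = 1e-10 * np.abs(trace[:-1])
            assert np.all(np.diff(trace) >= -np.maximum(slack, 1e-10))

    def test_alpha_and_gamma_stay_normalized(self, rng):
        problem = random_problem(rng)
        state = run_em(problem, 1e-4, pipeline_init(problem), tol=1e-8)
        assert state.alpha.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            state.gamma.gamma.sum(axis=1), 1.0, atol=1e-9
        )

    def test_unpenalized_fixed_gamma_matches_classical_update(self, rng):
        # with lam=0 and gamma fixed at the observed profiles, one EM pass
        # reproduces the classical multinomial-mixture update c / sum(c)
        problem = random_problem(rng, m=3, n=15)
        gamma_rows = normalize_profiles(problem).gamma_init
        unk = np.full(problem.n_taxa, 1.0 / problem.n_taxa)
        gamma = LatentProfiles(np.vstack([gamma_rows, unk]))
        alpha = MixingProportions(np.full(4, 0.25))
        resp = e_step(alpha, gamma, problem.sink)
        c = resp.p @ problem.sink
        expected = c / c.sum()
        updated = m_step_alpha(resp, problem.sink, lam=0.0).alpha
        np.testing.assert_allclose(updated, expected, atol=1e-12)


class TestGridSearch:
    def test_singleton_grid_equals_run_em(self, small_panel):
        problem = small_panel.problems[0]
        init = pipeline_init(problem)
        a = grid_search(problem, [1e-6], init)
        b = run_em(problem, 1e-6, init)
        np.testing.assert_allclose(a.alpha.alpha, b.alpha.alpha, atol=1e-12)

    def test_returns_highest_loglik_member(self, small_panel):
        problem = small_panel.problems[1]
        init = pipeline_init(problem)
        grid = [1e-8, 1e-6, 1e-4, 1e-2]
        best = grid_search(problem, grid, init)
        logliks = [run_em(problem, lam, init).loglik for lam in grid]
        assert best.loglik >= max(logliks) - 1e-9

    def test_selected_support_subset_of_smallest_lambda(self):
        rng = np.random.default_rng(8)
        profiles = rng.dirichlet(np.full(120, 0.8), size=7)
        sources = np.stack([rng.multinomial(10_000, p) for p in profiles[:6]])
        beta = 0.5 * profiles[0] + 0.3 * profiles[3] + 0.2 * profiles[6]
        sink = rng.multinomial(10_000, beta)
        problem = SourceSinkProblem(
            sink=sink, sources=sources,
            taxon_ids=[f"t{j}" for j in range(120)],
            source_ids=[f"s{i}" for i in range(6)],
        )
        init = pipeline_init(problem)
        grid = [1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2]
        best = grid_search(problem, grid, init)
        smallest = run_em(problem, grid[0], init)
        sup_best = set(np.nonzero(best.alpha.alpha[:-1] > 1e-8)[0])
        sup_small = set(np.nonzero(smallest.alpha.alpha[:-1] > 1e-8)[0])
        assert sup_best <= sup_small

    def test_invalid_grid_rejected(self, small_panel):
        problem = small_panel.problems[0]
        init = pipeline_init(problem)
        with pytest.raises(ValueError):
            grid_search(problem, [], init)
        with pytest.raises(ValueError):
            grid_search(problem, [1e-4, 1e-6], init)


class TestBaseline:
    def test_baseline_spreads_mass_over_nuisance(self, small_panel):
        problem = small_panel.problems[0]
        state = baseline_em(problem)
        assert state.alpha.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        # uniform start with lam=0 leaves every source strictly positive
        assert np.all(state.alpha.alpha > 0)
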
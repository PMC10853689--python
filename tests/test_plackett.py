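import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from tricotkit import (
    DesignSpec,
    EstimabilityError,
    Ranking,
    RankingSet,
    SimulationSpec,
    build_ranking_set,
    fit_plackett_luce,
    generate_design,
    pl_log_likelihood,
    simulate_tricot_responses,
    win_probability,
)


def strict_rs(universe, orders):
    rankings = tuple(
        Ranking(groups=tuple((o,) for o in order), package_id=k + 1, trait="t")
        for k, order in enumerate(orders)
    )
    return RankingSet(universe=universe, rankings=rankings)


def brute_force_log_worths(rankings, n_restarts=3):
    """Independent oracle: direct numerical maximization of the likelihood."""
    t = len(rankings.universe)

    def nll(theta):
        full = np.append(theta, -theta.sum())
        return -pl_log_likelihood(rankings, full)

    best = None
    for s in range(n_restarts):
        x0 = np.random.default_rng(s).normal(scale=0.1, size=t - 1)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    return np.append(theta, -theta.sum())


class TestLogLikelihood:
    def test_equal_worths_single_ranking(self):
        rs = strict_rs(("X", "Y", "Z"), [("X", "Y", "Z")])
        ll = pl_log_likelihood(rs, np.zeros(3))
        assert ll == pytest.approx(math.log(1 / 6), abs=1e-12)

    def test_hand_arithmetic(self):
        # worths 0.5, 0.3, 0.2 -> P(X>Y>Z) = (0.5/1.0) * (0.3/0.5) = 0.3
        rs = strict_rs(("X", "Y", "Z"), [("X", "Y", "Z")])
        lw = np.log([0.5, 0.3, 0.2])
        assert pl_log_likelihood(rs, lw) == pytest.approx(math.log(0.3), abs=1e-12)

    def test_empty_set_is_zero(self):
        rs = RankingSet(universe=("X", "Y"), rankings=())
        assert pl_log_likelihood(rs, np.zeros(2)) == 0.0

    def test_length_mismatch_rejected(self):
        rs = strict_rs(("X", "Y", "Z"), [("X", "Y", "Z")])
        with pytest.raises(ValueError, match="length"):
            pl_log_likelihood(rs, np.zeros(2))

    def test_best_only_is_first_choice_marginal(self):
        r = Ranking(groups=(("X",), ("Y", "Z")), package_id=1, trait="t")
        rs = RankingSet(universe=("X", "Y", "Z"), rankings=(r,))
        lw = np.log([0.5, 0.3, 0.2])
        assert pl_log_likelihood(rs, lw) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_worst_only_is_sum_of_extensions(self):
        r = Ranking(groups=(("X", "Y"), ("Z",)), package_id=1, trait="t")
        rs = RankingSet(universe=("X", "Y", "Z"), rankings=(r,))
        lw = np.log([0.5, 0.3, 0.2])
        ll_xyz = pl_log_likelihood(strict_rs(("X", "Y", "Z"), [("X", "Y", "Z")]), lw)
        ll_yxz = pl_log_likelihood(strict_rs(("X", "Y", "Z"), [("Y", "X", "Z")]), lw)
        expected = math.log(math.exp(ll_xyz) + math.exp(ll_yxz))
        assert pl_log_likelihood(rs, lw) == pytest.approx(expected, abs=1e-12)

    @given(
        lw=st.lists(
            st.floats(min_value=-2, max_value=2), min_size=3, max_size=3
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_probabilities_sum_to_one(self, lw):
        lw = np.array(lw) - np.mean(lw)
        total = 0.0
        for perm in itertools.permutations(("X", "Y", "Z")):
            rs = strict_rs(("X", "Y", "Z"), [perm])
            total += math.exp(pl_log_likelihood(rs, lw))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_two_item_closed_form(self):
        # X beats Y in 2 of 3 pairwise rankings -> worth ratio exactly 2
        rs = strict_rs(("X", "Y"), [("X", "Y"), ("X", "Y"), ("Y", "X")])
        fit = fit_plackett_luce(rs, regularization=0.0)
        assert fit.converged
        diff = fit.log_worth("X") - fit.log_worth("Y")
        assert diff == pytest.approx(math.log(2), abs=1e-6)

    def test_symmetric_data_gives_zero_worths(self):
        orders = list(itertools.permutations(("X", "Y", "Z")))
        rs = strict_rs(("X", "Y", "Z"), orders)
        fit = fit_plackett_luce(rs, regularization=0.0)
        np.testing.assert_allclose(fit.log_worths, 0.0, atol=1e-7)

    def test_always_last_option_is_inestimable(self):
        # an option that never wins has no finite MLE; the strict check
        # must reject rather than return a diverging estimate
        orders = [("X", "Y", "Z")] * 2 + [("Y", "X", "Z")]
        rs = strict_rs(("X", "Y", "Z"), orders)
        with pytest.raises(EstimabilityError):
            fit_plackett_luce(rs, regularization=0.0)

    def test_matches_brute_force_oracle(self):
        orders = [("X", "Y", "Z")] * 2 + [("Y", "X", "Z")] + [("Z", "X", "Y")]
        rs = strict_rs(("X", "Y", "Z"), orders)
        fit = fit_plackett_luce(rs, regularization=0.0)
        oracle = brute_force_log_worths(rs)
        np.testing.assert_allclose(fit.log_worths, oracle, atol=1e-4)

    def test_matches_brute_force_with_partials(self):
        rankings = (
            Ranking(groups=(("X",), ("Y",), ("Z",)), package_id=1, trait="t"),
            Ranking(groups=(("Y",), ("X", "Z")), package_id=2, trait="t"),
            Ranking(groups=(("X", "Y"), ("Z",)), package_id=3, trait="t"),
            Ranking(groups=(("Z",), ("Y",), ("X",)), package_id=4, trait="t"),
            Ranking(groups=(("Y",), ("Z",), ("X",)), package_id=5, trait="t"),
            Ranking(groups=(("X",), ("Z",), ("Y",)), package_id=6, trait="t"),
        )
        rs = RankingSet(universe=("X", "Y", "Z"), rankings=rankings)
        fit = fit_plackett_luce(rs, regularization=0.0)
        oracle = brute_force_log_worths(rs)
        np.testing.assert_allclose(fit.log_worths, oracle, atol=1e-4)
        assert fit.loglik == pytest.approx(
            pl_log_likelihood(rs, oracle), abs=1e-6
        )

    def test_mm_iterations_monotone(self):
        rng = np.random.default_rng(0)
        orders = [
            tuple(rng.permutation(("X", "Y", "Z", "W")))
            for _ in range(30)
        ]
        rs = strict_rs(("X", "Y", "Z", "W"), orders)
        fit = fit_plackett_luce(rs, regularization=0.0, track_loglik_path=True)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_estimability_error_names_components(self):
        rs = strict_rs(("X", "Y", "Z"), [("X", "Y"), ("X", "Z")])
        with pytest.raises(EstimabilityError, match="X"):
            fit_plackett_luce(rs, regularization=0.0)

    def test_regularization_rescues_disconnected_data(self):
        rs = strict_rs(("X", "Y", "Z"), [("X", "Y"), ("X", "Z")])
        with pytest.warns(UserWarning, match="standard errors"):
            fit = fit_plackett_luce(rs, regularization=0.5)
        assert fit.converged
        assert np.all(np.isfinite(fit.log_worths))
        assert fit.stderr is None
        assert fit.log_worth("X") > fit.log_worth("Y")

    def test_label_permutation_invariance(self):
        orders = [("A", "B", "C")] * 3 + [("B", "C", "A")] * 2 + [("C", "A", "B")]
        rs1 = strict_rs(("A", "B", "C"), orders)
        swapped = [
            tuple({"A": "B", "B": "A", "C": "C"}[o] for o in order)
            for order in orders
        ]
        rs2 = strict_rs(("A", "B", "C"), swapped)
        f1 = fit_plackett_luce(rs1, regularization=0.0)
        f2 = fit_plackett_luce(rs2, regularization=0.0)
        assert f1.log_worth("A") == pytest.approx(f2.log_worth("B"), abs=1e-8)
        assert f1.log_worth("B") == pytest.approx(f2.log_worth("A"), abs=1e-8)

    def test_stderr_reported_when_unregularized(self):
        rng = np.random.default_rng(1)
        orders = [tuple(rng.permutation(("X", "Y", "Z"))) for _ in range(50)]
        rs = strict_rs(("X", "Y", "Z"), orders)
        fit = fit_plackett_luce(rs, regularization=0.0)
        assert fit.stderr is not None
        assert fit.stderr.shape == (3,)
        assert np.all(fit.stderr > 0)

    def test_empty_rankings_rejected(self):
        rs = RankingSet(universe=("X", "Y"), rankings=())
        with pytest.raises(ValueError, match="zero rankings"):
            fit_plackett_luce(rs)

    def test_loglik_nonpositive(self):
        rs = strict_rs(("X", "Y"), [("X", "Y"), ("Y", "X")])
        fit = fit_plackett_luce(rs, regularization=0.0)
        assert fit.loglik <= 0


class TestWinProbability:
    @staticmethod
    def _fit(lw):
        from tricotkit import PLFit

        return PLFit(
            universe=("X", "Y"),
            log_worths=np.asarray(lw, dtype=float),
            loglik=0.0,
            n_rankings=1,
            converged=True,
            iterations=1,
        )

    def test_worth_ratio_two_to_one(self):
        fit = self._fit([math.log(2), math.log(1)])
        assert win_probability(fit, "X", "Y") == pytest.approx(2 / 3)

    def test_equal_worths(self):
        fit = self._fit([0.0, 0.0])
        assert win_probability(fit, "X", "Y") == pytest.approx(0.5)

    def test_complement(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            lw = rng.normal(size=2)
            fit = self._fit(lw - lw.mean())
            total = win_probability(fit, "X", "Y") + win_probability(fit, "Y", "X")
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_unknown_option_rejected(self):
        fit = self._fit([0.0, 0.0])
        with pytest.raises(KeyError):
            win_probability(fit, "X", "Q")
        with pytest.raises(ValueError):
            win_probability(fit, "X", "X")


class TestSimulate:
    def _design(self, t, n, seed=0):
        return generate_design(
            DesignSpec(t, n, tuple(f"o{i}" for i in range(t)), seed=seed)
        )

    def test_degenerate_worths_force_order(self):
        design = self._design(3, 10)
        spec = SimulationSpec(
            design=design, log_worths=np.array([10.0, 0.0, -10.0]), seed=4
        )
        responses = simulate_tricot_responses(spec)
        for r in responses:
            pkg = design.package(r.package_id)
            assert pkg.option_at(r.best) == "o0"
            assert pkg.option_at(r.worst) == "o2"

    def test_equal_worths_uniform_orders(self):
        design = self._design(3, 6000)
        spec = SimulationSpec(design=design, log_worths=np.zeros(3), seed=8)
        responses = simulate_tricot_responses(spec)
        counts = {}
        for r in responses:
            counts[(r.best, r.worst)] = counts.get((r.best, r.worst), 0) + 1
        # each of the 6 orders: expected 1000, sd = sqrt(n p (1-p)) ~ 28.9
        se = math.sqrt(6000 * (1 / 6) * (5 / 6))
        for count in counts.values():
            assert abs(count - 1000) <= 3 * se

    def test_same_seed_identical(self):
        design = self._design(5, 40)
        spec = SimulationSpec(
            design=design, log_worths=np.linspace(0, 1, 5), seed=12,
            response_rate=0.8,
        )
        assert simulate_tricot_responses(spec) == simulate_tricot_responses(spec)

    def test_response_rate_respected(self):
        design = self._design(4, 2000)
        spec = SimulationSpec(
            design=design, log_worths=np.zeros(4), seed=2, response_rate=0.7
        )
        responses = simulate_tricot_responses(spec)
        n_answered = sum(1 for r in responses if r.best is not None)
        assert abs(n_answered - 1400) <= 3 * math.sqrt(2000 * 0.7 * 0.3)

    def test_recovery_round_trip(self):
        design = self._design(4, 400)
        true = np.array([0.6, 0.2, -0.2, -0.6])
        spec = SimulationSpec(design=design, log_worths=true, seed=5)
        responses = simulate_tricot_responses(spec)
        rs = build_ranking_set(responses, design, "overall")
        fit = fit_plackett_luce(rs, regularization=0.0, compute_stderr=False)
        np.testing.assert_allclose(fit.log_worths, true, atol=0.25)
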
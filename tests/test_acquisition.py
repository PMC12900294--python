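import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from eeldiet.acquisition import (
    AcquisitionConfig,
    AcquisitionError,
    _dedupe_topk,
    combined_log_pi,
    generate_candidates,
    probability_of_improvement,
    representative_formulation,
    sample_bounded_simplex,
)
from eeldiet.formulations import IngredientBounds, FREE_INGREDIENTS, SimplexPoint
from eeldiet.trials import PERIOD_EARLY


class TestProbabilityOfImprovement:
    def test_mean_at_threshold_gives_exactly_half(self):
        assert probability_of_improvement(1.001, 2.3, 1.0, 0.001) == 0.5

    def test_degenerate_sd_is_an_indicator(self):
        assert probability_of_improvement(1.0, 0.0, 0.5, 0.0) == 1.0
        assert probability_of_improvement(0.4, 0.0, 0.5, 0.0) == 0.0

    def test_normal_cdf_oracle(self):
        got = probability_of_improvement(1.0, 1.0, 0.0, 1e-3)
        assert got == pytest.approx(norm.cdf(0.999), abs=1e-12)
        assert got == pytest.approx(0.84114, abs=1e-4)

    @given(
        mu=st.floats(-3, 3),
        sd=st.floats(0.01, 10),
        f_best=st.floats(-3, 3),
        xi=st.floats(0, 1e-3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_mu_and_xi(self, mu, sd, f_best, xi):
        base = probability_of_improvement(mu, sd, f_best, xi)
        assert probability_of_improvement(mu + 0.1, sd, f_best, xi) >= base
        assert probability_of_improvement(mu, sd, f_best, xi + 0.1) <= base

    def test_large_sd_limits_to_half(self):
        assert probability_of_improvement(0.0, 1e12, 5.0, 1e-3) == pytest.approx(
            0.5, abs=1e-9
        )


class TestCombinedLogPI:
    def test_both_certain_scores_zero(self):
        assert combined_log_pi(1.0, 1.0) == 0.0

    def test_equal_half_probabilities(self):
        assert combined_log_pi(0.5, 0.5) == pytest.approx(2 * np.log(0.5))

    def test_zero_pi_floored_finite(self):
        assert np.isfinite(combined_log_pi(0.0, 0.5))

    @given(
        pi_s=st.floats(1e-6, 1.0),
        pi_t=st.floats(1e-6, 1.0),
        bump=st.floats(1e-6, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_pi(self, pi_s, pi_t, bump):
        base = combined_log_pi(pi_s, pi_t)
        assert combined_log_pi(min(pi_s + bump, 1.0), pi_t) >= base
        assert combined_log_pi(pi_s, min(pi_t + bump, 1.0)) >= base


class TestSampling:
    def test_unbounded_samples_on_simplex(self):
        rng = np.random.default_rng(0)
        pts = sample_bounded_simplex(None, 500, rng)
        assert pts.shape == (500, 7)
        assert np.allclose(pts.sum(axis=1), 1.0)
        assert (pts >= 0).all()

    def test_bounded_samples_respect_bounds(self, bounds):
        rng = np.random.default_rng(1)
        pts = sample_bounded_simplex(bounds, 300, rng)
        lo, hi = bounds.normalized()
        assert (pts >= lo - 1e-9).all()
        assert (pts <= hi + 1e-9).all()
        assert np.allclose(pts.sum(axis=1), 1.0)

    def test_tight_bounds_fall_back_to_hit_and_run(self):
        # a narrow box around the centroid: rejection yield is ~0
        center = 1 / 7
        tight = IngredientBounds(
            lower={k: (center - 0.01) * 95.6 for k in FREE_INGREDIENTS},
            upper={k: (center + 0.01) * 95.6 for k in FREE_INGREDIENTS},
        )
        rng = np.random.default_rng(2)
        pts = sample_bounded_simplex(tight, 50, rng)
        lo, hi = tight.normalized()
        assert pts.shape == (50, 7)
        assert (pts >= lo - 1e-6).all() and (pts <= hi + 1e-6).all()
        assert np.allclose(pts.sum(axis=1), 1.0, atol=1e-9)

    def test_infeasible_bounds_rejected_at_construction(self):
        from eeldiet.formulations import FormulationError

        with pytest.raises(FormulationError, match="infeasible"):
            IngredientBounds(
                lower={k: 0.0 for k in FREE_INGREDIENTS},
                upper={k: 10.0 for k in FREE_INGREDIENTS},
            )


class TestGenerateCandidates:
    def test_exactly_n_select_under_defaults(self, fitted_surrogates):
        result, _ = fitted_surrogates
        assert len(result.periods[PERIOD_EARLY].candidates) == 100

    def test_candidates_on_simplex_and_in_bounds(self, fitted_surrogates, bounds):
        result, _ = fitted_surrogates
        lo, hi = bounds.normalized()
        for c in result.periods[PERIOD_EARLY].candidates:
            p = c.point.proportions
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p >= lo - 2e-3).all() and (p <= hi + 2e-3).all()

    def test_ranked_descending_and_score_consistent(self, fitted_surrogates):
        result, _ = fitted_surrogates
        cands = result.periods[PERIOD_EARLY].candidates
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)
        for c in cands[:10]:
            assert c.score == pytest.approx(
                combined_log_pi(c.pi_survival, c.pi_tl), abs=1e-12
            )

    def test_top_candidates_match_brute_force_pool_rescoring(
        self, fitted_surrogates, bounds
    ):
        """Regenerating the seeded pool and rescoring it from scratch yields
        the same deduplicated top-10."""
        result, cfg = fitted_surrogates
        pr = result.periods[PERIOD_EARLY]
        acq = cfg.acquisition
        import zlib

        seed = acq.seed + zlib.crc32(PERIOD_EARLY.encode()) % 1000
        rng = np.random.default_rng(seed)
        pool = sample_bounded_simplex(bounds, acq.pool_size, rng)
        mu_s, sd_s = pr.surrogate_survival.predict(pool)
        mu_t, sd_t = pr.surrogate_tl.predict(pool)
        f_s = float(pr.surrogate_survival.model.y.max())
        f_t = float(pr.surrogate_tl.model.y.max())
        pi_s = probability_of_improvement(mu_s, sd_s, f_s, acq.xi)
        pi_t = probability_of_improvement(mu_t, sd_t, f_t, acq.xi)
        scores = acq.weights[0] * np.log(np.maximum(pi_s, 1e-300)) + (
            acq.weights[1] * np.log(np.maximum(pi_t, 1e-300))
        )
        keep = _dedupe_topk(pool, scores, 10, acq.dedupe_l1)
        for c, i in zip(pr.candidates[:10], keep):
            assert np.allclose(c.point.proportions, pool[i] / pool[i].sum())
            assert c.score == pytest.approx(float(scores[i]), abs=1e-9)

    def test_deterministic_given_seed(self, fitted_surrogates, bounds):
        result, _ = fitted_surrogates
        pr = result.periods[PERIOD_EARLY]
        cfg = AcquisitionConfig(pool_size=5000, n_select=20, seed=42)
        a = generate_candidates(pr.surrogate_survival, pr.surrogate_tl, bounds, cfg)
        b = generate_candidates(pr.surrogate_survival, pr.surrogate_tl, bounds, cfg)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.point.proportions, cb.point.proportions)
            assert ca.score == cb.score

    def test_smaller_xi_never_decreases_pi(self, fitted_surrogates, bounds):
        """Exploitation (smaller xi) raises or preserves every candidate's PI."""
        result, _ = fitted_surrogates
        pr = result.periods[PERIOD_EARLY]
        rng = np.random.default_rng(7)
        pool = sample_bounded_simplex(bounds, 200, rng)
        mu, sd = pr.surrogate_survival.predict(pool)
        f_best = float(pr.surrogate_survival.model.y.max())
        pi_explore = probability_of_improvement(mu, sd, f_best, 1e-3)
        pi_exploit = probability_of_improvement(mu, sd, f_best, 1e-6)
        assert (pi_exploit >= pi_explore).all()


class TestRepresentative:
    def test_identical_candidates_return_that_point(self):
        p = SimplexPoint(np.full(7, 1 / 7))
        from eeldiet.acquisition import Candidate

        cands = [Candidate(p, 0.5, 0.5, -1.0)] * 3
        rep = representative_formulation(cands)
        assert np.allclose(rep.proportions, p.proportions)

    def test_two_points_give_renormalized_midpoint(self):
        from eeldiet.acquisition import Candidate

        a = np.array([0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        b = np.array([0.1, 0.4, 0.1, 0.1, 0.1, 0.1, 0.1])
        cands = [Candidate(SimplexPoint(a), 0.5, 0.5, -1.0),
                 Candidate(SimplexPoint(b), 0.5, 0.5, -1.0)]
        rep = representative_formulation(cands)
        mid = (a + b) / 2
        assert np.allclose(rep.proportions, mid / mid.sum())

    def test_mean_lies_in_convex_hull_coordinate_wise(self):
        from eeldiet.acquisition import Candidate

        rng = np.random.default_rng(3)
        pts = rng.dirichlet(np.ones(7), size=25)
        cands = [Candidate(SimplexPoint(p), 0.5, 0.5, -1.0) for p in pts]
        rep = representative_formulation(cands)
        assert (rep.proportions >= pts.min(axis=0) - 1e-12).all()
        assert (rep.proportions <= pts.max(axis=0) + 1e-12).all()

    def test_empty_list_rejected(self):
        with pytest.raises(AcquisitionError, match="empty"):
            representative_formulation([])
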
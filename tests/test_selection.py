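import math
import warnings
from collections import Counter

import numpy as np
import pytest

import conncrit as cc
from conncrit.errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ValidationError,
)

from conftest import POWERLAW_REF, RESTRICTED_REF, TRUNCATED_REF


class TestPrepareFitData:
    def test_too_few_positive_values(self):
        with pytest.raises(InsufficientDataError):
            cc.prepare_fit_data(np.array([0.0, 0.0, 3.0, 1.0]))

    def test_all_positive_unchanged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.array_equal(cc.prepare_fit_data(x), x)

    def test_zero_filtering_count(self, rng):
        x = rng.uniform(1, 5, size=100)
        x[rng.choice(100, 12, replace=False)] = 0.0
        assert cc.prepare_fit_data(x).size == 88

    def test_accepts_node_stat_vector(self):
        stats = cc.NodeStatVector(
            values=np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]),
            stat_kind="strength",
            threshold=0.3,
        )
        assert cc.prepare_fit_data(stats).size == 5


class TestAicc:
    def test_arithmetic(self):
        assert cc.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
        assert cc.aicc(-10.0, 1, 1000) == pytest.approx(22 + 4 / 998)

    def test_correction_vanishes_large_n(self):
        # the finite-sample correction tends to zero as N grows
        corr = cc.aicc(0.0, 2, 10**7) - 4.0
        assert corr == pytest.approx(0.0, abs=1e-5)

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            cc.aicc(0.0, 2, 3)

    def test_monotonicity(self):
        assert cc.aicc(-5.0, 1, 100) > cc.aicc(-4.0, 1, 100)
        assert cc.aicc(-5.0, 2, 100) > cc.aicc(-5.0, 1, 100)


class TestFitPowerlaw:
    def test_closed_form_small_sample(self):
        # alpha = 1 + N / sum(log(x_i / x_min))
        fit = cc.fit_powerlaw(np.array([1.0, 2.0, 4.0, 1.0, 2.0]))
        n, total = 5, 4 * math.log(2)
        assert fit.params.alpha == pytest.approx(1 + n / total)
        assert fit.K == 1 and fit.N == 5

    def test_recovery_at_n5000(self):
        draws = cc.sample("powerlaw", POWERLAW_REF, 5000, seed=2)
        fit = cc.fit_powerlaw(draws)
        assert fit.params.alpha == pytest.approx(2.5, abs=0.06)

    def test_all_equal_rejected(self):
        with pytest.raises(DegenerateSampleError):
            cc.fit_powerlaw(np.full(10, 2.0))

    def test_matches_grid_maximization(self, rng):
        sample = cc.sample("powerlaw", POWERLAW_REF, 60, seed=5)
        fit = cc.fit_powerlaw(sample)
        grid = np.linspace(1.2, 5.0, 3801)
        x_min = sample.min()
        ll = [
            np.sum(cc.PowerLaw(alpha=a, x_min=x_min).logpdf(sample)) for a in grid
        ]
        assert fit.params.alpha == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)


class TestFitTruncated:
    def test_recovery_at_n5000(self):
        draws = cc.sample("truncated", TRUNCATED_REF, 5000, seed=3)
        fit = cc.fit_truncated(draws)
        assert fit.params.alpha == pytest.approx(2.17, abs=0.15)
        assert fit.params.x_c == pytest.approx(5.67, rel=0.15)
        assert fit.K == 2

    def test_optimum_beats_random_feasible_points(self, rng):
        sample = cc.sample("truncated", TRUNCATED_REF, 400, seed=4)
        fit = cc.fit_truncated(sample)
        x_min = float(sample.min())
        for _ in range(100):
            alpha = rng.uniform(-2.0, 6.0)
            x_c = rng.uniform(0.2, 50.0)
            rival = cc.TruncatedPowerLaw(alpha=alpha, x_c=x_c, x_min=x_min)
            assert fit.log_likelihood >= np.sum(rival.logpdf(sample)) - 1e-6

    def test_powerlaw_limit_pushes_cutoff_out(self):
        # data without a cutoff: the fitted truncation scale exceeds the data range
        draws = cc.sample("powerlaw", POWERLAW_REF, 2000, seed=6)
        fit = cc.fit_truncated(draws)
        assert fit.params.x_c > draws.max()


class TestFitRestricted:
    def test_recovery_at_n5000(self):
        draws = cc.sample("restricted", RESTRICTED_REF, 5000, seed=7)
        fit = cc.fit_restricted(draws)
        assert fit.params.gamma == pytest.approx(2.22, abs=0.15)
        assert fit.params.x_max == pytest.approx(33.5, rel=0.05)
        assert fit.params.x_max > draws.max()

    def test_uniform_data_gives_gamma_near_zero(self):
        draws = cc.sample(
            "restricted", dict(gamma=0.0, x_min=1.0, x_max=5.0), 5000, seed=8
        )
        fit = cc.fit_restricted(draws)
        assert abs(fit.params.gamma) < 0.1

    def test_optimum_beats_random_feasible_points(self, rng):
        sample = cc.sample("restricted", RESTRICTED_REF, 400, seed=9)
        fit = cc.fit_restricted(sample)
        x_min, x_hi = float(sample.min()), float(sample.max())
        for _ in range(100):
            gamma = rng.uniform(-0.9, 6.0)
            x_max = x_hi * rng.uniform(1.0 + 1e-5, 50.0)
            rival = cc.RestrictedPowerLaw(gamma=gamma, x_min=x_min, x_max=x_max)
            assert fit.log_likelihood >= np.sum(rival.logpdf(sample)) - 1e-6

    def test_all_equal_rejected(self):
        with pytest.raises(DegenerateSampleError):
            cc.fit_restricted(np.full(10, 3.0))


class TestCompareModels:
    def test_delta_minimum_is_zero(self):
        sample = cc.sample("restricted", RESTRICTED_REF, 200, seed=10)
        res = cc.compare_models(sample)
        assert min(res.delta_aic.values()) == 0.0
        assert res.delta_aic[res.best_model] == 0.0
        assert set(res.fits) == {"restricted", "truncated", "powerlaw"}

    @pytest.mark.parametrize(
        "model_id,params",
        [
            ("restricted", RESTRICTED_REF),
            ("truncated", TRUNCATED_REF),
            ("powerlaw", POWERLAW_REF),
        ],
    )
    def test_generator_recovery_plurality(self, model_id, params):
        # quick selection-consistency check (the full 200-replicate version
        # runs in the acceptance suite)
        wins = Counter()
        rng = np.random.default_rng(123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(30):
                res = cc.compare_models(
                    cc.make_model(model_id, params).sample(150, rng)
                )
                wins[res.best_model] += 1
        top = wins.most_common(1)[0][0]
        assert top == model_id

    def test_likelihood_dominance_of_generator(self):
        """The generating model's maximised log-likelihood beats non-nested
        rivals in at least 90% of replicates.  The power law is nested inside
        the truncated family (x_c -> inf), so its raw likelihood can never
        strictly dominate the richer model; there the AICc penalty must
        recover the generator in a clear majority instead."""
        specs = {
            "restricted": RESTRICTED_REF,
            "truncated": TRUNCATED_REF,
            "powerlaw": POWERLAW_REF,
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for model_id, params in specs.items():
                rng = np.random.default_rng(77)
                dominated = 0
                aicc_wins_vs_nesting = 0
                for _ in range(20):
                    res = cc.compare_models(
                        cc.make_model(model_id, params).sample(1000, rng)
                    )
                    own = res.fits[model_id]
                    ok = True
                    for rival_id, rival in res.fits.items():
                        if rival_id == model_id:
                            continue
                        if model_id == "powerlaw" and rival_id == "truncated":
                            aicc_wins_vs_nesting += own.aicc < rival.aicc
                            continue
                        ok &= own.log_likelihood >= rival.log_likelihood
                    dominated += ok
                assert dominated >= 18, model_id
                if model_id == "powerlaw":
                    assert aicc_wins_vs_nesting >= 14

    def test_all_fits_failing_raises(self):
        # an all-equal sample is degenerate for every candidate
        with pytest.raises(cc.FitConvergenceError):
            cc.compare_models(np.full(10, 1.0))


class TestSummarizeSelection:
    def _mk_result(self, best):
        sample = cc.sample("restricted", RESTRICTED_REF, 100, seed=1)
        res = cc.compare_models(sample)
        res.best_model = best
        return res

    def test_unanimous_selection(self):
        results = [self._mk_result("truncated") for _ in range(4)]
        s = cc.summarize_selection(results, 0.3)
        assert s.selection_ratio["truncated"] == 1.0
        assert s.selection_ratio["powerlaw"] == 0.0

    def test_count_arithmetic(self):
        results = (
            [self._mk_result("powerlaw")] * 858
            + [self._mk_result("truncated")] * 100
            + [self._mk_result("restricted")] * 28
        )
        s = cc.summarize_selection(results, 0.7)
        assert s.selection_ratio["powerlaw"] == pytest.approx(858 / 986)
        assert s.selection_ratio["truncated"] == pytest.approx(100 / 986)
        assert s.selection_ratio["restricted"] == pytest.approx(28 / 986)
        assert sum(s.selection_ratio.values()) == pytest.approx(1.0)
        assert min(s.mean_delta_aic.values()) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cc.summarize_selection([], 0.3)
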
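"""Single-patch Monte-Carlo fitness and R* inference."""

import numpy as np
import pytest

from phagepatch.analytic import (
    PatchRates,
    fitness_generalist,
    fitness_specialist,
    r_star,
)
from phagepatch.single_patch import (
    InferenceFailureError,
    SinglePatchConfig,
    bootstrap_r_star,
    estimate_fitness,
    infer_r_star,
    sample_fate,
    simulate_trials,
)

REF_RATES = dict(theta=0.35, p=0.5, alpha=0.1, lam=0.01, F_A=50.0)


def _config(n_trials=100_000, seed=11, **kw):
    rates = PatchRates(**{**REF_RATES, "F_B": 10.0, **kw.pop("rates", {})})
    return SinglePatchConfig(rates=rates, n_trials=n_trials, seed=seed, **kw)


class TestSampleFate:
    def test_certain_exit(self):
        cfg = SinglePatchConfig(
            rates=PatchRates(theta=0.0, p=0.5, alpha=1.0, lam=0.0, F_A=50),
            n_trials=10,
        )
        rng = np.random.default_rng(0)
        assert all(
            sample_fate(cfg, s, rng) == 1.0
            for s in ("generalist", "specialist")
            for _ in range(20)
        )

    def test_certain_decay(self):
        cfg = SinglePatchConfig(
            rates=PatchRates(theta=0.0, p=0.5, alpha=0.0, lam=1.0, F_A=50),
            n_trials=10,
        )
        rng = np.random.default_rng(0)
        assert all(sample_fate(cfg, "generalist", rng) == 0.0 for _ in range(20))

    def test_burst_inside_one_step_recursion(self):
        # certain infection of A, certain in-patch burst: the progeny each
        # certainly infect A and are valued at its burst size
        cfg = SinglePatchConfig(
            rates=PatchRates(theta=0.2, p=1.0, alpha=0.0, lam=0.0, F_A=50),
            omega=1.0,
            n_trials=10,
        )
        rng = np.random.default_rng(0)
        assert sample_fate(cfg, "generalist", rng) == pytest.approx(50.0 * 50.0)

    def test_outcome_support(self):
        """Every trial value is 0, 1, a burst size, or a burst-inside value."""
        cfg = _config(n_trials=100, omega=0.5)
        r = cfg.rates
        wg = fitness_generalist(r)
        ws = fitness_specialist(r)
        allowed_g = {0.0, 1.0, r.F_A, r.F_B, r.F_A * wg, r.F_B * wg}
        allowed_s = {0.0, 1.0, r.F_A, r.F_A * ws}
        rng = np.random.default_rng(3)
        for _ in range(300):
            g = sample_fate(cfg, "generalist", rng)
            s = sample_fate(cfg, "specialist", rng)
            assert any(g == pytest.approx(v) for v in allowed_g)
            assert any(s == pytest.approx(v) for v in allowed_s)


class TestEstimateFitness:
    @pytest.mark.parametrize("strategy,oracle", [
        ("generalist", fitness_generalist),
        ("specialist", fitness_specialist),
    ])
    def test_matches_closed_form_at_omega_zero(self, strategy, oracle):
        cfg = _config()
        est = estimate_fitness(cfg, strategy)
        assert abs(est.mean - oracle(cfg.rates)) < 4 * est.se
        assert est.n == cfg.n_trials

    def test_no_contact_binomial_case(self):
        rates = PatchRates(theta=0.0, p=0.5, alpha=0.1, lam=0.01, F_A=50)
        cfg = SinglePatchConfig(rates=rates, n_trials=50_000, seed=5)
        est = estimate_fitness(cfg, "generalist")
        assert abs(est.mean - 0.1 / 0.11) < 4 * est.se

    def test_unbiased_across_random_parameters(self):
        """Monte-Carlo mean tracks the closed forms over a parameter sweep."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            rates = PatchRates(
                theta=rng.uniform(0.05, 0.8),
                p=rng.uniform(0.1, 0.9),
                alpha=rng.uniform(0.01, 0.4),
                lam=rng.uniform(0.0, 0.1),
                F_A=rng.uniform(5, 80),
                F_B=rng.uniform(0, 40),
            )
            cfg = SinglePatchConfig(rates=rates, n_trials=30_000,
                                    seed=int(rng.integers(2**31)))
            for strategy, oracle in [
                ("generalist", fitness_generalist),
                ("specialist", fitness_specialist),
            ]:
                est = estimate_fitness(cfg, strategy)
                assert abs(est.mean - oracle(rates)) < 4.5 * est.se

    def test_trials_reproducible_under_seed(self):
        cfg = _config(n_trials=1000)
        a = simulate_trials(cfg, "generalist", np.random.default_rng(7))
        b = simulate_trials(cfg, "generalist", np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestInferRStar:
    def test_recovers_analytic_value(self):
        cfg = _config(seed=23)
        est = infer_r_star(cfg, np.linspace(0, 55, 12), n_boot=500)
        target = r_star(cfg.rates, "approximate")
        assert est.ci_low <= target <= est.ci_high
        assert est.point == pytest.approx(target, abs=0.02)

    def test_f_a_invariance_of_point_estimate(self):
        grid = np.linspace(0, 11, 10)
        small = infer_r_star(
            _config(seed=29, rates={"F_A": 10.0}), grid, n_boot=300
        )
        grid50 = np.linspace(0, 55, 10)
        big = infer_r_star(_config(seed=29), grid50, n_boot=300)
        assert small.point == pytest.approx(big.point, abs=0.03)

    def test_grid_extension_when_crossing_above_grid(self):
        cfg = _config(seed=31)
        # crossing is near F_B = 31; a grid topping out at 20 has no sign
        # change and triggers one automatic upward extension
        est = infer_r_star(cfg, np.linspace(0, 20, 6), n_boot=200)
        target = r_star(cfg.rates, "approximate")
        assert est.point == pytest.approx(target, abs=0.05)

    def test_small_patches_bias_r_star_downward(self):
        """Binomial host-composition noise lowers inferred R* (Jensen)."""
        grid = np.linspace(0, 55, 10)
        tiny = infer_r_star(_config(seed=37, n_eff=4), grid, n_boot=300)
        large = infer_r_star(_config(seed=41, n_eff=1000), grid, n_boot=300)
        assert tiny.point < large.point
        assert tiny.ci_high < large.ci_low


class TestBootstrap:
    @staticmethod
    def _tables_from_values(per_point_values):
        tables = []
        for vals in per_point_values:
            v, c = np.unique(np.asarray(vals, float), return_counts=True)
            tables.append((v, c))
        return tables

    def test_zero_noise_degenerate_interval(self):
        fb = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        gen = self._tables_from_values([[0.5 * f + 2.0] * 50 for f in fb])
        spec = self._tables_from_values([[12.0] * 50 for _ in fb])
        rng = np.random.default_rng(0)
        draws, swap = bootstrap_r_star(fb, gen, spec, 49.0, 200, rng)
        true = ((12.0 - 2.0) / 0.5 - 1.0) / 49.0
        assert np.ptp(draws) < 1e-9
        assert draws[0] == pytest.approx(true)
        assert swap == 0.0

    def test_coverage_with_noise(self):
        """The 95% interval covers the true crossing in most repetitions."""
        fb = np.linspace(0, 40, 6)
        true_cross = 24.0
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            gen = self._tables_from_values(
                [0.5 * (f - true_cross) + 12.0
                 + rng.normal(0, 0.6, size=200) for f in fb]
            )
            spec = self._tables_from_values(
                [12.0 + rng.normal(0, 0.6, size=200) for _ in fb]
            )
            draws, _ = bootstrap_r_star(fb, gen, spec, 49.0, 200, rng)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            true_r = (true_cross - 1.0) / 49.0
            hits += lo <= true_r <= hi
        assert hits >= 0.9 * n_rep

    def test_parallel_lines_raise(self):
        fb = np.linspace(0, 40, 5)
        rng = np.random.default_rng(1)
        # flat generalist data: slope estimate is non-positive in ~half of
        # resamples, far beyond the 1% swapping allowance
        gen = self._tables_from_values(
            [10.0 + rng.normal(0, 0.1, size=100) for _ in fb]
        )
        spec = self._tables_from_values(
            [12.0 + rng.normal(0, 0.1, size=100) for _ in fb]
        )
        with pytest.raises(InferenceFailureError):
            bootstrap_r_star(fb, gen, spec, 49.0, 200, rng)
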
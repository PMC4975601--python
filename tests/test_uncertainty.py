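"""Triangular sampling, Monte Carlo evaluation and convergence diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocogs import fixtures
from biocogs.errors import ConfigurationError
from biocogs.uncertainty import (
    MCConfig,
    TriangularDist,
    moving_average_convergence,
    parameter_spans,
    run_monte_carlo,
    sample_triangular,
    summarize,
)


class TestTriangularSampler:
    def test_support_endpoints_and_mode(self):
        d = TriangularDist(12.8, 25.6, 51.2)
        assert sample_triangular(d, 0.0) == pytest.approx(12.8)
        assert sample_triangular(d, 1.0) == pytest.approx(51.2)
        f_mode = (d.mode - d.min) / (d.max - d.min)
        assert sample_triangular(d, f_mode) == pytest.approx(25.6)

    def test_u_outside_unit_interval_rejected(self):
        d = TriangularDist(0.0, 1.0, 2.0)
        with pytest.raises(ConfigurationError):
            sample_triangular(d, -0.1)
        with pytest.raises(ConfigurationError):
            sample_triangular(d, 1.1)

    def test_unordered_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            TriangularDist(1.0, 0.5, 2.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_nondecreasing_in_u(self, u1, u2):
        d = TriangularDist(-25.0, 0.0, 25.0)
        lo, hi = sorted((u1, u2))
        assert sample_triangular(d, lo) <= sample_triangular(d, hi)

    def test_moments_match_closed_forms(self):
        """Empirical mean and variance at n=1e5 agree with (a+b+c)/3 and
        (a^2+b^2+c^2-ab-ac-bc)/18 within three standard errors."""
        d = TriangularDist(12.8, 25.6, 51.2)
        rng = np.random.default_rng(42)
        n = 100_000
        x = np.array([d.ppf(u) for u in rng.random(n)])
        assert d.mean == pytest.approx((12.8 + 25.6 + 51.2) / 3)
        se_mean = np.sqrt(d.variance / n)
        assert abs(x.mean() - d.mean) < 3 * se_mean
        m4 = np.mean((x - x.mean()) ** 4)
        se_var = np.sqrt((m4 - d.variance**2) / n)
        assert abs(x.var(ddof=1) - d.variance) < 3 * se_var

    def test_matches_scipy_inverse_cdf(self):
        from scipy.stats import triang

        a, c, b = 0.108, 0.242, 0.376
        d = TriangularDist(a, c, b)
        ref = triang(c=(c - a) / (b - a), loc=a, scale=b - a)
        u = np.linspace(0.0, 1.0, 101)
        ours = np.array([d.ppf(v) for v in u])
        assert np.allclose(ours, ref.ppf(u), atol=1e-12)


class TestMovingAverageConvergence:
    def test_constant_series_converges_at_window(self):
        assert moving_average_convergence([5.0] * 200, window=50, tolerance=0.01) == 50

    def test_alternating_series_never_converges(self):
        series = [1.0, 1000.0] * 100
        assert moving_average_convergence(series, window=10, tolerance=1e-6) is None

    def test_short_series_rejected(self):
        with pytest.raises(ConfigurationError):
            moving_average_convergence([1.0, 2.0], window=10, tolerance=0.01)

    def test_before_fixture_converges_within_300_runs(self, mc_before):
        assert mc_before.runs_to_convergence is not None
        assert mc_before.runs_to_convergence <= 300


class TestRunMonteCarlo:
    def test_degenerate_distributions_reproduce_base_cog(self, model, base):
        cfg = MCConfig(
            distributions={
                "titer": TriangularDist(base.titer, base.titer, base.titer),
                "target_output": TriangularDist(base.target_output, base.target_output,
                                                base.target_output),
            },
            max_runs=20, ma_window=5, ma_tolerance=0.01, seed=7,
        )
        result = run_monte_carlo(cfg, model, base)
        expected = model.cog(base)
        assert np.allclose(result.samples["cog_per_g"], expected)
        assert result.runs_to_convergence == 5

    def test_same_seed_reproduces_identical_result(self, model, base):
        cfg = fixtures.mc_config_before(seed=11, max_runs=60)
        r1 = run_monte_carlo(cfg, model, base)
        r2 = run_monte_carlo(cfg, model, base)
        assert r1.samples.equals(r2.samples)
        assert r1.summary == r2.summary
        assert r1.runs_to_convergence == r2.runs_to_convergence

    def test_samples_stay_inside_supports(self, mc_before):
        cfg = fixtures.mc_config_before()
        for name, dist in cfg.distributions.items():
            col = mc_before.samples[name]
            assert col.min() >= dist.min and col.max() <= dist.max

    def test_summary_matches_brute_force_recomputation(self, mc_before):
        cog = mc_before.samples["cog_per_g"].to_numpy()
        assert mc_before.summary == summarize(cog)
        assert mc_before.summary["mean"] == pytest.approx(cog.mean())
        assert mc_before.summary["range"] == pytest.approx(cog.max() - cog.min())

    def test_overflow_draws_are_flagged_not_dropped(self, mc_before):
        # the low-titer/high-target corner overflows the single train
        assert mc_before.n_capacity_expanded > 0
        assert len(mc_before.samples) == 300
        assert mc_before.samples["capacity_expanded"].sum() == mc_before.n_capacity_expanded

    @pytest.mark.parametrize("which", ["before", "after"])
    def test_cog_envelope_bounds(self, model, base, mc_before, mc_after, which):
        """Every sampled CoG/g lies inside the provable envelope obtained by
        bounding the fixed-cost and variable-cost per-gram terms separately
        over the sampled support (including ceiling slack and train count)."""
        result, cfg = (
            (mc_before, fixtures.mc_config_before()) if which == "before"
            else (mc_after, fixtures.mc_config_after())
        )
        d = cfg.distributions
        fs = model.flowsheet_at(base.dsp_yield)

        def per_batch(titer):
            return titer * fs.fermenter_working_volume * fs.overall_yield

        bd0 = model.breakdown(base)
        r = model.prices.other_overhead_rate
        fixed = bd0.by_category["capital"] + bd0.by_category["labor"] * (1 + r)
        # per-batch variable cost at deviation dev, from a one-batch breakdown
        def var_per_batch(dev):
            tiny = base.replace(target_output=1e-6, material_cost_deviation=dev)
            bd1 = model.breakdown(tiny)
            return bd1.total - fixed

        pb_lo, pb_hi = per_batch(d["titer"].min), per_batch(d["titer"].max)
        tgt_lo = d["target_output"].min * 1000.0
        tgt_hi = d["target_output"].max * 1000.0
        dev_lo, dev_hi = (d["material_cost_deviation"].min,
                          d["material_cost_deviation"].max)
        trains_max = int(np.ceil(
            np.ceil(tgt_hi / pb_lo) / fs.max_batches_per_year(trains=1)))

        lower = fixed / (tgt_hi + pb_hi) + var_per_batch(dev_lo) / pb_hi
        upper = (fixed - bd0.by_category["capital"]
                 + bd0.by_category["capital"] * trains_max) / tgt_lo \
            + var_per_batch(dev_hi) / pb_lo
        cog = result.samples["cog_per_g"]
        assert cog.min() >= lower
        assert cog.max() <= upper

    def test_after_optimization_cheaper_and_tighter(self, mc_before, mc_after):
        assert mc_after.summary["mean"] < mc_before.summary["mean"]
        assert mc_after.summary["std"] < mc_before.summary["std"]
        assert mc_after.summary["range"] < mc_before.summary["range"]

    def test_parameter_spans(self):
        spans = parameter_spans(fixtures.mc_config_before())
        assert spans["titer"] == pytest.approx(2 * fixtures.TITER_SD)
        assert spans["material_cost_deviation"] == pytest.approx(50.0)

    def test_config_invariants(self):
        with pytest.raises(ConfigurationError):
            MCConfig(distributions={}, max_runs=10, ma_window=5)
        with pytest.raises(ConfigurationError):
            MCConfig(distributions={"not_a_param": TriangularDist(0, 1, 2)},
                     max_runs=10, ma_window=5)
        with pytest.raises(ConfigurationError):
            MCConfig(distributions={"titer": TriangularDist(0.1, 0.2, 0.3)},
                     max_runs=4, ma_window=5)
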
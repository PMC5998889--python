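"""Leave-one-out regulation-intensity estimation."""

import numpy as np
import pytest

import regushift as rs
from regushift.intensity import IntensityConfig, fit_parent_model


def sine(rng, n, scale=3.0):
    t = np.arange(n, dtype=float)
    return scale * np.sin(
        2 * np.pi * rng.uniform(1.5, 4.0) * t / n + rng.uniform(0, 2 * np.pi)
    )


class TestFitParentModel:
    def test_exact_linear_fit(self):
        x = np.arange(5.0)
        fit = fit_parent_model(2 * x + 1, x)
        assert fit.coef == pytest.approx([1.0, 2.0], abs=1e-10)
        assert fit.residual_scale == pytest.approx(1e-8)
        assert not fit.degenerate

    def test_constant_parent_is_degenerate(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_parent_model(y, np.full(4, 7.0))
        assert fit.degenerate
        assert fit.intercept == pytest.approx(y.mean())
        assert fit.slopes == pytest.approx([0.0])

    def test_slope_recovery_under_noise(self):
        # closed-form OLS on a seeded draw; slope must land near truth
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 100)
        y = x + rng.normal(0, 1, 100)
        fit = fit_parent_model(y, x)
        assert 0.8 <= fit.slopes[0] <= 1.2

    def test_too_few_points(self):
        with pytest.raises(rs.ValidationError):
            fit_parent_model([1.0, 2.0], [[1.0], [2.0]])


class TestLooIntensity:
    def test_exact_fit_scores_lambda_everywhere(self, pair_network):
        t = np.arange(6.0)
        prof = rs.ExpressionProfile(["p", "c"], t, np.vstack([t, 2 * t]))
        M = rs.loo_intensity(prof, pair_network)
        assert M.gene_ids == ("c",)
        assert M.values == pytest.approx(np.full((1, 6), 2.0), abs=1e-6)

    def test_custom_lambda(self, pair_network):
        t = np.arange(6.0)
        prof = rs.ExpressionProfile(["p", "c"], t, np.vstack([t, 2 * t]))
        M = rs.loo_intensity(prof, pair_network, IntensityConfig(lambda_offset=5.0))
        assert M.values == pytest.approx(np.full((1, 6), 5.0), abs=1e-6)

    def test_unregulated_genes_have_no_row(self):
        net = rs.RegulatoryNetwork([rs.Edge("a", "b")])
        rng = np.random.default_rng(0)
        prof = rs.ExpressionProfile(
            ["a", "b", "orphan"], np.arange(8.0), rng.normal(size=(3, 8))
        )
        M = rs.loo_intensity(prof, net)
        assert M.gene_ids == ("b",)

    def test_missing_regulated_gene_is_named(self):
        net = rs.RegulatoryNetwork([rs.Edge("a", "zzz")])
        prof = rs.ExpressionProfile(
            ["a"], np.arange(8.0), np.random.default_rng(0).normal(size=(1, 8))
        )
        with pytest.raises(rs.ValidationError, match="zzz"):
            rs.loo_intensity(prof, net)

    def test_too_few_time_points(self, pair_network):
        prof = rs.ExpressionProfile(
            ["p", "c"], np.arange(3.0), np.arange(6.0).reshape(2, 3)
        )
        with pytest.raises(rs.ValidationError, match="time points"):
            rs.loo_intensity(prof, pair_network)

    def test_affine_invariance_of_child(self, pair_network):
        rng = np.random.default_rng(5)
        x = sine(rng, 12)
        y = x + rng.normal(0, 0.5, 12)
        t = np.arange(12.0)
        m1 = rs.loo_intensity(
            rs.ExpressionProfile(["p", "c"], t, np.vstack([x, y])), pair_network
        )
        m2 = rs.loo_intensity(
            rs.ExpressionProfile(["p", "c"], t, np.vstack([x, 3.7 * y - 2.2])),
            pair_network,
        )
        assert m1.values == pytest.approx(m2.values, abs=1e-8)

    def test_permutation_of_columns_permutes_intensities(self, pair_network):
        rng = np.random.default_rng(8)
        x = sine(rng, 10)
        y = x + rng.normal(0, 0.4, 10)
        t = np.arange(10.0)
        perm = rng.permutation(10)
        vals = np.vstack([x, y])
        m1 = rs.loo_intensity(
            rs.ExpressionProfile(["p", "c"], t, vals), pair_network
        )
        m2 = rs.loo_intensity(
            rs.ExpressionProfile(["p", "c"], t, vals[:, perm]), pair_network
        )
        assert m2.values == pytest.approx(m1.values[:, perm], abs=1e-8)

    def test_active_regulation_scores_positive_on_average(self, pair_network):
        t = np.arange(20.0)
        means = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = sine(rng, 20)
            y = x + rng.normal(0, 0.3, 20)
            prof = rs.ExpressionProfile(["p", "c"], t, np.vstack([x, y]))
            means.append(rs.loo_intensity(prof, pair_network).values.mean())
        assert np.mean(means) > 0.5

    def test_decoupled_child_scores_negative_on_average(self, pair_network):
        # inactive regulation: pure-noise child against a strong ramp parent
        t = np.arange(20.0)
        x = np.linspace(0, 10, 20)
        means = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            prof = rs.ExpressionProfile(
                ["p", "c"], t, np.vstack([x, rng.normal(0, 1, 20)])
            )
            means.append(rs.loo_intensity(prof, pair_network).values.mean())
        assert np.mean(means) < 0

    def test_intensities_bounded_by_rho_cap(self, pair_network):
        cfg = IntensityConfig()
        t = np.arange(20.0)
        x = np.linspace(0, 10, 20)
        rng = np.random.default_rng(1)
        prof = rs.ExpressionProfile(
            ["p", "c"], t, np.vstack([x, rng.normal(0, 1, 20)])
        )
        M = rs.loo_intensity(prof, pair_network, cfg)
        assert (M.values >= cfg.lambda_offset - cfg.rho_cap - 1e-12).all()
        assert (M.values <= cfg.lambda_offset + 1e-12).all()

    def test_self_loop_parent_is_excluded(self):
        net = rs.RegulatoryNetwork([rs.Edge("a", "a"), rs.Edge("b", "a")])
        rng = np.random.default_rng(2)
        x = sine(rng, 10)
        prof = rs.ExpressionProfile(
            ["a", "b"], np.arange(10.0), np.vstack([x + rng.normal(0, 0.3, 10), x])
        )
        M = rs.loo_intensity(prof, net)
        # "a" is regulated by "b" only; its own expression is not a predictor
        assert M.gene_ids == ("a",)
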
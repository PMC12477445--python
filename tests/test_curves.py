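import numpy as np
import pytest

import taxometrics as tx
from taxometrics.curves import factor_scores

from ._oracles import mambac_y, window_cov, zero_diag_max_eig


def _tie_free(rng, n, k):
    """Continuous columns (no ties), so sort order is deterministic."""
    return rng.normal(size=(n, k)) + np.linspace(0, 1e-6, n)[:, None]


class TestMambac:
    def test_separated_halves_give_unit_difference(self):
        data = np.column_stack([np.arange(1, 7), [0, 0, 0, 1, 1, 1]]).astype(float)
        curve = tx.mambac_curve(data, 0, 1, n_cuts=1, end_margin=3, replications=1, seed=0)
        assert curve.x == pytest.approx([3.0])
        assert curve.y == pytest.approx([1.0])

    def test_constant_output_gives_zero_curve(self, rng):
        data = np.column_stack([rng.normal(size=60), np.full(60, 2.0)])
        with pytest.warns(UserWarning, match="constant output"):
            curve = tx.mambac_curve(data, 0, 1, n_cuts=5, end_margin=10, replications=2, seed=1)
        assert np.all(curve.y == 0)

    def test_matches_exhaustive_partition_oracle(self, rng):
        data = _tie_free(rng, 40, 2)
        curve = tx.mambac_curve(data, 0, 1, n_cuts=5, end_margin=8, replications=1, seed=2)
        assert np.allclose(curve.y, mambac_y(data[:, 0], data[:, 1], curve.x.astype(int)),
                           atol=1e-10)

    def test_invariant_to_monotone_input_relabeling(self, rng):
        data = _tie_free(rng, 50, 2)
        relabeled = data.copy()
        relabeled[:, 0] = np.exp(data[:, 0])  # strictly monotone, rank-preserving
        a = tx.mambac_curve(data, 0, 1, n_cuts=6, end_margin=10, replications=1, seed=3)
        b = tx.mambac_curve(relabeled, 0, 1, n_cuts=6, end_margin=10, replications=1, seed=3)
        assert np.allclose(a.y, b.y, atol=1e-12)

    def test_too_few_cases_is_error(self, rng):
        with pytest.raises(tx.PreconditionError):
            tx.mambac_curve(_tie_free(rng, 30, 2), 0, 1, n_cuts=20, end_margin=10)

    def test_same_input_output_rejected(self, rng):
        with pytest.raises(tx.ConfigurationError):
            tx.mambac_curve(_tie_free(rng, 100, 2), 0, 0)


class TestMambacPanel:
    def test_two_indicators_give_two_curves(self, rng):
        curves, _ = tx.mambac_panel(_tie_free(rng, 80, 2), n_cuts=5, end_margin=15,
                                    replications=1, seed=4)
        assert len(curves) == 2

    def test_panel_mean_of_identical_curves_is_member(self, rng):
        col = _tie_free(rng, 80, 1)[:, 0]
        data = np.column_stack([col, col + 0.5])  # perfectly rank-aligned pair
        curves, mean = tx.mambac_panel(data, n_cuts=5, end_margin=15, replications=1, seed=5)
        assert np.allclose(mean.y, curves[0].y, atol=1e-12)

    def test_panel_mean_equals_oracle_mean(self, rng):
        data = _tie_free(rng, 60, 4)
        curves, mean = tx.mambac_panel(data, n_cuts=5, end_margin=12, replications=1, seed=6)
        assert len(curves) == 12
        assert np.allclose(mean.y, np.mean([c.y for c in curves], axis=0), atol=1e-12)


class TestMaxeig:
    def test_two_outputs_equal_abs_covariance(self, rng):
        data = _tie_free(rng, 30, 3)
        curve = tx.maxeig_curve(data, 0, n_windows=1, replications=1, seed=7)
        cov = np.cov(data[:, 1], data[:, 2], ddof=1)
        assert curve.y[0] == pytest.approx(abs(cov[0, 1]), abs=1e-12)

    def test_independent_outputs_give_near_zero(self, rng):
        data = rng.normal(size=(5000, 3))
        curve = tx.maxeig_curve(data, 0, n_windows=10, overlap=0.5, replications=2, seed=8)
        assert np.max(np.abs(curve.y)) < 0.15

    def test_matches_characteristic_polynomial_oracle(self, rng):
        data = _tie_free(rng, 50, 4)
        curve = tx.maxeig_curve(data, 0, n_windows=1, replications=1, seed=9)
        order = np.argsort(data[:, 0])
        win = data[order][:, 1:]
        assert curve.y[0] == pytest.approx(zero_diag_max_eig(window_cov(win)), abs=1e-10)

    def test_too_many_windows_is_error(self, rng):
        with pytest.raises(tx.PreconditionError):
            tx.maxeig_curve(_tie_free(rng, 40, 3), 0, n_windows=39, overlap=0.0)

    def test_needs_three_indicators(self, rng):
        with pytest.raises(tx.PreconditionError):
            tx.maxeig_curve(_tie_free(rng, 100, 2), 0)


class TestMaxeigPanel:
    def test_three_indicators_give_three_curves(self, rng):
        curves, _ = tx.maxeig_panel(_tie_free(rng, 100, 3), n_windows=5, overlap=0.5,
                                    replications=1, seed=10)
        assert len(curves) == 3

    def test_panel_mean_equals_oracle_mean(self, rng):
        data = _tie_free(rng, 100, 3)
        curves, mean = tx.maxeig_panel(data, n_windows=5, overlap=0.5, replications=1, seed=11)
        assert np.allclose(mean.y, np.mean([c.y for c in curves], axis=0), atol=1e-12)

    def test_rank_aligned_indicators_give_identical_curves(self):
        base = np.sort(np.random.default_rng(12).normal(size=90))
        data = np.column_stack([base, base * 2, base + 1])  # identical rank structure
        curves, _ = tx.maxeig_panel(data, n_windows=4, overlap=0.5, replications=1, seed=13)
        assert np.allclose(curves[0].x, curves[1].x)


class TestLMode:
    def test_exact_one_factor_loadings_recovered(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        loadings, communalities = tx.principal_axis_loadings(corr)
        assert np.allclose(loadings, lam, atol=1e-4)
        assert np.allclose(communalities, lam**2, atol=1e-4)

    def test_unimodal_on_dimensional_data(self, dimensional_sample):
        curve = tx.lmode_curve(dimensional_sample.indicators)
        assert curve.meta["n_modes"] == 1

    def test_bimodal_with_base_rate_estimate_on_separated_groups(self):
        sample = tx.make_taxonic(2000, n_indicators=4, base_rate=0.5, separation=3.0,
                                 within_group_r=0.1, seed=15)
        curve = tx.lmode_curve(sample.indicators)
        assert curve.meta["n_modes"] >= 2
        assert 0.4 <= curve.meta["base_rate_estimate"] <= 0.6

    def test_density_integrates_to_one(self, taxonic_sample):
        curve = tx.lmode_curve(taxonic_sample.indicators)
        assert np.trapezoid(curve.y, curve.x) == pytest.approx(1.0, abs=1e-3)

    def test_scores_standardized(self, dimensional_sample):
        x = dimensional_sample.indicators.values.astype(float)
        corr = np.corrcoef(x, rowvar=False)
        loadings, _ = tx.principal_axis_loadings(corr)
        scores = factor_scores(x, loadings, corr)
        assert scores.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_indicator_is_error(self, rng):
        data = np.column_stack([rng.normal(size=100), np.full(100, 3.0)])
        with pytest.raises(tx.PreconditionError):
            tx.lmode_curve(data)

    def test_too_few_cases_is_error(self, rng):
        with pytest.raises(tx.PreconditionError):
            tx.lmode_curve(rng.normal(size=(30, 3)))


def test_curve_serialization_roundtrip(rng):
    data = _tie_free(rng, 60, 3)
    curve = tx.maxeig_curve(data, 0, n_windows=3, overlap=0.5, replications=1, seed=16)
    d = curve.to_dict()
    assert d["procedure"] == "MAXEIG"
    assert len(d["x"]) == len(d["y"]) == 3
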
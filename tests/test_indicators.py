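import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taxometrics as tx
from taxometrics.indicators import DSM5_SPEC, ICD11_SPEC, ItemMatrix

from ._oracles import pairwise_mean_r, pooled_d


def _items_from_codes(codes: np.ndarray) -> ItemMatrix:
    return ItemMatrix(codes, [f"csas{i:02d}" for i in range(1, codes.shape[1] + 1)])


class TestBuildIndicators:
    def test_sum_of_pairs(self):
        codes = np.tile([3, 2] + [0] * 16, (4, 1))
        mat = tx.build_indicators(_items_from_codes(codes), DSM5_SPEC)
        assert mat.indicator_ids[0] == "Preoccupation"
        assert np.all(mat.values[:, 0] == 5)
        assert np.all(mat.values[:, 1:] == 0)

    def test_minimum_codes_give_zero(self):
        mat = tx.build_indicators(_items_from_codes(np.zeros((3, 18), dtype=int)), DSM5_SPEC)
        assert np.all(mat.values == 0)

    def test_matches_brute_force_row_sums(self, rng):
        codes = rng.integers(0, 4, size=(10, 18))
        mat = tx.build_indicators(_items_from_codes(codes), DSM5_SPEC)
        for row in range(10):
            for c, (label, (a, b)) in enumerate(DSM5_SPEC.criteria):
                ja, jb = int(a[4:]) - 1, int(b[4:]) - 1
                assert mat.values[row, c] == codes[row, ja] + codes[row, jb]

    def test_permutation_equivariant_over_cases(self, rng):
        codes = rng.integers(0, 4, size=(25, 18))
        perm = rng.permutation(25)
        direct = tx.build_indicators(_items_from_codes(codes), DSM5_SPEC).values
        permuted = tx.build_indicators(_items_from_codes(codes[perm]), DSM5_SPEC).values
        assert np.array_equal(direct[perm], permuted)

    def test_unknown_item_is_configuration_error(self):
        spec = tx.IndicatorSetSpec("custom", (("Preoccupation", ("nope01", "nope02")),))
        with pytest.raises(tx.ConfigurationError, match="nope01"):
            tx.build_indicators(_items_from_codes(np.zeros((2, 18), dtype=int)), spec)

    def test_missing_values_name_offending_rows(self):
        codes = np.zeros((4, 18), dtype=float)
        codes[2, 5] = np.nan
        with pytest.raises(tx.PreconditionError, match=r"\[2\]"):
            _items_from_codes(codes)

    def test_raw_coding_recode(self):
        raw = np.full((2, 18), 4)
        items = ItemMatrix.from_raw(raw, [f"csas{i:02d}" for i in range(1, 19)], coding="1-4")
        assert items.values.max() == 3
        mat = tx.build_indicators(items, DSM5_SPEC)
        assert np.all(mat.values == 6)


class TestDiagnosticAssignment:
    def test_all_max_is_taxon_under_both_rules(self):
        for spec in (DSM5_SPEC, ICD11_SPEC):
            mat = tx.IndicatorMatrix(np.full((3, len(spec.labels)), 6), spec.labels, spec.name)
            assert tx.diagnostic_assignment(mat).all()

    def test_all_min_is_complement(self):
        mat = tx.IndicatorMatrix(np.zeros((3, 9), dtype=int), DSM5_SPEC.labels, "DSM5")
        assert not tx.diagnostic_assignment(mat).any()

    def test_matches_brute_force_criterion_count(self, rng):
        vals = rng.integers(0, 7, size=(20, 9))
        labels = tx.diagnostic_assignment(tx.IndicatorMatrix(vals, DSM5_SPEC.labels, "DSM5"))
        for row in range(20):
            met = sum(1 for v in vals[row] if v >= 4)
            assert labels[row] == (met >= 5)

    def test_rule_set_mismatch_is_configuration_error(self):
        mat = tx.IndicatorMatrix(np.zeros((3, 9), dtype=int), DSM5_SPEC.labels, "DSM5")
        with pytest.raises(tx.ConfigurationError):
            tx.diagnostic_assignment(mat, spec=ICD11_SPEC)

    def test_unknown_set_requires_min_met(self):
        mat = tx.IndicatorMatrix(np.zeros((3, 2), dtype=int), ["a", "b"], "custom")
        with pytest.raises(tx.ConfigurationError):
            tx.diagnostic_assignment(mat)
        assert not tx.diagnostic_assignment(mat, min_met=1).any()


def _exact_corr_pair(r: float, n: int = 64) -> np.ndarray:
    """Two columns with Pearson correlation exactly r (orthonormal basis)."""
    t = np.linspace(-1, 1, n)
    u = t - t.mean()
    u /= np.linalg.norm(u)
    v = t**2
    v -= v.mean()
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    return np.column_stack([u, r * u + np.sqrt(1 - r**2) * v])


class TestSuitabilityReport:
    def test_textbook_pooled_d(self):
        g0 = np.array([0.0, 0.0, 1.0, 1.0])
        g1 = g0 + 2.0
        x = np.concatenate([g1, g0])[:, None]
        x = np.column_stack([x, x])  # two identical indicators
        labels = np.array([True] * 4 + [False] * 4)
        rep = tx.suitability_report(x, labels)
        expected = 2.0 / np.sqrt(1 / 3)
        assert rep.cohens_d == pytest.approx([expected, expected], abs=1e-12)
        assert rep.cohens_d[0] == pytest.approx(pooled_d(g1, g0), abs=1e-12)

    def test_identical_groups_give_zero_d_and_fail_validity(self, rng):
        x = rng.integers(0, 7, size=(40, 3)).astype(float)
        labels = np.array([True, False] * 20)
        x[labels] = x[~labels]
        rep = tx.suitability_report(x, labels)
        assert rep.cohens_d == pytest.approx([0, 0, 0], abs=1e-12)
        assert not rep.validity_ok

    def test_mean_r_equals_double_loop_oracle(self, rng):
        x = rng.normal(size=(50, 5))
        labels = np.array([True] * 25 + [False] * 25)
        rep = tx.suitability_report(x, labels)
        assert rep.mean_inter_r == pytest.approx(pairwise_mean_r(x), abs=1e-12)

    def test_recovers_planted_separation(self):
        sample = tx.make_taxonic(5000, n_indicators=4, base_rate=0.25,
                                 separation=2.0, within_group_r=0.2, seed=21)
        rep = tx.suitability_report(sample.indicators, sample.labels)
        assert np.mean(rep.cohens_d) == pytest.approx(2.0, abs=0.1)
        assert rep.r_within_taxon == pytest.approx(0.2, abs=0.07)
        assert rep.r_within_complement == pytest.approx(0.2, abs=0.07)

    @pytest.mark.parametrize("factor,expect", [(1.001, True), (0.999, False)])
    def test_validity_flag_flips_at_d_threshold(self, rng, factor, expect):
        g0 = rng.normal(size=(50, 2))
        sp = np.sqrt(g0.var(axis=0, ddof=1))  # shift keeps variances, so pooled sd = sd(g0)
        g1 = g0 + 1.25 * sp * factor
        x = np.vstack([g1, g0])
        labels = np.array([True] * 50 + [False] * 50)
        rep = tx.suitability_report(x, labels)
        assert rep.validity_ok is expect

    @pytest.mark.parametrize("r,expect", [(0.301, True), (0.299, False)])
    def test_inter_r_flag_flips_at_threshold(self, r, expect):
        x = _exact_corr_pair(r)
        labels = np.array([True, False] * 32)
        rep = tx.suitability_report(x, labels)
        assert rep.mean_inter_r == pytest.approx(r, abs=1e-12)
        assert rep.inter_r_ok is expect

    @pytest.mark.parametrize("r,expect", [(0.299, True), (0.301, False)])
    def test_within_r_flag_flips_at_threshold(self, r, expect):
        block = _exact_corr_pair(r)
        x = np.vstack([block, block])  # both putative groups carry exactly r
        labels = np.array([True] * 64 + [False] * 64)
        rep = tx.suitability_report(x, labels)
        assert rep.within_r_ok is expect

    def test_tiny_group_marks_validity_undefined(self):
        x = np.arange(20, dtype=float).reshape(10, 2)
        labels = np.zeros(10, dtype=bool)
        labels[0] = True
        with pytest.warns(UserWarning):
            rep = tx.suitability_report(x, labels)
        assert not rep.validity_ok
        assert np.all(~np.isfinite(rep.cohens_d))

    def test_empty_group_is_precondition_error(self):
        x = np.arange(20, dtype=float).reshape(10, 2)
        with pytest.raises(tx.PreconditionError):
            tx.suitability_report(x, np.zeros(10, dtype=bool))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 3), st.integers(0, 3))
def test_single_pair_sum_property(a, b):
    codes = np.zeros((1, 18), dtype=int)
    codes[0, 0], codes[0, 1] = a, b
    mat = tx.build_indicators(_items_from_codes(codes), DSM5_SPEC)
    assert mat.values[0, 0] == a + b
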
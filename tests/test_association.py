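"""Pearson screen, critical r, and the Westfall-Young maxT adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from bxdtwas import association, preprocess
from bxdtwas.io import StrainTraitVector
from .conftest import expression_from_values


def _pair(values, trait_values):
    expr = expression_from_values(np.asarray(values, dtype=float))
    trait = StrainTraitVector(
        pd.DataFrame(
            {"trait_value": trait_values, "n_individuals": 1}, index=expr.strain_ids
        )
    )
    return preprocess.AlignedPair(expr, trait)


def test_pearson_hand_example():
    # r((1,2,3),(1,3,2)) = 0.5 by the covariance definition
    r, p, n = association.pearson_r_p(
        np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])
    )
    assert r == pytest.approx(0.5)
    assert n == 3


def test_screen_self_correlation_and_sorting():
    rng = np.random.default_rng(0)
    trait = rng.normal(70, 15, 8)
    values = rng.standard_normal((5, 8))
    values[3] = trait  # gene identical to the trait
    table = association.pearson_screen(_pair(values, trait))
    assert table.iloc[0]["gene"] == "G0004"
    assert table.iloc[0]["r"] == pytest.approx(1.0)
    assert (np.abs(table["r"]).diff().dropna() <= 1e-15).all()  # |r| descending


def test_screen_matches_brute_force_loop():
    rng = np.random.default_rng(7)
    values = rng.standard_normal((50, 10))
    trait = rng.standard_normal(10)
    table = association.pearson_screen(_pair(values, trait)).set_index("gene")
    for i in range(50):
        r_ref, p_ref = stats.pearsonr(values[i], trait)
        row = table.loc[f"G{i + 1:04d}"]
        assert abs(row["r"] - r_ref) < 1e-12
        assert abs(row["p_raw"] - p_ref) < 1e-12


def test_screen_excludes_zero_variance_genes():
    rng = np.random.default_rng(1)
    values = rng.standard_normal((4, 8))
    values[2] = 5.0
    table = association.pearson_screen(_pair(values, rng.standard_normal(8)))
    assert table.attrs["excluded_genes"] == ["G0003"]
    assert len(table) == 3


def test_p_raw_matches_integrated_null_density():
    # under H0 the density of r is (1-r^2)^((n-4)/2) / B(1/2, (n-2)/2);
    # the t-transform p must agree with 2 * integral_{|r|}^{1} to 1e-8
    for n in (6, 10, 26):
        norm = special.beta(0.5, (n - 2) / 2)
        for r in (0.05, 0.2, 0.388, 0.6, 0.9):
            tail, _ = integrate.quad(
                lambda x: (1 - x**2) ** ((n - 4) / 2) / norm, r, 1.0
            )
            p_t = float(
                2 * stats.t.sf(r * np.sqrt(n - 2) / np.sqrt(1 - r**2), n - 2)
            )
            assert abs(p_t - 2 * tail) < 1e-8


class TestCriticalR:
    def test_reference_values(self):
        assert association.critical_r(26, 0.05) == pytest.approx(0.388, abs=5e-4)
        # n=3: t*(df=1) = 12.706 -> r* = 0.997
        assert association.critical_r(3, 0.05) == pytest.approx(0.997, abs=5e-4)

    def test_monotone_decreasing_in_n(self):
        rs = [association.critical_r(n) for n in range(3, 200)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_alpha_to_one_limit(self):
        assert association.critical_r(26, 0.9999) < 1e-3

    def test_consistency_with_screen_p(self):
        # |r| just above the critical value must give p_raw just below alpha
        for n in (6, 26, 50):
            r_star = association.critical_r(n, 0.05)
            p_hi = 2 * stats.t.sf(
                (r_star + 1e-9) * np.sqrt(n - 2) / np.sqrt(1 - (r_star + 1e-9) ** 2),
                n - 2,
            )
            assert p_hi < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            association.critical_r(2, 0.05)
        with pytest.raises(ValueError):
            association.critical_r(26, 0.0)


class TestWestfallYoung:
    def test_maxt_worked_example(self):
        # observed |r| = 0.5 vs maxima (0.1, 0.2, 0.3, 0.4): no maximum
        # reaches 0.5, so p = (1 + 0) / (4 + 1) = 0.2
        p = association.maxt_adjusted_p(np.array([0.5]), np.array([0.1, 0.2, 0.3, 0.4]))
        assert p[0] == pytest.approx(0.2)

    def test_maxt_zero_statistic_worst_case(self):
        p = association.maxt_adjusted_p(np.array([0.0]), np.array([0.1, 0.2, 0.3, 0.4]))
        assert p[0] == pytest.approx(1.0)

    def test_ties_counted_conservatively(self):
        # M_b == |r_obs| counts against the gene (>= comparison)
        p = association.maxt_adjusted_p(np.array([0.3]), np.array([0.1, 0.3, 0.3, 0.4]))
        assert p[0] == pytest.approx(4 / 5)

    def _random_pair(self, seed, n_genes=40, n=12):
        rng = np.random.default_rng(seed)
        return _pair(rng.standard_normal((n_genes, n)), rng.normal(70, 10, n))

    def test_adjusted_dominates_raw_and_is_monotone(self):
        pair = self._random_pair(3)
        table = association.westfall_young_adjust(
            pair, association.PermutationConfig(99, seed=5)
        )
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adjusted"] > 0).all()
        # sorted by |r| desc, p_adjusted must be nondecreasing down the table
        assert (table["p_adjusted"].diff().dropna() >= -1e-15).all()

    def test_seed_reproducibility(self):
        pair = self._random_pair(4)
        cfg = association.PermutationConfig(50, seed=11)
        t1 = association.westfall_young_adjust(pair, cfg)
        t2 = association.westfall_young_adjust(pair, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_step_down_no_larger_than_single_step(self):
        pair = self._random_pair(5)
        single = association.westfall_young_adjust(
            pair, association.PermutationConfig(199, seed=1)
        )
        step = association.westfall_young_adjust(
            pair, association.PermutationConfig(199, seed=1, step_down=True)
        )
        merged = single.merge(step, on="gene", suffixes=("_ss", "_sd"))
        assert (merged["p_adjusted_sd"] <= merged["p_adjusted_ss"] + 1e-15).all()

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            association.PermutationConfig(0)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_label_invariance(seed):
    """Permuting strain labels of BOTH expression and trait leaves r unchanged."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((10, 9))
    trait = rng.normal(70, 10, 9)
    perm = rng.permutation(9)
    t1 = association.pearson_screen(_pair(values, trait)).set_index("gene")["r"]
    t2 = association.pearson_screen(_pair(values[:, perm], trait[perm])).set_index("gene")["r"]
    np.testing.assert_allclose(t1.sort_index(), t2.sort_index(), atol=1e-12)


class TestFilterSignificant:
    table = pd.DataFrame(
        {
            "gene": ["a", "b", "c"],
            "r": [0.5, 0.2, 0.6],
            "p_raw": [0.01, 0.01, 0.2],
            "n": 26,
        }
    )

    def test_joint_rule(self):
        assert association.filter_significant(self.table, 0.05, 0.3) == ["a"]

    def test_thresholds_disabled(self):
        assert association.filter_significant(self.table, None, None) == ["a", "b", "c"]

    def test_negative_r_passes_magnitude_rule(self):
        flipped = self.table.assign(r=[-0.5, 0.2, 0.6])
        assert association.filter_significant(flipped, 0.05, 0.3) == ["a"]
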
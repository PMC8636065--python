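"""Modified-Z normalization, ABR aggregation, alignment and the age check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bxdtwas import preprocess
from bxdtwas.io import AbrRecordTable, ExpressionMatrix, Scale, StrainTraitVector
from .conftest import expression_from_values


def _expr(values, scale=Scale.RAW_LOG2):
    return expression_from_values(np.asarray(values, dtype=float), scale)


class TestModifiedZ:
    def test_hand_computed_column(self):
        # column (1,2,3): sample SD is 1, so z = (-1,0,1) -> 2z+8 = (6,8,10)
        out = preprocess.modified_z_normalize(_expr([[1], [2], [3]]))
        np.testing.assert_allclose(out.values.ravel(), [6, 8, 10])
        assert out.scale is Scale.MODIFIED_Z

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, derandomize=True)
    def test_location_invariance(self, shift):
        base = preprocess.modified_z_normalize(_expr([[1], [2], [3]]))
        shifted = preprocess.modified_z_normalize(_expr([[1 + shift], [2 + shift], [3 + shift]]))
        np.testing.assert_allclose(shifted.values, base.values, atol=1e-9)

    def test_columns_forced_to_mean8_sd2(self):
        rng = np.random.default_rng(3)
        out = preprocess.modified_z_normalize(_expr(rng.normal(7, 1.3, (100, 8))))
        np.testing.assert_allclose(out.values.mean(axis=0), 8.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 2.0, atol=1e-9)

    def test_zero_variance_column_names_strain(self):
        values = np.ones((4, 2))
        values[:, 0] = [1, 2, 3, 4]
        with pytest.raises(ValueError, match="BXD002"):
            preprocess.modified_z_normalize(_expr(values))

    def test_rejects_already_normalized_input(self):
        with pytest.raises(ValueError, match="raw_log2"):
            preprocess.modified_z_normalize(_expr([[1], [2], [3]], Scale.MODIFIED_Z))


def _records(rows):
    return AbrRecordTable(
        pd.DataFrame(
            rows,
            columns=["strain", "individual", "sex", "age_months", "frequency_khz", "threshold_db"],
        )
    )


class TestAggregateAbr:
    def _toy(self):
        rows = []
        for mouse, (t8, t16, t32) in [("m1", (40, 50, 60)), ("m2", (60, 70, 80))]:
            for f, t in zip((8, 16, 32), (t8, t16, t32)):
                rows.append(("BXD1", mouse, "F", 20, f, t))
        return _records(rows)

    def test_two_step_mean(self):
        # per-frequency means (50, 60, 70) -> hearing acuity 60
        trait = preprocess.aggregate_abr(self._toy())
        assert trait.values["BXD1"] == pytest.approx(60.0)
        assert trait.table.loc["BXD1", "n_individuals"] == 2

    def test_single_frequency_restriction(self):
        trait = preprocess.aggregate_abr(self._toy(), frequencies=[8])
        assert trait.values["BXD1"] == pytest.approx(50.0)

    def test_constant_mouse_is_identity(self):
        rows = [("BXD1", "m1", "M", 22, f, 75.0) for f in (8, 16, 32)]
        trait = preprocess.aggregate_abr(_records(rows))
        assert trait.values["BXD1"] == pytest.approx(75.0)

    def test_two_step_differs_from_pooled_mean_when_unbalanced(self):
        # 3 mice at 8 kHz but 1 at 16/32 kHz: pooling would overweight 8 kHz
        rows = [("BXD1", f"m{i}", "M", 20, 8, t) for i, t in enumerate((30, 40, 50))]
        rows += [("BXD1", "m0", "M", 20, 16, 80), ("BXD1", "m0", "M", 20, 32, 90)]
        trait = preprocess.aggregate_abr(_records(rows))
        two_step = (np.mean([30, 40, 50]) + 80 + 90) / 3
        pooled = np.mean([30, 40, 50, 80, 90])
        assert trait.values["BXD1"] == pytest.approx(two_step)
        assert trait.values["BXD1"] != pytest.approx(pooled)

    def test_repeated_measurements_averaged_within_mouse_first(self):
        # m1 measured twice at 8 kHz; its within-mouse mean (45) must carry
        # the same weight as m2's single measurement
        rows = [
            ("BXD1", "m1", "M", 20, 8, 40),
            ("BXD1", "m1", "M", 20, 8, 50),
            ("BXD1", "m2", "M", 20, 8, 65),
        ]
        trait = preprocess.aggregate_abr(_records(rows), frequencies=[8])
        assert trait.values["BXD1"] == pytest.approx((45 + 65) / 2)

    def test_missing_frequency_is_an_error(self):
        rows = [("BXD1", "m1", "M", 20, 8, 40)]
        with pytest.raises(ValueError, match=r"BXD1.*16"):
            preprocess.aggregate_abr(_records(rows), frequencies=[8, 16])


def _trait(strains, values):
    return StrainTraitVector(
        pd.DataFrame({"trait_value": values, "n_individuals": 1}, index=strains)
    )


class TestAlign:
    def test_intersection_and_drop_reporting(self):
        expr = expression_from_values(np.arange(21.0).reshape(3, 7))
        expr.data.columns = list("ABCDEFG")
        trait = _trait(list("BCDEFGH"), np.arange(7.0))
        pair = preprocess.align(expr, trait)
        assert pair.n_shared == 6
        assert pair.strains == list("BCDEFG")
        assert pair.dropped_expression_strains == ("A",)
        assert pair.dropped_trait_strains == ("H",)

    def test_identical_sets_no_drops(self):
        expr = expression_from_values(np.random.default_rng(0).normal(size=(3, 6)))
        trait = _trait(expr.strain_ids, np.arange(6.0))
        pair = preprocess.align(expr, trait)
        assert pair.n_shared == 6
        assert pair.dropped_expression_strains == ()

    def test_disjoint_sets_error(self):
        expr = expression_from_values(np.zeros((3, 6)))
        trait = _trait([f"X{i}" for i in range(6)], np.arange(6.0))
        with pytest.raises(ValueError, match="0 strains shared"):
            preprocess.align(expr, trait)

    def test_idempotence(self):
        expr = expression_from_values(np.random.default_rng(1).normal(size=(4, 8)))
        trait = _trait(expr.strain_ids[2:] + ["ZZZ"], np.arange(7.0))
        once = preprocess.align(expr, trait)
        twice = preprocess.align(once.expression, once.trait)
        assert twice.strains == once.strains
        np.testing.assert_array_equal(twice.expression.values, once.expression.values)
        pd.testing.assert_frame_equal(twice.trait.table, once.trait.table)


class TestAgeConfound:
    def test_noiseless_line(self):
        ages = np.array([19.0, 21.0, 23.0, 25.0])
        slope, p, r2 = preprocess.age_confound_check(2 * ages + 1, ages)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_n3_closed_form_t_with_1df(self):
        ages = np.array([20.0, 22.0, 24.0])
        expr = np.array([1.0, 2.0, 4.0])
        slope, p, r2 = preprocess.age_confound_check(expr, ages)
        # closed form: slope 0.75, t = slope / se with 1 df
        xc = ages - ages.mean()
        yc = expr - expr.mean()
        b = (xc @ yc) / (xc @ xc)
        sse = ((yc - b * xc) ** 2).sum()
        t = b / np.sqrt(sse / 1 / (xc @ xc))
        assert slope == pytest.approx(b)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 1))

    def test_null_calibration(self):
        # expression independent of age: slope p must be uniform
        rng = np.random.default_rng(42)
        ages = rng.uniform(19, 25, 26)
        hits = sum(
            preprocess.age_confound_check(rng.standard_normal(26), ages)[1] < 0.05
            for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(hits / 1000 - 0.05) < 3 * se

    def test_zero_age_variance_error(self):
        with pytest.raises(ValueError, match="age"):
            preprocess.age_confound_check([1.0, 2.0, 3.0], [20.0, 20.0, 20.0])
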
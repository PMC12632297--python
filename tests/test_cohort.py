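import numpy as np
import pandas as pd
import pytest

from boldwaves import (
    CollinearityError,
    anova_oneway,
    assign_groups,
    correlate,
    exclude_missing_scores,
    ordinal_trend,
    residualize_age,
    two_sample_t,
    wave_memory_model,
)


def _table(menop, mri, ids=None):
    n = len(menop)
    return pd.DataFrame({
        "subject_id": ids if ids is not None else [f"s{i:02d}" for i in range(n)],
        "age_at_mri": np.asarray(mri, float),
        "age_at_menopause": np.asarray(menop, float),
    })


class TestAssignGroups:
    def _toy12(self):
        # early (menop 45): MRI 45 (below overlap), 53..60; late (menop 52):
        # MRI 53..60 plus 66, 68 (above overlap). Overlap = [53, 60].
        menop = [45] * 6 + [52] * 6
        mri = [45, 53, 54, 55, 56, 60, 53, 55, 57, 60, 66, 68]
        return _table(menop, mri)

    def test_overlap_exclusion_and_tertiles(self):
        out = assign_groups(self._toy12())
        assert out.attrs["mri_age_overlap"] == (53.0, 60.0)
        assert out["included"].sum() == 9
        assert out["group"].value_counts().to_dict() == {
            "earlier": 3, "intermediate": 3, "later": 3}
        # excluded subjects carry no group label
        assert out.loc[~out["included"], "group"].isna().all()

    def test_row_order_invariance(self, rng):
        toy = self._toy12()
        out1 = assign_groups(toy)
        shuffled = toy.sample(frac=1.0, random_state=7)
        out2 = assign_groups(shuffled)
        m1 = out1.set_index("subject_id")["group"]
        m2 = out2.set_index("subject_id")["group"]
        pd.testing.assert_series_equal(m1.sort_index(), m2.sort_index())

    def test_all_same_menopause_age_tie_broken_by_id(self):
        toy = _table([50] * 6, [55, 56, 57, 58, 59, 60])
        out = assign_groups(toy)
        assert out["included"].all()
        # ids sort lexically: s00,s01 -> earlier ... s04,s05 -> later
        assert list(out.sort_values("subject_id")["group"]) == [
            "earlier", "earlier", "intermediate", "intermediate",
            "later", "later"]

    def test_flagged_rows_never_enter(self):
        toy = self._toy12()
        toy["excluded"] = False
        toy.loc[3, "excluded"] = True  # abnormal phenotype response
        out = assign_groups(toy)
        assert not out.loc[3, "included"]
        assert out["included"].sum() == 8

    def test_uneven_remainder_sizes_differ_by_one(self):
        toy = _table([45, 46, 47, 48, 52, 53, 54],
                     [55, 56, 57, 58, 55, 56, 58])
        out = assign_groups(toy)
        sizes = out["group"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 7


class TestResidualize:
    def test_pure_age_effect_vanishes(self, rng):
        ages = rng.uniform(50, 70, 40)
        res = residualize_age(2.0 * ages, ages)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)

    def test_uncorrelated_values_just_centered(self):
        ages = np.array([50.0, 55.0, 60.0, 65.0])
        vals = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to age
        np.testing.assert_allclose(residualize_age(vals, ages), vals, atol=1e-10)

    def test_orthogonality(self, rng):
        ages = rng.uniform(50, 70, 90)
        vals = rng.normal(size=90) + 0.1 * ages
        res = residualize_age(vals, ages)
        assert abs(res @ (ages - ages.mean())) < 1e-8
        assert abs(res.sum()) < 1e-8


class TestTTest:
    def test_identical_samples(self, rng):
        x = rng.normal(size=10)
        res = two_sample_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_swap_flips_sign(self, rng):
        x, y = rng.normal(size=(2, 12))
        assert two_sample_t(x, y).statistic == pytest.approx(
            -two_sample_t(y, x).statistic)

    def test_closed_form_3_plus_3(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        # pooled-variance t computed by hand
        sp2 = (2 * x.var(ddof=1) + 2 * y.var(ddof=1)) / 4
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = two_sample_t(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        from scipy import stats
        assert res.pvalue == pytest.approx(
            2 * stats.t.sf(abs(t_hand), df=4), abs=1e-12)


class TestAnova:
    def test_equal_means_F_near_zero(self):
        g = [np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
             np.array([2.0, 2.0, 2.0])]
        assert anova_oneway(g).statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_t_squared(self, rng):
        x, y = rng.normal(size=(2, 15))
        f = anova_oneway([x, y]).statistic
        t = two_sample_t(x, y).statistic
        assert f == pytest.approx(t**2, rel=1e-10)


class TestTrend:
    labels = np.repeat(["earlier", "intermediate", "later"], 10)

    def test_flat_metric_null(self):
        res = ordinal_trend(np.ones(30), self.labels)
        assert res.estimate == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_monotone_means_detected(self, rng):
        metric = np.repeat([0.0, 1.0, 2.0], 10) + 0.05 * rng.normal(size=30)
        res = ordinal_trend(metric, self.labels)
        assert res.pvalue < 0.01
        assert res.estimate > 0

    def test_reversed_order_flips_slope(self, rng):
        metric = np.repeat([0.0, 1.0, 2.0], 10) + 0.05 * rng.normal(size=30)
        fwd = ordinal_trend(metric, self.labels)
        rev = ordinal_trend(metric, self.labels,
                            order=("later", "intermediate", "earlier"))
        assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-10)

    def test_continuous_predictor_switch(self, rng):
        menop_age = rng.uniform(40, 56, 30)
        metric = 0.3 * menop_age + rng.normal(size=30)
        res = ordinal_trend(metric, self.labels, predictor=menop_age)
        from scipy import stats
        lin = stats.linregress(menop_age, metric)
        assert res.estimate == pytest.approx(lin.slope, abs=1e-12)


class TestCorrelate:
    def test_identity_and_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        assert correlate(x, x).estimate == pytest.approx(1.0)
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert correlate(x, y).estimate == pytest.approx(r_hand, abs=1e-12)

    def test_independent_within_null_band(self, rng):
        vals = [correlate(rng.normal(size=100), rng.normal(size=100)).estimate
                for _ in range(50)]
        assert np.mean(np.abs(vals) < 2.5 / np.sqrt(100)) > 0.9


class TestWaveMemoryModel:
    def test_zero_score_effect(self, rng):
        age = rng.uniform(50, 70, 80)
        score = rng.normal(size=80)
        activation = 3.0 * age + rng.normal(size=80)
        res = wave_memory_model(activation, age, score)
        assert abs(res.statistic) < 4.0
        assert res.extras["age_pvalue"] < 1e-10

    def test_recovers_planted_coefficient(self, rng):
        age = rng.uniform(50, 70, 200)
        score = rng.normal(size=200)
        activation = 0.8 * score + 0.3 * age + 0.5 * rng.normal(size=200)
        res = wave_memory_model(activation, age, score)
        assert res.estimate == pytest.approx(0.8, abs=0.15)
        assert res.pvalue < 1e-6

    def test_collinear_predictors_flagged(self, rng):
        age = rng.uniform(50, 70, 30)
        with pytest.raises(CollinearityError):
            wave_memory_model(rng.normal(size=30), age, 2.0 * age)


class TestExcludeMissing:
    def test_sentinel_nan_and_identity(self):
        df = pd.DataFrame({"subject_id": list("abcde"),
                           "psmt_score": [100.0, 999.0, np.nan, 90.0, 85.0]})
        out = exclude_missing_scores(df, "psmt_score")
        assert list(out["subject_id"]) == ["a", "d", "e"]
        clean = df.iloc[[0, 3, 4]]
        pd.testing.assert_frame_equal(
            exclude_missing_scores(clean, "psmt_score"), clean)
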
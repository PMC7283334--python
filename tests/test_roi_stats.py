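import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from petref import phantom as ph
from petref import roi_stats


class TestRoiMeans:
    def test_constant_map(self, atlas):
        vol = np.full(atlas.labels.shape, 2.5)
        means = roi_stats.roi_means(vol, atlas)
        np.testing.assert_allclose(means["value"], 2.5)
        assert len(means) == 84

    def test_planted_values_recovered_exactly_without_blur(self, atlas):
        rng = np.random.default_rng(3)
        lut = np.zeros(int(atlas.labels.max()) + 1)
        lut[1:] = rng.uniform(1, 5, len(lut) - 1)
        vol = lut[atlas.labels]
        means = roi_stats.roi_means(vol, atlas).set_index("region")
        ids = atlas.candidates.set_index("name")["region_id"]
        for name in ("pons", "left_precuneus", "right_putamen"):
            assert means.loc[name, "value"] == pytest.approx(lut[ids[name]])

    def test_region_with_no_valid_voxels_is_nan(self, atlas):
        vol = np.ones(atlas.labels.shape)
        validity = atlas.labels != atlas.candidates.set_index("name")["region_id"]["pons"]
        means = roi_stats.roi_means(vol, atlas, validity).set_index("region")
        assert np.isnan(means.loc["pons", "value"])
        assert means.loc["pons", "n_valid"] == 0


def _paired_table(n_sub, bases, values):
    """Long table for paired regions; values[(base, hemi)] is (n_sub,)."""
    rows = []
    for i in range(n_sub):
        sid = f"s{i:02d}"
        for base in bases:
            for hemi in ("left", "right"):
                rows.append((sid, f"{hemi}_{base}", base, hemi, "cmrg_pvc",
                             values[(base, hemi)][i]))
    return pd.DataFrame(rows, columns=["subject_id", "region", "base", "hemisphere",
                                       "measure", "value"])


class TestLateralityMerge:
    def test_identical_sides_are_merged(self):
        v = np.linspace(1, 2, 10)
        table = _paired_table(10, ["cuneus"], {("cuneus", "left"): v, ("cuneus", "right"): v})
        merged, dec = roi_stats.laterality_merge(table)
        assert set(merged["region"]) == {"cuneus"}
        assert dec.iloc[0]["merged"]
        np.testing.assert_allclose(merged.sort_values("subject_id")["value"], v)

    def test_large_offset_keeps_sides_separate(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 0.1, 20)
        table = _paired_table(20, ["cuneus"],
                              {("cuneus", "left"): v + 5.0, ("cuneus", "right"): v})
        merged, dec = roi_stats.laterality_merge(table)
        assert set(merged["region"]) == {"left_cuneus", "right_cuneus"}
        assert not dec.iloc[0]["merged"]

    def test_single_planted_asymmetry_detected_against_oracle(self):
        rng = np.random.default_rng(7)
        bases = ["cuneus", "insula", "lingual"]
        values = {}
        for b in bases:
            v = rng.normal(10, 0.5, 30)
            values[(b, "left")] = v + rng.normal(0, 0.3, 30)
            values[(b, "right")] = v + rng.normal(0, 0.3, 30)
        values[("insula", "left")] = values[("insula", "right")] + 2.0
        table = _paired_table(30, bases, values)
        merged, dec = roi_stats.laterality_merge(table, alpha=0.05)
        dec = dec.set_index("base")
        # independent paired-test recomputation
        for b in bases:
            p_oracle = stats.ttest_rel(values[(b, "left")], values[(b, "right")]).pvalue
            assert dec.loc[b, "p_value"] == pytest.approx(p_oracle)
            assert dec.loc[b, "merged"] == (p_oracle >= 0.05)
        assert not dec.loc["insula", "merged"]
        assert dec.drop("insula")["merged"].all()

    def test_volume_measure_sums_and_weights_cmrg(self):
        rng = np.random.default_rng(4)
        rows = []
        vols, cmrgs = {}, {}
        for i in range(8):
            sid = f"s{i}"
            vl, vr = rng.uniform(100, 300, 2)
            cl, cr = 3.0 + rng.normal(0, 0.2, 2)  # symmetric on average
            vols[sid], cmrgs[sid] = (vl, vr), (cl, cr)
            rows += [
                (sid, "left_cuneus", "cuneus", "left", "volume", vl),
                (sid, "right_cuneus", "cuneus", "right", "volume", vr),
                (sid, "left_cuneus", "cuneus", "left", "cmrg_pvc", cl),
                (sid, "right_cuneus", "cuneus", "right", "cmrg_pvc", cr),
            ]
        table = pd.DataFrame(rows, columns=["subject_id", "region", "base", "hemisphere",
                                            "measure", "value"])
        merged, dec = roi_stats.laterality_merge(table)
        assert dec["merged"].all()
        m = merged.set_index(["subject_id", "measure"])["value"]
        for sid in vols:
            vl, vr = vols[sid]
            cl, cr = cmrgs[sid]
            assert m.loc[(sid, "volume")] == pytest.approx(vl + vr)
            assert m.loc[(sid, "cmrg_pvc")] == pytest.approx((cl * vl + cr * vr) / (vl + vr))

    def test_unpaired_subjects_raise(self):
        v = np.ones(5)
        table = _paired_table(5, ["cuneus"], {("cuneus", "left"): v, ("cuneus", "right"): v})
        table = table.drop(table[(table.subject_id == "s03")
                                 & (table.hemisphere == "right")].index)
        with pytest.raises(ValueError, match="s03"):
            roi_stats.laterality_merge(table)


def _lmg_bruteforce(y, age, sex):
    """LMG shares by explicit enumeration of predictor orderings (statsmodels)."""
    X = {"age": age, "sex": sex}

    def r2(preds):
        if not preds:
            return 0.0
        A = sm.add_constant(np.column_stack([X[p] for p in preds]))
        return sm.OLS(y, A).fit().rsquared

    shares = {p: 0.0 for p in X}
    orders = list(itertools.permutations(X))
    for order in orders:
        so_far = []
        for p in order:
            shares[p] += (r2(so_far + [p]) - r2(so_far)) / len(orders)
            so_far.append(p)
    return shares


class TestRelativeImportance:
    def test_lmg_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        age = rng.uniform(20, 80, 12)
        sex = (rng.random(12) < 0.5).astype(float)
        y = 1.0 - 0.002 * age + 0.05 * sex + rng.normal(0, 0.05, 12)
        res = roi_stats.relative_importance(y, age, sex)
        oracle = _lmg_bruteforce(y, age, sex)
        assert res.r2_age == pytest.approx(oracle["age"], abs=1e-12)
        assert res.r2_sex == pytest.approx(oracle["sex"], abs=1e-12)
        assert res.r2_age + res.r2_sex == pytest.approx(res.total_r2, abs=1e-12)

    def test_p_value_matches_statsmodels_t_test(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(20, 80, 30)
        sex = (rng.random(30) < 0.5).astype(float)
        y = 2.0 - 0.01 * age + rng.normal(0, 0.2, 30)
        res = roi_stats.relative_importance(y, age, sex)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([age, sex]))).fit()
        assert res.p_age == pytest.approx(fit.pvalues[1], rel=1e-10)

    def test_orthogonal_design_share_equals_marginal_r2(self):
        # balanced sex within two age values -> exactly orthogonal predictors
        age = np.repeat([30.0, 70.0], 6)
        sex = np.tile([0.0, 1.0], 6)
        rng = np.random.default_rng(2)
        y = 5 - 0.01 * age + 0.3 * sex + rng.normal(0, 0.1, 12)
        res = roi_stats.relative_importance(y, age, sex)
        A = sm.add_constant(age)
        marginal = sm.OLS(y, A).fit().rsquared
        assert res.r2_age == pytest.approx(marginal, abs=1e-10)

    def test_pure_age_signal_partitions_fully(self):
        age = np.linspace(20, 80, 20)
        sex = np.tile([0.0, 1.0], 10)
        y = 3.0 - 0.005 * age
        res = roi_stats.relative_importance(y, age, sex)
        assert res.r2_age + res.r2_sex == pytest.approx(1.0, abs=1e-9)
        assert res.p_age < 1e-12

    def test_shares_nonnegative_and_permutation_invariant(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(20, 80, 25)
        sex = (rng.random(25) < 0.5).astype(float)
        y = -0.002 * age + rng.normal(0, 0.1, 25)
        res = roi_stats.relative_importance(y, age, sex)
        perm = rng.permutation(25)
        res_p = roi_stats.relative_importance(y[perm], age[perm], sex[perm])
        assert res.r2_age == pytest.approx(res_p.r2_age, rel=1e-10)
        assert res.p_age == pytest.approx(res_p.p_age, rel=1e-10)
        assert res.r2_age >= 0 and res.r2_sex >= -1e-12

    def test_constant_response_flagged(self):
        age = np.linspace(20, 80, 10)
        sex = np.tile([0.0, 1.0], 5)
        res = roi_stats.relative_importance(np.ones(10), age, sex)
        assert res.total_r2 == 0.0 and np.isnan(res.p_age)

    def test_sex_strings_accepted(self):
        age = np.linspace(20, 80, 10)
        sex = np.array(["M", "F"] * 5)
        res = roi_stats.relative_importance(age * 0.01, age, sex)
        assert res.n == 10

    def test_too_few_or_constant_predictors_raise(self):
        with pytest.raises(ValueError):
            roi_stats.relative_importance([1, 2, 3], [20, 30, 40], [0, 1, 0])
        with pytest.raises(ValueError, match="non-constant"):
            roi_stats.relative_importance([1, 2, 3, 4], [20, 30, 40, 50], [1, 1, 1, 1])


class TestRegressAll:
    def test_per_region_results_cover_measures(self):
        rng = np.random.default_rng(0)
        rows = []
        subs = [f"s{i}" for i in range(12)]
        ages = rng.uniform(20, 80, 12)
        sexes = np.where(rng.random(12) < 0.5, "F", "M")
        for region in ("a", "b"):
            for measure in ("cmrg_pvc", "volume"):
                for s, a in zip(subs, ages):
                    rows.append((s, region, measure, 10 - 0.01 * a + rng.normal(0, 0.1)))
        table = pd.DataFrame(rows, columns=["subject_id", "region", "measure", "value"])
        cov = pd.DataFrame({"subject_id": subs, "age": ages, "sex": sexes})
        out = roi_stats.regress_all(table, cov)
        assert len(out) == 4
        assert set(out["measure"]) == {"cmrg_pvc", "volume"}
        assert ((out["r2_age"] + out["r2_sex"] - out["total_r2"]).abs() < 1e-10).all()
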
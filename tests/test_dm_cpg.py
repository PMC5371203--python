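import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cimpscan.dm_cpg import (
    SamParameters,
    choose_s0,
    sam_d_statistic,
    sam_permutation_fdr,
    select_top_k,
)

from _oracles import sam_exhaustive_q


def frame_33(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(values.shape[0])],
        columns=["t1", "t2", "t3", "n1", "n2", "n3"],
    )


LABELS_33 = pd.Series(
    ["tumour"] * 3 + ["normal"] * 3, index=["t1", "t2", "t3", "n1", "n2", "n3"]
)


def fixed_params(s0=0.0, **kw):
    return SamParameters(s0_mode="fixed", s0=s0, **kw)


class TestDStatistic:
    def test_equal_means_give_zero(self):
        X = frame_33([[0.1, 0.2, 0.3, 0.3, 0.2, 0.1]])
        res = sam_d_statistic(X, LABELS_33, fixed_params(s0=0.01))
        assert res.table["d"].iloc[0] == pytest.approx(0.0)

    def test_large_s0_shrinks_d_to_zero(self):
        X = frame_33(np.random.default_rng(1).uniform(0, 1, (20, 6)))
        res = sam_d_statistic(X, LABELS_33, fixed_params(s0=1e9))
        assert np.abs(res.table["d"]).max() < 1e-6

    def test_hand_computed_value(self):
        # tumour (0.5, 0.6, 0.7), normal (0.1, 0.2, 0.3)
        X = frame_33([[0.5, 0.6, 0.7, 0.1, 0.2, 0.3]])
        num = 0.6 - 0.2
        pooled = np.sqrt((1 / 3 + 1 / 3) * (2 * 0.01 + 2 * 0.01) / 4)
        res = sam_d_statistic(X, LABELS_33, fixed_params(s0=0.05))
        assert res.table["d"].iloc[0] == pytest.approx(num / (pooled + 0.05))
        assert res.table["s"].iloc[0] == pytest.approx(pooled)

    def test_antisymmetric_under_label_swap(self):
        X = frame_33(np.random.default_rng(2).uniform(0, 1, (30, 6)))
        flipped = LABELS_33.map({"tumour": "normal", "normal": "tumour"})
        d1 = sam_d_statistic(X, LABELS_33, fixed_params(s0=0.02)).table["d"]
        d2 = sam_d_statistic(X, flipped, fixed_params(s0=0.02)).table["d"]
        assert np.allclose(d1, -d2)

    def test_s0_zero_proportional_to_t_statistic(self):
        X = frame_33(np.random.default_rng(3).uniform(0, 1, (25, 6)))
        d = sam_d_statistic(X, LABELS_33, fixed_params(s0=0.0)).table["d"].values
        t = stats.ttest_ind(
            X[["t1", "t2", "t3"]], X[["n1", "n2", "n3"]], axis=1
        ).statistic
        assert np.allclose(d, t)

    def test_small_group_rejected(self):
        X = pd.DataFrame([[0.1, 0.2, 0.3]], columns=["t1", "n1", "n2"])
        labels = pd.Series(["tumour", "normal", "normal"], index=X.columns)
        with pytest.raises(ValueError):
            sam_d_statistic(X, labels, fixed_params())

    def test_paired_mode_uses_difference_se(self):
        X = frame_33([[0.5, 0.6, 0.7, 0.4, 0.4, 0.4]])
        res = sam_d_statistic(X, LABELS_33, fixed_params(s0=0.0, paired=True))
        diffs = np.array([0.1, 0.2, 0.3])
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert res.table["d"].iloc[0] == pytest.approx(expected)


class TestChooseS0:
    def test_constant_s_returns_constant(self):
        s = np.full(50, 0.7)
        assert choose_s0(s, np.ones(50)) == pytest.approx(0.7)

    def test_median_mode(self):
        assert choose_s0(np.array([1.0, 2.0, 3.0]), np.ones(3), mode="median") == 2.0

    def test_all_zero_gets_floor(self):
        assert choose_s0(np.zeros(10), np.ones(10)) > 0

    def test_cv_mode_damps_scale_dependence(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.001, 0.2, 2000)
        # numerator spread has an s-independent component, so with s0 = 0
        # the statistic blows up at small s; a positive s0 stabilises it
        num = rng.normal(0, 1, 2000) * np.sqrt(s**2 + 0.05**2)
        s0 = choose_s0(s, num, mode="cv_min")
        assert s0 > 0

        def decile_cv(s0_val):
            d = np.abs(num / (s + s0_val))
            order = np.argsort(s)
            mads = [
                np.median(chunk) for chunk in np.array_split(d[order], 10)
            ]
            return np.std(mads) / np.mean(mads)

        assert decile_cv(s0) < decile_cv(0.0)


class TestPermutationFdr:
    def test_matches_exhaustive_enumeration_3v3(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (40, 6))
        X[:5, :3] += 0.8  # strong signal in five probes
        frame = frame_33(np.clip(X, 0, 0.99))
        params = fixed_params(s0=0.01, n_permutations=100, seed=0)  # 100 >= C(6,3)
        res = sam_permutation_fdr(frame, LABELS_33, params)
        assert res.exhaustive
        expected = sam_exhaustive_q(frame.values, 3, 0.01)
        assert np.allclose(res.table["q"].values, expected)

    def test_null_data_q_near_one(self):
        rng = np.random.default_rng(7)
        frame = frame_33(rng.uniform(0.2, 0.8, (300, 6)))
        res = sam_permutation_fdr(frame, LABELS_33, fixed_params(s0=0.01, n_permutations=50, seed=1))
        assert res.table["q"].median() > 0.8

    def test_identical_rows_give_q_one(self):
        frame = frame_33(np.full((10, 6), 0.4))
        res = sam_permutation_fdr(frame, LABELS_33, fixed_params(s0=0.01, n_permutations=30, seed=2))
        assert np.allclose(res.table["d"], 0.0)
        assert np.allclose(res.table["q"], 1.0)

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(8)
        frame = frame_33(rng.uniform(0, 1, (100, 6)))
        res = sam_permutation_fdr(frame, LABELS_33, fixed_params(s0=0.01, n_permutations=60, seed=3))
        t = res.table.sort_values("d", key=lambda c: -c.abs())
        assert (np.diff(t["q"].values) >= -1e-12).all()


class TestTopK:
    def test_boundary_cases_and_sort_oracle(self):
        rng = np.random.default_rng(9)
        frame = frame_33(rng.uniform(0, 1, (10, 6)))
        res = sam_d_statistic(frame, LABELS_33, fixed_params(s0=0.01))
        assert set(select_top_k(res, 10)) == set(frame.index)
        full_sort = (
            res.table.assign(a=res.table["d"].abs())
            .sort_values(["a", "probe_id"], ascending=[False, True])["probe_id"]
            .tolist()
        )
        assert select_top_k(res, 1) == full_sort[:1]
        assert select_top_k(res, 5) == full_sort[:5]
        with pytest.raises(ValueError):
            select_top_k(res, 0)
        with pytest.raises(ValueError):
            select_top_k(res, 11)
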
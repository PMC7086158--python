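from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from nascentkit.proteomics import (
    BinnedIqrParams,
    binned_iqr_outliers,
    filter_rows,
    impute_missing,
    overlap_significance,
    permutation_fdr_ttest,
)
from nascentkit import simulate as sim

from oracles import oracle_binned_boxplot, oracle_hypergeom_tail


class TestRowFilters:
    def _table(self):
        return pd.DataFrame(
            {
                "Score": [39.9, 40.0, 200, 200, 200, 200],
                "Localization prob": [0.9, 0.9, 0.75, 0.76, 0.9, 0.9],
                "PEP": [1e-4, 1e-4, 1e-4, 1e-4, 0.05, 1e-4],
                "Reverse": ["", "", "", "", "", "+"],
                "Potential contaminant": ["", "", "", "", "", ""],
                "Razor + unique peptides": [5, 5, 5, 5, 5, 5],
            },
            index=list("abcdef"),
        )

    def test_stated_boundaries(self):
        kept = filter_rows(self._table())
        # a: score<40 out; b: score==40 kept; c: locprob==0.75 out;
        # e: PEP==0.05 out; f: reverse out
        assert list(kept.index) == ["b", "d"]

    def test_valid_values_in_at_least_one_group(self):
        t = pd.DataFrame(
            {
                "t1": [1.0, np.nan, 1.0],
                "t2": [1.0, np.nan, np.nan],
                "c1": [np.nan, 1.0, np.nan],
                "c2": [np.nan, 1.0, np.nan],
            },
            index=list("xyz"),
        )
        kept = filter_rows(t, groups={"t": ["t1", "t2"], "c": ["c1", "c2"]})
        assert list(kept.index) == ["x", "y"]
        relaxed = filter_rows(
            t, groups={"t": ["t1", "t2"], "c": ["c1", "c2"]}, min_valid=1
        )
        assert list(relaxed.index) == ["x", "y", "z"]

    def test_criteria_are_order_independent(self):
        # applying single-criterion filters in any order gives the same set
        table = self._table()
        cols = ["Score", "Localization prob", "PEP", "Reverse"]
        baseline = set(filter_rows(table).index)
        for order in list(permutations(cols))[:8]:
            t = table
            for c in order:
                sub = table[[c, "Razor + unique peptides",
                             "Potential contaminant"]]
                t = t.loc[t.index.intersection(filter_rows(sub).index)]
            assert set(t.index) == baseline


class TestImputation:
    def _table(self, rng, n=400, missing=0.3):
        vals = 10.0 ** rng.normal(6, 1, size=(n, 2))
        mask = rng.random((n, 2)) < missing
        vals[mask] = np.nan
        return pd.DataFrame(vals, columns=["c1", "c2"])

    def test_no_missing_is_identity(self, rng):
        t = pd.DataFrame({"c1": [1.0, 2.0], "c2": [3.0, 4.0]})
        out, mask = impute_missing(t, ["c1", "c2"], seed=0)
        pd.testing.assert_frame_equal(out, t)
        assert not mask.any().any()

    def test_observed_never_overwritten_and_seed_reproducible(self, rng):
        t = self._table(rng)
        out1, mask = impute_missing(t, ["c1", "c2"], seed=7)
        out2, _ = impute_missing(t, ["c1", "c2"], seed=7)
        pd.testing.assert_frame_equal(out1, out2)
        obs = t.notna()
        pd.testing.assert_frame_equal(out1[obs], t[obs])
        assert (mask == t.isna()).all().all()

    def test_monte_carlo_calibration(self, rng):
        """Imputed log10 values center on the 5% quantile with sd 0.1."""
        t = self._table(rng, n=20_000, missing=0.5)
        observed = np.log10(t.to_numpy()[np.isfinite(t.to_numpy())])
        q05 = np.quantile(observed, 0.05)
        out, mask = impute_missing(t, ["c1", "c2"], seed=1)
        imp = np.log10(out.to_numpy()[mask.to_numpy()])
        n = imp.size
        assert abs(imp.mean() - q05) < 3 * 0.1 / np.sqrt(n)
        assert abs(imp.std() - 0.1) < 0.05 * 0.1


class TestBinnedIqr:
    def _table(self, rng, n, planted=()):
        base = rng.normal(6, 1, n)
        b = 10.0 ** (base + rng.normal(0, 0.1, n))
        c = 10.0 ** (base + rng.normal(0, 0.1, n))
        t = pd.DataFrame({"bait_1": b, "ctrl_1": c})
        for i, shift in planted:
            t.iloc[i, 0] *= 2.0**shift
        return t

    def test_matches_naive_boxplot_oracle(self, rng):
        for n in (250, 1000, 2500):
            t = self._table(rng, n, planted=[(0, 10), (1, -10)])
            if n < 300:
                with pytest.warns(UserWarning, match="single bin"):
                    calls = binned_iqr_outliers(t, ["bait_1"], ["ctrl_1"])
            else:
                calls = binned_iqr_outliers(t, ["bait_1"], ["ctrl_1"])
            want = oracle_binned_boxplot(
                calls["mean_log10_intensity"].to_numpy(),
                calls["mean_log2_ratio"].to_numpy(),
            )
            assert calls["status"].tolist() == want

    def test_planted_extreme_called_and_fence_is_strict(self, rng):
        t = self._table(rng, 600, planted=[(5, 10)])
        calls = binned_iqr_outliers(t, ["bait_1"], ["ctrl_1"])
        assert calls["status"].iloc[5] == "extreme"
        assert calls["enriched"].iloc[5]
        # a ratio exactly on the fence is not an outlier: build a tiny bin
        ratios = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # q1=1, q3=3, iqr=2
        tt = pd.DataFrame(
            {"bait_1": 10.0 ** (ratios * np.log10(2)), "ctrl_1": np.ones(5)}
        )
        with pytest.warns(UserWarning):
            fence = binned_iqr_outliers(
                tt, ["bait_1"], ["ctrl_1"],
                params=BinnedIqrParams(k_potential=0.5, k_extreme=3.0),
            )
        # fence at q3 + 0.5*iqr = 4.0 exactly: strict comparison, no call
        assert fence["status"].iloc[4] == "none"

    def test_shift_invariance_of_calls(self, rng):
        t = self._table(rng, 900, planted=[(3, 9)])
        base = binned_iqr_outliers(t, ["bait_1"], ["ctrl_1"])
        shifted = binned_iqr_outliers(t * 100.0, ["bait_1"], ["ctrl_1"])
        assert (base["status"] == shifted["status"]).all()
        assert (base["bin"] == shifted["bin"]).all()

    def test_bin_sizes_at_least_min_bin(self, rng):
        t = self._table(rng, 1000)
        calls = binned_iqr_outliers(t, ["bait_1"], ["ctrl_1"])
        sizes = calls["bin"].value_counts()
        assert sizes.min() >= 300
        assert calls["bin"].nunique() == 3


class TestPermutationFdr:
    def test_identical_groups_t_zero_not_significant(self):
        t = pd.DataFrame(
            {"a1": [1.0, 5], "a2": [2, 6], "b1": [1, 5], "b2": [2, 6]}
        )
        res = permutation_fdr_ttest(t, ["a1", "a2"], ["b1", "b2"])
        assert res["t_s0"].to_numpy() == pytest.approx(0.0)
        assert not res["significant"].any()

    def test_group_too_small_is_error(self):
        t = pd.DataFrame({"a1": [1.0], "b1": [2.0], "b2": [3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            permutation_fdr_ttest(t, ["a1"], ["b1", "b2"])

    def test_null_pvalues_uniformish_and_few_flags(self, rng):
        x = rng.normal(0, 1, size=(2_000, 8))
        t = pd.DataFrame(x, columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        res = permutation_fdr_ttest(
            t, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)], seed=3
        )
        assert res["significant"].mean() <= 0.02
        # pooled permutation null should make |t| quantiles uniform-ish:
        # compare observed |t| to its own permutation-derived ranks via KS
        # against the empirical null distribution
        from nascentkit.proteomics import _t_s0
        from itertools import combinations as combs

        null = np.concatenate(
            [
                np.abs(
                    _t_s0(x, np.array(c), np.setdiff1d(np.arange(8), c), 0.1)
                )
                for c in combs(range(8), 4)
            ]
        )
        pvals = 1.0 - np.searchsorted(np.sort(null), np.abs(res["t_s0"])) / null.size
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effects_rank_above_null(self, rng):
        """Planted shifts dominate the top of the |t| ranking even when the
        stringent FDR cut flags few of them."""
        x = rng.normal(0, 1, size=(500, 8))
        x[:25, :4] += 3.0
        t = pd.DataFrame(
            x, columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        )
        res = permutation_fdr_ttest(
            t, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)], seed=1
        )
        top50 = np.argsort(-np.abs(res["t_s0"].to_numpy()))[:50]
        assert (np.arange(25)[:, None] == top50[None, :]).any(axis=1).mean() >= 0.8
        assert (res["q"].iloc[:25] < res["q"].iloc[25:].median()).all()

    def test_q_monotone_in_abs_t(self, rng):
        x = rng.normal(0, 1, size=(300, 8))
        x[:10, :4] += 2.0
        t = pd.DataFrame(
            x, columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        )
        res = permutation_fdr_ttest(
            t, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)], seed=2
        )
        srt = res.sort_values("t_s0", key=lambda s: -s.abs())
        assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()


class TestOverlap:
    def test_full_overlap_10_5_5(self):
        a = set(range(5))
        p = overlap_significance(a, a, 10)
        assert p == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_is_certain(self):
        p = overlap_significance({1, 2}, {3, 4}, 10)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(10):
            m = int(rng.integers(4, 13))
            na = int(rng.integers(1, m + 1))
            nb = int(rng.integers(1, m + 1))
            a = set(range(na))
            b = set(rng.choice(m, size=nb, replace=False).tolist())
            p = overlap_significance(a, b, m)
            want = oracle_hypergeom_tail(m, na, nb, len(a & b))
            assert p == pytest.approx(want, rel=1e-9)

    def test_universe_membership_enforced(self):
        with pytest.raises(ValueError, match="subsets"):
            overlap_significance({"x"}, {"y"}, {"y", "z"})
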
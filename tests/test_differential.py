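"""Feature/global/FMF differential testing and p-value aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import secdiff as sd
from conftest import make_traceset


def design_3v3():
    return sd.DesignMatrix(pd.DataFrame({
        "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
        "condition": ["A"] * 3 + ["B"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    }))


def feature(owner="P1", members=("p1", "p2"), left=10, apex=11, right=12):
    return sd.ElutionFeature(owner, list(members), apex, left, right)


class TestFeatureMemberIntensity:
    def test_direct_sum_over_boundaries(self):
        t = np.zeros((1, 20))
        t[0, 9:12] = [1.0, 2.0, 3.0]
        tr = make_traceset({"p1": t, "p2": t})
        rng = np.random.default_rng(0)
        members, table, _ = sd.feature_member_intensity(
            feature(), tr, rng)
        assert table.loc["p1", "s1"] == pytest.approx(6.0)

    def test_missing_member_imputed_below_min(self):
        a = np.full((2, 20), np.nan)
        a[0, 9:13] = 8.0      # sample 1 detected, min signal 8
        tr = make_traceset({"p1": a, "p2": np.abs(a) * 2})
        rng = np.random.default_rng(1)
        members, table, block = sd.feature_member_intensity(
            feature(right=13), tr, rng)
        # sample 2 entirely imputed: each cell in [0, 8)
        imputed = block[0, 1, :]
        assert np.all((imputed >= 0) & (imputed < 8.0))

    def test_equals_loop_oracle(self):
        rng_data = np.random.default_rng(5)
        data = rng_data.lognormal(3, 1, size=(3, 2, 20))
        tr = sd.PeptideTraceSet(data, ["p1", "p2", "p3"], ["P1"] * 3,
                                ["s1", "s2"])
        members, table, _ = sd.feature_member_intensity(
            feature(members=("p1", "p2", "p3"), left=5, apex=7, right=9),
            tr, np.random.default_rng(0))
        for i, p in enumerate(members):
            for s in range(2):
                expected = sum(data[i, s, f] for f in range(4, 9))
                assert table.iloc[i, s] == pytest.approx(expected)


class TestImputeDifferential:
    def _traces(self):
        data = np.full((1, 2, 10), np.nan)
        data[0, 0, 2:6] = [8.0, 12.0, 9.0, 20.0]
        return sd.PeptideTraceSet(data, ["p1"], ["P1"], ["s1", "s2"])

    def test_values_in_range_and_deterministic(self):
        tr = self._traces()
        k1, b1 = sd.impute_differential(tr, ["p1"], np.random.default_rng(7))
        k2, b2 = sd.impute_differential(tr, ["p1"], np.random.default_rng(7))
        assert np.array_equal(b1, b2)
        filled = b1[0][np.isnan(tr.data[0])]
        assert np.all((filled >= 0) & (filled < 8.0))

    def test_never_detected_member_excluded(self):
        data = np.full((2, 1, 5), np.nan)
        data[0, 0] = 1.0
        tr = sd.PeptideTraceSet(data, ["p1", "p2"], ["P1"] * 2, ["s1"])
        kept, _ = sd.impute_differential(tr, ["p1", "p2"],
                                         np.random.default_rng(0))
        assert kept == ["p1"]

    def test_uniform_distribution(self):
        data = np.full((1, 1, 10000), np.nan)
        data[0, 0, 0] = 5.0
        tr = sd.PeptideTraceSet(data, ["p1"], ["P1"], ["s1"])
        _, block = sd.impute_differential(tr, ["p1"],
                                          np.random.default_rng(123))
        draws = block[0, 0, 1:]
        assert stats.kstest(draws / 5.0, "uniform").pvalue > 0.01


class TestFeatureDifferential:
    def _dataset(self, mult_a=1.0, mult_b=1.0, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        x = np.arange(1, 31, dtype=float)
        peak = 100 * np.exp(-0.5 * ((x - 15) / 2) ** 2)
        arrays = {}
        for p, factor in [("p1", 1.0), ("p2", 2.0)]:
            samples = []
            for mult in [mult_a] * 3 + [mult_b] * 3:
                noise_mult = rng.lognormal(0, noise) if noise else 1.0
                samples.append(peak * factor * mult * noise_mult)
            arrays[p] = np.vstack(samples)
        return make_traceset(arrays, {"p1": "P1", "p2": "P1"},
                             sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"])

    def test_exact_fourfold_change(self):
        tr = self._dataset(mult_a=4.0, mult_b=1.0)
        r = sd.feature_differential(feature(left=10, apex=15, right=20), tr,
                                    design_3v3(), "A", "B",
                                    rng=np.random.default_rng(0))
        assert r.log2fc == pytest.approx(2.0, abs=1e-9)

    def test_identical_groups_null(self):
        tr = self._dataset()
        r = sd.feature_differential(feature(left=10, apex=15, right=20), tr,
                                    design_3v3(), "A", "B",
                                    rng=np.random.default_rng(0))
        assert r.log2fc == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self):
        tr = self._dataset(mult_a=3.0, mult_b=1.0, noise=0.1, seed=4)
        f = feature(left=10, apex=15, right=20)
        r_ab = sd.feature_differential(f, tr, design_3v3(), "A", "B",
                                       rng=np.random.default_rng(0))
        r_ba = sd.feature_differential(f, tr, design_3v3(), "B", "A",
                                       rng=np.random.default_rng(0))
        assert r_ab.log2fc == pytest.approx(-r_ba.log2fc)
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    def test_welch_p_matches_direct_ttest(self):
        tr = self._dataset(mult_a=2.0, mult_b=1.0, noise=0.15, seed=8)
        f = feature(members=("p1",), left=10, apex=15, right=20)
        r = sd.feature_differential(f, tr, design_3v3(), "A", "B",
                                    rng=np.random.default_rng(0))
        sums = tr.data[0, :, 9:20].sum(axis=1)
        expected = stats.ttest_ind(sums[:3], sums[3:], equal_var=False)[1]
        assert r.p_value == pytest.approx(expected)  # m=1: Beta(1,1) identity


class TestGlobalVsFeature:
    def test_uniform_scaling_equal_everywhere(self):
        x = np.arange(1, 31, dtype=float)
        peak = 100 * np.exp(-0.5 * ((x - 15) / 2) ** 2)
        arrays = {p: np.vstack([peak * f * 2] * 3 + [peak * f] * 3)
                  for p, f in [("p1", 1.0), ("p2", 1.5)]}
        tr = make_traceset(arrays, {"p1": "P1", "p2": "P1"},
                           sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"])
        rf = sd.feature_differential(feature(left=12, apex=15, right=18), tr,
                                     design_3v3(), "A", "B",
                                     rng=np.random.default_rng(0))
        rg = sd.global_differential("P1", tr, design_3v3(), "A", "B",
                                    rng=np.random.default_rng(0),
                                    protein_peptides=["p1", "p2"])
        assert rf.log2fc == pytest.approx(1.0, abs=1e-9)
        assert rg.log2fc == pytest.approx(1.0, abs=1e-9)

    def test_redistribution_nulls_global_but_not_features(self):
        # mass moves between two peaks; total constant
        x = np.arange(1, 41, dtype=float)
        g1 = np.exp(-0.5 * ((x - 10) / 1.5) ** 2)
        g2 = np.exp(-0.5 * ((x - 28) / 1.5) ** 2)
        cond_a = 800 * g1 + 200 * g2
        cond_b = 200 * g1 + 800 * g2
        arrays = {p: np.vstack([cond_a * f] * 3 + [cond_b * f] * 3)
                  for p, f in [("p1", 1.0), ("p2", 1.3)]}
        tr = make_traceset(arrays, {"p1": "P1", "p2": "P1"},
                           sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"])
        rg = sd.global_differential("P1", tr, design_3v3(), "A", "B",
                                    rng=np.random.default_rng(0),
                                    protein_peptides=["p1", "p2"])
        f1 = feature(left=5, apex=10, right=15)
        f2 = feature(left=23, apex=28, right=33)
        r1 = sd.feature_differential(f1, tr, design_3v3(), "A", "B",
                                     rng=np.random.default_rng(0))
        r2 = sd.feature_differential(f2, tr, design_3v3(), "A", "B",
                                     rng=np.random.default_rng(0))
        assert abs(rg.log2fc) < 0.05
        assert r1.log2fc == pytest.approx(2.0, abs=0.05)
        assert r2.log2fc == pytest.approx(-2.0, abs=0.05)
        # and the FMF view flags the rewiring
        y1 = sd.compute_fmf(f1, tr)
        diff = y1.loc["p1", ["a1", "a2", "a3"]].mean() - \
            y1.loc["p1", ["b1", "b2", "b3"]].mean()
        assert abs(diff) >= 0.3


class TestComputeFMF:
    def test_feature_spanning_grid_is_one(self):
        tr = make_traceset({"p1": np.ones((1, 10))})
        f = feature(members=("p1",), left=1, apex=5, right=10)
        assert sd.compute_fmf(f, tr).iloc[0, 0] == 1.0

    def test_half_signal_inside(self):
        t = np.zeros((1, 10))
        t[0, :4] = 5.0
        t[0, 6:8] = 10.0
        tr = make_traceset({"p1": t})
        f = feature(members=("p1",), left=7, apex=7, right=8)
        assert sd.compute_fmf(f, tr).iloc[0, 0] == pytest.approx(0.5)

    def test_zero_total_excluded(self):
        t = np.full((2, 10), np.nan)
        t[0, 2:5] = 3.0
        tr = make_traceset({"p1": t})
        f = feature(members=("p1",), left=1, apex=3, right=6)
        vals = sd.compute_fmf(f, tr)
        assert np.isfinite(vals.iloc[0, 0])
        assert np.isnan(vals.iloc[0, 1])


class TestAggregateToParent:
    def test_single_member_identity(self):
        fc, p = sd.aggregate_to_parent([1.7], [0.034])
        assert fc == 1.7 and p == pytest.approx(0.034, abs=1e-12)

    def test_three_concordant_closed_form(self):
        fc, p = sd.aggregate_to_parent([2.0, 2.1, 1.9], [0.01, 0.02, 0.03])
        # j=2 of m=3: Beta(2,2) CDF at the median 0.02 = 3x^2 - 2x^3
        assert p == pytest.approx(3 * 0.02**2 - 2 * 0.02**3, abs=1e-9)
        assert fc == pytest.approx(2.0)

    def test_discordant_member_p_flipped(self):
        # discordant member's tiny p becomes 1-p and lands at the top
        fc, p = sd.aggregate_to_parent([2.0, 1.8, -2.0], [0.5, 0.5, 0.001])
        adj = sorted([0.5, 0.5, 0.999])
        expected = stats.beta.cdf(adj[1], 2, 2)
        assert p == pytest.approx(expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        fcs = rng.normal(0, 2, 7)
        ps = rng.uniform(0, 1, 7)
        ref = sd.aggregate_to_parent(fcs, ps)
        for _ in range(5):
            perm = rng.permutation(7)
            assert sd.aggregate_to_parent(fcs[perm], ps[perm]) == \
                pytest.approx(ref)

    def test_monotone_in_concordant_p(self):
        fcs = [1.0, 1.2, 0.8]
        _, p_hi = sd.aggregate_to_parent(fcs, [0.2, 0.3, 0.4])
        _, p_lo = sd.aggregate_to_parent(fcs, [0.05, 0.3, 0.4])
        assert p_lo <= p_hi

    def test_null_calibration_uniform(self):
        # independent uniform member p-values with random signs -> the
        # aggregated p is uniform (order-statistic null is exact here)
        rng = np.random.default_rng(99)
        agg = []
        for _ in range(4000):
            m = 3
            ps = rng.uniform(0, 1, m)
            fcs = rng.choice([-1.0, 1.0], m) * rng.uniform(0.5, 2, m)
            agg.append(sd.aggregate_to_parent(fcs, ps)[1])
        assert stats.kstest(agg, "uniform").pvalue > 0.01

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            sd.aggregate_to_parent([], [])


class TestDifferentialTable:
    def test_bh_and_thresholds(self):
        results = [
            sd.DifferentialResult("e1", "feature", log2fc=2.0, p_value=0.001),
            sd.DifferentialResult("e2", "feature", log2fc=0.5, p_value=0.001),
            sd.DifferentialResult("e3", "feature", log2fc=3.0, p_value=0.9),
        ]
        sd.differential_table(results)
        assert results[0].significant
        assert not results[1].significant  # |log2FC| < 1
        assert not results[2].significant  # adjusted p > 0.05
        for r in results:
            assert r.adjusted_p >= r.p_value - 1e-12
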
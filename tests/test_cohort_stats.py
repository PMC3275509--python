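import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from suturelax import (
    CollagenMeasurement,
    PhaseMetrics,
    SensorConfig,
    ZeroVarianceError,
    collagen_correlations,
    kruskal_wallis,
    mann_whitney,
    pearson_correlation,
    segment_phases,
    simulate_cohort,
    summarize_by_tissue,
)


def brute_force_mw_p(x, y):
    """Independent exact oracle: enumerate all index splits of the pool."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    mu = nx * len(y) / 2.0

    def u_of(ix):
        a = pooled[list(ix)]
        b = np.delete(pooled, list(ix))
        return (a[:, None] > b[None, :]).sum() + 0.5 * (
            a[:, None] == b[None, :]
        ).sum()

    dev_obs = abs(u_of(range(nx)) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_of(combo) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def brute_force_kw_p(groups):
    """Independent exact oracle via scipy's H on every label permutation."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_of(perm):
        parts = []
        i = 0
        for s in sizes:
            parts.append(perm[i:i + s])
            i += s
        try:
            return sps.kruskal(*parts).statistic
        except ValueError:  # all values identical
            return 0.0

    h_obs = h_of(pooled)
    hits = total = 0
    for perm in itertools.permutations(pooled):
        total += 1
        if h_of(np.asarray(perm)) >= h_obs - 1e-12:
            hits += 1
    return hits / total


class TestKruskalWallis:
    def test_two_separated_groups_exact(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        # H for ranks {1,2,3} vs {4,5,6}: 12/42*(36/3+225/3)-21
        assert res.statistic == pytest.approx(12 / 42 * 87 - 21)
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact_permutation"

    def test_identically_patterned_groups_near_one(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.p_value > 0.9

    def test_all_equal_degenerate(self):
        res = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "groups",
        [
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
            ([1.0, 1.0, 2.0], [2.0, 3.0, 3.0]),
            ([5.0, 1.0], [2.0, 2.0], [4.0, 3.0]),
            ([1.0, 2.0], [2.0, 2.0, 4.0], [5.0, 1.0]),
        ],
    )
    def test_exact_p_matches_brute_force(self, groups):
        res = kruskal_wallis(groups)
        assert res.p_value == pytest.approx(brute_force_kw_p(
            [np.asarray(g) for g in groups]))

    def test_large_sample_uses_chi_square(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 1.0)]
        res = kruskal_wallis(groups)
        assert res.method == "chi2"
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_rejects_empty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0  # U counts x > y pairs
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == 9 / 2  # ties counted half: n^2/2
        assert res.p_value == pytest.approx(1.0)

    def test_swap_symmetry(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0]
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.statistic + b.statistic == len(x) * len(y)
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 1, 2], [2, 3, 3]),
            ([1, 5, 3, 3], [2, 2]),
            ([0.5, 0.5, 0.5], [0.5, 0.5]),
        ],
    )
    def test_exact_p_matches_brute_force(self, x, y):
        res = mann_whitney(x, y)
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(
            brute_force_mw_p(np.asarray(x, float), np.asarray(y, float))
        )

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        res = mann_whitney(x, y)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_tissue_mean_collagen_vs_rcp_loss(self):
        # hand-computed product-moment r on the five per-tissue means
        r, p, n = pearson_correlation([25, 45, 49, 43, 44],
                                      [34, 16, 18, 27, 17])
        assert n == 5
        assert r == pytest.approx(-0.8665, abs=0.001)

    def test_zero_variance_flagged(self):
        with pytest.raises(ZeroVarianceError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 50),
        shift=st.floats(-100, 100),
    )
    def test_affine_invariance_positive_slope(self, scale, shift):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        r0, _, _ = pearson_correlation(x, y)
        r1, _, _ = pearson_correlation(scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-9)


def metrics_row(sid, tissue, p0=2.0, p1=1.5, pplat=1.0, ht=20.0,
                censored=False):
    return PhaseMetrics(
        suture_id=sid, tissue=tissue, p0=p0, p1=p1, pplat=pplat,
        rcp_loss_pct=100 * (p0 - p1) / p0,
        plateau_ratio_pct=100 * pplat / p0,
        half_time_min=ht, half_time_censored=censored,
    )


class TestCollagenCorrelations:
    def test_constant_collagen_flagged_invalid(self):
        metrics = [metrics_row(f"s{i}", "liver", p1=1.5 - 0.05 * i)
                   for i in range(6)]
        collagen = [CollagenMeasurement(f"s{i}", "liver", 25.0)
                    for i in range(6)]
        records = collagen_correlations(metrics, collagen)
        pooled = [r for r in records if r.level == "sutures"]
        assert pooled and all(not r.valid for r in pooled)

    def test_orphan_ids_rejected(self):
        metrics = [metrics_row("a", "liver"), metrics_row("b", "liver"),
                   metrics_row("c", "liver")]
        collagen = [CollagenMeasurement("a", "liver", 25.0),
                    CollagenMeasurement("z", "liver", 30.0)]
        with pytest.raises(ValueError, match="unmatched"):
            collagen_correlations(metrics, collagen)

    def test_reference_cohort_signs(self):
        sensor = SensorConfig(sampling_hz=50.0)
        traces, _, collagen = simulate_cohort(sensor=sensor, seed=123)
        metrics = [segment_phases(t) for t in traces]
        records = {(r.y_name, r.level): r
                   for r in collagen_correlations(metrics, collagen)}
        assert records[("rcp_loss_pct", "sutures")].r < 0
        assert records[("plateau_ratio_pct", "sutures")].r > 0
        assert records[("rcp_loss_pct", "sutures")].n == 30


class TestSummarize:
    def test_identical_rows_zero_sd(self):
        metrics = [metrics_row(f"s{i}", "liver") for i in range(6)]
        summary = summarize_by_tissue(metrics)
        row = summary.table.loc["liver"]
        assert row["p0_sd"] == 0.0
        assert row["rcp_loss_pct_sd"] == 0.0
        assert row["n"] == 6

    def test_single_suture_missing_sd_and_no_tests(self):
        metrics = [metrics_row("a", "liver"), metrics_row("b", "skin")]
        with pytest.warns(UserWarning, match="skipped"):
            summary = summarize_by_tissue(metrics)
        assert np.isnan(summary.table.loc["liver", "p0_sd"])
        assert summary.omnibus == {}
        assert "tests_skipped_insufficient_n" in summary.flags

    def test_all_censored_tissue_rendered_as_lower_bound(self):
        metrics = [metrics_row(f"l{i}", "liver", ht=20.0) for i in range(3)]
        metrics += [metrics_row(f"k{i}", "skin", ht=60.0, censored=True)
                    for i in range(3)]
        summary = summarize_by_tissue(metrics, record_min=60.0)
        md = summary.to_markdown()
        assert "> 60" in md
        assert np.isnan(summary.table.loc["skin", "half_time_mean"])
        assert summary.table.loc["skin", "half_time_censored_n"] == 3

    def test_zero_sd_noiseless_cohort_recovers_generator_values(self,
                                                                profiles):
        zeroed = [p.with_zero_sds() for p in profiles.values()]
        sensor = SensorConfig(sampling_hz=10.0, noise_sd_n=0.0)
        traces, truth, collagen = simulate_cohort(
            n_per_tissue=3, mode="absolute", sensor=sensor, seed=0,
            profiles=zeroed,
        )
        metrics = [segment_phases(t) for t in traces]
        summary = summarize_by_tissue(metrics, collagen=collagen)
        for profile in zeroed:
            row = summary.table.loc[profile.tissue]
            assert row["p0_mean"] == pytest.approx(profile.p0_mean, abs=0.01)
            assert row["pplat_mean"] == pytest.approx(
                profile.pplat_mean, abs=0.01 * profile.p0_mean
            )
            assert row["collagen_mean"] == pytest.approx(
                profile.collagen_mean, abs=1e-9
            )
            assert row["p0_sd"] == pytest.approx(0.0, abs=1e-6)
        # pairwise tests only where the omnibus is significant
        for metric, pairs in summary.pairwise.items():
            assert summary.omnibus[metric].p_value < 0.05
            assert len(pairs) == 10
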
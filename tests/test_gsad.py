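"""Comonotonic aggregation, gSAD construction, skewness machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import avabund as av
from avabund.abundance import AbundanceDistribution
from avabund.gsad import quantile_resample_skewness


def dist(species_id, draws):
    return AbundanceDistribution.from_draws(species_id, np.asarray(draws,
                                                                   dtype=float))


def brute_skew(x, t=3):
    """Independent moment-formula oracle for the skewness."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m2 = np.sum((x - x.mean()) ** 2) / n
    m3 = np.sum((x - x.mean()) ** 3) / n
    g1 = m3 / m2 ** 1.5
    if t == 1:
        return g1
    if t == 2:
        return g1 * np.sqrt(n * (n - 1)) / (n - 2)
    return g1 * ((n - 1) / n) ** 1.5


class TestComonotonicSum:
    def test_hand_sum(self):
        tot = av.comonotonic_sum([dist("a", [3, 1, 2]), dist("b", [30, 10, 20])])
        assert list(tot.draws) == [11, 22, 33]
        assert tot.median == 22

    def test_single_distribution_identity(self):
        d = dist("a", [5.0, 1.0, 3.0])
        tot = av.comonotonic_sum([d])
        assert np.allclose(tot.draws, np.sort(d.draws))

    def test_mismatched_draws_rejected(self):
        with pytest.raises(ValueError):
            av.comonotonic_sum([dist("a", [1, 2]), dist("b", [1, 2, 3])])

    def test_quantile_additivity_random(self):
        rng = np.random.default_rng(0)
        dists = [dist(f"s{i}", rng.lognormal(2, 1, 200)) for i in range(50)]
        tot = av.comonotonic_sum(dists)
        for q in (0.025, 0.1, 0.5, 0.9, 0.975):
            part = sum(np.quantile(np.sort(d.draws), q) for d in dists)
            assert tot.median if q == 0.5 else True
            assert np.quantile(tot.draws, q) == pytest.approx(part, rel=1e-12)
        assert tot.median == pytest.approx(
            sum(np.median(d.draws) for d in dists), rel=1e-12)


class TestBuildGsad:
    def test_zero_becomes_zero_log(self):
        assert av.build_gsad([0.0])[0] == 0.0

    def test_log10_values(self):
        got = av.build_gsad([1e6, 10.0, 0.0, 1.0])
        assert np.allclose(got, [6.0, 1.0, 0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            av.build_gsad([-1.0])


class TestSkewness:
    def test_symmetric_zero(self):
        assert av.skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_type3(self):
        """(1,1,1,5): g1 = 6/3^1.5, type-3 factor (3/4)^1.5 -> 0.75."""
        assert av.skewness([1, 1, 1, 5], estimator_type=3) == \
            pytest.approx(0.75, abs=1e-12)
        assert av.skewness([1, 1, 1, 5], estimator_type=1) == \
            pytest.approx(6 / 3 ** 1.5, abs=1e-12)

    def test_antisymmetry(self):
        x = [0.3, 1.1, 4.2, 0.9, 2.0]
        for t in (1, 2, 3):
            assert av.skewness([-v for v in x], t) == \
                pytest.approx(-av.skewness(x, t), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            av.skewness([1.0, 2.0])
        with pytest.raises(ValueError):
            av.skewness([2.0, 2.0, 2.0])

    @given(hnp.arrays(np.float64, st.integers(5, 60),
                      elements=st.floats(-50, 50)))
    @settings(deadline=None, max_examples=150)
    def test_matches_brute_force_moments(self, x):
        if np.var(x) < 1e-8:
            return
        for t in (1, 2, 3):
            assert av.skewness(x, t) == pytest.approx(brute_skew(x, t),
                                                      abs=1e-10, rel=1e-10)


@pytest.fixture(scope="module")
def skew_world():
    """Left-skewed log-abundance world with a nested grouping table.

    Rarity is clustered at the clade level (whole orders/families can be
    rare), so group sums inherit the extra rare mass and the log left skew
    persists — weakened — up the taxonomy.
    """
    rng = np.random.default_rng(3)
    n = 240
    genus_idx = np.arange(n) // 3       # 80 genera of 3 species
    family_idx = np.arange(n) // 12     # 20 families of 12
    order_idx = np.arange(n) // 48      # 5 orders of 48

    def skewed_effect(k, scale=0.6, rare_frac=0.3, rare_scale=1.8):
        e = rng.normal(0.0, scale, k)
        rare = rng.random(k) < rare_frac
        e[rare] -= rng.exponential(rare_scale, rare.sum())
        return e

    logs = (5.0 + skewed_effect(5)[order_idx]
            + skewed_effect(20)[family_idx]
            + skewed_effect(80)[genus_idx]
            + skewed_effect(n))
    meds = 10 ** logs
    dists = [
        AbundanceDistribution.from_draws(
            f"s{i}", meds[i] * 10 ** rng.normal(0, 0.3, 400))
        for i in range(n)
    ]
    grouping = pd.DataFrame({
        "species_id": [f"s{i}" for i in range(n)],
        "genus": [f"g{g}" for g in genus_idx],
        "family": [f"f{f}" for f in family_idx],
        "order": [f"o{o}" for o in order_idx],
    })
    return dists, grouping


class TestQuantileResample:
    def test_degenerate_distributions_zero_width(self, skew_world):
        _, grouping = skew_world
        rng = np.random.default_rng(1)
        meds = 10 ** rng.normal(5, 1, 120)
        dists = [dist(f"s{i}", np.full(200, meds[i])) for i in range(120)]
        rep = quantile_resample_skewness(dists, grouping, reps=50, seed=2)
        for lv in ("species", "genus", "family", "order"):
            lo, hi = rep[lv].resampled_ci95
            assert hi - lo == pytest.approx(0.0, abs=1e-12)
            assert rep[lv].resampled_mean == pytest.approx(rep[lv].point)

    def test_left_skew_at_every_level(self, skew_world):
        dists, grouping = skew_world
        rep = quantile_resample_skewness(dists, grouping, reps=300, seed=4)
        for lv in ("species", "genus", "family", "order"):
            assert rep[lv].resampled_mean < 0, lv
            assert rep[lv].point < 0, lv

    def test_seed_determinism(self, skew_world):
        dists, grouping = skew_world
        a = quantile_resample_skewness(dists, grouping, reps=100, seed=9)
        b = quantile_resample_skewness(dists, grouping, reps=100, seed=9)
        for lv in a:
            assert a[lv].resampled_mean == b[lv].resampled_mean
            assert a[lv].resampled_ci95 == b[lv].resampled_ci95

    def test_missing_species_in_grouping_rejected(self, skew_world):
        dists, grouping = skew_world
        with pytest.raises(ValueError, match="missing species"):
            quantile_resample_skewness(dists, grouping.iloc[:-5], reps=10,
                                       seed=0)


class TestBootstrap:
    def test_ci_brackets_point_outlier_vector(self):
        x = np.r_[np.full(20, 2.0), 9.0] + np.linspace(0, 0.01, 21)
        point = av.skewness(x)
        lo, hi = av.bootstrap_skewness_ci(x, B=200, seed=5)
        assert lo <= point <= hi

    def test_single_resample_degenerate_interval(self):
        x = [1.0, 2.0, 5.0, 0.5, 3.0]
        lo, hi = av.bootstrap_skewness_ci(x, B=1, seed=6)
        assert lo == hi

    def test_seed_determinism(self):
        x = np.random.default_rng(7).normal(size=40)
        assert av.bootstrap_skewness_ci(x, B=100, seed=8) == \
            av.bootstrap_skewness_ci(x, B=100, seed=8)


class TestGroupSummaries:
    def test_one_group_equals_global(self, skew_world):
        dists, grouping = skew_world
        g = grouping.assign(all="world")
        out = av.group_summaries(dists, g, by="all")
        tot = av.comonotonic_sum(dists)
        assert out.loc[0, "median"] == pytest.approx(tot.median)

    def test_disjoint_groups_sum_to_global_median(self, skew_world):
        dists, grouping = skew_world
        half = {d.species_id: ("left" if i < 60 else "right")
                for i, d in enumerate(dists)}
        g = grouping.assign(side=grouping["species_id"].map(half))
        out = av.group_summaries(dists, g, by="side").set_index("side")
        tot = av.comonotonic_sum(dists)
        assert out["median"].sum() == pytest.approx(tot.median, rel=1e-12)

    def test_unlabeled_species_rejected(self, skew_world):
        dists, grouping = skew_world
        g = grouping.iloc[:-1]
        with pytest.raises(ValueError):
            av.group_summaries(dists, g, by="genus")

    def test_empty_group_label_absent(self, skew_world):
        dists, grouping = skew_world
        g = grouping.copy()
        g["guild"] = "a"
        out = av.group_summaries(dists, g, by="guild")
        assert set(out["guild"]) == {"a"}  # no phantom groups
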
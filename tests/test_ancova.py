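"""Slope/intercept ANCOVA against explicit RSS-comparison oracles."""

from dataclasses import replace

import numpy as np
import pytest

from reservesar import (
    pairwise_intercepts,
    subset_group,
    test_intercept_differences as intercept_differences_test,
    test_slope_homogeneity as slope_homogeneity_test,
)
from reservesar.data import GroupDataset


def make_dataset(name, x, y):
    """Minimal transformed GroupDataset with log-area as sole predictor."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    import pandas as pd

    return GroupDataset(
        group=name,
        reserve_ids=tuple(range(1, len(x) + 1)),
        response=y,
        predictors={"log_area": x},
        raw=pd.DataFrame({"area_km2": 10.0**x}),
        plus_one_response=False,
    )


def random_groups(rng, n_groups=3):
    out = []
    for i in range(n_groups):
        n = int(rng.integers(5, 12))
        x = rng.normal(size=n)
        y = rng.normal(0.5, 1.0) + rng.normal(0.2, 0.3) * x + rng.normal(0, 0.4, n)
        out.append(make_dataset(f"g{i}", x, y))
    return out


def stacked_designs(datasets):
    """Dummy designs built independently of the implementation's internals."""
    x = np.concatenate([d.predictors["log_area"] for d in datasets])
    y = np.concatenate([d.response for d in datasets])
    g = np.concatenate([np.full(d.n, i) for i, d in enumerate(datasets)])
    D = np.column_stack([(g == i).astype(float) for i in range(len(datasets))])
    sep = np.column_stack([D, D * x[:, None]])
    common = np.column_stack([D, x])
    single = np.column_stack([np.ones(len(y)), x])
    return y, sep, common, single


class TestOverallTests:
    def test_duplicated_group_has_exactly_zero_slope_f(self, reserves):
        ds = subset_group(reserves, "Carabidae")
        res = slope_homogeneity_test([ds, replace(ds, group="copy")])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_group_has_exactly_zero_intercept_f(self, reserves):
        ds = subset_group(reserves, "Carabidae")
        res = intercept_differences_test([ds, replace(ds, group="copy")])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_rss_oracle_on_random_instances(self, ancova_oracle):
        rng = np.random.default_rng(7)
        for _ in range(50):
            groups = random_groups(rng, n_groups=int(rng.integers(2, 5)))
            y, sep, common, single = stacked_designs(groups)
            f_s, p_s = ancova_oracle(y, sep, common)
            f_i, p_i = ancova_oracle(y, common, single)
            slope = slope_homogeneity_test(groups)
            inter = intercept_differences_test(groups)
            assert slope.f_statistic == pytest.approx(f_s, rel=1e-9)
            assert slope.p_value == pytest.approx(p_s, rel=1e-9)
            assert inter.f_statistic == pytest.approx(f_i, rel=1e-9)
            assert inter.p_value == pytest.approx(p_i, rel=1e-9)

    def test_degrees_of_freedom(self, trophic_datasets):
        res = slope_homogeneity_test(trophic_datasets)
        n = sum(d.n for d in trophic_datasets)
        assert res.df_num == len(trophic_datasets) - 1
        assert res.df_den == n - 2 * len(trophic_datasets)

    def test_relabelling_groups_leaves_f_unchanged(self):
        rng = np.random.default_rng(3)
        groups = random_groups(rng)
        shuffled = [groups[2], groups[0], groups[1]]
        assert slope_homogeneity_test(groups).f_statistic == pytest.approx(
            slope_homogeneity_test(shuffled).f_statistic
        )

    def test_shifting_one_group_moves_intercepts_not_slopes(self):
        rng = np.random.default_rng(4)
        groups = random_groups(rng)
        shifted = [groups[0], groups[1], replace(groups[2], response=groups[2].response + 1.5)]
        assert slope_homogeneity_test(shifted).f_statistic == pytest.approx(
            slope_homogeneity_test(groups).f_statistic, rel=1e-9
        )
        assert intercept_differences_test(shifted).f_statistic != pytest.approx(
            intercept_differences_test(groups).f_statistic, rel=1e-6
        )

    def test_fewer_than_two_groups_rejected(self, trophic_datasets):
        with pytest.raises(ValueError, match="two groups"):
            slope_homogeneity_test(trophic_datasets[:1])

    def test_tiny_group_rejected(self):
        good = make_dataset("a", [0, 1, 2, 3], [0.1, 1.2, 1.9, 3.1])
        tiny = make_dataset("b", [0, 1], [0.0, 1.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            slope_homogeneity_test([good, tiny])


class TestPairwise:
    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(11)
        a, b = random_groups(rng, 2)
        res_ab = intercept_differences_test([a, b])
        res_ba = intercept_differences_test([b, a])
        assert res_ab.f_statistic == pytest.approx(res_ba.f_statistic, rel=1e-9)

    def test_identical_pair_never_significant(self, reserves):
        ds = subset_group(reserves, "Tenebrionidae")
        comps, _, _ = pairwise_intercepts(
            [ds, replace(ds, group="copy")], alpha=0.9999
        )
        assert len(comps) == 1
        assert not comps[0].significant

    def test_constructed_intercept_ties_are_detected(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 3, 12)

        def grp(name, intercept):
            return make_dataset(name, x, intercept + 0.3 * x + rng.normal(0, 0.01, 12))

        groups = [grp("a", 1.0), grp("b", 1.0), grp("c", 2.0)]
        comps, ordering, text = pairwise_intercepts(groups)
        sig = {frozenset((c.group_a, c.group_b)): c.significant for c in comps}
        assert not sig[frozenset(("a", "b"))]
        assert sig[frozenset(("a", "c"))] and sig[frozenset(("b", "c"))]
        assert ordering[0] == "c"

    def test_holm_correction_is_no_less_conservative(self, trophic_datasets):
        raw, _, _ = pairwise_intercepts(trophic_datasets)
        holm, _, _ = pairwise_intercepts(trophic_datasets, holm=True)
        assert sum(c.significant for c in holm) <= sum(c.significant for c in raw)
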
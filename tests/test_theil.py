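"""Theil statistic and decomposition: frozen oracle cases plus invariants.

The independent oracle for the grouped decomposition is the ungrouped
brute-force sum Σ p_i·ln(p_i/y_i); by the decomposition theorem the grouped
total must equal it exactly.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healtheil import theil as th
from healtheil.data_model import ProvinceRecord, ResourcePanel


def brute_force_theil(populations, amounts):
    """Direct evaluation from raw amounts — reference for everything else."""
    p = np.asarray(populations, float)
    y = np.asarray(amounts, float)
    p, y = p / p.sum(), y / y.sum()
    return float(np.sum(p * np.log(p / y)))


def make_panel(populations, amounts, regions, year=2018, resource="beds"):
    records = [
        ProvinceRecord(
            province=f"p{i:03d}", year=year, population=pop, region=reg,
            **{resource: amt},
        )
        for i, (pop, amt, reg) in enumerate(zip(populations, amounts, regions))
    ]
    return ResourcePanel(records=records)


random_panels = st.integers(4, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(1.0, 1e4), min_size=n, max_size=n),
        st.lists(st.floats(1.0, 1e6), min_size=n, max_size=n),
        st.lists(st.sampled_from(["western", "middle", "eastern"]), min_size=n, max_size=n),
    )
)


class TestTheilTotal:
    def test_perfect_equality_is_zero(self):
        shares = th.ShareVector(
            labels=("a", "b", "c", "d"),
            p=np.full(4, 0.25), y=np.full(4, 0.25),
        )
        assert th.theil_total(shares) == 0.0

    def test_two_unit_value_matches_hand_computation(self):
        shares = th.ShareVector(
            labels=("a", "b"), p=np.array([0.5, 0.5]), y=np.array([0.8, 0.2])
        )
        expected = 0.5 * math.log(0.5 / 0.8) + 0.5 * math.log(0.5 / 0.2)
        assert th.theil_total(shares) == pytest.approx(expected, abs=1e-15)
        assert round(th.theil_total(shares), 4) == 0.2231

    def test_permutation_symmetry(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.25, 0.25, 0.3, 0.2])
        base = th.theil_total(th.ShareVector(("a", "b", "c", "d"), p, y))
        perm = np.array([2, 0, 3, 1])
        shuffled = th.theil_total(th.ShareVector(("c", "a", "d", "b"), p[perm], y[perm]))
        assert shuffled == pytest.approx(base, abs=1e-15)

    def test_zero_resource_share_names_unit(self):
        shares = th.ShareVector(("a", "b"), np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        with pytest.raises(th.ZeroShareError, match="b"):
            th.theil_total(shares)

    def test_share_sums_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            th.ShareVector(("a", "b"), np.array([0.6, 0.6]), np.array([0.5, 0.5]))


class TestZeroPolicy:
    def test_error_policy_default(self):
        with pytest.raises(th.ZeroShareError, match="b"):
            th.ShareVector.from_amounts(["a", "b"], [1.0, 1.0], [5.0, 0.0])

    def test_drop_policy_renormalizes_with_warning(self):
        with pytest.warns(UserWarning, match="b"):
            shares = th.ShareVector.from_amounts(
                ["a", "b", "c"], [1.0, 1.0, 2.0], [5.0, 0.0, 5.0], zero_policy="drop"
            )
        assert shares.labels == ("a", "c")
        assert shares.p.sum() == pytest.approx(1.0)
        assert shares.y.sum() == pytest.approx(1.0)


class TestDecompose:
    def test_reference_case_components(self, two_group_panel):
        """Equal populations, resource shares (0.4, 0.2 | 0.3, 0.1)."""
        d = th.theil_decompose(two_group_panel, "beds", 2018)
        assert round(d.T_between, 4) == 0.0204
        assert round(d.T_within, 4) == 0.1014
        assert round(d.T_total, 4) == 0.1218
        assert round(d.between_contribution_rate, 4) == 0.1676
        rates = {g.group: round(g.contribution_rate, 4) for g in d.groups}
        assert rates == {"western": 0.2418, "middle": 0.5906}
        total_rate = d.between_contribution_rate + sum(
            g.contribution_rate for g in d.groups
        )
        assert total_rate == pytest.approx(1.0, abs=1e-12)

    def test_proportional_shares_give_zero_everywhere(self):
        pops = [10.0, 20.0, 30.0, 40.0]
        panel = make_panel(pops, [p * 7 for p in pops], ["western", "western", "middle", "middle"])
        d = th.theil_decompose(panel, "beds", 2018)
        assert d.T_total == pytest.approx(0.0, abs=1e-15)
        assert d.between_contribution_rate is None  # undefined at zero total

    def test_singleton_groups_put_everything_between(self):
        panel = make_panel([10.0, 30.0], [5.0, 5.0], ["western", "middle"])
        d = th.theil_decompose(panel, "beds", 2018)
        assert d.T_within == pytest.approx(0.0, abs=1e-15)
        assert d.T_between == pytest.approx(d.T_total, abs=1e-15)

    def test_density_panel_rejected(self, provinces_panel):
        with pytest.raises(ValueError, match="counts"):
            th.theil_decompose(provinces_panel, "beds", 2018)

    def test_scale_invariance(self):
        pops = [10.0, 25.0, 30.0, 5.0]
        amts = [100.0, 40.0, 200.0, 30.0]
        regs = ["western", "western", "middle", "eastern"]
        d1 = th.theil_decompose(make_panel(pops, amts, regs), "beds", 2018)
        d2 = th.theil_decompose(make_panel(pops, [a * 37.5 for a in amts], regs), "beds", 2018)
        assert d2.T_total == pytest.approx(d1.T_total, abs=1e-12)
        assert d2.T_between == pytest.approx(d1.T_between, abs=1e-12)
        for g1, g2 in zip(d1.groups, d2.groups):
            assert g2.contribution_rate == pytest.approx(g1.contribution_rate, abs=1e-12)

    @given(random_panels)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identity_and_oracle_on_random_panels(self, data):
        pops, amts, regs = data
        panel = make_panel(pops, amts, regs)
        if len(set(regs)) < 2:
            return
        d = th.theil_decompose(panel, "beds", 2018)
        # exact decomposition identity
        assert abs(d.T_total - d.T_within - d.T_between) < 1e-12
        # grouped total equals ungrouped brute force
        assert d.T_total == pytest.approx(brute_force_theil(pops, amts), abs=1e-10)
        # every component is a relative entropy, hence non-negative
        assert d.T_total >= 0 and d.T_between >= 0
        assert all(g.T >= 0 for g in d.groups)

    @given(random_panels)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_merging_groups_never_increases_between(self, data):
        """Coarsening the partition moves inequality from between to within."""
        pops, amts, regs = data
        if len(set(regs)) < 3:
            return
        panel = make_panel(pops, amts, regs)
        fine = th.theil_decompose(panel, "beds", 2018)
        merged = ["western" if r in ("western", "middle") else r for r in regs]
        coarse = th.theil_decompose(make_panel(pops, amts, merged), "beds", 2018)
        assert coarse.T_between <= fine.T_between + 1e-12
        assert coarse.T_total == pytest.approx(fine.T_total, abs=1e-10)

    def test_zero_iff_proportional(self):
        pops = np.array([10.0, 20.0, 30.0])
        regs = ["western", "middle", "middle"]
        prop = th.theil_decompose(make_panel(pops, pops * 3, regs), "beds", 2018)
        assert prop.T_total < 1e-12
        skew = th.theil_decompose(make_panel(pops, [30.0, 60.0, 91.0], regs), "beds", 2018)
        assert skew.T_total > 1e-12


class TestTrend:
    def _multi_year(self, shares_by_year):
        records = []
        for year, amts in shares_by_year.items():
            for i, amt in enumerate(amts):
                region = ["western", "middle", "eastern"][i % 3]
                records.append(
                    ProvinceRecord(
                        province=f"p{i}", year=year, population=10.0 + i,
                        region=region, beds=amt,
                    )
                )
        return ResourcePanel(records=records)

    def test_constant_shares_flat_series(self):
        amts = [50.0, 80.0, 10.0, 40.0, 70.0, 20.0]
        panel = self._multi_year({y: amts for y in range(2013, 2019)})
        series = th.theil_trend(panel, "beds")
        values = [d.T_total for d in series]
        assert all(v == pytest.approx(values[0], abs=1e-15) for v in values)

    def test_growing_concentration_monotone_total(self):
        pops = np.array([10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
        panels = {}
        for step, year in enumerate(range(2013, 2019)):
            amts = pops * np.exp(np.linspace(0, 0.3 * step, len(pops)))
            panels[year] = list(amts)
        series = th.theil_trend(self._multi_year(panels), "beds")
        values = [d.T_total for d in series]
        # per-year direct computation as independent check
        for d, (year, amts) in zip(series, sorted(panels.items())):
            assert d.T_total == pytest.approx(brute_force_theil(pops, amts), abs=1e-10)
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_series_sorted_by_year_regardless_of_input_order(self):
        amts = [50.0, 80.0, 10.0]
        records = []
        for year in (2014, 2013):
            for i, amt in enumerate(amts):
                records.append(
                    ProvinceRecord(
                        province=f"p{i}", year=year, population=10.0,
                        region=["western", "middle", "eastern"][i], beds=amt,
                    )
                )
        series = th.theil_trend(ResourcePanel(records=records), "beds")
        assert [d.year for d in series] == [2013, 2014]

    def test_year_missing_resource_skipped_with_warning(self):
        panel = self._multi_year({2013: [10.0, 20.0, 30.0], 2014: [None, None, None]})
        with pytest.warns(UserWarning, match="2014"):
            series = th.theil_trend(panel, "beds")
        assert [d.year for d in series] == [2013]

    def test_tidy_frames_have_expected_shape(self):
        panel = self._multi_year({y: [50.0, 80.0, 10.0] for y in (2013, 2014)})
        series = th.theil_trend(panel, "beds")
        assert len(th.trend_frame(series)) == 2 * 3  # total/within/between per year
        assert set(th.region_within_frame(series)["region"]) == {"western", "middle", "eastern"}
        rates = th.contribution_frame(series)
        sums = rates.groupby("year")["contribution_rate"].sum()
        assert np.allclose(sums, 1.0)
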
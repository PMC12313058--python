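import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmdkit.filtering import (
    FilterConfig,
    apply_filters,
    correlation_filter,
    filter_summary,
    minimum_concentration_filter,
    negative_control_filter,
    spearman_rho,
)

from conftest import group_from_counts, group_from_plates


def _mid_ranks(v):
    """Independent average-rank assignment (sort-and-scan, no scipy)."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def rho_oracle(x, y):
    """Brute-force Spearman: mid-rank both vectors, then Pearson."""
    rx, ry = _mid_ranks(x), _mid_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        assert spearman_rho([0, 1, 10, 100], [0.0, 0.1, 0.4, 0.9]) == pytest.approx(1.0)

    def test_strictly_decreasing_is_minus_one(self):
        assert spearman_rho([0, 1, 10, 100], [0.9, 0.4, 0.1, 0.0]) == pytest.approx(-1.0)

    def test_single_swap_gives_point_eight(self):
        # ranks of (0.1, 0.3, 0.2, 0.4) vs ascending doses: d^2 sum = 2,
        # rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_rho([1, 2, 3, 4], [0.1, 0.3, 0.2, 0.4]) == pytest.approx(0.8)

    def test_na_pairs_removed(self):
        rho = spearman_rho([1, 2, 3, 4, 5], [0.1, np.nan, 0.2, 0.3, 0.4])
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y",
        [([1, 2], [0.1, 0.2]), ([1, 2, 3], [0.5, 0.5, 0.5]), ([2, 2, 2], [0.1, 0.2, 0.3])],
    )
    def test_degenerate_inputs_are_nan(self, x, y):
        assert np.isnan(spearman_rho(x, y))

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.uniform(0, 100, 8)
            y = rng.uniform(0, 1, 8)
            base = spearman_rho(x, y)
            assert spearman_rho(np.exp(x / 50), y) == pytest.approx(base, abs=1e-12)
            assert spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=12).filter(lambda v: len(set(v)) > 1),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_rank_then_pearson_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 4, size=len(xs)).astype(float)
        if len(set(y)) == 1:
            y[0] += 1.0
        x = np.asarray(xs, float)
        assert spearman_rho(x, y) == pytest.approx(rho_oracle(x, y), abs=1e-12)


class TestNegativeControl:
    def _groups(self, control_responses, threshold_plate_wells=10):
        # one chemical, one endpoint, one plate per control response
        recs = []
        n = threshold_plate_wells
        for i, r in enumerate(control_responses):
            plate = f"P{i}"
            recs.append((0.0, plate, r * n, n))
            for c in (1.0, 5.0, 10.0):
                recs.append((c, plate, n // 2, n))
        return [group_from_plates(recs)]

    def test_plate_above_half_removed(self):
        groups = self._groups([0.6, 0.0])
        surv, entries, plates = negative_control_filter(groups, 0.5)
        assert plates["removed"].tolist() == [True, False]
        assert surv[0].plate_counts["plate_id"].nunique() == 1

    def test_clean_plate_kept(self):
        surv, entries, plates = negative_control_filter(self._groups([0.0]), 0.5)
        assert not plates["removed"].any()

    def test_boundary_is_strictly_greater(self):
        surv, entries, plates = negative_control_filter(self._groups([0.50, 0.51], 100), 0.50)
        removed = dict(zip(plates["control_response"].round(2), plates["removed"]))
        assert not bool(removed[0.50])
        assert bool(removed[0.51])

    def test_group_without_plates_passes_with_flag(self):
        g = group_from_counts([0, 1, 10], [1, 2, 5], [10, 10, 10])
        surv, entries, _ = negative_control_filter([g], 0.5)
        assert len(surv) == 1 and "no_plate_info" in surv[0].flags

    def test_group_without_controls_passes_with_flag(self):
        g = group_from_plates([(1.0, "P1", 2, 10), (5.0, "P1", 5, 10), (10.0, "P1", 9, 10)])
        surv, entries, _ = negative_control_filter([g], 0.5)
        assert len(surv) == 1 and "no_control_data" in surv[0].flags

    def test_plate_removed_from_all_groups_of_chemical(self):
        bad = [(0.0, "P1", 8, 10)] + [(c, "P1", 5, 10) for c in (1.0, 5.0, 10.0)]
        good = [(0.0, "P2", 0, 10)] + [(c, "P2", 5, 10) for c in (1.0, 5.0, 10.0)]
        g1 = group_from_plates(bad + good, ep="MORT")
        g2 = group_from_plates(bad + good, ep="YSE")
        surv, entries, plates = negative_control_filter([g1, g2], 0.5)
        for g in surv:
            assert g.plate_counts["plate_id"].unique().tolist() == ["P2"]


class TestMinimumConcentration:
    @pytest.mark.parametrize(
        "concs,expected_kept",
        [
            ([0, 1, 10], False),  # 2 distinct non-zero
            ([0, 0.1, 1, 10], True),  # exactly 3
            ([0, 1, 10, 100], True),
        ],
    )
    def test_distinct_nonzero_count_rule(self, concs, expected_kept):
        g = group_from_counts(concs, [1] * len(concs), [10] * len(concs))
        surv, entries = minimum_concentration_filter([g], 3)
        assert (len(surv) == 1) is expected_kept

    def test_zero_total_concentrations_do_not_count(self):
        g = group_from_counts([0, 1, 5, 10], [1, 1, 0, 2], [10, 10, 0, 10])
        surv, entries = minimum_concentration_filter([g], 3)
        assert surv == []
        assert entries["n_nonzero_concentrations"].iloc[0] == 2


class TestCorrelation:
    def test_positive_trend_kept(self):
        g = group_from_counts([1, 2, 3, 4], [1, 3, 2, 4], [10] * 4)  # rho = 0.8
        surv, entries = correlation_filter([g], 0.2)
        assert len(surv) == 1 and entries["spearman_rho"].iloc[0] == pytest.approx(0.8)

    def test_rho_exactly_at_threshold_kept(self):
        g = group_from_counts([1, 2, 3, 4], [1, 3, 2, 4], [10] * 4)
        surv, _ = correlation_filter([g], 0.8)
        assert len(surv) == 1

    def test_flat_all_zero_is_degenerate_removed(self):
        g = group_from_counts([0, 1, 10, 100], [0, 0, 0, 0], [10] * 4)
        surv, entries = correlation_filter([g], 0.2)
        assert surv == [] and bool(entries["correlation_degenerate"].iloc[0])

    def test_negative_trend_removed(self):
        g = group_from_counts([0, 1, 10, 100], [9, 6, 3, 1], [10] * 4)
        surv, _ = correlation_filter([g], 0.2)
        assert surv == []


class TestOrchestration:
    def _mixed_groups(self):
        keep = group_from_counts([0, 1, 5, 10], [1, 3, 6, 9], [10] * 4, chem="K")
        sparse = group_from_counts([0, 1, 10], [1, 3, 9], [10] * 3, chem="S")
        anti = group_from_counts([0, 1, 5, 10], [9, 6, 3, 1], [10] * 4, chem="A")
        return [keep, sparse, anti]

    def test_conservation_and_attribution(self):
        result = apply_filters(self._mixed_groups(), FilterConfig())
        s = filter_summary(result)
        assert s["kept_groups"] + sum(s["removed_per_filter"].values()) == s["input_groups"]
        led = result.ledger.set_index("chemical_id")
        assert led.loc["K", "status"] == "kept"
        assert led.loc["S", "removing_filter"] == "minimum_concentration"
        assert led.loc["A", "removing_filter"] == "correlation"

    def test_rho_recorded_for_every_group(self):
        result = apply_filters(self._mixed_groups(), FilterConfig())
        assert result.ledger["spearman_rho"].notna().all()

    def test_histogram_split_reconciles(self):
        result = apply_filters(self._mixed_groups(), FilterConfig())
        s = filter_summary(result)
        n_with_rho = result.ledger["spearman_rho"].notna().sum()
        assert s["rho_hist_keep"].sum() + s["rho_hist_remove"].sum() == n_with_rho

    def test_raising_thresholds_never_keeps_more(self):
        groups = self._mixed_groups()
        base = filter_summary(apply_filters(groups, FilterConfig()))["kept_groups"]
        for cfg in (
            FilterConfig(negative_control_threshold=0.2),
            FilterConfig(min_nonzero_concentrations=5),
            FilterConfig(correlation_threshold=0.95),
        ):
            kept = filter_summary(apply_filters(self._mixed_groups(), cfg))["kept_groups"]
            assert kept <= base

    def test_removal_attributed_to_first_failing_filter(self):
        # fails both minimum-concentration and correlation; attribution = min conc
        g = group_from_counts([0, 1, 10], [9, 5, 1], [10] * 3)
        result = apply_filters([g], FilterConfig())
        assert result.ledger["removing_filter"].iloc[0] == "minimum_concentration"
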
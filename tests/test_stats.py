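"""Summary statistics and Mann-Whitney machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dabquant as dq
from dabquant.roi import ROIResult, SubjectResult
from dabquant.stats import collect_values, mann_whitney_u, summarize_group


def _subject(sid, group, peak_pos, peak_n, sub_pos, sub_n, area=0.1):
    mk = lambda npos, n, x: ROIResult(  # noqa: E731
        x_um=x, y_um=0.0, side_um=316.23, roi_area_mm2=area,
        n_cells=n, n_positive=npos,
    )
    return SubjectResult(
        subject_id=sid, peak=mk(peak_pos, peak_n, 0.0),
        subpeak=mk(sub_pos, sub_n, 400.0), group=group,
    )


def enumeration_mann_whitney(a, b):
    """Independent oracle: exact U and two-tailed p by enumerating all
    rank assignments (tie-free samples only)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = na + nb
    lo = min(u_obs, na * nb - u_obs)
    count = total = 0
    for ranks in itertools.combinations(range(1, n + 1), na):
        u = sum(ranks) - na * (na + 1) // 2
        total += 1
        count += u <= lo
    return u_obs, min(1.0, 2.0 * count / total)


class TestSummarizeGroup:
    def test_small_sample_values(self):
        s = summarize_group([1, 2, 3, 4])
        assert s.median == 2.5 and s.mean == 2.5
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_too_few_values_raises_with_group_name(self):
        with pytest.raises(ValueError, match="HV"):
            summarize_group([1.0], group="HV")

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_iqr_identity_and_quartile_ordering(self, values):
        s = summarize_group(values)
        assert s.iqr == pytest.approx(s.p75 - s.p25, abs=1e-9)
        assert s.p25 <= s.median <= s.p75


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_constant_values_give_p_one(self):
        r = mann_whitney_u([5.0] * 10, [5.0] * 12)
        assert r.p_value == 1.0

    def test_u_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            na, nb = rng.integers(2, 30, 2)
            a, b = rng.normal(size=na), rng.normal(0.5, 1, size=nb)
            u_ab = mann_whitney_u(a, b).u_statistic
            u_ba = mann_whitney_u(b, a).u_statistic
            assert u_ab + u_ba == pytest.approx(na * nb)

    def test_agrees_with_enumeration_oracle_for_all_small_sizes(self):
        """Exact agreement with rank-assignment enumeration, nA, nB <= 8."""
        rng = np.random.default_rng(42)
        for na in range(1, 9):
            for nb in range(1, 9):
                a = rng.normal(size=na)
                b = rng.normal(0.3, 1.0, size=nb)
                u_ref, p_ref = enumeration_mann_whitney(a, b)
                r = mann_whitney_u(a, b)
                assert r.u_statistic == pytest.approx(u_ref)
                assert r.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_bounds_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(size=21)
        r = mann_whitney_u(a, b)
        assert 0 <= r.u_statistic <= 15 * 21
        assert 0 < r.p_value <= 1


class TestCollectValues:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(5)
        out = []
        for g, n, rate in (("HV", 15, 0.2), ("GERD", 21, 0.5), ("EoE", 20, 0.6)):
            for i in range(n):
                n1, n2 = rng.integers(40, 80, 2)
                p1 = rng.binomial(n1, rate)
                p2 = min(p1, rng.binomial(n2, rate))
                out.append(_subject(f"{g}{i}", g, p1, n1, p2, n2))
        return out

    def test_pooled_contributes_two_values_per_subject(self, cohort):
        vals = collect_values(cohort, "two_rois_pooled", "pos_per_mm2")
        assert len(vals["HV"]) == 30 and len(vals["GERD"]) == 42 and len(vals["EoE"]) == 40

    def test_mean_of_two_arithmetic(self):
        s = _subject("x", "HV", 1, 10, 1, 10)
        # peak 1/0.1 = 10 per mm2, subpeak 10 -> but use distinct counts
        s2 = _subject("y", "HV", 1, 10, 0, 10)
        assert s2.mean_of_two("pos_per_mm2") == pytest.approx((10 + 0) / 2)
        assert s.mean_of_two("pos_percent") == pytest.approx(10.0)

    def test_pooled_mean_equals_mean_of_two_mean(self, cohort):
        pooled = collect_values(cohort, "two_rois_pooled", "pos_per_mm2")
        m2 = collect_values(cohort, "mean_of_two", "pos_per_mm2")
        for g in pooled:
            assert np.mean(pooled[g]) == pytest.approx(np.mean(m2[g]))

    def test_unknown_mode_raises(self, cohort):
        with pytest.raises(ValueError, match="mode"):
            collect_values(cohort, "bogus", "pos_percent")

    def test_missing_pos_percent_dropped(self):
        s = _subject("x", "HV", 0, 0, 2, 10)  # empty peak window
        vals = collect_values([s], "two_rois_pooled", "pos_percent")
        assert len(vals["HV"]) == 1


class TestBuildComparisonTable:
    def test_row_counts(self):
        rng = np.random.default_rng(6)
        cohort = [
            _subject(f"{g}{i}", g, rng.integers(1, 20), 40, rng.integers(0, 10), 40)
            for g in ("HV", "GERD", "EoE")
            for i in range(4)
        ]
        summaries, comparisons = dq.build_comparison_table(cohort)
        assert len(summaries) == 3 * 2 * 3  # modes x metrics x groups
        assert len(comparisons) == 3 * 2 * 3  # modes x metrics x pairs
        assert (summaries["iqr"] == summaries["p75"] - summaries["p25"]).all()

    def test_missing_group_raises(self):
        cohort = [_subject(f"HV{i}", "HV", 5, 20, 3, 20) for i in range(4)]
        with pytest.raises(ValueError, match="missing groups"):
            dq.build_comparison_table(cohort)

    def test_large_effect_detected_reliably(self):
        """A strongly shifted EoE group is significant in pooled mode."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cohort = []
            for g, rate in (("HV", 0.1), ("GERD", 0.3), ("EoE", 0.8)):
                n = {"HV": 15, "GERD": 21, "EoE": 20}[g]
                for i in range(n):
                    n1, n2 = rng.integers(50, 90, 2)
                    p1, p2 = rng.binomial(n1, rate), rng.binomial(n2, rate)
                    cohort.append(_subject(f"{g}{i}", g, max(p1, p2), n1, min(p1, p2), n2))
            _, cmp_tbl = dq.build_comparison_table(cohort)
            row = cmp_tbl[
                (cmp_tbl["mode"] == "two_rois_pooled")
                & (cmp_tbl["metric"] == "pos_percent")
                & (cmp_tbl["group_a"] == "HV")
                & (cmp_tbl["group_b"] == "EoE")
            ]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 10 * 0.95
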
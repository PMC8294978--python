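"""Cohort summaries, Wilcoxon signed-rank, endpoint table, graphs."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from octanv.exceptions import ParameterError
from octanv.io import load_table1
from octanv.stats import (
    endpoint_table,
    render_graphs,
    summarize,
    wilcoxon_signed_rank,
)

#: Per-NV posttreatment NV-angio regressions (percent).
ANGIO_POST = [76, 78, 100, 11, 65, 24, 32, 33, 48]
#: Per-NV posttreatment FD-structure decreases (percentage points).
FDS_POST = [26, 37, 61, 39, 30, 53, 14, 3, 7]


def textbook_summary(values):
    """Direct-formula recomputation, independent of numpy reductions."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    ordered = sorted(values)
    median = (
        ordered[n // 2]
        if n % 2
        else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    )
    half = 1.96 * sd / math.sqrt(n)
    return median, mean, sd, mean - half, mean + half


class TestSummarize:
    def test_reported_angio_regression_summary(self):
        s = summarize(ANGIO_POST)
        assert round(s.mean, 1) == 51.9
        assert round(s.sd, 1) == 29.5
        assert round(s.ci_low, 1) == 32.6
        assert round(s.ci_high, 1) == 71.2
        assert s.median == 48
        assert (s.range_low, s.range_high) == (11, 100)

    def test_constant_list(self):
        s = summarize([5, 5, 5])
        assert s.sd == 0.0
        assert (s.ci_low, s.ci_high) == (5.0, 5.0)
        assert s.median == 5.0

    def test_matches_textbook_formulas(self, rng):
        values = list(rng.normal(10, 4, size=50))
        s = summarize(values)
        median, mean, sd, lo, hi = textbook_summary(values)
        for got, want in [
            (s.median, median), (s.mean, mean), (s.sd, sd),
            (s.ci_low, lo), (s.ci_high, hi),
        ]:
            assert got == pytest.approx(want, abs=1e-12)

    def test_permutation_and_shift_invariance(self, rng):
        values = list(rng.normal(0, 1, size=9))
        s1 = summarize(values)
        s2 = summarize(list(np.random.default_rng(1).permutation(values)))
        assert s2.mean == pytest.approx(s1.mean)
        assert s2.median == s1.median
        assert s2.sd == pytest.approx(s1.sd)
        s3 = summarize([v + 7.5 for v in values])
        assert s3.mean == pytest.approx(s1.mean + 7.5)
        assert s3.median == pytest.approx(s1.median + 7.5)
        assert s3.sd == pytest.approx(s1.sd)
        assert s3.ci_high - s3.ci_low == pytest.approx(
            s1.ci_high - s1.ci_low
        )

    def test_single_value_rejected(self):
        with pytest.raises(ParameterError):
            summarize([1.0])


class TestWilcoxon:
    def test_nine_all_positive_differences(self):
        res = wilcoxon_signed_rank(FDS_POST)
        assert res.w_plus == 45.0
        assert res.z == pytest.approx(2.666, abs=1e-3)
        assert res.p == pytest.approx(0.0077, abs=5e-5)

    def test_symmetric_pair(self):
        res = wilcoxon_signed_rank([+1, -1])
        assert res.w_plus == 1.5
        assert res.z == 0.0
        assert res.p == 1.0

    def test_all_positive_w_plus_is_rank_total(self, rng):
        for n in (5, 8, 12):
            d = list(rng.random(n) + 0.1)
            assert wilcoxon_signed_rank(d).w_plus == n * (n + 1) / 2

    def test_monotone_transform_invariance(self, rng):
        d = rng.normal(0, 1, size=9)
        d = d[d != 0]
        p1 = wilcoxon_signed_rank(d).p
        transformed = np.sign(d) * np.exp(np.abs(d))  # rank-preserving
        assert wilcoxon_signed_rank(transformed).p == pytest.approx(p1)

    def test_matches_scipy_approx_variant(self, rng):
        for seed in range(4):
            r = np.random.default_rng(seed)
            d = np.round(r.normal(0, 10, size=9))
            d = d[d != 0]
            res = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(
                d, correction=False, method="approx",
                zero_method="wilcox", alternative="two-sided",
            )
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_method_matches_enumeration_oracle(self, rng):
        # consistency of the rank machinery against an exhaustive
        # enumeration of all 2^8 sign assignments
        d = list(np.round(rng.normal(0, 5, size=8), 1))
        d = [v if v != 0 else 1.0 for v in d]
        res = wilcoxon_signed_rank(d, method="exact")
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        mean_w = 8 * 9 / 4.0
        obs = abs(res.w_plus - mean_w)
        count = sum(
            abs(float(np.dot(signs, ranks)) - mean_w) >= obs - 1e-12
            for signs in product((0, 1), repeat=8)
        )
        assert res.p == pytest.approx(count / 256.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestEndpointTable:
    def test_reported_structure_posttreatment_summary(self):
        report = endpoint_table(load_table1())
        s = report["nv_structure_regression_post"]
        assert s.median == 15
        assert round(s.mean, 1) == 18.7
        assert round(s.sd, 1) == 39.0

    def test_single_row_degenerates_gracefully(self):
        df = load_table1().iloc[:1]
        report = endpoint_table(df)
        s = report["nv_angio_regression_post"]
        assert s.n == 1
        assert s.median == s.mean == 76
        assert s.p_wilcoxon is None

    def test_scale_invariance_of_relative_changes(self):
        # doubling all raw areas leaves the change columns (and hence
        # every summary) untouched
        df = load_table1()
        scaled = df.copy()
        for col in df.columns:
            if col.endswith("_mm2"):
                scaled[col] = 2 * df[col]
        r1 = endpoint_table(df)
        r2 = endpoint_table(scaled)
        assert r1 == r2

    def test_fd_level_medians_match_reported(self):
        report = endpoint_table(load_table1())
        expected = {
            "fd_structure_baseline": (72, 44, 82),
            "fd_structure_post": (38, 0, 73),
            "fd_structure_last": (40, 0, 70),
            "fd_angio_baseline": (72, 48, 89),
            "fd_angio_post": (58, 0, 84),
            "fd_angio_last": (54, 0, 75),
        }
        for key, (median, lo, hi) in expected.items():
            s = report[key]
            assert (s.median, s.range_low, s.range_high) == (median, lo, hi)


class TestRenderGraphs:
    def test_panel_files_produced(self, tmp_path):
        written = render_graphs(load_table1(), tmp_path)
        assert len(written) == 6  # 2 box-plot + 4 longitudinal panels
        for p in written:
            assert p.exists() and p.stat().st_size > 0

    def test_normalized_curves_equal_area_over_baseline(self):
        from octanv.stats import _pseudo_series

        df = load_table1()
        series = _pseudo_series(df)
        merged = series.merge(
            df[["nv_id", "structure_area_baseline_mm2",
                "structure_area_post_mm2", "posttreatment_week"]],
            on="nv_id",
        )
        post = merged[merged.week == merged.posttreatment_week]
        np.testing.assert_allclose(
            post["nv_structure_rel"],
            post["structure_area_post_mm2"]
            / post["structure_area_baseline_mm2"],
            atol=1e-12,
        )

    def test_flat_series_stays_at_one(self):
        df = load_table1().iloc[:1].copy()
        for col in ("change_structure_post", "change_structure_last"):
            df[col] = 0.0
        from octanv.stats import _pseudo_series

        series = _pseudo_series(df)
        assert (series["nv_structure_rel"] == 1.0).all()
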
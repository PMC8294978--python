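"""Cohort-level statistics over NV endpoint rows.

The study cohort is summarized endpoint-wise as median with range and
mean ± sample SD with a normal-approximation 95% confidence interval
(mean ± 1.96·SD/√n).  Change-from-baseline endpoints are tested against
zero with the Wilcoxon signed-rank test in its large-sample form: zero
differences dropped, average ranks for ties, z computed with the
tie-corrected variance and *no* continuity correction, two-sided p from
the normal distribution.  An exact-enumeration alternative is available
for small n but is not the default.  No multiple-testing correction is
applied.

Area endpoints are summarized on the *regression* scale
(decrease-positive, i.e. the negative of the signed change), and FD
endpoints as decreases from baseline in percentage points — matching
the reporting convention of the per-NV table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import ParameterError
from .longitudinal import EndpointRow

__all__ = [
    "StatSummary",
    "WilcoxonResult",
    "summarize",
    "wilcoxon_signed_rank",
    "endpoint_table",
    "render_graphs",
    "Z_95",
]

#: Normal 95% CI multiplier (identified from the reporting convention).
Z_95 = 1.96


@dataclass(frozen=True)
class StatSummary:
    """Median/range/mean/SD/CI/p bundle for one endpoint."""

    n: int
    median: float
    range_low: float
    range_high: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    p_wilcoxon: float | None = None

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "n": self.n,
            "median": self.median,
            "range_low": self.range_low,
            "range_high": self.range_high,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_wilcoxon": self.p_wilcoxon,
        }


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic W+ (sum of positive ranks), z, and
    two-sided p."""

    w_plus: float
    z: float
    p: float
    n: int  # nonzero differences used


def summarize(values: Sequence[float]) -> StatSummary:
    """Median with range, mean ± sample SD, and normal 95% CI.

    The median uses the midpoint-of-two rule for even n; the SD uses
    the n−1 denominator; the CI is mean ± 1.96·SD/√n.  Requires n ≥ 2.
    """
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n < 2:
        raise ParameterError("summarize requires at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = Z_95 * sd / np.sqrt(n)
    return StatSummary(
        n=n,
        median=float(np.median(x)),
        range_low=float(np.min(x)),
        range_high=float(np.max(x)),
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def wilcoxon_signed_rank(
    differences: Sequence[float], method: str = "approx"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Zero differences are dropped; |differences| receive average ranks
    for ties; ``W+`` is the rank sum over positive differences.  With
    ``method='approx'`` (default) the two-sided p comes from

        z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)

    without continuity correction, where t runs over tie-group sizes.
    ``method='exact'`` enumerates all 2^n sign assignments of the
    observed ranks instead (n ≤ 20) and returns the two-sided tail
    probability of |W+ − n(n+1)/4|; z is still reported for reference.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ParameterError("all differences are zero: test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var_w -= float(np.sum(counts**3 - counts)) / 48.0
    z = 0.0 if var_w == 0 else (w_plus - mean_w) / np.sqrt(var_w)
    if method == "approx":
        p = float(2.0 * norm.sf(abs(z)))
    elif method == "exact":
        if n > 20:
            raise ParameterError("exact enumeration limited to n <= 20")
        obs_dev = abs(w_plus - mean_w)
        count = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mean_w) >= obs_dev - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        raise ParameterError(f"unknown method {method!r}")
    return WilcoxonResult(w_plus=w_plus, z=z, p=min(p, 1.0), n=n)


#: Endpoint name → (source column, decrease-positive sign flip).
_CHANGE_ENDPOINTS: dict[str, str] = {
    "nv_structure_regression_post": "change_structure_post",
    "nv_structure_regression_last": "change_structure_last",
    "nv_angio_regression_post": "change_angio_post",
    "nv_angio_regression_last": "change_angio_last",
}
_FD_DECREASE_ENDPOINTS: dict[str, tuple[str, str]] = {
    "fd_structure_decrease_post": ("fd_structure_baseline", "fd_structure_post"),
    "fd_structure_decrease_last": ("fd_structure_baseline", "fd_structure_last"),
    "fd_angio_decrease_post": ("fd_angio_baseline", "fd_angio_post"),
    "fd_angio_decrease_last": ("fd_angio_baseline", "fd_angio_last"),
}
_FD_LEVELS = [
    "fd_structure_baseline", "fd_structure_post", "fd_structure_last",
    "fd_angio_baseline", "fd_angio_post", "fd_angio_last",
]


def _rows_to_frame(rows: Iterable[EndpointRow] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame([r.__dict__ for r in rows])


def endpoint_table(
    rows: Iterable[EndpointRow] | pd.DataFrame,
    method: str = "approx",
) -> dict[str, StatSummary]:
    """Cohort report over endpoint rows.

    Emits a :class:`StatSummary` for each of the eight
    change-from-baseline endpoints — NV-structure and NV-angio area
    regression (decrease-positive percent) and FD-structure / FD-angio
    decrease (percentage points), each at posttreatment and last
    follow-up — with a Wilcoxon p versus zero change, plus plain
    summaries (no p) of the six raw FD levels.  A single-row input
    yields degenerate summaries (median = mean = the value, SD/CI NaN,
    p omitted).
    """
    df = _rows_to_frame(rows)
    if len(df) < 1:
        raise ParameterError("endpoint_table requires at least one row")

    def summary_of(values: np.ndarray, with_p: bool) -> StatSummary:
        if len(values) == 1:
            v = float(values[0])
            return StatSummary(
                n=1, median=v, range_low=v, range_high=v,
                mean=v, sd=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"),
            )
        s = summarize(values)
        if with_p and np.any(values != 0):
            res = wilcoxon_signed_rank(values, method=method)
            s = StatSummary(**{**s.as_dict(), "p_wilcoxon": res.p})  # type: ignore[arg-type]
        return s

    report: dict[str, StatSummary] = {}
    for name, col in _CHANGE_ENDPOINTS.items():
        report[name] = summary_of(-df[col].to_numpy(float), with_p=True)
    for name, (b, v) in _FD_DECREASE_ENDPOINTS.items():
        report[name] = summary_of(
            df[b].to_numpy(float) - df[v].to_numpy(float), with_p=True
        )
    for col in _FD_LEVELS:
        report[col] = summary_of(df[col].to_numpy(float), with_p=False)
    return report


def report_frame(report: Mapping[str, StatSummary]) -> pd.DataFrame:
    """Flatten a cohort report into a tidy DataFrame (one endpoint per
    row), full precision."""
    return pd.DataFrame(
        [{"endpoint": k, **v.as_dict()} for k, v in report.items()]
    ).set_index("endpoint")


def render_graphs(
    rows: Iterable[EndpointRow] | pd.DataFrame,
    outdir: str | Path,
    series: pd.DataFrame | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Box plots of endpoint changes and per-NV longitudinal curves.

    Writes two box-plot panels (area changes relative to baseline; FD
    levels at the three key visits) and four longitudinal panels
    (NV-structure and NV-angio relative to baseline = 1; FD-structure
    and FD-angio in percent), with injection weeks marked when
    ``series`` provides them.  ``series`` is a long DataFrame with
    columns ``nv_id, week, nv_structure_rel, nv_angio_rel,
    fd_structure_pct, fd_angio_pct`` and optionally ``injection_weeks``
    per NV; when absent, three-point curves are built from the endpoint
    rows at nominal weeks.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _rows_to_frame(rows)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # Panel 1: area changes (% of baseline, signed) at the two visits.
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(
        [
            df["change_structure_post"], df["change_structure_last"],
            df["change_angio_post"], df["change_angio_last"],
        ],
        tick_labels=[
            "structure\npost", "structure\nlast",
            "angio\npost", "angio\nlast",
        ],
    )
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_ylabel("NV area change from baseline (%)")
    p1 = outdir / f"boxplot_area_changes.{fmt}"
    fig.savefig(p1, dpi=120)
    plt.close(fig)
    written.append(p1)

    # Panel 2: FD levels at baseline / posttreatment / last follow-up.
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(
        [df[c] for c in _FD_LEVELS],
        tick_labels=[
            "FD-s\nbase", "FD-s\npost", "FD-s\nlast",
            "FD-a\nbase", "FD-a\npost", "FD-a\nlast",
        ],
    )
    ax.set_ylabel("flow density (%)")
    p2 = outdir / f"boxplot_fd_levels.{fmt}"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    written.append(p2)

    if series is None:
        series = _pseudo_series(df)
    panels = [
        ("nv_structure_rel", "NV-structure area (baseline = 1)"),
        ("nv_angio_rel", "NV-angio area (baseline = 1)"),
        ("fd_structure_pct", "FD-structure (%)"),
        ("fd_angio_pct", "FD-angio (%)"),
    ]
    for col, label in panels:
        fig, ax = plt.subplots(figsize=(6, 4))
        for nv_id, grp in series.groupby("nv_id"):
            grp = grp.sort_values("week")
            ax.plot(grp["week"], grp[col], marker="o", ms=3, label=str(nv_id))
            if "injection_week" in grp.columns:
                for wk in grp["injection_week"].dropna().unique():
                    ax.axvline(wk, color="0.85", lw=0.6, zorder=0)
        if col.endswith("_rel"):
            ax.axhline(1.0, color="gray", lw=0.8)
        ax.set_xlabel("weeks from baseline")
        ax.set_ylabel(label)
        ax.legend(fontsize=6, ncol=3)
        p = outdir / f"longitudinal_{col}.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def _pseudo_series(df: pd.DataFrame) -> pd.DataFrame:
    """Three-point curves from endpoint rows at nominal visit weeks."""
    post_wk = df["posttreatment_week"] if "posttreatment_week" in df else 17
    last_wk = df["last_week"] if "last_week" in df else 45
    recs = []
    for i, row in df.reset_index(drop=True).iterrows():
        pw = post_wk if np.isscalar(post_wk) else post_wk.iloc[i]
        lw = last_wk if np.isscalar(last_wk) else last_wk.iloc[i]
        for wk, suffix in ((0, "baseline"), (pw, "post"), (lw, "last")):
            recs.append(
                {
                    "nv_id": row.get("nv_id", f"NV{i + 1}"),
                    "week": wk,
                    "nv_structure_rel": 1.0
                    + (0 if suffix == "baseline"
                       else row[f"change_structure_{suffix}"] / 100.0),
                    "nv_angio_rel": 1.0
                    + (0 if suffix == "baseline"
                       else row[f"change_angio_{suffix}"] / 100.0),
                    "fd_structure_pct": row[f"fd_structure_{suffix}"],
                    "fd_angio_pct": row[f"fd_angio_{suffix}"],
                }
            )
    return pd.DataFrame(recs)
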
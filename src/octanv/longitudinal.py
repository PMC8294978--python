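"""Per-NV time series and treatment-response endpoints.

Each neovascularization (NV) is followed from baseline through an
initial block of three to four monthly anti-VEGF injections and a
variable follow-up.  The endpoints compare two visits against baseline:

* *posttreatment* — the visit 5 ± 1 weeks after the last injection of
  the initial block;
* *last follow-up* — the final available visit.

Area endpoints are relative changes from baseline (baseline = 100%;
negative = regression, exactly as reported per NV).  Flow-density (FD)
endpoints are differences in percentage points, reported
decrease-positive (baseline − visit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bscan import BscanMeasurement
from .enface import EnfaceMeasurement
from .exceptions import EndpointError

__all__ = [
    "VisitRecord",
    "NvSeries",
    "EndpointRow",
    "relative_change",
    "fd_change",
    "select_endpoints",
    "POSTTREATMENT_WINDOW_WEEKS",
    "INITIAL_BLOCK_MAX_GAP_WEEKS",
]

#: Posttreatment visit window: [4, 6] weeks after the last
#: initial-block injection (nominal 5 weeks).
POSTTREATMENT_WINDOW_WEEKS: tuple[float, float] = (4.0, 6.0)

#: Injections separated by at most this many weeks belong to the same
#: (monthly-cadence) initial treatment block.
INITIAL_BLOCK_MAX_GAP_WEEKS: float = 8.0


@dataclass(frozen=True)
class VisitRecord:
    """All measurements of one NV at one visit."""

    week: float
    enface: EnfaceMeasurement
    bscan: BscanMeasurement | None = None


@dataclass(frozen=True)
class NvSeries:
    """One NV's timeline: visits, injections, endpoint indices.

    Visits must be in strictly increasing week order with baseline at
    week 0.  B-scan measurements may be missing at any visit.
    """

    nv_id: str
    visits: tuple[VisitRecord, ...]
    injection_weeks: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.visits:
            raise EndpointError("a series needs at least one visit")
        weeks = [v.week for v in self.visits]
        if weeks[0] != 0:
            raise EndpointError("baseline visit must be at week 0")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise EndpointError("visit weeks must be strictly increasing")
        object.__setattr__(self, "visits", tuple(self.visits))
        object.__setattr__(
            self, "injection_weeks", tuple(sorted(self.injection_weeks))
        )

    @property
    def weeks(self) -> tuple[float, ...]:
        return tuple(v.week for v in self.visits)

    def last_initial_block_injection(
        self, max_gap: float = INITIAL_BLOCK_MAX_GAP_WEEKS
    ) -> float:
        """Week of the final injection of the initial treatment block.

        The block is the leading run of injections whose gaps stay
        within the monthly cadence (``max_gap``); later reinjections
        (for recurrence or macular edema) are excluded.
        """
        if not self.injection_weeks:
            raise EndpointError(f"{self.nv_id}: no injections recorded")
        last = self.injection_weeks[0]
        for wk in self.injection_weeks[1:]:
            if wk - last > max_gap:
                break
            last = wk
        return last


@dataclass(frozen=True)
class EndpointRow:
    """One NV's endpoint bundle (the per-NV report columns).

    ``change_*`` are signed relative area changes in percent (negative
    = regression); ``fd_*`` are raw flow densities in percent at the
    three key visits.
    """

    nv_id: str
    change_structure_post: float
    change_structure_last: float
    change_angio_post: float
    change_angio_last: float
    fd_structure_baseline: float
    fd_structure_post: float
    fd_structure_last: float
    fd_angio_baseline: float
    fd_angio_post: float
    fd_angio_last: float

    def __post_init__(self) -> None:
        for name in (
            "fd_structure_baseline", "fd_structure_post", "fd_structure_last",
            "fd_angio_baseline", "fd_angio_post", "fd_angio_last",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 100.0:
                raise ValueError(f"{name} = {val} outside [0, 100]")


def relative_change(baseline_area: float, visit_area: float) -> float:
    """Signed relative area change from baseline, in percent.

    ``100 * (visit - baseline) / baseline``: negative values are
    regression, −100 is complete disappearance, growth is unbounded
    above.  A zero (or negative) baseline is degenerate.
    """
    if baseline_area <= 0:
        raise EndpointError("baseline area must be positive")
    return 100.0 * (visit_area - baseline_area) / baseline_area


def fd_change(baseline_fd: float, visit_fd: float) -> float:
    """Flow-density difference in percentage points, decrease-positive.

    ``baseline_fd - visit_fd``: positive values mean the flow density
    decreased from baseline.
    """
    for v in (baseline_fd, visit_fd):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"flow density {v} outside [0, 100]")
    return baseline_fd - visit_fd


def select_endpoints(
    series: NvSeries,
    window: tuple[float, float] = POSTTREATMENT_WINDOW_WEEKS,
) -> EndpointRow:
    """Pick the posttreatment and last-follow-up visits and compute
    the endpoint row.

    The posttreatment visit is the one within ``window`` weeks after
    the last initial-block injection; if several qualify, the one
    closest to the nominal 5 weeks wins, ties going to the earlier
    visit.  The last visit is the final one in the series and must come
    after baseline.
    """
    lo, hi = window
    if not lo < hi:
        raise EndpointError("window bounds must satisfy low < high")
    ref = series.last_initial_block_injection()
    target = ref + (lo + hi) / 2.0
    candidates = [
        (i, v) for i, v in enumerate(series.visits)
        if ref + lo <= v.week <= ref + hi
    ]
    if not candidates:
        raise EndpointError(
            f"{series.nv_id}: no visit in [{ref + lo}, {ref + hi}] weeks; "
            f"visits at weeks {list(series.weeks)}"
        )
    post_i, post = min(
        candidates, key=lambda iv: (abs(iv[1].week - target), iv[1].week)
    )
    last = series.visits[-1]
    if last.week <= 0:
        raise EndpointError(f"{series.nv_id}: no follow-up after baseline")
    base = series.visits[0].enface

    return EndpointRow(
        nv_id=series.nv_id,
        change_structure_post=relative_change(
            base.nv_structure_area, post.enface.nv_structure_area
        ),
        change_structure_last=relative_change(
            base.nv_structure_area, last.enface.nv_structure_area
        ),
        change_angio_post=relative_change(
            base.nv_angio_area, post.enface.nv_angio_area
        ),
        change_angio_last=relative_change(
            base.nv_angio_area, last.enface.nv_angio_area
        ),
        fd_structure_baseline=base.fd_structure,
        fd_structure_post=post.enface.fd_structure,
        fd_structure_last=last.enface.fd_structure,
        fd_angio_baseline=base.fd_angio,
        fd_angio_post=post.enface.fd_angio,
        fd_angio_last=last.enface.fd_angio,
    )
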
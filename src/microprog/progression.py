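"""Per-eye longitudinal analysis: eligibility, trend slopes, events, floor.

Trend-based analysis fits ordinary least squares to the per-visit metric
mean against years since baseline and reports the slope (dB/year).
Event-based analysis implements the FDA clinically-meaningful-change
criterion: a mean change ≤ −7 dB from baseline across ≥ 5 prespecified
loci with baseline sensitivity ≥ 8 dB.

Analysis windows: ``all`` uses every follow-up-mode visit; ``2y`` and the
sub-windows ``0.5y``/``1y``/``1.5y`` restrict to visits within the window
plus a 0.1-year tolerance (observed follow-ups cluster slightly above the
nominal window).  For the event endpoint the ``2y`` target visit is the
visit nearest 2.0 years within ±0.5 years, reflecting real visit-schedule
jitter.

Floor mitigation: a locus is considered to have reached scotoma after two
consecutive −1 dB readings; the optional ``censor_scotoma`` rule drops such
a locus from the metric mean from its second consecutive −1 dB visit
onward.  It defaults off, matching how rates are usually reported.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .registration import RingPolygon
from .selection import FLOOR, LociSelection, Metric, SensitivityField

__all__ = [
    "EyeSeries",
    "TrendResult",
    "EventResult",
    "WINDOWS",
    "check_eligibility",
    "trend",
    "event",
    "floor_diagnostics",
    "analyze_eye",
]

#: Named analysis windows in years; None = all available data.
WINDOWS: dict[str, float | None] = {
    "0.5y": 0.5,
    "1y": 1.0,
    "1.5y": 1.5,
    "2y": 2.0,
    "all": None,
}

TREND_WINDOW_TOL = 0.1   # years added to a trend window
EVENT_2Y_TOL = 0.5       # half-width of the 2-year event target-visit window
EVENT_THRESHOLD_DB = -7.0

MIN_SPAN_YEARS = 2.0
MIN_TESTS = 3


@dataclass
class EyeSeries:
    """Dated follow-up series of sensitivity fields for one eye.

    Visit 0 is baseline; ``years`` are elapsed years per visit (years[0]=0).
    ``selections`` holds the four baseline-frozen loci selections and
    ``ring`` the baseline ring polygon in degrees (None when no complete
    ring was available).  Only follow-up-mode visits enter longitudinal
    computation.
    """

    eye_id: str
    visits: list[SensitivityField]
    years: np.ndarray
    selections: dict[Metric, LociSelection] = field(default_factory=dict)
    ring: RingPolygon | None = None
    age_at_baseline: float | None = None
    baseline_date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        if len(self.visits) != len(self.years):
            raise ValueError("one elapsed-years entry per visit is required")
        if len(self.years) and (self.years[0] != 0.0 or np.any(np.diff(self.years) <= 0)):
            raise ValueError("visits must be strictly time-ordered from baseline 0")

    def followup_indices(self) -> np.ndarray:
        return np.array(
            [i for i, v in enumerate(self.visits) if v.followup_mode], dtype=int
        )


def check_eligibility(
    series: EyeSeries,
    min_span_years: float = MIN_SPAN_YEARS,
    min_tests: int = MIN_TESTS,
) -> tuple[bool, list[str]]:
    """Longitudinal eligibility: follow-up span ≥ 2 years and ≥ 3 tests."""
    idx = series.followup_indices()
    reasons = []
    span = float(series.years[idx[-1]] - series.years[idx[0]]) if len(idx) else 0.0
    if len(idx) < min_tests:
        reasons.append(f"only {len(idx)} follow-up-mode tests (< {min_tests})")
    if span < min_span_years:
        reasons.append(f"follow-up span {span:.2f} y (< {min_span_years} y)")
    return (not reasons), reasons


@dataclass(frozen=True)
class TrendResult:
    metric: Metric
    window: str
    slope: float           # dB/year; NaN when undefined
    intercept: float
    n_visits: int
    follow_up: float       # years spanned by the visits used


@dataclass(frozen=True)
class EventResult:
    metric: Metric
    window: str
    eligible: bool
    n_loci: int
    mean_change: float     # dB, target visit − baseline; NaN when no target
    event: bool
    mean_rate: float       # dB/year = mean_change / elapsed years at target
    target_years: float
    reason: str = ""


def _window_indices(series: EyeSeries, window: str) -> np.ndarray:
    """Follow-up-mode visit indices inside a trend window."""
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {list(WINDOWS)}")
    idx = series.followup_indices()
    w = WINDOWS[window]
    if w is None:
        return idx
    return idx[series.years[idx] <= w + TREND_WINDOW_TOL]


def _visit_matrix(
    series: EyeSeries, loci: list[int], indices: np.ndarray
) -> np.ndarray:
    """(visits × loci) dB matrix over the given visit indices."""
    return np.array(
        [[series.visits[i][l] for l in loci] for i in indices], dtype=float
    )


def _censor_scotoma_mask(values: np.ndarray) -> np.ndarray:
    """Mask (True = keep) dropping a locus from its 2nd consecutive −1 onward.

    ``values`` is (visits × loci) in visit order.
    """
    keep = np.ones_like(values, dtype=bool)
    floor = values == FLOOR
    for j in range(values.shape[1]):
        run = floor[1:, j] & floor[:-1, j]
        hits = np.nonzero(run)[0]
        if len(hits):
            keep[hits[0] + 1 :, j] = False
    return keep


def metric_means(
    series: EyeSeries, metric: Metric, window: str = "all", censor_scotoma: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-visit metric means and their elapsed years within a window.

    With ``censor_scotoma``, loci that reached scotoma (two consecutive −1 dB
    readings, judged over the full series) are dropped from the mean from the
    second such visit onward.  Visits whose effective locus set is empty are
    omitted.
    """
    sel = series.selections[metric]
    loci = sorted(sel.trend_ids)
    idx = _window_indices(series, window)
    if not loci or not len(idx):
        return np.array([]), np.array([])
    if censor_scotoma:
        all_idx = series.followup_indices()
        full = _visit_matrix(series, loci, all_idx)
        keep_full = _censor_scotoma_mask(full)
        pos = {v: k for k, v in enumerate(all_idx)}
        vals = _visit_matrix(series, loci, idx)
        keep = keep_full[[pos[i] for i in idx], :]
        with np.errstate(invalid="ignore"):
            means = np.where(
                keep.any(axis=1),
                np.nanmean(np.where(keep, vals, np.nan), axis=1),
                np.nan,
            )
    else:
        means = _visit_matrix(series, loci, idx).mean(axis=1)
    years = series.years[idx]
    ok = np.isfinite(means)
    return years[ok], means[ok]


def trend(
    series: EyeSeries,
    metric: Metric,
    window: str = "all",
    censor_scotoma: bool = False,
) -> TrendResult:
    """OLS slope of the metric mean against years (dB/year)."""
    years, means = metric_means(series, metric, window, censor_scotoma)
    if len(years) < 2 or np.ptp(years) == 0:
        return TrendResult(metric, window, math.nan, math.nan, len(years),
                           float(np.ptp(years)) if len(years) else 0.0)
    fit = _stats.linregress(years, means)
    return TrendResult(
        metric=metric,
        window=window,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_visits=len(years),
        follow_up=float(years[-1] - years[0]),
    )


def _event_target_index(series: EyeSeries, window: str) -> int | None:
    idx = series.followup_indices()
    idx = idx[idx > 0]  # baseline cannot be its own target
    if not len(idx):
        return None
    if window == "all":
        return int(idx[-1])
    if window == "2y":
        dist = np.abs(series.years[idx] - 2.0)
        j = int(np.argmin(dist))
        return int(idx[j]) if dist[j] <= EVENT_2Y_TOL else None
    raise ValueError("event analysis supports windows '2y' and 'all'")


def event(
    series: EyeSeries,
    metric: Metric,
    window: str = "2y",
    threshold_db: float = EVENT_THRESHOLD_DB,
    min_loci: int = 5,
) -> EventResult:
    """FDA-style event outcome: mean change ≤ threshold over prespecified loci.

    Eligibility requires ≥ ``min_loci`` prespecified loci with baseline
    ≥ 8 dB.  The target visit is the final visit (``all``) or the visit
    nearest 2.0 years within ±0.5 years (``2y``).  The boundary is
    inclusive: a mean change exactly at the threshold is an event.
    """
    sel = series.selections[metric]
    loci = sorted(sel.event_ids)
    if len(loci) < min_loci:
        return EventResult(metric, window, False, len(loci), math.nan, False,
                           math.nan, math.nan,
                           reason=f"only {len(loci)} event-eligible loci (< {min_loci})")
    t = _event_target_index(series, window)
    if t is None:
        return EventResult(metric, window, True, len(loci), math.nan, False,
                           math.nan, math.nan, reason="no target visit in window")
    base, tgt = series.visits[0], series.visits[t]
    changes = np.array([tgt[l] - base[l] for l in loci], dtype=float)
    mean_change = float(changes.mean())
    elapsed = float(series.years[t])
    return EventResult(
        metric=metric,
        window=window,
        eligible=True,
        n_loci=len(loci),
        mean_change=mean_change,
        event=mean_change <= threshold_db,
        mean_rate=mean_change / elapsed,
        target_years=elapsed,
    )


def floor_diagnostics(
    series: EyeSeries, metric: Metric, window: str = "all"
) -> float:
    """Fraction of the metric's loci reaching scotoma within the window.

    Reached-scotoma means ≥ 2 consecutive −1 dB readings among the window's
    follow-up visits; a single isolated −1 does not count.
    """
    sel = series.selections[metric]
    loci = sorted(sel.locus_ids)
    if not loci:
        return math.nan
    idx = _window_indices(series, window)
    if len(idx) < 2:
        return 0.0
    vals = _visit_matrix(series, loci, idx)
    floor = vals == FLOOR
    reached = (floor[1:] & floor[:-1]).any(axis=0)
    return float(reached.mean())


def analyze_eye(
    series: EyeSeries,
    windows: tuple[str, ...] = ("2y", "all"),
    censor_scotoma: bool = False,
    event_threshold_db: float = EVENT_THRESHOLD_DB,
):
    """Per-eye result rows: one dict per metric × window.

    Columns follow the results-file schema: eye_id, metric, window, slope,
    n_visits, follow_up_years, n_event_loci, mean_change, event, mean_rate,
    prop_floor.
    """
    rows = []
    for metric in series.selections:
        for window in windows:
            tr = trend(series, metric, window, censor_scotoma)
            ev = (
                event(series, metric, window, threshold_db=event_threshold_db)
                if window in ("2y", "all")
                else None
            )
            rows.append(
                {
                    "eye_id": series.eye_id,
                    "metric": metric.value,
                    "window": window,
                    "slope": tr.slope,
                    "intercept": tr.intercept,
                    "n_visits": tr.n_visits,
                    "follow_up_years": tr.follow_up,
                    "n_event_loci": ev.n_loci if ev else np.nan,
                    "mean_change": ev.mean_change if ev else np.nan,
                    "event": ev.event if ev and ev.eligible else np.nan,
                    "event_eligible": ev.eligible if ev else np.nan,
                    "mean_rate": ev.mean_rate if ev else np.nan,
                    "prop_floor": floor_diagnostics(series, metric, window),
                }
            )
    return rows
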
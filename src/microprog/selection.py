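"""Baseline loci preselection: MMS, ESS, mFTP and HRS.

Four baseline-frozen subsets of the 68-locus grid are compared as candidate
progression endpoints:

* **MMS** (mean macular sensitivity): all 68 loci, −1 dB floor values
  included arithmetically in the mean.
* **ESS** (edge-of-scotoma sensitivity): the seeing loci adjacent to at
  least one scotomatous (−1 dB) locus at baseline.
* **mFTP** (modified functional transition point): loci with baseline
  sensitivity ≥ 8 dB, ranked by the proportion of adjacent loci that are
  ≥ 7 dB lower; all 100%-proportion loci are taken, expanding whole
  next-highest-proportion tiers until at least 5 loci are selected.
* **HRS** (hyperautofluorescent-ring sensitivity): loci whose 2°×2° squares
  are transected by the registered ring boundary; loci already at −1 dB at
  baseline are excluded from trend analysis.

Selections are frozen at baseline and reused at every follow-up visit.
Event-based analysis additionally requires ≥ 5 prespecified loci with
baseline sensitivity ≥ 8 dB.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import TestGrid
from .registration import RingPolygon, transects

__all__ = [
    "Metric",
    "SensitivityField",
    "LociSelection",
    "FtpRanking",
    "select_mms",
    "select_ess",
    "rank_ftp",
    "select_mftp",
    "select_hrs",
    "freeze_selections",
    "evaluate",
    "FTP_DROP_DB",
    "EVENT_BASELINE_MIN_DB",
    "MIN_EVENT_LOCI",
]

#: Neighbour decrease (dB) counting as a transition-zone drop.
FTP_DROP_DB = 7
#: Minimum baseline sensitivity (dB) for mFTP membership and event eligibility.
EVENT_BASELINE_MIN_DB = 8
#: Minimum number of prespecified loci for event-based analysis.
MIN_EVENT_LOCI = 5

FLOOR = -1  # dB code for "not seen at maximum luminance"


class Metric(str, Enum):
    MMS = "MMS"
    ESS = "ESS"
    MFTP = "mFTP"
    HRS = "HRS"


@dataclass(frozen=True)
class SensitivityField:
    """One visit's sensitivity value (integer dB) per grid locus.

    Values are integers in {−1, 0..36}; −1 encodes "not seen at the
    brightest stimulus".
    """

    values: Mapping[int, int]
    visit_date: _dt.date | None = None
    followup_mode: bool = True

    def validate(self, grid: TestGrid) -> None:
        missing = set(grid.locus_ids) - set(self.values)
        extra = set(self.values) - set(grid.locus_ids)
        if missing or extra:
            raise ValueError(
                f"field does not match grid: missing loci {sorted(missing)}, "
                f"unknown loci {sorted(extra)}"
            )
        for i, v in self.values.items():
            if not float(v).is_integer() or not (v == FLOOR or 0 <= v <= 36):
                raise ValueError(
                    f"locus {i}: threshold {v} not an integer in {{-1, 0..36}}"
                )

    def __getitem__(self, locus_id: int) -> int:
        return int(self.values[locus_id])


@dataclass(frozen=True)
class LociSelection:
    """A named, baseline-frozen locus subset with eligibility bookkeeping.

    ``trend_ids`` are the loci entering per-visit metric means (for HRS this
    excludes loci already at −1 dB at baseline); ``event_ids`` are the loci
    with baseline ≥ 8 dB usable for the event-based endpoint.  ``provenance``
    records per-locus selection evidence (e.g. the mFTP proportion, or
    "transected" for HRS).  ``flags`` carries warnings such as
    ``no_scotoma``, ``no_hrs_loci`` or ``ineligible_for_event``.
    """

    metric: Metric
    locus_ids: frozenset[int]
    trend_ids: frozenset[int]
    event_ids: frozenset[int]
    provenance: Mapping[int, object] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.event_ids <= self.locus_ids:
            raise ValueError("event-eligible loci must be a subset of the selection")
        if not self.trend_ids <= self.locus_ids:
            raise ValueError("trend loci must be a subset of the selection")

    @property
    def event_eligible(self) -> bool:
        return len(self.event_ids) >= MIN_EVENT_LOCI


def _event_ids(ids, baseline: SensitivityField) -> frozenset[int]:
    return frozenset(i for i in ids if baseline[i] >= EVENT_BASELINE_MIN_DB)


def select_mms(baseline: SensitivityField, grid: TestGrid) -> LociSelection:
    """All 68 loci; −1 dB values participate in the mean."""
    ids = frozenset(grid.locus_ids)
    return LociSelection(
        metric=Metric.MMS,
        locus_ids=ids,
        trend_ids=ids,
        event_ids=_event_ids(ids, baseline),
        provenance={i: "all" for i in ids},
    )


def select_ess(baseline: SensitivityField, grid: TestGrid) -> LociSelection:
    """Seeing loci adjacent to a scotomatous (−1 dB) locus at baseline.

    Scotomatous loci themselves are excluded: the metric measures the seeing
    edge of the scotoma.  If the baseline has no scotomatous locus the
    selection is empty and flagged ``no_scotoma``.
    """
    scotoma = {i for i in grid.locus_ids if baseline[i] == FLOOR}
    edge = frozenset(
        i
        for i in grid.locus_ids
        if baseline[i] != FLOOR and grid.neighbors(i) & scotoma
    )
    flags = ("no_scotoma",) if not scotoma else ()
    if len(_event_ids(edge, baseline)) < MIN_EVENT_LOCI:
        flags += ("ineligible_for_event",)
    return LociSelection(
        metric=Metric.ESS,
        locus_ids=edge,
        trend_ids=edge,
        event_ids=_event_ids(edge, baseline),
        provenance={i: "edge_of_scotoma" for i in edge},
        flags=flags,
    )


@dataclass(frozen=True)
class FtpRanking:
    """Per-locus transition-point ranking table.

    One row per locus with baseline ≥ 8 dB (and ≥ 1 neighbour): columns
    ``locus_id``, ``baseline_db``, ``n_neighbors``, ``n_drops`` (adjacent
    loci ≥ 7 dB lower) and ``proportion`` = n_drops / n_neighbors.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.table["proportion"]
        if len(p) and not ((p >= 0) & (p <= 1)).all():
            raise ValueError("proportions must lie in [0, 1]")


def rank_ftp(
    baseline: SensitivityField,
    grid: TestGrid,
    drop_db: int = FTP_DROP_DB,
    min_baseline_db: int = EVENT_BASELINE_MIN_DB,
    peripheral_only: bool = False,
) -> FtpRanking:
    """Rank loci by the proportion of adjacent loci ≥ ``drop_db`` dB lower.

    Only loci with baseline ≥ ``min_baseline_db`` are ranked.  Floor-coded
    neighbours enter arithmetically (a −1 dB neighbour of an 8 dB locus is a
    9 dB drop).  With ``peripheral_only`` the neighbourhood is restricted to
    more eccentric neighbours; loci left with no neighbours are excluded
    (undefined denominator).
    """
    rows = []
    for locus in grid.loci:
        v = baseline[locus.id]
        if v == FLOOR or v < min_baseline_db:
            continue
        nbrs = grid.neighbors(locus.id)
        if peripheral_only:
            ecc = locus.eccentricity
            nbrs = frozenset(
                j for j in nbrs if grid.locus(j).eccentricity > ecc
            )
        if not nbrs:
            continue
        drops = sum(1 for j in nbrs if v - baseline[j] >= drop_db)
        rows.append(
            {
                "locus_id": locus.id,
                "baseline_db": v,
                "n_neighbors": len(nbrs),
                "n_drops": drops,
                "proportion": drops / len(nbrs),
            }
        )
    table = pd.DataFrame(
        rows, columns=["locus_id", "baseline_db", "n_neighbors", "n_drops", "proportion"]
    )
    return FtpRanking(table)


def select_mftp(
    ranking: FtpRanking,
    baseline: SensitivityField,
    min_loci: int = MIN_EVENT_LOCI,
) -> LociSelection:
    """Select modified-FTP loci from a ranking.

    All loci with proportion 1.0 are taken; while fewer than ``min_loci``
    are selected and a strictly positive next-highest proportion tier
    exists, the entire tier is added (ties are never broken arbitrarily, so
    the selection may exceed ``min_loci``).  Zero-proportion loci carry no
    transition-zone signal and are never selectable; an eye without
    ``min_loci`` positive-proportion loci is flagged
    ``ineligible_for_event`` rather than padded.
    """
    t = ranking.table
    selected: set[int] = set()
    prov: dict[int, float] = {}
    flags: tuple[str, ...] = ()
    if len(t):
        positive = t[t["proportion"] > 0]
        tiers = sorted(positive["proportion"].unique(), reverse=True)
        for tier in tiers:
            if tier < 1.0 and len(selected) >= min_loci:
                break
            members = positive.loc[positive["proportion"] == tier, "locus_id"]
            selected.update(int(i) for i in members)
            prov.update({int(i): float(tier) for i in members})
    if len(selected) < min_loci:
        flags += ("ineligible_for_event",)
    ids = frozenset(selected)
    return LociSelection(
        metric=Metric.MFTP,
        locus_ids=ids,
        trend_ids=ids,
        event_ids=_event_ids(ids, baseline),
        provenance=prov,
        flags=flags,
    )


def select_hrs(
    baseline: SensitivityField, grid: TestGrid, ring: RingPolygon
) -> LociSelection:
    """Loci whose 2°×2° squares are transected by the ring boundary.

    Loci at −1 dB at baseline stay in the selection but are excluded from
    trend analysis.  A ring whose boundary misses every square (e.g. a ring
    larger than the grid) yields an empty selection flagged ``no_hrs_loci``.
    """
    hit = frozenset(
        i for i, sq in grid.squares.items() if transects(sq, ring)
    )
    trend = frozenset(i for i in hit if baseline[i] != FLOOR)
    flags: tuple[str, ...] = ()
    if not hit:
        flags += ("no_hrs_loci",)
    if len(_event_ids(hit, baseline)) < MIN_EVENT_LOCI:
        flags += ("ineligible_for_event",)
    prov = {
        i: ("transected, excluded_from_trend" if i not in trend else "transected")
        for i in hit
    }
    return LociSelection(
        metric=Metric.HRS,
        locus_ids=hit,
        trend_ids=trend,
        event_ids=_event_ids(hit, baseline),
        provenance=prov,
        flags=flags,
    )


def freeze_selections(
    baseline: SensitivityField,
    grid: TestGrid,
    ring: RingPolygon | None,
    drop_db: int = FTP_DROP_DB,
    min_baseline_db: int = EVENT_BASELINE_MIN_DB,
    min_loci: int = MIN_EVENT_LOCI,
    peripheral_only: bool = False,
) -> dict[Metric, LociSelection]:
    """Compute all four baseline selections for one eye.

    HRS is omitted when no ring is available.
    """
    baseline.validate(grid)
    out = {
        Metric.MMS: select_mms(baseline, grid),
        Metric.ESS: select_ess(baseline, grid),
        Metric.MFTP: select_mftp(
            rank_ftp(baseline, grid, drop_db, min_baseline_db, peripheral_only),
            baseline,
            min_loci,
        ),
    }
    if ring is not None:
        out[Metric.HRS] = select_hrs(baseline, grid, ring)
    return out


def evaluate(selection: LociSelection, field: SensitivityField) -> float:
    """Mean sensitivity (dB) of a visit over the selection's trend loci.

    Floor-coded −1 dB readings enter arithmetically (MMS/ESS/mFTP
    definition); HRS baseline-scotomatous loci were already removed from
    ``trend_ids`` at selection time.  An empty effective set yields NaN,
    never a silent 0.
    """
    if not selection.trend_ids:
        return math.nan
    return float(np.mean([field[i] for i in selection.trend_ids]))
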
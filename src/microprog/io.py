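"""File formats, study configuration, and the end-to-end pipeline.

The native device export format is proprietary and undocumented, so the
package defines a simple headered-CSV dialect for each artifact:

* **visit file** — one row per locus: ``locus_id, x_deg, y_deg,
  threshold_db, visit_date, followup_mode, eye_id, laterality``; exactly one
  row per grid locus, integer thresholds in {−1, 0..36}, positions matching
  the constructed grid to 1e−6°.
* **ring file** — vertices, either in degrees (``x_deg, y_deg``) or in AF
  pixels (``x_px, y_px``).
* **landmark file** — ``src_x, src_y, dst_x, dst_y`` (AF px → MAIA px).
* **selection file** — ``metric, locus_id, x_deg, y_deg, baseline_db,
  provenance, trend_eligible, event_eligible``.
* **results file** — one row per eye × metric × window (see
  :func:`microprog.progression.analyze_eye`).

A cohort directory holds ``<eye>_visit<k>.csv`` files plus per-eye
``<eye>_ring_deg.csv`` (or ``_ring_px.csv`` + ``_landmarks.csv``) inputs.

All analysis thresholds (7 dB neighbour drop, 8 dB baseline eligibility,
−7 dB event threshold, 5-locus minimum) live in :class:`StudyConfig` as
data, not code, and every run logs the thresholds it used.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import progression, selection as _sel, stats as _stats
from .grid import AdjacencyScheme, TestGrid, build_grid
from .progression import EyeSeries, analyze_eye, check_eligibility
from .registration import (
    MAIA_IMAGE,
    SWAF_IMAGE,
    ImageSpec,
    RingPolygon,
    fit_similarity,
    ring_to_degrees,
)
from .selection import Metric, SensitivityField, freeze_selections

__all__ = [
    "StudyConfig",
    "VisitFileError",
    "load_visit",
    "save_visit",
    "load_ring_degrees",
    "save_ring_degrees",
    "load_ring_pixels",
    "save_ring_pixels",
    "load_landmarks",
    "save_landmarks",
    "save_selections",
    "save_grid",
    "load_grid",
    "write_cohort",
    "load_cohort",
    "run_pipeline",
]

log = logging.getLogger("microprog")

VISIT_COLUMNS = [
    "locus_id", "x_deg", "y_deg", "threshold_db",
    "visit_date", "followup_mode", "eye_id", "laterality",
]


class VisitFileError(ValueError):
    """A visit export violating the file contract (message cites row numbers)."""


@dataclass
class StudyConfig:
    """Every tunable of the analysis, defaulted to the study values."""

    # grid
    eccentricity_cut: float = 9.2
    adjacency_scheme: str = AdjacencyScheme.CHEBYSHEV8.value
    mirror_right_eyes: bool = False
    # registration
    af_fov: float = SWAF_IMAGE.field_of_view
    af_res: int = SWAF_IMAGE.resolution
    maia_fov: float = MAIA_IMAGE.field_of_view
    maia_res: int = MAIA_IMAGE.resolution
    # analysis thresholds
    drop_db: int = 7                 # neighbour decrease defining a transition drop
    baseline_min_db: int = 8         # event/mFTP baseline eligibility
    event_threshold_db: float = -7.0  # mean change <= this is an event
    min_event_loci: int = 5
    peripheral_only: bool = False
    censor_scotoma: bool = False
    windows: tuple[str, ...] = ("2y", "all")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "windows" in d:
            d["windows"] = tuple(d["windows"])
        return cls(**d)

    def build_grid(self) -> TestGrid:
        return build_grid(self.eccentricity_cut, self.adjacency_scheme)

    @property
    def af_image(self) -> ImageSpec:
        return ImageSpec(self.af_fov, self.af_res)

    @property
    def maia_image(self) -> ImageSpec:
        return ImageSpec(self.maia_fov, self.maia_res)


# --------------------------------------------------------------------------
# Visit files


def save_visit(
    path: str | Path,
    fieldmap: SensitivityField,
    grid: TestGrid,
    eye_id: str,
    laterality: str = "OS",
) -> None:
    rows = [
        {
            "locus_id": l.id,
            "x_deg": l.x,
            "y_deg": l.y,
            "threshold_db": fieldmap[l.id],
            "visit_date": fieldmap.visit_date.isoformat() if fieldmap.visit_date else "",
            "followup_mode": int(fieldmap.followup_mode),
            "eye_id": eye_id,
            "laterality": laterality,
        }
        for l in grid.loci
    ]
    pd.DataFrame(rows, columns=VISIT_COLUMNS).to_csv(path, index=False)


def load_visit(
    path: str | Path, grid: TestGrid, mirror: bool = False
) -> SensitivityField:
    """Read and validate one visit export.

    ``mirror`` flips x (for right eyes when mirroring is enabled) before
    matching positions against the grid.  Violations raise
    :class:`VisitFileError` naming the offending rows (1-based, excluding
    the header).
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in VISIT_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise VisitFileError(f"{path}: missing columns {missing_cols}")
    values: dict[int, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        lid = int(row.locus_id)
        thr = row.threshold_db
        if float(thr) != int(thr):
            raise VisitFileError(
                f"{path} row {row_no}: threshold {thr} is not an integer"
            )
        thr = int(thr)
        if not (thr == -1 or 0 <= thr <= 36):
            raise VisitFileError(
                f"{path} row {row_no}: threshold {thr} outside {{-1, 0..36}}"
            )
        x, y = float(row.x_deg), float(row.y_deg)
        if mirror:
            # right-eye mirroring: re-identify the locus by flipped position
            try:
                locus = grid.locus_at(-x, y, tol=1e-6)
            except KeyError:
                raise VisitFileError(
                    f"{path} row {row_no}: mirrored position ({-x}, {y}) "
                    f"matches no grid locus"
                )
            if locus.id in values:
                raise VisitFileError(
                    f"{path} row {row_no}: duplicate mirrored locus {locus.id}"
                )
            values[locus.id] = thr
            continue
        if lid in values:
            raise VisitFileError(f"{path} row {row_no}: duplicate locus id {lid}")
        try:
            locus = grid.locus(lid)
        except KeyError:
            raise VisitFileError(f"{path} row {row_no}: unknown locus id {lid}")
        if abs(locus.x - x) > 1e-6 or abs(locus.y - y) > 1e-6:
            raise VisitFileError(
                f"{path} row {row_no}: position ({x}, {y}) does not "
                f"match locus {lid} at ({locus.x}, {locus.y})"
            )
        values[lid] = thr
    missing = set(grid.locus_ids) - set(values)
    if missing:
        raise VisitFileError(
            f"{path}: missing loci {sorted(missing)} ({len(values)} of "
            f"{len(grid)} rows present)"
        )
    first = df.iloc[0]
    date = (
        _dt.date.fromisoformat(str(first["visit_date"]))
        if "visit_date" in df.columns and str(first.get("visit_date", "")) not in ("", "nan")
        else None
    )
    followup = bool(int(first["followup_mode"])) if "followup_mode" in df.columns else True
    return SensitivityField(values=values, visit_date=date, followup_mode=followup)


# --------------------------------------------------------------------------
# Rings, landmarks, grids, selections


def save_ring_degrees(path: str | Path, ring: RingPolygon) -> None:
    pd.DataFrame(ring.vertices, columns=["x_deg", "y_deg"]).to_csv(path, index=False)


def load_ring_degrees(path: str | Path, is_complete: bool = True) -> RingPolygon:
    df = pd.read_csv(path)
    return RingPolygon(df[["x_deg", "y_deg"]].to_numpy(float), is_complete=is_complete)


def save_ring_pixels(path: str | Path, vertices: np.ndarray) -> None:
    pd.DataFrame(np.asarray(vertices), columns=["x_px", "y_px"]).to_csv(path, index=False)


def load_ring_pixels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["x_px", "y_px"]].to_numpy(float)


def save_landmarks(path: str | Path, src: np.ndarray, dst: np.ndarray) -> None:
    arr = np.hstack([np.asarray(src, float), np.asarray(dst, float)])
    pd.DataFrame(arr, columns=["src_x", "src_y", "dst_x", "dst_y"]).to_csv(
        path, index=False
    )


def load_landmarks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df[["src_x", "src_y"]].to_numpy(float),
        df[["dst_x", "dst_y"]].to_numpy(float),
    )


def save_grid(path: str | Path, grid: TestGrid) -> None:
    pd.DataFrame(
        [{"id": l.id, "x_deg": l.x, "y_deg": l.y} for l in grid.loci]
    ).to_csv(path, index=False)


def load_grid(path: str | Path, config: StudyConfig | None = None) -> TestGrid:
    """Rebuild the grid from config and check it matches the stored CSV."""
    config = config or StudyConfig()
    grid = config.build_grid()
    df = pd.read_csv(path)
    stored = list(zip(df["id"], df["x_deg"], df["y_deg"]))
    built = [(l.id, l.x, l.y) for l in grid.loci]
    if [(int(i), float(x), float(y)) for i, x, y in stored] != built:
        raise ValueError(f"{path}: stored grid does not match the configured grid")
    return grid


def save_selections(
    path: str | Path,
    selections: dict[Metric, _sel.LociSelection],
    baseline: SensitivityField,
    grid: TestGrid,
) -> None:
    rows = []
    for metric, sel in selections.items():
        for i in sorted(sel.locus_ids):
            l = grid.locus(i)
            rows.append(
                {
                    "metric": metric.value,
                    "locus_id": i,
                    "x_deg": l.x,
                    "y_deg": l.y,
                    "baseline_db": baseline[i],
                    "provenance": sel.provenance.get(i, ""),
                    "trend_eligible": int(i in sel.trend_ids),
                    "event_eligible": int(i in sel.event_ids),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "metric", "locus_id", "x_deg", "y_deg", "baseline_db",
            "provenance", "trend_eligible", "event_eligible",
        ],
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Cohort directories


def write_cohort(out_dir: str | Path, eyes, grid: TestGrid) -> None:
    """Write simulated eyes as a cohort directory of CSV inputs.

    Accepts :class:`microprog.simulate.SimulatedEye` objects; writes visit
    files, the degree-space ring, the pixel-space ring and landmarks (so the
    registration stage can be exercised end to end), and a ground-truth
    summary JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_grid(out / "grid.csv", grid)
    meta = {}
    for sim in eyes:
        s = sim.series
        for k, visit in enumerate(s.visits):
            save_visit(out / f"{s.eye_id}_visit{k}.csv", visit, grid, s.eye_id)
        if s.ring is not None:
            save_ring_degrees(out / f"{s.eye_id}_ring_deg.csv", s.ring)
        reg = sim.registration
        save_ring_pixels(out / f"{s.eye_id}_ring_px.csv", reg.ring_af_px)
        save_landmarks(
            out / f"{s.eye_id}_landmarks.csv", reg.landmarks_src, reg.landmarks_dst
        )
        meta[s.eye_id] = {
            "years": [float(y) for y in s.years],
            "age_at_baseline": s.age_at_baseline,
            "ring_in_grid": bool(sim.ring_in_grid),
        }
    (out / "cohort.json").write_text(json.dumps(meta, indent=1))


def load_cohort(
    in_dir: str | Path, config: StudyConfig | None = None
) -> tuple[list[EyeSeries], TestGrid]:
    """Load a cohort directory, running registration where needed.

    Rings provided directly in degrees are used as-is; otherwise a pixel
    ring plus landmarks is registered into degrees.  Selections are frozen
    from each eye's baseline visit.
    """
    config = config or StudyConfig()
    in_dir = Path(in_dir)
    grid = config.build_grid()
    meta_path = in_dir / "cohort.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no cohort.json in {in_dir}")
    meta = json.loads(meta_path.read_text())
    if not meta:
        raise ValueError(f"{in_dir}: cohort contains no eyes")
    out = []
    for eye_id, info in meta.items():
        years = np.asarray(info["years"], dtype=float)
        visits = [
            load_visit(in_dir / f"{eye_id}_visit{k}.csv", grid)
            for k in range(len(years))
        ]
        deg_path = in_dir / f"{eye_id}_ring_deg.csv"
        px_path = in_dir / f"{eye_id}_ring_px.csv"
        lm_path = in_dir / f"{eye_id}_landmarks.csv"
        ring = None
        if deg_path.exists():
            ring = load_ring_degrees(deg_path)
        elif px_path.exists() and lm_path.exists():
            src, dst = load_landmarks(lm_path)
            t = fit_similarity(src, dst)
            log.info("%s: registration rmse %.3f px", eye_id, t.rmse)
            ring = ring_to_degrees(
                load_ring_pixels(px_path), t, config.af_image, config.maia_image
            )
        series = EyeSeries(
            eye_id=eye_id,
            visits=visits,
            years=years,
            ring=ring,
            age_at_baseline=info.get("age_at_baseline"),
        )
        series.selections = freeze_selections(
            visits[0], grid, ring,
            drop_db=config.drop_db,
            min_baseline_db=config.baseline_min_db,
            min_loci=config.min_event_loci,
            peripheral_only=config.peripheral_only,
        )
        out.append(series)
    return out, grid


# --------------------------------------------------------------------------
# End-to-end pipeline


def run_pipeline(
    config: StudyConfig,
    input_dir: str | Path | None = None,
    cohort: list[EyeSeries] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """register → select → progress → compare over a cohort.

    Either ``input_dir`` (a cohort directory) or a pre-loaded ``cohort`` must
    be given.  Returns a dict with the per-eye results DataFrame
    (``results``), per-window ANOVA comparisons of slopes (``anova``), and
    eligibility bookkeeping; optionally writes CSV/JSON outputs.
    """
    log.info(
        "thresholds: drop_db=%s baseline_min_db=%s event_threshold_db=%s "
        "min_event_loci=%s censor_scotoma=%s",
        config.drop_db, config.baseline_min_db, config.event_threshold_db,
        config.min_event_loci, config.censor_scotoma,
    )
    if cohort is None:
        if input_dir is None:
            raise ValueError("either input_dir or cohort is required")
        cohort, _ = load_cohort(input_dir, config)
    if not cohort:
        raise ValueError("no eyes to analyze")

    rows, eligibility = [], {}
    for series in cohort:
        ok, reasons = check_eligibility(series)
        eligibility[series.eye_id] = {"eligible": ok, "reasons": reasons}
        if not ok:
            log.info("%s excluded: %s", series.eye_id, "; ".join(reasons))
            continue
        try:
            rows.extend(
                analyze_eye(
                    series,
                    windows=config.windows,
                    censor_scotoma=config.censor_scotoma,
                    event_threshold_db=config.event_threshold_db,
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(
                f"progression analysis failed for eye {series.eye_id}"
            ) from exc
    results = pd.DataFrame(rows)

    anova = {}
    for window in config.windows:
        sub = results[results["window"] == window]
        matrix = sub.pivot(index="eye_id", columns="metric", values="slope")
        try:
            anova[window] = _stats.compare_metrics(matrix)
        except ValueError as exc:
            log.info("ANOVA skipped for window %s: %s", window, exc)
            anova[window] = None

    bundle = {"results": results, "anova": anova, "eligibility": eligibility}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        (out / "anova.json").write_text(json.dumps(
            {
                w: _anova_to_dict(a) for w, a in anova.items()
            },
            indent=1,
        ))
    return bundle


def _anova_to_dict(a) -> dict | None:
    if a is None:
        return None
    d = {"F": a.F, "df": list(a.df), "p": a.p, "n_subjects": a.n_subjects}
    if a.pairwise:
        d["pairwise"] = [
            {
                "pair": list(e.pair),
                "mean_diff": e.mean_diff,
                "p_raw": None if math.isnan(e.p_raw) else e.p_raw,
                "p_bonferroni": None if math.isnan(e.p_bonferroni) else e.p_bonferroni,
                "degenerate": e.degenerate,
            }
            for e in a.pairwise
        ]
    return d
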
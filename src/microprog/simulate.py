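"""Synthetic longitudinal microperimetry cohorts with known ground truth.

No public dataset pairs longitudinal 10-2 microperimetry with segmented
hyperautofluorescent rings, so the pipeline is exercised on a generative
model of rod-cone degeneration with a contracting ring:

* a "hill of vision" with a preserved central plateau (``s_max`` dB), a
  degenerate periphery at ``floor_level`` dB (below the measurable floor),
  and a logistic transition of width ``width`` centred on the ring radius:
  ``s(r, t) = floor + (s_max − floor) · σ((R(t) − r) / width)``;
* ring contraction ``R(t) = R0 − contraction·t`` (degrees/year), baseline
  radius drawn per eye from U[3, 8]°;
* heteroscedastic test-retest noise, steeper where the spatial gradient is
  larger (sensitivity at scotoma borders retests worse than in normal
  retina): sd = ``sigma0 + sigma1·|∂s/∂r|``;
* thresholds rounded to integer dB and floor-censored: values below 0 dB
  are recorded as −1 ("not seen"), values above 36 dB clip to 36.

Each eye also gets a consistent registration exercise: the ring is expressed
in SW-AF pixels through the inverse of a random per-eye similarity transform
between the AF and MAIA pixel frames, plus four corner landmark pairs from
which that transform can be re-estimated.  Everything is deterministic under
the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import TestGrid, build_grid
from .progression import EyeSeries
from .registration import (
    MAIA_IMAGE,
    SWAF_IMAGE,
    ImageSpec,
    RingPolygon,
    SimilarityTransform,
    circle_polygon,
)
from .selection import LociSelection, SensitivityField

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RegistrationArtifacts",
    "SimulatedEye",
    "generate",
    "truth_rates",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative-model parameters (defaults are the study conditions).

    Nine 6-monthly visits give 4 years of follow-up, matching the observed
    mean follow-up of such natural-history series; the 24 dB plateau,
    −5 dB latent floor, 0.25°/year ring contraction and 1.5° transition
    width produce baseline metric levels and progression rates of the order
    seen in rod-cone degeneration.
    """

    n_eyes: int = 30
    n_visits: int = 9
    visit_interval: float = 0.5     # years
    s_max: float = 24.0             # dB plateau of the preserved centre
    floor_level: float = -5.0       # dB latent level of degenerate retina
    r0_range: tuple[float, float] = (3.0, 8.0)  # per-eye baseline ring radius, deg
    contraction: float = 0.25       # ring contraction, degrees/year
    width: float = 1.5              # transition-zone width, degrees
    sigma0: float = 1.0             # baseline test-retest sd, dB
    sigma1: float = 0.5             # extra sd per dB/degree of local gradient
    ring_offset: float = 0.0        # ring radius minus half-sensitivity radius, deg
    axis_ratio: float = 1.0         # ellipse x/y semi-axis ratio of the ring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 1 or self.n_eyes < 1:
            raise ValueError("n_eyes and n_visits must be positive")
        if min(self.visit_interval, self.width, self.sigma0 + 1, self.axis_ratio) <= 0:
            raise ValueError("visit_interval, width and axis_ratio must be positive")
        if (self.n_visits - 1) * self.visit_interval < 2.0:
            raise ValueError(
                "n_visits * visit_interval must give >= 2 years of follow-up "
                "to produce eligible eyes"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless disease model underlying a generated cohort."""

    config: SimConfig
    r0: np.ndarray  # per-eye baseline ring radius (degrees)

    def ring_radius(self, eye: int, t: float) -> float:
        return float(self.r0[eye] - self.config.contraction * t)

    def field_value(self, eye: int, r, t: float):
        """Latent sensitivity s(r, t) in dB (uncensored, unrounded)."""
        c = self.config
        z = (self.ring_radius(eye, t) - np.asarray(r, dtype=float)) / c.width
        return c.floor_level + (c.s_max - c.floor_level) / (1.0 + np.exp(-z))

    def radial_gradient(self, eye: int, r, t: float):
        """∂s/∂r (dB/degree); magnitude drives the heteroscedastic noise."""
        c = self.config
        z = (self.ring_radius(eye, t) - np.asarray(r, dtype=float)) / c.width
        sig = 1.0 / (1.0 + np.exp(-z))
        return -(c.s_max - c.floor_level) * sig * (1.0 - sig) / c.width

    def decline_rate(self, eye: int, r, t: float):
        """∂s/∂t (dB/year) of the latent field."""
        return -self.radial_gradient(eye, r, t) * (-self.config.contraction)


@dataclass(frozen=True)
class RegistrationArtifacts:
    """Per-eye registration inputs consistent with the degree-space ring."""

    landmarks_src: np.ndarray   # AF pixels
    landmarks_dst: np.ndarray   # MAIA pixels
    ring_af_px: np.ndarray      # ring vertices in AF pixels
    transform: SimilarityTransform  # true AF px -> MAIA px transform
    af: ImageSpec = SWAF_IMAGE
    maia: ImageSpec = MAIA_IMAGE


@dataclass
class SimulatedEye:
    """One generated eye: the observable series plus its latent truth."""

    series: EyeSeries
    registration: RegistrationArtifacts
    eye_index: int
    ring_in_grid: bool = True


def _eye_radii(grid: TestGrid) -> np.ndarray:
    return np.array([l.eccentricity for l in grid.loci])


def generate(
    config: SimConfig = SimConfig(), grid: TestGrid | None = None
) -> tuple[list[SimulatedEye], GroundTruth]:
    """Generate a cohort of eyes under ``config`` (deterministic per seed)."""
    if grid is None:
        grid = build_grid()
    rng = np.random.default_rng(config.seed)
    r0 = rng.uniform(*config.r0_range, size=config.n_eyes)
    truth = GroundTruth(config=config, r0=r0)
    radii = _eye_radii(grid)
    ids = list(grid.locus_ids)
    times = np.arange(config.n_visits) * config.visit_interval

    eyes: list[SimulatedEye] = []
    grid_reach = max(radii) + math.sqrt(2.0)  # farthest square corner
    for e in range(config.n_eyes):
        visits = []
        for t in times:
            s = truth.field_value(e, radii, t)
            sd = config.sigma0 + config.sigma1 * np.abs(
                truth.radial_gradient(e, radii, t)
            )
            obs = np.rint(s + rng.normal(0.0, 1.0, size=len(radii)) * sd)
            obs = np.where(obs < 0, -1, np.minimum(obs, 36)).astype(int)
            visits.append(
                SensitivityField(values=dict(zip(ids, (int(v) for v in obs))))
            )
        ring_radius = truth.ring_radius(e, 0.0) + config.ring_offset
        ring_deg = circle_polygon(ring_radius, axis_ratio=config.axis_ratio)
        reg = _registration_artifacts(rng, ring_deg)
        series = EyeSeries(
            eye_id=f"sim{e:03d}",
            visits=visits,
            years=times.copy(),
            ring=ring_deg,
            age_at_baseline=float(rng.uniform(15.0, 60.0)),
        )
        eyes.append(
            SimulatedEye(
                series=series,
                registration=reg,
                eye_index=e,
                ring_in_grid=bool(
                    ring_radius * max(1.0, config.axis_ratio) <= grid_reach
                ),
            )
        )
    return eyes, truth


def _registration_artifacts(
    rng: np.random.Generator, ring_deg: RingPolygon
) -> RegistrationArtifacts:
    """Random AF→MAIA similarity + ring/landmarks consistent with it."""
    af, maia = SWAF_IMAGE, MAIA_IMAGE
    # Nominal frame-scale ratio jittered by the per-eye imaging geometry.
    scale = (af.degrees_per_pixel / maia.degrees_per_pixel) * rng.uniform(0.9, 1.1)
    rot = rng.uniform(-0.1, 0.1)
    c, s = math.cos(rot), math.sin(rot)
    m = scale * np.array([[c, -s], [s, c]])
    af_c = np.asarray(af.center_px)
    jitter = rng.uniform(-20.0, 20.0, size=2)
    trans = np.asarray(maia.center_px) + jitter - m @ af_c
    t = SimilarityTransform(scale, rot, (float(trans[0]), float(trans[1])))
    # Ring in MAIA px (undo the degrees conversion), then AF px via t^-1.
    deg = ring_deg.vertices.copy()
    deg[:, 1] *= -1.0
    maia_px = deg / maia.degrees_per_pixel + np.asarray(maia.center_px)
    ring_af_px = t.inverse().apply(maia_px)
    margin = 50.0
    corners = np.array(
        [
            [margin, margin],
            [af.resolution - margin, margin],
            [af.resolution - margin, af.resolution - margin],
            [margin, af.resolution - margin],
        ]
    )
    return RegistrationArtifacts(
        landmarks_src=corners,
        landmarks_dst=t.apply(corners),
        ring_af_px=ring_af_px,
        transform=t,
    )


def truth_rates(
    truth: GroundTruth,
    selection: LociSelection,
    eye: int,
    grid: TestGrid,
    window_years: float,
) -> float:
    """Exact time-averaged latent decline rate over a frozen selection.

    Mean over the selection's trend loci of ``(s(t_end) − s(0)) / t_end``
    from the noiseless model — the oracle for parameter-recovery checks.
    Returns NaN for an empty selection.
    """
    loci = sorted(selection.trend_ids)
    if not loci or window_years <= 0:
        return math.nan
    r = np.array([grid.locus(i).eccentricity for i in loci])
    s0 = truth.field_value(eye, r, 0.0)
    s1 = truth.field_value(eye, r, window_years)
    return float(np.mean(s1 - s0) / window_years)
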
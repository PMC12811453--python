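"""MAIA 10-2 stimulus grid: loci, square tessellation, adjacency, dB scale.

The 10-2 test pattern is a square array of 68 stimulus loci centred on the
fovea, spanning 18 degrees in diameter.  Loci sit on the lattice
``{±1, ±3, ±5, ±7, ±9}²`` (degrees from the vertical/horizontal meridians),
restricted to an eccentricity cut that drops the 8 outermost corners of each
quadrant.  Each locus is represented by a nonoverlapping, axis-aligned
2° × 2° square centred on it, used to test whether a hyperautofluorescent
ring boundary transects the locus.

Coordinates are *field* coordinates: origin at fixation, x positive to the
right, y positive up, units of degrees.  No left/right-eye mirroring is
applied here; mirroring is an I/O option (see :mod:`microprog.io`).

Sensitivity values are attenuations in dB relative to the brightest stimulus
(0 dB = 317.04 cd/m², 36 dB = 0.08 cd/m²); a −1 dB code marks a locus where
the brightest stimulus was not seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "AdjacencyScheme",
    "DbScale",
    "GridLocus",
    "TestGrid",
    "adjacency",
    "build_grid",
    "db_to_luminance",
    "luminance_to_db",
    "validate_neighbor_counts",
    "DEFAULT_ECCENTRICITY_CUT",
    "MAIA_DB_SCALE",
]

#: Half-grid coordinate levels of the 10-2 lattice (degrees).
_LEVELS = (-9, -7, -5, -3, -1, 1, 3, 5, 7, 9)

#: Open interval of admissible eccentricity cuts.  Any cut strictly between
#: the eccentricity of the most peripheral retained locus (|(9,1)| ≈ 9.0554)
#: and the nearest dropped lattice point (|(9,3)| ≈ 9.4868) yields the
#: standard 68-locus membership.
ECC_CUT_INTERVAL = (9.06, 9.49)

DEFAULT_ECCENTRICITY_CUT = 9.2


class AdjacencyScheme(str, Enum):
    """Which loci count as neighbours of a locus."""

    ORTHOGONAL4 = "orthogonal4"  #: Euclidean distance exactly 2° (rook moves)
    CHEBYSHEV8 = "chebyshev8"    #: Chebyshev distance ≤ 2° (rook + diagonal)
    CUSTOM = "custom"            #: user-supplied symmetric table


@dataclass(frozen=True)
class GridLocus:
    """One stimulus locus of the test grid."""

    id: int
    x: float
    y: float

    @property
    def eccentricity(self) -> float:
        """Euclidean distance from fixation, degrees."""
        return math.hypot(self.x, self.y)

    @property
    def square(self) -> tuple[float, float, float, float]:
        """The locus's 2°×2° tessellation square as (xmin, ymin, xmax, ymax)."""
        return (self.x - 1.0, self.y - 1.0, self.x + 1.0, self.y + 1.0)


@dataclass(frozen=True)
class DbScale:
    """Decibel attenuation scale of the microperimeter stimulus.

    ``luminance(d) = max_luminance * 10**(-d/10)`` — 0 dB is the brightest
    stimulus, larger dB means dimmer.  ``floor_code`` is the sentinel stored
    when the brightest stimulus was not detected; it is *not* a luminance.
    """

    max_luminance: float = 317.04  # cd/m² at 0 dB
    db_min: int = 0
    db_max: int = 36
    floor_code: int = -1

    def __post_init__(self) -> None:
        if not (self.floor_code < self.db_min or self.floor_code > self.db_max):
            raise ValueError("floor_code must lie outside the dB range")


#: The scale of the MAIA device used throughout.
MAIA_DB_SCALE = DbScale()


@dataclass(frozen=True)
class TestGrid:
    """The stimulus grid: ordered loci, squares, and an adjacency graph.

    Loci are ordered row-major from the superior-left (y descending, then
    x ascending) with ids 1..n; this ordering is stable under
    reconstruction and is the order used by the visit file format.
    """

    loci: tuple[GridLocus, ...]
    adjacency: Mapping[int, frozenset[int]]
    adjacency_scheme: AdjacencyScheme
    eccentricity_cut: float
    _by_id: Mapping[int, GridLocus] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {l.id: l for l in self.loci})

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, locus_id: int) -> GridLocus:
        return self._by_id[locus_id]

    @property
    def locus_ids(self) -> tuple[int, ...]:
        return tuple(l.id for l in self.loci)

    @property
    def squares(self) -> dict[int, tuple[float, float, float, float]]:
        """Mapping locus id → (xmin, ymin, xmax, ymax) of its 2°×2° square."""
        return {l.id: l.square for l in self.loci}

    def locus_at(self, x: float, y: float, tol: float = 1e-9) -> GridLocus:
        """Locus at field position (x, y); KeyError if none within tol."""
        for l in self.loci:
            if abs(l.x - x) <= tol and abs(l.y - y) <= tol:
                return l
        raise KeyError(f"no locus at ({x}, {y})")

    def neighbors(self, locus_id: int) -> frozenset[int]:
        return self.adjacency[locus_id]


def build_grid(
    eccentricity_cut: float = DEFAULT_ECCENTRICITY_CUT,
    adjacency_scheme: AdjacencyScheme | str = AdjacencyScheme.CHEBYSHEV8,
    custom_adjacency: Mapping[int, set[int]] | None = None,
) -> TestGrid:
    """Construct the 68-locus 10-2 grid.

    Parameters
    ----------
    eccentricity_cut
        Radial cut in degrees selecting lattice points; must lie in the open
        interval (9.06, 9.49), within which the standard 68-locus membership
        is reproduced.
    adjacency_scheme
        Neighbourhood definition used by edge-of-scotoma and transition-point
        loci selection; see :class:`AdjacencyScheme`.
    custom_adjacency
        Required iff ``adjacency_scheme`` is ``CUSTOM``: a symmetric,
        irreflexive table mapping locus id → set of neighbour ids.
    """
    lo, hi = ECC_CUT_INTERVAL
    if not (lo < eccentricity_cut < hi):
        raise ValueError(
            f"eccentricity_cut must lie in the open interval ({lo}, {hi}) "
            f"degrees to reproduce the 10-2 membership; got {eccentricity_cut}"
        )
    pts = [
        (x, y)
        for y in sorted(_LEVELS, reverse=True)
        for x in _LEVELS
        if math.hypot(x, y) <= eccentricity_cut
    ]
    loci = tuple(
        GridLocus(id=i + 1, x=float(x), y=float(y)) for i, (x, y) in enumerate(pts)
    )
    scheme = AdjacencyScheme(adjacency_scheme)
    grid = TestGrid(
        loci=loci,
        adjacency={},
        adjacency_scheme=scheme,
        eccentricity_cut=eccentricity_cut,
    )
    adj = adjacency(grid, scheme, custom_adjacency)
    return TestGrid(
        loci=loci,
        adjacency=adj,
        adjacency_scheme=scheme,
        eccentricity_cut=eccentricity_cut,
    )


def adjacency(
    grid: TestGrid,
    scheme: AdjacencyScheme | str,
    custom_table: Mapping[int, set[int]] | None = None,
) -> dict[int, frozenset[int]]:
    """Compute the locus adjacency graph under ``scheme``.

    ``orthogonal4`` connects loci at Euclidean distance exactly 2°;
    ``chebyshev8`` connects loci at Chebyshev distance ≤ 2° (orthogonal plus
    diagonal neighbours).  A ``custom`` table lets alternative published
    neighbourhood schematics (e.g. ones yielding 2–5 neighbours per locus)
    be transcribed without code changes; it is validated for symmetry,
    irreflexivity and known ids.
    """
    scheme = AdjacencyScheme(scheme)
    ids = set(grid.locus_ids)
    if scheme is AdjacencyScheme.CUSTOM:
        if custom_table is None:
            raise ValueError("custom adjacency scheme requires a table")
        adj: dict[int, set[int]] = {i: set() for i in ids}
        for a, nbrs in custom_table.items():
            if a not in ids:
                raise ValueError(f"custom adjacency references unknown locus id {a}")
            for b in nbrs:
                if b not in ids:
                    raise ValueError(
                        f"custom adjacency references unknown locus id {b}"
                    )
                if b == a:
                    raise ValueError(f"locus {a} listed adjacent to itself")
                adj[a].add(b)
        for a in ids:
            for b in adj[a]:
                if a not in custom_table.get(b, set()):
                    raise ValueError(
                        f"custom adjacency not symmetric: {a}->{b} without {b}->{a}"
                    )
        return {a: frozenset(v) for a, v in adj.items()}

    out: dict[int, frozenset[int]] = {}
    for a in grid.loci:
        nbrs = set()
        for b in grid.loci:
            if a.id == b.id:
                continue
            dx, dy = abs(a.x - b.x), abs(a.y - b.y)
            if scheme is AdjacencyScheme.ORTHOGONAL4:
                if math.hypot(dx, dy) == 2.0:
                    nbrs.add(b.id)
            else:  # chebyshev8
                if max(dx, dy) <= 2.0:
                    nbrs.add(b.id)
        out[a.id] = frozenset(nbrs)
    return out


def validate_neighbor_counts(
    adj: Mapping[int, frozenset[int]], min_count: int, max_count: int
) -> None:
    """Check every locus has a neighbour count within [min_count, max_count].

    Helper for validating transcribed custom schemes (e.g. a published
    schematic stating 2–5 neighbours per locus).
    """
    bad = {
        i: len(n) for i, n in adj.items() if not (min_count <= len(n) <= max_count)
    }
    if bad:
        raise ValueError(
            f"neighbour counts outside [{min_count}, {max_count}]: {bad}"
        )


def db_to_luminance(d: float, scale: DbScale = MAIA_DB_SCALE) -> float:
    """Stimulus luminance (cd/m²) at attenuation ``d`` dB.

    The −1 dB floor code has no luminance and raises.
    """
    if d == scale.floor_code:
        raise ValueError("floor code (-1 dB, stimulus not seen) has no luminance")
    if not (scale.db_min <= d <= scale.db_max):
        raise ValueError(f"dB value {d} outside [{scale.db_min}, {scale.db_max}]")
    return scale.max_luminance * 10.0 ** (-d / 10.0)


def luminance_to_db(lum: float, scale: DbScale = MAIA_DB_SCALE) -> float:
    """Inverse of :func:`db_to_luminance`."""
    if lum <= 0:
        raise ValueError("luminance must be positive")
    d = -10.0 * math.log10(lum / scale.max_luminance)
    if not (scale.db_min - 1e-9 <= d <= scale.db_max + 1e-9):
        raise ValueError(f"luminance {lum} outside the device dynamic range")
    return d
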
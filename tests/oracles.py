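"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (definitions and
elementary geometry), sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


# --------------------------------------------------------------------------
# Segment/rectangle geometry (Liang–Barsky clipping, vectorized over edges)


def segments_intersect_rect(p: np.ndarray, q: np.ndarray, rect) -> np.ndarray:
    """For segments p[i]→q[i], does each intersect the closed rectangle?"""
    xmin, ymin, xmax, ymax = rect
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    t0 = np.zeros(len(p))
    t1 = np.ones(len(p))
    ok = np.ones(len(p), dtype=bool)
    for axis, (lo, hi) in enumerate(((xmin, xmax), (ymin, ymax))):
        pi, di = p[:, axis], d[:, axis]
        parallel = di == 0
        ok &= ~(parallel & ((pi < lo) | (pi > hi)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo - pi) / di
            tb = (hi - pi) / di
        lo_t = np.minimum(ta, tb)
        hi_t = np.maximum(ta, tb)
        move = ~parallel
        t0 = np.where(move, np.maximum(t0, lo_t), t0)
        t1 = np.where(move, np.minimum(t1, hi_t), t1)
    return ok & (t0 <= t1)


def transects_oracle(square, vertices: np.ndarray) -> bool:
    """Does any edge of the closed polygon intersect the closed square?"""
    v = np.asarray(vertices, float)
    closed = np.vstack([v, v[:1]])
    return bool(segments_intersect_rect(closed[:-1], closed[1:], square).any())


# --------------------------------------------------------------------------
# Loci-selection re-implementations (plain loops over the definitions)


def ess_oracle(values: dict[int, int], adjacency) -> set[int]:
    """Seeing loci with at least one -1 dB neighbour."""
    out = set()
    for i, v in values.items():
        if v == -1:
            continue
        for j in adjacency[i]:
            if values[j] == -1:
                out.add(i)
                break
    return out


def ftp_proportions_oracle(
    values: dict[int, int], adjacency, drop: int = 7, min_db: int = 8
) -> dict[int, float]:
    props = {}
    for i, v in values.items():
        if v < min_db or not adjacency[i]:
            continue
        drops = [1 for j in adjacency[i] if v - values[j] >= drop]
        props[i] = sum(drops) / len(adjacency[i])
    return props


def mftp_oracle(props: dict[int, float], min_loci: int = 5) -> set[int]:
    chosen = {i for i, p in props.items() if p == 1.0}
    remaining = sorted(
        {p for p in props.values() if 0 < p < 1.0}, reverse=True
    )
    for tier in remaining:
        if len(chosen) >= min_loci:
            break
        chosen |= {i for i, p in props.items() if p == tier}
    return chosen


def hrs_oracle(squares: dict[int, tuple], vertices: np.ndarray) -> set[int]:
    return {i for i, sq in squares.items() if transects_oracle(sq, vertices)}


# --------------------------------------------------------------------------
# Repeated-measures ANOVA via the textbook sums-of-squares partition


def rm_anova_oracle(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    """F statistic of a one-way within-subjects ANOVA, from raw SS."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    return (ss_cond / df1) / (ss_err / df2), (df1, df2)


# --------------------------------------------------------------------------
# Random test-field construction


def random_field(rng: np.random.Generator, locus_ids, p_scotoma: float = 0.25):
    """Random integer dB field with a tunable share of floor readings."""
    vals = {}
    for i in locus_ids:
        if rng.random() < p_scotoma:
            vals[i] = -1
        else:
            vals[i] = int(rng.integers(0, 37))
    return vals
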
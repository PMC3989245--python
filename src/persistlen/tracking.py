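"""Filament backbone tracing on skeletonized images.

The input is a binary skeleton: 1-pixel-wide, 8-connected filament
backbones, possibly marred by pre-processing artifacts (1-2 pixel gaps,
short spurious branches).  Tracking proceeds in two stages:

1. *Endpoint detection.*  A pixel is a filament end when its on-neighbors
   are confined to one direction: at Chebyshev radius 1 it has a single
   neighbor or two mutually adjacent ("side-by-side") neighbors, and all
   on-pixels within a two-pixel radius fall in one half-plane.  The
   radius-2 condition keeps the boundary pixels of a small gap from
   masquerading as ends.  Candidates are reported in image scan order:
   starting at the bottom left, each row left to right, rows bottom to
   top.

2. *Directional tracing.*  From an end, the tracer repeatedly steps to
   the unvisited on-neighbor most collinear with the running direction
   (averaged over the last three steps), which carries it straight
   through spurious branches and crossings.  When no adjacent pixel
   exists it searches outward up to ``gap_skip`` missing pixels along the
   running direction (within +/-45 degrees) and continues across the
   gap; larger gaps terminate the trace, splitting the filament.

Coordinates are 0-based (row, col) with row 0 at the top of the array;
"bottom" therefore means the highest row index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonImage",
    "TrackingConfig",
    "FilamentTrace",
    "TraceTooShortError",
    "NoFilamentsError",
    "find_endpoints",
    "trace_filament",
    "select_filaments",
]

Coord = tuple[int, int]

_NEIGH1 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@dataclass
class SkeletonImage:
    """Binary skeleton frame with its physical pixel size (um/pixel)."""

    grid: np.ndarray
    pixel_size: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("skeleton grid must be 2D")
        # grayscale 0/255 (or any nonzero-on) maps to off/on
        self.grid = grid != 0
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def on_pixels(self) -> int:
        return int(self.grid.sum())


@dataclass
class TrackingConfig:
    """Knobs of the tracking stage.

    ``min_pixels`` must be at least 4: a backbone spanning fewer pixels
    shows essentially no resolvable curvature (and a cubic reconstruction
    needs 4 points).  ``max_filaments`` may be ``math.inf`` to accept
    every filament found.  ``manual_review`` is a hook called with each
    candidate trace; returning False rejects it (default accepts all).
    """

    min_pixels: int = 4
    pixel_size: float = 1.0
    max_filaments: float = math.inf
    start_frame: int = 0
    gap_skip: int = 2
    manual_review: Callable[["FilamentTrace"], bool] | None = None

    def __post_init__(self) -> None:
        if self.min_pixels < 4:
            raise ValueError(
                f"min_pixels must be at least 4, got {self.min_pixels}")
        if not (self.max_filaments >= 1):
            raise ValueError(
                f"max_filaments must be at least 1, got {self.max_filaments}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.gap_skip < 0:
            raise ValueError("gap_skip must be non-negative")
        if self.start_frame < 0:
            raise ValueError("start_frame must be non-negative")


@dataclass
class FilamentTrace:
    """Ordered backbone pixels of one filament, end to end."""

    pixels: list[Coord]
    source_frame: int = 0
    skipped_gaps: int = 0

    def __post_init__(self) -> None:
        if len(set(self.pixels)) != len(self.pixels):
            raise ValueError("trace pixels must be distinct")

    def __len__(self) -> int:
        return len(self.pixels)


class TraceTooShortError(Exception):
    """Raised when a traced backbone falls below min_pixels."""

    def __init__(self, trace: FilamentTrace, min_pixels: int):
        self.trace = trace
        self.min_pixels = min_pixels
        super().__init__(
            f"trace of {len(trace)} pixels is shorter than min_pixels={min_pixels}")


class NoFilamentsError(Exception):
    """Raised when a selection run accepts zero traces."""


def _scan_order(shape: tuple[int, int]) -> Iterable[Coord]:
    """Bottom-left origin scan: rows bottom to top, columns left to right."""
    n_rows, n_cols = shape
    for r in range(n_rows - 1, -1, -1):
        for c in range(n_cols):
            yield (r, c)


def _neighbors_within(grid: np.ndarray, p: Coord, radius: int) -> list[Coord]:
    """On-pixels within Chebyshev ``radius`` of p, excluding p."""
    n_rows, n_cols = grid.shape
    r0, c0 = p
    out = []
    for r in range(max(0, r0 - radius), min(n_rows, r0 + radius + 1)):
        for c in range(max(0, c0 - radius), min(n_cols, c0 + radius + 1)):
            if (r, c) != p and grid[r, c]:
                out.append((r, c))
    return out


def _one_directional(p: Coord, neighbors: Sequence[Coord]) -> bool:
    """True if all neighbor directions fit strictly inside a half-plane."""
    angles = np.sort([math.atan2(r - p[0], c - p[1]) for r, c in neighbors])
    if len(angles) == 1:
        return True
    gaps = np.diff(angles)
    wrap = 2 * math.pi - (angles[-1] - angles[0])
    return max(gaps.max(), wrap) > math.pi + 1e-9


def is_endpoint(grid: np.ndarray, p: Coord) -> bool:
    """Endpoint criterion for a single pixel (assumed on)."""
    near = _neighbors_within(grid, p, 1)
    if len(near) == 0 or len(near) > 2:
        return False
    if len(near) == 2:
        (r1, c1), (r2, c2) = near
        if max(abs(r1 - r2), abs(c1 - c2)) > 1:  # not side-by-side
            return False
    wide = _neighbors_within(grid, p, 2)
    return _one_directional(p, wide)


def find_endpoints(image: SkeletonImage) -> list[Coord]:
    """All filament-end candidates, in bottom-left scan order."""
    grid = image.grid
    return [p for p in _scan_order(grid.shape) if grid[p] and is_endpoint(grid, p)]


def _mean_direction(path: list[Coord], k: int = 3) -> tuple[float, float] | None:
    """Unit mean of the last k step vectors, or None for a fresh trace."""
    if len(path) < 2:
        return None
    pts = path[-(k + 1):]
    steps = []
    for a, b in zip(pts[:-1], pts[1:]):
        dr, dc = b[0] - a[0], b[1] - a[1]
        norm = math.hypot(dr, dc)
        steps.append((dr / norm, dc / norm))
    mr = sum(s[0] for s in steps) / len(steps)
    mc = sum(s[1] for s in steps) / len(steps)
    norm = math.hypot(mr, mc)
    if norm == 0:
        return None
    return (mr / norm, mc / norm)


def _collinearity(p: Coord, q: Coord, direction: tuple[float, float]) -> float:
    dr, dc = q[0] - p[0], q[1] - p[1]
    norm = math.hypot(dr, dc)
    return (dr * direction[0] + dc * direction[1]) / norm


def _scan_key(shape: tuple[int, int], p: Coord) -> tuple[int, int]:
    # earlier in bottom-to-top, left-to-right scan == larger row, smaller col
    return (shape[0] - 1 - p[0], p[1])


def trace_filament(
    image: SkeletonImage,
    start: Coord,
    config: TrackingConfig,
    occupied: set[Coord] | None = None,
) -> FilamentTrace:
    """Trace one backbone from an endpoint to the far end.

    ``occupied`` holds pixels already claimed by accepted traces; they
    are never entered, so no filament is traced twice.  Raises
    :class:`TraceTooShortError` for backbones below ``min_pixels`` — the
    caller decides whether to release the pixels.
    """
    grid = image.grid
    if not grid[start]:
        raise ValueError(f"start pixel {start} is not on")
    occupied = occupied if occupied is not None else set()
    path: list[Coord] = [start]
    visited: set[Coord] = {start} | occupied
    skipped = 0
    max_steps = grid.size

    for _ in range(max_steps):
        cur = path[-1]
        direction = _mean_direction(path)
        cands = [q for q in _neighbors_within(grid, cur, 1) if q not in visited]
        gap_jump = 0
        if not cands and config.gap_skip > 0 and direction is not None:
            cos45 = math.cos(math.pi / 4) - 1e-9
            for radius in range(2, config.gap_skip + 2):
                ring = [
                    q for q in _neighbors_within(grid, cur, radius)
                    if q not in visited
                    and max(abs(q[0] - cur[0]), abs(q[1] - cur[1])) == radius
                    and _collinearity(cur, q, direction) >= cos45
                ]
                if ring:
                    cands = ring
                    gap_jump = radius - 1
                    break
        if not cands:
            break
        if direction is None:
            # first step: prefer the 4-adjacent neighbor, then scan order
            nxt = min(cands, key=lambda q: (
                abs(q[0] - cur[0]) + abs(q[1] - cur[1]),
                _scan_key(grid.shape, q)))
        else:
            last = path[-2] if len(path) >= 2 else None
            def key(q):
                primary = -_collinearity(cur, q, direction)
                if last is not None:
                    ldir = (cur[0] - last[0], cur[1] - last[1])
                    lnorm = math.hypot(*ldir)
                    turn = -_collinearity(cur, q, (ldir[0] / lnorm, ldir[1] / lnorm))
                else:
                    turn = 0.0
                return (primary, turn, _scan_key(grid.shape, q))
            nxt = min(cands, key=key)
        skipped += gap_jump
        path.append(nxt)
        visited.add(nxt)

    trace = FilamentTrace(pixels=path, source_frame=image.frame_index,
                          skipped_gaps=skipped)
    if len(trace) < config.min_pixels:
        raise TraceTooShortError(trace, config.min_pixels)
    return trace


def _junction_fraction(grid: np.ndarray) -> float:
    """Fraction of on-pixels with more than two 8-neighbors (branch points)."""
    on = np.argwhere(grid)
    if len(on) == 0:
        return 0.0
    n_junction = sum(
        1 for p in map(tuple, on) if len(_neighbors_within(grid, p, 1)) > 2)
    return n_junction / len(on)


def select_filaments(
    stack: Sequence[SkeletonImage],
    config: TrackingConfig,
    log: list[dict] | None = None,
) -> list[FilamentTrace]:
    """Collect accepted traces frame by frame, in scan order.

    Frames are processed from ``config.start_frame`` until
    ``config.max_filaments`` traces have been accepted.  Every candidate
    trace passes through the ``manual_review`` hook (default: accept
    all).  Pixels of accepted traces are retired for the rest of the
    frame; pixels of discarded traces are released for re-tracing.  A
    ``log`` list, if given, receives one record per candidate.
    """
    if not stack:
        raise ValueError("empty image stack")
    review = config.manual_review or (lambda trace: True)
    accepted: list[FilamentTrace] = []

    for image in stack[config.start_frame:]:
        if len(accepted) >= config.max_filaments:
            break
        jfrac = _junction_fraction(image.grid)
        if jfrac > 0.02:
            logger.warning(
                "frame %d: %.1f%% of skeleton pixels are branch/crossing points; "
                "traces may join crossing filaments", image.frame_index, 100 * jfrac)
        consumed: set[Coord] = set()
        for p in find_endpoints(image):
            if len(accepted) >= config.max_filaments:
                break
            if p in consumed:
                continue
            try:
                trace = trace_filament(image, p, config, occupied=consumed)
            except TraceTooShortError as exc:
                if log is not None:
                    log.append({"frame": image.frame_index, "start": p,
                                "n_pixels": len(exc.trace), "accepted": False,
                                "reason": "below min_pixels"})
                # released: pixels of the short trace stay available
                continue
            if set(trace.pixels) & consumed:
                continue  # endpoint led into an already-claimed backbone
            ok = review(trace)
            if log is not None:
                log.append({"frame": image.frame_index, "start": p,
                            "n_pixels": len(trace), "accepted": bool(ok),
                            "reason": "" if ok else "rejected by review hook"})
            if ok:
                consumed.update(trace.pixels)
                accepted.append(trace)

    if not accepted:
        raise NoFilamentsError(
            "no filament traces were accepted; check min_pixels, the review "
            "hook, and the skeleton quality")
    return accepted
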
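"""Continuous filament shapes from pixel traces.

A skeleton trace is a jagged chain of pixel centres; its raw chain-code
directions alternate by 45-degree steps and would wreck any tangent-angle
statistic.  ``reconstruct_shape`` therefore fits overlapping cubic
(third-order Bezier-equivalent) segments over sliding windows of the
trace and averages all window evaluations at each backbone pixel, which
suppresses pixelation to well below half a pixel, then resamples the
smooth curve at uniform arc-length steps.

The resulting :class:`FilamentShape` carries everything downstream
analyses need: sampled points (um), arc positions s, unwrapped tangent
angles theta(s), and the contour length L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import interpolate

__all__ = [
    "FilamentShape",
    "ModeAmplitudes",
    "reconstruct_shape",
    "end_to_end_distance",
    "compute_mode_amplitudes",
]


@dataclass
class FilamentShape:
    """Arc-length-parameterized filament curve in physical units (um)."""

    points: np.ndarray          # (N, 2) x, y in um
    arc_positions: np.ndarray   # (N,) cumulative arc length s, um
    tangent_angles: np.ndarray  # (N,) theta(s), radians, unwrapped
    contour_length: float       # um
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.tangent_angles = np.asarray(self.tangent_angles, dtype=float)
        n = len(self.points)
        if not (len(self.arc_positions) == len(self.tangent_angles) == n):
            raise ValueError("points, arc_positions and tangent_angles must align")
        if n < 2:
            raise ValueError("a shape needs at least 2 samples")
        ds = np.diff(self.arc_positions)
        if np.any(ds <= 0):
            raise ValueError("arc_positions must be strictly increasing")
        if abs(self.arc_positions[0]) > 1e-12:
            raise ValueError("arc_positions must start at 0")
        if not math.isclose(self.arc_positions[-1], self.contour_length,
                            rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError("arc_positions must end at contour_length")
        r = float(np.linalg.norm(self.points[-1] - self.points[0]))
        if r > self.contour_length * (1 + 1e-6) + 1e-9:
            raise ValueError("end-to-end distance exceeds contour length")

    @property
    def n_samples(self) -> int:
        return len(self.points)


@dataclass
class ModeAmplitudes:
    """Cosine bending-mode amplitudes a_n per frame of one filament."""

    mode_numbers: list[int]
    amplitudes: np.ndarray    # (n_frames, n_modes), um^(1/2)
    filament_length: float    # um
    n_frames: int

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.shape != (self.n_frames, len(self.mode_numbers)):
            raise ValueError("amplitudes must be (n_frames, n_modes)")

    def variances(self) -> np.ndarray:
        """Per-mode amplitude variance across frames (ddof=1)."""
        return np.var(self.amplitudes, axis=0, ddof=1)


def _window_average_smooth(xy: np.ndarray, window: int) -> np.ndarray:
    """Average of cubic least-squares fits over sliding windows.

    Every window of ``window`` consecutive backbone points gets its own
    cubic parametric fit (chord-length parameter); each point's smoothed
    position is the mean of the evaluations of all windows covering it.
    """
    n = len(xy)
    w = min(window, n)
    deg = min(3, w - 1)
    acc = np.zeros_like(xy)
    cnt = np.zeros(n)
    for j in range(n - w + 1):
        seg = xy[j:j + w]
        t = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(seg, axis=0), axis=1))))
        if t[-1] == 0:
            raise ValueError("degenerate trace: repeated coordinates")
        t = t / t[-1]
        fit = np.empty_like(seg)
        for dim in range(2):
            coef = np.polyfit(t, seg[:, dim], deg)
            fit[:, dim] = np.polyval(coef, t)
        acc[j:j + w] += fit
        cnt[j:j + w] += 1
    return acc / cnt[:, None]


def _reflect_pad(xy: np.ndarray, pad: int) -> np.ndarray:
    """Point-reflect ``pad`` samples beyond each end of the backbone.

    Reflection through the terminal point continues the curve with the
    same end tangent, which keeps the sliding windows that reach an end
    from being fit on one-sided, quantization-dominated data.
    """
    pad = min(pad, len(xy) - 1)
    head = 2 * xy[0] - xy[pad:0:-1]
    tail = 2 * xy[-1] - xy[-2:-pad - 2:-1]
    return np.vstack([head, xy, tail])


def reconstruct_shape(
    trace,
    pixel_size: float,
    sample_step: float | None = None,
    window: int = 7,
) -> FilamentShape:
    """Build a smooth, uniformly arc-sampled curve from a pixel trace.

    Parameters
    ----------
    trace : FilamentTrace or sequence of (row, col)
        Ordered backbone pixel coordinates.
    pixel_size : float
        Physical size of one pixel, um.
    sample_step : float, optional
        Arc-length sampling step, um; default 0.5 * pixel_size.
    window : int
        Sliding-window length (pixels) for the averaged cubic fits.
    """
    pixels = getattr(trace, "pixels", trace)
    pix = np.asarray(pixels, dtype=float)
    if pix.ndim != 2 or pix.shape[1] != 2:
        raise ValueError("trace must be an ordered list of (row, col) pairs")
    if len(pix) < 4:
        raise ValueError(f"need at least 4 trace pixels for a cubic fit, got {len(pix)}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if sample_step is None:
        sample_step = 0.5 * pixel_size

    # (row, col) -> (x, y): x along columns, y along rows.  The handedness
    # of the image frame is irrelevant to arc lengths and relative angles.
    xy = np.column_stack([pix[:, 1], pix[:, 0]]) * pixel_size
    if np.allclose(xy, xy[0]):
        raise ValueError("degenerate trace: all coordinates coincide")

    pad = min(window, len(xy) - 1)
    smooth = _window_average_smooth(_reflect_pad(xy, pad), window)

    # chord-length parameterized smoothing spline through the averaged
    # backbone; the residual budget matches the ~1/3-pixel error left by
    # quantization after window averaging
    chord = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(smooth, axis=0), axis=1))))
    keep = np.concatenate(([True], np.diff(chord) > 1e-12))
    pad_lo = int(keep[:pad + 1].sum()) - 1
    pad_hi = int(keep[len(chord) - pad:].sum())
    chord, smooth = chord[keep], smooth[keep]
    residual_budget = len(smooth) * (0.35 * pixel_size) ** 2
    tck, _ = interpolate.splprep(
        [smooth[:, 0], smooth[:, 1]], u=chord, s=residual_budget,
        k=min(3, len(smooth) - 1))

    # uniform arc-length resampling over the unpadded span only
    u_lo, u_hi = chord[pad_lo], chord[len(chord) - 1 - pad_hi]
    dense_u = np.linspace(u_lo, u_hi, max(20 * len(pix), 200))
    dense_xy = np.column_stack(interpolate.splev(dense_u, tck))
    seglen = np.linalg.norm(np.diff(dense_xy, axis=0), axis=1)
    dense_s = np.concatenate(([0.0], np.cumsum(seglen)))
    L = float(dense_s[-1])

    n_out = max(int(math.floor(L / sample_step)) + 1, 4)
    s_grid = np.linspace(0.0, L, n_out)
    u_grid = np.interp(s_grid, dense_s, dense_u)
    pts = np.column_stack(interpolate.splev(u_grid, tck))
    deriv = np.column_stack(interpolate.splev(u_grid, tck, der=1))
    theta = np.unwrap(np.arctan2(deriv[:, 1], deriv[:, 0]))

    source = {"n_trace_pixels": len(pix), "pixel_size_um": pixel_size}
    frame = getattr(trace, "source_frame", None)
    if frame is not None:
        source["frame"] = frame
    return FilamentShape(
        points=pts, arc_positions=s_grid, tangent_angles=theta,
        contour_length=L, source=source,
    )


def end_to_end_distance(shape: FilamentShape) -> float:
    """Euclidean distance between the first and last sampled points, um."""
    return float(np.linalg.norm(shape.points[-1] - shape.points[0]))


def compute_mode_amplitudes(
    shapes: Sequence[FilamentShape],
    modes: Sequence[int] = tuple(range(1, 11)),
    length_tolerance: float = 0.05,
) -> ModeAmplitudes:
    """Cosine Fourier decomposition of theta(s) for a fluctuating filament.

    For each frame the mean-subtracted tangent-angle profile is projected
    onto cosine modes with the discrete midpoint rule

        a_n = sqrt(2/L) * sum_k theta(s_mid,k) * cos(n*pi*s_mid,k / L) * ds_k,

    using each frame's segment midpoints.  Mean subtraction reflects a
    free filament with no imposed boundary orientation.  Frames whose
    contour length deviates from the median by more than
    ``length_tolerance`` (default 5%) are rejected with a warning: a
    blurred or out-of-focus end changes the apparent length and corrupts
    the mode variances.
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 frames for mode analysis")
    lengths = np.array([sh.contour_length for sh in shapes])
    L = float(np.median(lengths))
    ok = np.abs(lengths - L) <= length_tolerance * L
    if not ok.all():
        warnings.warn(
            f"rejected {int((~ok).sum())} of {len(shapes)} frames whose contour "
            f"length deviates more than {length_tolerance:.0%} from the median "
            f"({L:.3g} um); blurred filament ends are the usual cause",
            stacklevel=2,
        )
    kept = [sh for sh, good in zip(shapes, ok) if good]
    if len(kept) < 2:
        raise ValueError("fewer than 2 frames survive the contour-length filter")

    modes = [int(n) for n in modes]
    amps = np.empty((len(kept), len(modes)))
    for i, sh in enumerate(kept):
        s = sh.arc_positions
        th = sh.tangent_angles
        ds = np.diff(s)
        s_mid = 0.5 * (s[:-1] + s[1:])
        th_mid = 0.5 * (th[:-1] + th[1:])
        Lf = sh.contour_length
        th_mid = th_mid - np.sum(th_mid * ds) / Lf
        basis = np.cos(np.outer(modes, np.pi * s_mid / Lf))  # (n_modes, n_seg)
        amps[i] = math.sqrt(2.0 / Lf) * basis @ (th_mid * ds)
    return ModeAmplitudes(
        mode_numbers=modes, amplitudes=amps, filament_length=L, n_frames=len(kept),
    )
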
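"""Ground-truth 2D wormlike chains and synthetic skeleton images.

A 2D equilibrium wormlike chain of persistence length Lp has tangent
angle theta(s) performing a Brownian walk along the contour with
variance rate 1/Lp:

    theta(s + ds) - theta(s) ~ Normal(0, ds / Lp),

which yields <cos(theta(s) - theta(0))> = exp(-s / (2 Lp)) exactly, the
2D decay the analysis stack assumes.  Chains are generated as discrete
realizations of this walk; fluctuating-filament time series are drawn as
independent equilibrium conformations of fixed contour length (the mode
analysis needs only equilibrium variances, so no temporal dynamics are
modelled).

``rasterize_skeleton`` turns a chain into the kind of image the tracker
ingests: a 1-pixel-wide, 8-connected on-pixel path, optionally damaged
with gaps (missing pixels) and spurs (short false branches) that emulate
thresholding artifacts.  ``render_microscopy_image`` instead draws a
blurred, noisy grayscale filament for exercising the pre-processing
chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .geometry import FilamentShape
from .tracking import SkeletonImage

__all__ = [
    "WLCParams",
    "RasterParams",
    "simulate_wlc_2d",
    "simulate_wlc_ensemble",
    "simulate_fluctuating_filament",
    "rasterize_skeleton",
    "render_microscopy_image",
]


@dataclass
class WLCParams:
    """Parameters of a simulated chain ensemble (lengths in um)."""

    lp: float = 10.0
    contour_length: float = 20.0
    step: float | None = None   # default contour_length / 500
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not self.lp > 0:
            raise ValueError("lp must be positive")
        if not self.contour_length > 0:
            raise ValueError("contour_length must be positive")
        if self.step is None:
            self.step = self.contour_length / 500.0
        if self.step > self.contour_length / 10.0:
            raise ValueError("step must be at most contour_length/10")
        if self.n_chains < 1:
            raise ValueError("n_chains must be at least 1")


@dataclass
class RasterParams:
    """How a chain is drawn onto a pixel grid, and which artifacts to add.

    ``gap_specs`` is a list of (position_fraction, n_pixels) pairs: at the
    given fraction of the backbone path, that many consecutive pixels are
    turned off.  ``spur_specs`` is a list of (position_fraction,
    length_pixels, direction_degrees) triples adding short false
    branches.  ``angle_noise_sd`` perturbs each segment direction before
    drawing, emulating a ragged skeleton.
    """

    pixel_size: float = 0.1  # um per pixel
    image_shape: tuple[int, int] | None = None  # None: auto-fit with margin
    margin: int = 5
    gap_specs: list[tuple[float, int]] = field(default_factory=list)
    spur_specs: list[tuple[float, int, float]] = field(default_factory=list)
    angle_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be non-negative")


def _chain_shape(theta: np.ndarray, step: float, source: dict) -> FilamentShape:
    """Build a FilamentShape from per-sample tangent angles."""
    n_seg = len(theta) - 1
    seg = step * np.column_stack([np.cos(theta[:-1]), np.sin(theta[:-1])])
    pts = np.vstack([[0.0, 0.0], np.cumsum(seg, axis=0)])
    arc = step * np.arange(n_seg + 1)
    return FilamentShape(
        points=pts, arc_positions=arc, tangent_angles=theta,
        contour_length=float(arc[-1]), source=source,
    )


def _draw_chain(rng: np.random.Generator, lp: float, length: float,
                step: float, index: int) -> FilamentShape:
    n_seg = max(int(round(length / step)), 10)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    increments = rng.normal(0.0, math.sqrt(step / lp), n_seg)
    theta = theta0 + np.concatenate(([0.0], np.cumsum(increments)))
    return _chain_shape(theta, step, {"true_lp": lp, "chain": index})


def simulate_wlc_2d(params: WLCParams) -> list[FilamentShape]:
    """Independent equilibrium 2D wormlike chains, reproducible by seed."""
    rng = np.random.default_rng(params.seed)
    return [
        _draw_chain(rng, params.lp, params.contour_length, params.step, i)
        for i in range(params.n_chains)
    ]


def simulate_wlc_ensemble(
    lp: float,
    lengths: Sequence[float],
    step: float | None = None,
    seed: int = 0,
) -> list[FilamentShape]:
    """Chains of mixed contour lengths at one persistence length.

    ``step`` defaults per chain to length/500 so that the tangent-walk
    increments stay small for every chain.
    """
    rng = np.random.default_rng(seed)
    shapes = []
    for i, L in enumerate(lengths):
        st = step if step is not None else L / 500.0
        shapes.append(_draw_chain(rng, lp, float(L), st, i))
    return shapes


def simulate_fluctuating_filament(
    params: WLCParams, n_frames: int,
) -> list[FilamentShape]:
    """Time series of one filament: independent equilibrium conformations.

    All frames share the exact contour length and discretization; frames
    carry no temporal correlation.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(params.seed)
    frames = []
    for i in range(n_frames):
        sh = _draw_chain(rng, params.lp, params.contour_length, params.step, 0)
        sh.source["frame"] = i
        frames.append(sh)
    return frames


def _minimal_8_path(raw: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop pixels whose removal keeps the path 8-connected (corner doubles)."""
    out = [raw[0]]
    for i in range(1, len(raw) - 1):
        p, nxt = raw[i], raw[i + 1]
        if p == out[-1]:
            continue
        if max(abs(out[-1][0] - nxt[0]), abs(out[-1][1] - nxt[1])) <= 1:
            continue  # out[-1] and nxt already adjacent: p is redundant
        out.append(p)
    if len(raw) > 1 and raw[-1] != out[-1]:
        out.append(raw[-1])
    return out


def rasterize_skeleton(
    shape: FilamentShape,
    params: RasterParams,
    frame_index: int = 0,
    return_path: bool = False,
):
    """Draw a chain as a 1-pixel-wide 8-connected skeleton image.

    The curve is marched sample to sample with Bresenham lines, the pixel
    chain is pruned to a minimal 8-connected path, and configured gaps
    and spurs are applied afterwards.  Raises if the chain leaves a
    caller-specified frame.  With ``return_path=True`` also returns the
    ordered (row, col) pixel sequence before artifacts were applied.
    """
    rng = np.random.default_rng(params.seed)
    pts = shape.points.copy()
    if params.angle_noise_sd > 0:
        seg = np.diff(shape.points, axis=0)
        ang = np.arctan2(seg[:, 1], seg[:, 0])
        ang = ang + rng.normal(0.0, params.angle_noise_sd, len(ang))
        ln = np.linalg.norm(seg, axis=1)
        pts = np.vstack([
            shape.points[0],
            shape.points[0] + np.cumsum(
                np.column_stack([ln * np.cos(ang), ln * np.sin(ang)]), axis=0),
        ])

    # physical (x, y) -> pixel (row, col)
    cols = pts[:, 0] / params.pixel_size
    rows = pts[:, 1] / params.pixel_size
    if params.image_shape is None:
        row_off = params.margin - math.floor(rows.min())
        col_off = params.margin - math.floor(cols.min())
        n_rows = int(math.ceil(rows.max() - rows.min())) + 2 * params.margin + 1
        n_cols = int(math.ceil(cols.max() - cols.min())) + 2 * params.margin + 1
        image_shape = (n_rows, n_cols)
    else:
        row_off = col_off = 0
        image_shape = params.image_shape
    rr = np.round(rows + row_off).astype(int)
    cc = np.round(cols + col_off).astype(int)
    if (rr.min() < 0 or cc.min() < 0
            or rr.max() >= image_shape[0] or cc.max() >= image_shape[1]):
        raise ValueError("chain leaves the image frame; enlarge image_shape")

    raw: list[tuple[int, int]] = []
    for k in range(len(rr) - 1):
        lr, lc = draw_line(rr[k], cc[k], rr[k + 1], cc[k + 1])
        seg_px = list(zip(lr.tolist(), lc.tolist()))
        if raw:
            seg_px = seg_px[1:]
        raw.extend(seg_px)
    if len(raw) < 2:
        raise ValueError("chain rasterizes to fewer than 2 pixels")
    path = _minimal_8_path(raw)

    grid = np.zeros(image_shape, dtype=bool)
    for p in path:
        grid[p] = True

    for frac, n_gap in params.gap_specs:
        c = int(round(frac * (len(path) - 1)))
        for p in path[c:c + n_gap]:
            grid[p] = False

    path_set = set(path)
    for frac, length_px, direction_deg in params.spur_specs:
        c = int(round(frac * (len(path) - 1)))
        r0, c0 = path[c]
        drad = math.radians(direction_deg)
        for k in range(1, length_px + 1):
            q = (int(round(r0 + k * math.sin(drad))),
                 int(round(c0 + k * math.cos(drad))))
            if (0 <= q[0] < image_shape[0] and 0 <= q[1] < image_shape[1]
                    and q not in path_set):
                grid[q] = True

    image = SkeletonImage(grid=grid, pixel_size=params.pixel_size,
                          frame_index=frame_index)
    if return_path:
        return image, path
    return image


def render_microscopy_image(
    shape: FilamentShape,
    pixel_size: float = 0.1,
    margin: int = 12,
    filament_intensity: float = 200.0,
    background: float = 30.0,
    psf_sigma_px: float = 1.5,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> np.ndarray:
    """Grayscale synthetic fluorescence image of one filament.

    Draws the backbone, convolves with a Gaussian point-spread function,
    and adds a constant background plus Gaussian read noise — the kind of
    raw frame the pre-processing chain is meant to reduce to a skeleton.
    Returns a float image (arbitrary intensity units).
    """
    skel = rasterize_skeleton(
        shape, RasterParams(pixel_size=pixel_size, margin=margin))
    img = np.zeros(skel.shape, dtype=float)
    img[skel.grid] = filament_intensity
    img = ndimage.gaussian_filter(img, psf_sigma_px)
    # renormalize peak so blur does not wash out the signal
    if img.max() > 0:
        img *= filament_intensity / img.max()
    rng = np.random.default_rng(seed)
    img = img + background + rng.normal(0.0, noise_sd, img.shape)
    return img
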
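"""End-to-end runs: pre-processing, configuration, caching and reports.

The analysis chain is

    raw images --preprocess--> skeletons --track--> traces
    --reconstruct--> shapes --aggregate--> statistics --fit--> Lp

``run_analysis`` executes everything after pre-processing, persists the
selected traces immediately (so a crashed or interrupted analysis can be
re-run without re-selecting filaments), and writes CSV statistics, JSON
fit results, a text report and an overlay image per frame.

Pre-processing is the conventional five-step reduction of a fluorescence
image to a skeleton: background subtraction, smoothing, contrast
normalization, global thresholding, and morphological thinning to a
1-pixel-wide backbone.  Each intermediate can be saved so the result of
every step can be compared against the original — the quickest way to
catch artifact-generating settings (a cutoff too high fragments dim
filaments; too low lets noise sprout spurious branches).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import exposure, filters, morphology

from . import ensemble, geometry, tracking, wlc
from .tracking import FilamentTrace, SkeletonImage, TrackingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessOptions",
    "RunConfig",
    "preprocess",
    "run_analysis",
    "load_skeleton_stack",
    "load_gray_stack",
    "save_skeleton_stack",
    "traces_to_frame",
    "traces_from_frame",
    "read_config_file",
]


# ----------------------------------------------------------------- images

def _read_pages(path: str | Path) -> list[np.ndarray]:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            return [arr]
        return [arr[i] for i in range(arr.shape[0])]
    img = iio.imread(path)
    if img.ndim == 3:  # RGB(A): collapse to gray
        img = img[..., :3].mean(axis=-1)
    return [img]


def load_gray_stack(paths: Sequence[str | Path]) -> list[np.ndarray]:
    """Read TIFF (multi-page) / PNG inputs as a list of 2D float arrays."""
    frames: list[np.ndarray] = []
    for p in paths:
        frames.extend(np.asarray(page, dtype=float) for page in _read_pages(p))
    if not frames:
        raise ValueError("no image frames found")
    return frames


def load_skeleton_stack(
    paths: Sequence[str | Path], pixel_size: float,
) -> list[SkeletonImage]:
    """Read already-skeletonized frames; nonzero pixels become 'on'."""
    return [
        SkeletonImage(grid=frame, pixel_size=pixel_size, frame_index=i)
        for i, frame in enumerate(load_gray_stack(paths))
    ]


def save_skeleton_stack(images: Sequence[SkeletonImage], path: str | Path) -> None:
    """Write skeleton frames as a 0/255 uint8 multi-page TIFF.

    Frames of unequal size (auto-fitted rasters) are zero-padded to a
    common canvas.
    """
    n_rows = max(img.shape[0] for img in images)
    n_cols = max(img.shape[1] for img in images)
    data = np.zeros((len(images), n_rows, n_cols), dtype=np.uint8)
    for i, img in enumerate(images):
        data[i, :img.shape[0], :img.shape[1]] = img.grid.astype(np.uint8) * 255
    tifffile.imwrite(path, data)


# ------------------------------------------------------------ preprocess

@dataclass
class PreprocessOptions:
    """Settings for the five-step image reduction.

    ``threshold`` is a fraction of the contrast-normalized intensity
    range in [0, 1]; None selects Otsu's threshold per frame.
    """

    background_radius_px: int = 15
    blur_sigma_px: float = 1.0
    threshold: float | None = None
    save_intermediates_to: str | Path | None = None

    def __post_init__(self) -> None:
        if self.background_radius_px < 1:
            raise ValueError("background_radius_px must be at least 1")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be non-negative")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def preprocess(
    stack: Sequence[np.ndarray],
    pixel_size: float,
    options: PreprocessOptions | None = None,
) -> list[SkeletonImage]:
    """Reduce grayscale frames to 1-pixel-wide binary skeletons.

    Steps, in order: (1) background subtraction by a morphological
    opening (rolling-ball style) with ``background_radius_px``;
    (2) Gaussian smoothing; (3) contrast normalization to [0, 1];
    (4) global thresholding (fixed fraction or Otsu); (5) morphological
    thinning.  A threshold that turns a frame all-on or all-off raises an
    error naming the step.
    """
    options = options or PreprocessOptions()
    save_dir = None
    if options.save_intermediates_to is not None:
        save_dir = Path(options.save_intermediates_to)
        save_dir.mkdir(parents=True, exist_ok=True)

    out: list[SkeletonImage] = []
    for i, frame in enumerate(stack):
        img = np.asarray(frame, dtype=float)
        footprint = morphology.disk(options.background_radius_px)
        background = morphology.opening(img, footprint)
        img = img - background
        img = filters.gaussian(img, options.blur_sigma_px, preserve_range=True)
        img = exposure.rescale_intensity(img, out_range=(0.0, 1.0))
        thr = (options.threshold if options.threshold is not None
               else filters.threshold_otsu(img))
        binary = img > thr
        if binary.all() or not binary.any():
            state = "all-on" if binary.all() else "all-off"
            raise ValueError(
                f"thresholding failed on frame {i}: image is {state} at "
                f"threshold {thr:.3g}; adjust the threshold")
        skeleton = morphology.skeletonize(binary)
        if save_dir is not None:
            tifffile.imwrite(save_dir / f"frame{i:04d}_1_background_subtracted.tif",
                             (img * 255).astype(np.uint8))
            tifffile.imwrite(save_dir / f"frame{i:04d}_2_binary.tif",
                             binary.astype(np.uint8) * 255)
            tifffile.imwrite(save_dir / f"frame{i:04d}_3_skeleton.tif",
                             skeleton.astype(np.uint8) * 255)
        out.append(SkeletonImage(grid=skeleton, pixel_size=pixel_size,
                                 frame_index=i))
    return out


# ------------------------------------------------------------ run config

_MODES = ("adsorbed", "fluctuating")


@dataclass
class RunConfig:
    """Resolved settings of one analysis run.

    ``mode`` is "adsorbed" (many surface-adsorbed filaments: cosine and
    end-to-end analyses) or "fluctuating" (time series of one freely
    fluctuating filament: all three analyses including bending modes).
    Validation mirrors the entry checks of an interactive front end:
    ``min_pixels`` below 4 and ``max_filaments`` below 1 are rejected
    outright, while a physically absurd ``pixel_size`` only warns — no
    software can know the microscope's actual magnification.
    """

    mode: str = "adsorbed"
    input_paths: list[str] = field(default_factory=list)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    sample_step: float | None = None       # um; default 0.5 * pixel_size
    bin_width: float | None = None         # um; default 2 * sample_step
    fit_range: tuple[float, float] | None = None  # um; default auto
    pairing: str = "all_pairs"
    modes: tuple[int, ...] = tuple(range(1, 11))
    output_dir: str | Path = "persistlen_out"
    temperature: float = 298.15
    reuse_traces: bool = False
    write_overlays: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        px = self.tracking.pixel_size
        if px > 10.0 or px < 1e-4:
            warnings.warn(
                f"pixel size of {px} um/pixel is physically implausible for "
                f"light microscopy; the value is accepted but results scale "
                f"with it", stacklevel=2)
        if any(not 1 <= m <= wlc.MAX_MODE for m in self.modes):
            raise ValueError(f"mode numbers must lie in 1..{wlc.MAX_MODE}")

    def resolved(self) -> dict:
        """Echo of every effective setting, written beside the outputs."""
        t = self.tracking
        return {
            "mode": self.mode,
            "input_paths": [str(p) for p in self.input_paths],
            "pixel_size_um": t.pixel_size,
            "min_pixels": t.min_pixels,
            "max_filaments": ("inf" if math.isinf(t.max_filaments)
                              else int(t.max_filaments)),
            "start_frame": t.start_frame,
            "gap_skip": t.gap_skip,
            "sample_step_um": (self.sample_step if self.sample_step is not None
                               else 0.5 * t.pixel_size),
            "bin_width_um": self.bin_width,
            "fit_range_um": list(self.fit_range) if self.fit_range else None,
            "pairing": self.pairing,
            "modes": list(self.modes),
            "output_dir": str(self.output_dir),
            "temperature_K": self.temperature,
            "reuse_traces": self.reuse_traces,
        }


def read_config_file(path: str | Path) -> dict:
    """Parse a simple ``key = value`` config file into a dict.

    Blank lines and ``#`` comments are ignored; values are parsed as
    JSON where possible (numbers, lists, booleans), else kept as strings.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = json.loads(value)
        except json.JSONDecodeError:
            out[key] = value
    return out


# ---------------------------------------------------------- trace caching

def traces_to_frame(traces: Sequence[FilamentTrace]) -> pd.DataFrame:
    rows = []
    for fid, tr in enumerate(traces):
        for k, (r, c) in enumerate(tr.pixels):
            rows.append((tr.source_frame, fid, k, r, c, tr.skipped_gaps))
    return pd.DataFrame(
        rows, columns=["frame", "filament_id", "point_index", "row", "col",
                       "skipped_gaps"])


def traces_from_frame(df: pd.DataFrame) -> list[FilamentTrace]:
    traces = []
    for fid, grp in df.groupby("filament_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(FilamentTrace(
            pixels=[(int(r), int(c)) for r, c in zip(grp["row"], grp["col"])],
            source_frame=int(grp["frame"].iloc[0]),
            skipped_gaps=int(grp["skipped_gaps"].iloc[0]),
        ))
    return traces


def _write_overlay(image: SkeletonImage, traces: Sequence[FilamentTrace],
                   path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.grid, cmap="gray_r", interpolation="nearest")
    for fid, tr in enumerate(traces):
        if tr.source_frame != image.frame_index:
            continue
        px = np.asarray(tr.pixels)
        ax.plot(px[:, 1], px[:, 0], lw=1.0, label=f"filament {fid}")
        ax.plot(px[0, 1], px[0, 0], "o", ms=3)
    ax.set_title(f"frame {image.frame_index}: {sum(t.source_frame == image.frame_index for t in traces)} traces")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ------------------------------------------------------------ run analysis

def run_analysis(
    config: RunConfig,
    stack: Sequence[SkeletonImage] | None = None,
) -> dict:
    """Track, reconstruct, aggregate and fit; write all outputs.

    Returns a bundle with the traces, shapes, statistics and
    :class:`~persistlen.wlc.FitResult` objects.  Outputs written under
    ``config.output_dir``: ``resolved_config.json``, ``traces.csv``
    (written right after selection, before any analysis), statistic CSVs,
    ``fits.json``, ``report.txt`` and per-frame overlay PNGs.

    With ``reuse_traces=True`` and a ``traces.csv`` already present, the
    selection stage is skipped and the cached traces are re-analyzed;
    the statistics are bit-identical to the original run.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    (out_dir / "resolved_config.json").write_text(json.dumps(resolved, indent=2))
    logger.info("resolved configuration: %s", resolved)

    if stack is None:
        if not config.input_paths:
            raise ValueError("no input images and no in-memory stack given")
        stack = load_skeleton_stack(config.input_paths, config.tracking.pixel_size)

    trace_path = out_dir / "traces.csv"
    selection_log: list[dict] = []
    if config.reuse_traces and trace_path.exists():
        traces = traces_from_frame(pd.read_csv(trace_path))
        logger.info("reusing %d cached traces from %s", len(traces), trace_path)
    else:
        traces = tracking.select_filaments(stack, config.tracking,
                                           log=selection_log)
        traces_to_frame(traces).to_csv(trace_path, index=False)
        pd.DataFrame(selection_log).to_csv(out_dir / "selection_log.csv",
                                           index=False)

    px = config.tracking.pixel_size
    sample_step = (config.sample_step if config.sample_step is not None
                   else 0.5 * px)
    shapes = [geometry.reconstruct_shape(tr, px, sample_step) for tr in traces]

    shape_rows = []
    for fid, sh in enumerate(shapes):
        for s, (x, y), th in zip(sh.arc_positions, sh.points, sh.tangent_angles):
            shape_rows.append((fid, sh.source.get("frame", 0), s, x, y, th))
    pd.DataFrame(
        shape_rows,
        columns=["filament_id", "frame", "s_um", "x_um", "y_um", "theta_rad"],
    ).to_csv(out_dir / "shapes.csv", index=False)

    context = wlc.PhysicalContext(temperature=config.temperature)
    corr = ensemble.compute_cosine_correlation(
        shapes, bin_width=config.bin_width, pairing=config.pairing)
    pd.DataFrame({
        "s_um": corr.s_bins, "mean_cosine": corr.mean_cosine,
        "count": corr.counts.astype(int),
    }).to_csv(out_dir / "cosine_correlation.csv", index=False)

    records = ensemble.compute_end_to_end_records(shapes)
    pd.DataFrame(records, columns=["L_um", "R2_um2"]).to_csv(
        out_dir / "end_to_end.csv", index=False)

    fits: dict[str, wlc.FitResult] = {}
    fits["cosine"] = wlc.fit_cosine_correlation(
        corr, fit_range=config.fit_range, context=context)
    if len(records) >= 10:
        fits["end_to_end"] = wlc.fit_end_to_end(records, context=context)
    else:
        logger.warning("only %d filaments: end-to-end fit skipped "
                       "(needs >= 10)", len(records))

    if config.mode == "fluctuating":
        mode_amps = geometry.compute_mode_amplitudes(shapes, modes=config.modes)
        amp_df = pd.DataFrame(
            mode_amps.amplitudes,
            columns=[f"a{n}" for n in mode_amps.mode_numbers])
        amp_df.insert(0, "frame", range(mode_amps.n_frames))
        amp_df.to_csv(out_dir / "mode_amplitudes.csv", index=False)
        fits["modes"] = wlc.fit_modes(mode_amps, modes=config.modes,
                                      context=context)

    (out_dir / "fits.json").write_text(json.dumps(
        {name: fr.to_dict() for name, fr in fits.items()}, indent=2))
    report = "\n\n".join(fr.report() for fr in fits.values())
    (out_dir / "report.txt").write_text(report + "\n")

    if config.write_overlays:
        for image in stack:
            if any(t.source_frame == image.frame_index for t in traces):
                _write_overlay(image, traces,
                               out_dir / f"overlay_frame{image.frame_index:04d}.png")

    return {
        "traces": traces,
        "shapes": shapes,
        "correlation": corr,
        "end_to_end_records": records,
        "fits": fits,
        "selection_log": selection_log,
        "output_dir": out_dir,
    }
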
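"""Ensemble statistics consumed by the persistence-length fits.

Aggregates per-filament shapes into (i) the binned tangent-angle cosine
correlation C(s) = <cos(theta(s2) - theta(s1))> as a function of segment
length s = s2 - s1, and (ii) one (contour length, squared end-to-end
distance) record per filament.  Sample counts are kept per bin so that
fits can weight by occupancy and users can judge the (correlated)
sampling within single filaments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .geometry import FilamentShape, end_to_end_distance

__all__ = [
    "CorrelationData",
    "compute_cosine_correlation",
    "compute_end_to_end_records",
    "noisy_angle_cosine_experiment",
]


@dataclass
class CorrelationData:
    """Binned cosine correlation: segment length vs mean cosine, with counts."""

    s_bins: np.ndarray       # bin centers, um, strictly increasing
    mean_cosine: np.ndarray  # <cos(dtheta)> per bin, in [-1, 1]
    counts: np.ndarray       # samples per bin, >= 1

    def __post_init__(self) -> None:
        self.s_bins = np.asarray(self.s_bins, dtype=float)
        self.mean_cosine = np.asarray(self.mean_cosine, dtype=float)
        self.counts = np.asarray(self.counts)
        if not (len(self.s_bins) == len(self.mean_cosine) == len(self.counts)):
            raise ValueError("s_bins, mean_cosine and counts must align")
        if np.any(np.diff(self.s_bins) <= 0):
            raise ValueError("s_bins must be strictly increasing")
        if np.any(np.abs(self.mean_cosine) > 1 + 1e-9):
            raise ValueError("mean cosines must lie in [-1, 1]")
        if np.any(self.counts < 1):
            raise ValueError("reported bins must hold at least one sample")

    def low_confidence(self, min_count: int = 10) -> np.ndarray:
        """Boolean mask of bins with fewer than ``min_count`` samples."""
        return self.counts < min_count


def _pair_sums_all(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of cos(theta[j+k] - theta[j]) over j, for every lag k >= 1.

    Uses the identity sum_j cos(t_{j+k} - t_j) = Re sum_j z_{j+k} conj(z_j)
    with z = exp(i*theta), evaluated for all lags at once by FFT
    autocorrelation.  Returns (sums, counts) indexed by lag 1..n-1.
    """
    n = len(theta)
    z = np.exp(1j * theta)
    m = sfft.next_fast_len(2 * n)
    Z = sfft.fft(z, m)
    corr = sfft.ifft(Z * np.conj(Z))[:n].real
    counts = n - np.arange(n)
    return corr[1:], counts[1:].astype(float)


def compute_cosine_correlation(
    shapes: Sequence[FilamentShape],
    bin_width: float | None = None,
    pairing: str = "all_pairs",
) -> CorrelationData:
    """Accumulate the binned cosine correlation over a set of shapes.

    Parameters
    ----------
    shapes : filament shapes with uniform arc sampling.
    bin_width : segment-length bin width in um; default twice the median
        arc sampling step of the input shapes.
    pairing : "all_pairs" uses every ordered pair of sample points
        (maximal sample count; the default), "from_origin" references
        every angle to the first point only, theta(s) - theta(0).

    Filaments shorter than a given s contribute nothing to that bin, and
    bins that receive no samples are absent from the output rather than
    reported as zero.
    """
    if not shapes:
        raise ValueError("need at least one shape")
    if pairing not in ("all_pairs", "from_origin"):
        raise ValueError(f"unknown pairing {pairing!r}")
    steps = [np.median(np.diff(sh.arc_positions)) for sh in shapes]
    if bin_width is None:
        bin_width = 2.0 * float(np.median(steps))
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")

    max_s = max(sh.contour_length for sh in shapes)
    n_bins = int(math.ceil(max_s / bin_width)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)

    for sh, ds in zip(shapes, steps):
        theta = sh.tangent_angles
        if pairing == "all_pairs":
            lag_sums, lag_counts = _pair_sums_all(theta)
            lags_s = ds * np.arange(1, len(theta))
        else:
            lag_sums = np.cos(theta[1:] - theta[0])
            lag_counts = np.ones(len(theta) - 1)
            lags_s = sh.arc_positions[1:] - sh.arc_positions[0]
        idx = np.minimum((lags_s / bin_width).astype(int), n_bins - 1)
        np.add.at(sums, idx, lag_sums)
        np.add.at(counts, idx, lag_counts)

    occupied = counts > 0
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return CorrelationData(
        s_bins=centers[occupied],
        mean_cosine=np.clip(sums[occupied] / counts[occupied], -1.0, 1.0),
        counts=counts[occupied],
    )


def compute_end_to_end_records(
    shapes: Sequence[FilamentShape],
) -> list[tuple[float, float]]:
    """One (contour length L, squared end-to-end distance R^2) per filament."""
    if not shapes:
        raise ValueError("need at least one shape")
    return [(sh.contour_length, end_to_end_distance(sh) ** 2) for sh in shapes]


def noisy_angle_cosine_experiment(
    sigma: float, n_samples: int, seed: int,
) -> float:
    """Mean cosine of Gaussian-noised relative angles on a straight line.

    For a straight line the true relative tangent angle is zero at every
    segment length; a measured relative angle is then pure noise,
    eps ~ Normal(0, sigma).  Because cos is even and bounded by one, the
    error propagates asymmetrically: E[cos(eps)] = exp(-sigma^2/2) < 1.
    This Monte-Carlo estimate of that expectation quantifies how angle-
    determination noise depresses the fitted correlation amplitude.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if sigma == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    return float(np.mean(np.cos(rng.normal(0.0, sigma, n_samples))))
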
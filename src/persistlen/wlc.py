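"""Wormlike-chain model functions and the nonlinear fits that extract Lp.

A semiflexible polymer in thermal equilibrium decorrelates its tangent
direction exponentially along the contour.  For shapes confined to (or
equilibrated in) two dimensions the tangent-angle cosine correlation is

    C(s) = <cos(theta(s) - theta(0))> = A * exp(-s / (2 * Lp)),

where ``s`` is the segment (arc) length, ``Lp`` the bending persistence
length and ``A`` a free decay amplitude.  ``A`` is deliberately *not*
constrained to 1: uncertainty in the determination of relative angles
propagates asymmetrically through the cosine (cos is even and bounded by
1), depressing the measured correlation at all s by a factor
exp(-sigma^2/2) for Gaussian angle noise of sd sigma.

The companion observables are the mean square end-to-end distance

    <R^2>(L) = 4*Lp*L - 8*Lp^2 * (1 - exp(-L / (2*Lp)))

and, for a single filament fluctuating in 2D, the equilibrium variance of
the cosine bending-mode amplitudes

    var(a_n) = (1 / Lp) * (L / (n*pi))^2 ,   n = 1..10.

All lengths are in micrometres.  The flexural rigidity follows as
kappa = Lp * kT.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.optimize import curve_fit

__all__ = [
    "PhysicalContext",
    "FitResult",
    "cosine_correlation_model",
    "mean_square_end_to_end_model",
    "lp_from_mode_variance",
    "fit_cosine_correlation",
    "fit_end_to_end",
    "fit_modes",
]

#: highest bending mode used in mode analysis
MAX_MODE = 10

# Decay-exponent convention: 2D shape fluctuations decay as s/(2*Lp);
# fully 3D tangent correlations decay as s/Lp.
_DECAY_FACTOR = {"2d": 2.0, "3d": 1.0}


@dataclass(frozen=True)
class PhysicalContext:
    """Thermal context used to convert Lp to a flexural rigidity."""

    temperature: float = 298.15  # kelvin

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy in joules."""
        return constants.Boltzmann * self.temperature

    def flexural_rigidity(self, lp_um: float) -> float:
        """kappa = Lp * kT, in J*m, for a persistence length in um."""
        return lp_um * 1e-6 * self.kT


@dataclass
class FitResult:
    """Outcome of one persistence-length fit.

    ``amplitude`` is present only for the cosine-correlation method.  A
    non-converged fit carries ``converged=False``, ``lp=nan`` and a
    diagnostic ``message``; it is never silently replaced by a default.
    """

    lp: float
    lp_stderr: float
    method: str
    fit_range: tuple[float, float]
    n_samples: int
    amplitude: float | None = None
    amplitude_stderr: float | None = None
    flexural_rigidity: float | None = None
    converged: bool = True
    message: str = ""
    per_mode_lp: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("cosine", "end_to_end", "modes"):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.amplitude is not None) != (self.method == "cosine"):
            raise ValueError("amplitude is present iff method == 'cosine'")
        if self.converged:
            if not self.lp > 0:
                raise ValueError(f"converged fit must have lp > 0, got {self.lp}")
            if self.lp_stderr < 0:
                raise ValueError("lp_stderr must be non-negative")
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError(f"fit_range must be increasing, got {self.fit_range}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "lp_um": self.lp,
            "lp_stderr_um": self.lp_stderr,
            "amplitude": self.amplitude,
            "n_samples": self.n_samples,
            "converged": self.converged,
        }
        if self.method == "modes":
            d["modes_used"] = sorted(self.per_mode_lp)
        else:
            d["fit_range_um"] = list(self.fit_range)
        if self.flexural_rigidity is not None:
            d["flexural_rigidity_J_m"] = self.flexural_rigidity
        if self.per_mode_lp:
            d["per_mode_lp_um"] = {str(k): v for k, v in self.per_mode_lp.items()}
        if self.message:
            d["message"] = self.message
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def report(self) -> str:
        """Human-readable one-result report."""
        lines = [f"method: {self.method}"]
        if self.converged:
            lines.append(f"Lp = {self.lp:.4g} +/- {self.lp_stderr:.2g} um")
        else:
            lines.append(f"FIT FAILED: {self.message}")
        if self.amplitude is not None:
            lines.append(f"amplitude A = {self.amplitude:.4g}")
        if self.method == "modes":
            lines.append(f"modes used: {sorted(self.per_mode_lp)}")
        else:
            lines.append(f"fit range: {self.fit_range[0]:.4g} - {self.fit_range[1]:.4g} um")
        lines.append(f"n_samples: {self.n_samples}")
        if self.flexural_rigidity is not None:
            lines.append(f"flexural rigidity kappa = {self.flexural_rigidity:.4g} J*m")
        return "\n".join(lines)


def _check_lp(lp: float) -> None:
    if not lp > 0:
        raise ValueError(f"persistence length must be positive, got {lp}")


def cosine_correlation_model(s, lp: float, amplitude: float = 1.0, convention: str = "2d"):
    """Expected tangent-angle cosine correlation A*exp(-s/(2*Lp)).

    Parameters
    ----------
    s : array_like
        Segment length(s), um, >= 0.
    lp : float
        Persistence length, um, > 0.
    amplitude : float
        Free decay amplitude A.
    convention : {"2d", "3d"}
        "2d" uses the s/(2*Lp) exponent appropriate for shapes
        equilibrated in two dimensions; "3d" uses s/Lp for users
        analysing projections of 3D fluctuations.
    """
    _check_lp(lp)
    c = _DECAY_FACTOR[convention]
    return amplitude * np.exp(-np.asarray(s, dtype=float) / (c * lp))


def mean_square_end_to_end_model(L, lp: float):
    """Mean square end-to-end distance of a 2D wormlike chain, um^2.

    <R^2> = 4*Lp*L - 8*Lp^2*(1 - exp(-L/(2*Lp))).  Approaches L^2 for a
    rigid rod (Lp >> L) and 4*Lp*L in the flexible limit (L >> Lp).
    """
    _check_lp(lp)
    L = np.asarray(L, dtype=float)
    x = L / (2.0 * lp)
    # expm1 keeps the rigid-rod limit accurate when x is tiny
    return 4.0 * lp * L + 8.0 * lp**2 * np.expm1(-x)


def lp_from_mode_variance(n: int, L: float, var_an: float) -> float:
    """Invert the equipartition relation var(a_n) = (1/Lp)*(L/(n*pi))^2."""
    if not (isinstance(n, (int, np.integer)) and 1 <= n <= MAX_MODE):
        raise ValueError(f"mode index must be an integer in 1..{MAX_MODE}, got {n}")
    if not L > 0:
        raise ValueError(f"contour length must be positive, got {L}")
    if not var_an > 0:
        raise ValueError("mode-amplitude variance must be positive (no fluctuation observed)")
    return (L / (n * math.pi)) ** 2 / var_an


def _failed(method: str, fit_range, n_samples: int, message: str,
            with_amplitude: bool = False) -> FitResult:
    return FitResult(
        lp=math.nan, lp_stderr=math.nan, method=method,
        fit_range=tuple(fit_range), n_samples=n_samples,
        amplitude=math.nan if with_amplitude else None,
        converged=False, message=message,
    )


def _initial_lp_from_slope(s, c, decay: float) -> float:
    """Initial Lp from the log-slope of the first decade of positive bins."""
    pos = c > 0
    s, c = s[pos], c[pos]
    if len(s) < 2:
        return max(float(s[-1]), 1.0) if len(s) else 1.0
    k = max(2, len(s) // 10)
    slope = np.polyfit(s[:k], np.log(c[:k]), 1)[0]
    if slope >= 0:  # noise-dominated start; fall back to the data span
        return float(s[-1])
    return -1.0 / (decay * slope)


def fit_cosine_correlation(
    data,
    fit_range: tuple[float, float] | None = None,
    convention: str = "2d",
    context: PhysicalContext | None = None,
    max_iterations: int = 5,
) -> FitResult:
    """Fit A*exp(-s/(2*Lp)) to binned cosine-correlation data.

    Both A and Lp are free, following the practice of not constraining
    the zero-separation correlation to unity (angle-determination noise
    depresses it).  Bins are weighted by their occupancy: the standard
    error of a bin mean scales as 1/sqrt(count).

    When ``fit_range`` is None the semiflexible window [0, 8*Lp_hat] is
    found iteratively, starting from a log-slope estimate of Lp: the
    correlation is informative up to roughly eight persistence lengths,
    beyond which it is noise around zero.

    Parameters
    ----------
    data : CorrelationData
        Object with ``s_bins``, ``mean_cosine`` and ``counts`` arrays.
    fit_range : (s_min, s_max) in um, optional.
    """
    s_all = np.asarray(data.s_bins, dtype=float)
    c_all = np.asarray(data.mean_cosine, dtype=float)
    n_all = np.asarray(data.counts, dtype=float)
    if np.any(np.abs(c_all) > 1.0 + 1e-9):
        raise ValueError("cosine values must lie in [-1, 1]")
    decay = _DECAY_FACTOR[convention]

    def select(rng):
        m = (s_all >= rng[0]) & (s_all <= rng[1])
        return s_all[m], c_all[m], n_all[m]

    if fit_range is not None:
        ranges = [tuple(fit_range)]
    else:
        lp_hat = _initial_lp_from_slope(s_all, c_all, decay)
        ranges = [(0.0, 8.0 * lp_hat)]

    result = None
    for _ in range(max_iterations):
        rng = ranges[-1]
        s, c, n = select(rng)
        if len(s) < 3:
            return _failed("cosine", rng, int(n_all.sum()),
                           f"fewer than 3 bins inside fit range {rng}", with_amplitude=True)
        # derivative-free start: amplitude at the smallest s, Lp from the
        # bin nearest the median s
        a0 = float(np.clip(c[0], 1e-3, 1.0))
        i_mid = int(np.argmin(np.abs(s - np.median(s))))
        if c[i_mid] > 0 and s[i_mid] > 0 and c[i_mid] < a0:
            lp0 = -s[i_mid] / (decay * math.log(c[i_mid] / a0))
        else:
            lp0 = max(float(s[-1]) / decay, 1e-3)
        sigma = 1.0 / np.sqrt(n)
        try:
            popt, pcov = curve_fit(
                lambda ss, lp, a: cosine_correlation_model(ss, lp, a, convention),
                s, c, p0=[lp0, a0], sigma=sigma, absolute_sigma=False,
                bounds=([1e-9, 1e-9], [1e9, 2.0]),
                xtol=1e-8, maxfev=500,
            )
        except RuntimeError as exc:
            return _failed("cosine", rng, int(n.sum()),
                           f"nonlinear fit did not converge: {exc}", with_amplitude=True)
        lp_fit, a_fit = popt
        perr = np.sqrt(np.diag(pcov))
        result = FitResult(
            lp=float(lp_fit), lp_stderr=float(perr[0]), method="cosine",
            fit_range=rng, n_samples=int(n.sum()),
            amplitude=float(a_fit), amplitude_stderr=float(perr[1]),
            flexural_rigidity=(context.flexural_rigidity(lp_fit) if context else None),
        )
        if fit_range is not None:
            break
        new_rng = (0.0, 8.0 * lp_fit)
        if abs(new_rng[1] - rng[1]) <= 0.01 * rng[1]:
            break
        ranges.append(new_rng)
    return result


def fit_end_to_end(
    records: Sequence[tuple[float, float]],
    n_bins: int | None = None,
    context: PhysicalContext | None = None,
) -> FitResult:
    """Fit <R^2>(L) to per-filament (contour length, R^2) records.

    Each filament contributes a single data point; points are binned by
    contour length (default: ~sqrt(N) bins) and bin means are fitted with
    occupancy weighting.  This estimator uses only the global geometry of
    each filament, so it needs many filaments and is less precise than
    the cosine correlation; it serves as an independent verification.
    """
    records = [(float(L), float(r2)) for L, r2 in records]
    if len(records) < 10:
        raise ValueError(f"need at least 10 (L, R^2) records, got {len(records)}")
    L = np.array([r[0] for r in records])
    R2 = np.array([r[1] for r in records])
    if np.any(L <= 0):
        raise ValueError("contour lengths must be positive")
    bad = R2 > L**2 * (1 + 1e-9)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} records have R^2 > L^2, which is geometrically impossible")
    if np.ptp(L) == 0:
        raise ValueError("all records share the same contour length; "
                         "cannot constrain <R^2>(L)")

    if n_bins is None:
        n_bins = max(6, int(round(math.sqrt(len(records)))))
    edges = np.linspace(L.min(), L.max() * (1 + 1e-12), n_bins + 1)
    idx = np.digitize(L, edges) - 1
    centers, means, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            centers.append(L[m].mean())
            means.append(R2[m].mean())
            counts.append(m.sum())
    centers = np.array(centers)
    means = np.array(means)
    counts = np.array(counts, dtype=float)
    fit_range = (float(L.min()), float(L.max()))

    lp0 = float(np.clip(np.mean(R2) / (4.0 * np.mean(L)), 1e-3, 1e6))
    try:
        popt, pcov = curve_fit(
            mean_square_end_to_end_model, centers, means,
            p0=[lp0], sigma=1.0 / np.sqrt(counts), absolute_sigma=False,
            bounds=(1e-9, 1e9), xtol=1e-8, maxfev=500,
        )
    except RuntimeError as exc:
        return _failed("end_to_end", fit_range, len(records),
                       f"nonlinear fit did not converge: {exc}")
    lp_fit = float(popt[0])
    return FitResult(
        lp=lp_fit, lp_stderr=float(np.sqrt(pcov[0, 0])), method="end_to_end",
        fit_range=fit_range, n_samples=len(records),
        flexural_rigidity=(context.flexural_rigidity(lp_fit) if context else None),
    )


def fit_modes(
    mode_amplitudes,
    modes: Sequence[int] = tuple(range(1, MAX_MODE + 1)),
    context: PhysicalContext | None = None,
) -> FitResult:
    """Combine per-mode equipartition estimates of Lp.

    For each requested mode the amplitude variance across frames gives an
    independent Lp via ``lp_from_mode_variance``; the combined estimate
    is their mean (each mode's variance estimate has the same relative
    chi-square error for a given frame count), with the standard error of
    that mean reported.

    Parameters
    ----------
    mode_amplitudes : ModeAmplitudes
        Object with ``mode_numbers``, ``amplitudes`` (n_frames x n_modes)
        and ``filament_length``.
    modes : which mode numbers to include (default 1..10).
    """
    amps = np.asarray(mode_amplitudes.amplitudes, dtype=float)
    mode_numbers = list(mode_amplitudes.mode_numbers)
    L = float(mode_amplitudes.filament_length)
    n_frames = amps.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames to estimate mode variances")
    per_mode: dict[int, float] = {}
    for n in modes:
        if n not in mode_numbers:
            raise ValueError(f"mode {n} not present in the amplitude data")
        var_an = float(np.var(amps[:, mode_numbers.index(n)], ddof=1))
        per_mode[n] = lp_from_mode_variance(int(n), L, var_an)
    vals = np.array(list(per_mode.values()))
    lp_fit = float(vals.mean())
    stderr = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return FitResult(
        lp=lp_fit, lp_stderr=stderr, method="modes",
        fit_range=(min(modes), max(modes) + 0.5) if min(modes) < max(modes) else (min(modes) - 0.5, min(modes) + 0.5),
        n_samples=n_frames, per_mode_lp=per_mode,
        flexural_rigidity=(context.flexural_rigidity(lp_fit) if context else None),
    )
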
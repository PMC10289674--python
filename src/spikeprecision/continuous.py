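"""Spike-timing precision from MI degradation under uniform noise.

The headline procedure: corrupt every spike time with an independent
draw from U(0, r_c), re-estimate the count-decomposed mutual information
between spiking and motor output many times per noise width, and trace
the mean MI as r_c grows.  Information carried at timescales finer than
r_c is destroyed by the corruption, so the noise width at which the mean
MI falls below the uncertainty band of the zero-noise estimate
operationally defines the timing precision.

Three selection rules convert a noise curve into a precision value:

* ``precision_std`` -- first noise width where the mean MI drops below
  (zero-noise MI - its data-fraction uncertainty); the default rule.
* ``precision_derivative`` -- location of the qualifying peak of the
  second derivative of MI with respect to noise width.
* ``precision_twoline`` -- intersection of lines fit to the low-noise
  and high-noise ends of the curve, treating the drop as a transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .datamodel import (SpikeMatrix, MotorScores, PrecisionEstimate,
                        RunConfig, UNRESOLVED, ValidationError)
from .ksg import timing_mi_decomposed

__all__ = [
    "NoiseCurve",
    "corrupt_spikes",
    "noise_curve",
    "data_fraction_uncertainty",
    "precision_std",
    "precision_derivative",
    "precision_twoline",
]


@dataclass
class NoiseCurve:
    """Mean/std of MI (bits) over a grid of uniform-noise widths (ms).

    ``zero_noise_mi`` is the single estimate on the uncorrupted data and
    ``zero_noise_std`` its uncertainty extrapolated from non-overlapping
    data fractions; ``mi_mean[0]`` equals ``zero_noise_mi``.
    """

    grid: np.ndarray
    mi_mean: np.ndarray
    mi_std: np.ndarray
    zero_noise_mi: float
    zero_noise_std: float
    n_reps: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mi_mean = np.asarray(self.mi_mean, dtype=float)
        self.mi_std = np.asarray(self.mi_std, dtype=float)
        if not (self.grid.size == self.mi_mean.size == self.mi_std.size):
            raise ValidationError("grid, mi_mean, mi_std must have equal length")
        if np.any(self.mi_std < 0):
            raise ValidationError("mi_std must be non-negative")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"r_c_ms": self.grid, "mi_mean_bits": self.mi_mean,
                             "mi_std_bits": self.mi_std})


def corrupt_spikes(spikes: SpikeMatrix, r_c: float,
                   rng: np.random.Generator) -> SpikeMatrix:
    """Shift every spike time by an independent draw from U(0, r_c).

    The noise is one-sided exactly as defined (the common mean shift of
    r_c/2 affects neither distances between trials nor MI).  The NaN
    padding pattern is preserved and rows are re-sorted ascending.
    """
    if r_c < 0:
        raise ValidationError(f"noise width must be >= 0, got {r_c}")
    if r_c == 0:
        return spikes
    times = spikes.times.copy()
    mask = ~np.isnan(times)
    times[mask] = times[mask] + rng.uniform(0.0, r_c, size=int(mask.sum()))
    return spikes.with_times(times)


def noise_curve(spikes: SpikeMatrix, motor: MotorScores,
                config: RunConfig) -> NoiseCurve:
    """Sweep the noise grid, estimating MI ``n_noise_reps`` times per level.

    At r_c = 0 the input is deterministic, so a single estimate is taken
    and its uncertainty computed by data fractioning instead.
    """
    rng = config.rng(stream=1)
    grid = config.noise_grid
    k = config.k
    jitter_seed = config.seed

    zero_est = timing_mi_decomposed(spikes, motor, k=k,
                                    tie_jitter_seed=jitter_seed)
    zero_std = data_fraction_uncertainty(spikes, motor, config)

    n_reps = config.n_noise_reps
    if n_reps == 1:
        warnings.warn("n_noise_reps=1: per-level std undefined, reported as 0",
                      stacklevel=2)
    mi_mean = np.empty(grid.size)
    mi_std = np.empty(grid.size)
    mi_mean[0] = zero_est.value
    mi_std[0] = zero_std
    for g in range(1, grid.size):
        vals = np.empty(n_reps)
        for r in range(n_reps):
            corrupted = corrupt_spikes(spikes, grid[g], rng)
            vals[r] = timing_mi_decomposed(corrupted, motor, k=k,
                                           tie_jitter_seed=jitter_seed).value
        mi_mean[g] = vals.mean()
        mi_std[g] = vals.std(ddof=1) if n_reps > 1 else 0.0
    return NoiseCurve(grid=grid, mi_mean=mi_mean, mi_std=mi_std,
                      zero_noise_mi=zero_est.value, zero_noise_std=zero_std,
                      n_reps=n_reps)


def data_fraction_uncertainty(spikes: SpikeMatrix, motor: MotorScores,
                              config: RunConfig,
                              fractions=(2, 3, 4, 5)) -> float:
    """Zero-noise MI uncertainty extrapolated from disjoint data fractions.

    For f = 2..5, trials are randomly split into f disjoint subsets, MI
    estimated on each, and the std across subsets recorded.  Fitting
    std(n) = A / sqrt(n) by least squares over the fraction sizes and
    evaluating at the full N gives the uncertainty of the full-data
    estimate.
    """
    n = spikes.n_trials
    if n < 40:
        raise ValidationError(f"data fractioning needs N >= 40, got {n}")
    rng = config.rng(stream=2)
    k = config.k
    floor = 4 * (k + 2)  # smallest fraction with a chance of stable classes

    sizes = []
    stds = []
    for f in fractions:
        if n // f < floor:
            continue
        perm = rng.permutation(n)
        chunks = np.array_split(perm, f)
        vals = []
        for ch in chunks:
            sub = spikes.with_times(spikes.times[ch])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals.append(timing_mi_decomposed(
                    sub, MotorScores.from_array(motor.scores[ch]), k=k,
                    tie_jitter_seed=config.seed).value)
        sizes.append(n // f)
        stds.append(np.std(vals, ddof=1))
    if not sizes:
        raise ValidationError("all data fractions below the estimator floor")
    x = 1.0 / np.sqrt(np.asarray(sizes, dtype=float))
    s = np.asarray(stds)
    amp = float(np.sum(s * x) / np.sum(x * x))  # least squares through origin
    return max(amp / np.sqrt(n), 0.0)


def precision_std(curve: NoiseCurve) -> PrecisionEstimate:
    """Smallest noise width whose mean MI is below (zero-noise MI - std)."""
    threshold = curve.zero_noise_mi - curve.zero_noise_std
    below = np.flatnonzero(curve.mi_mean[1:] < threshold) + 1
    diag = {"threshold_bits": threshold,
            "zero_noise_mi": curve.zero_noise_mi,
            "zero_noise_std": curve.zero_noise_std}
    if below.size == 0:
        return PrecisionEstimate(UNRESOLVED, "std_threshold", curve.grid, diag)
    idx = int(below[0])
    diag["crossing_index"] = idx
    return PrecisionEstimate(float(curve.grid[idx]), "std_threshold",
                             curve.grid, diag)


def precision_derivative(curve: NoiseCurve, min_amplitude: float = 0.1,
                         prominence: float = 0.05) -> PrecisionEstimate:
    """Noise width at the qualifying peak of the 2nd derivative of the curve.

    The second finite difference of the mean MI is taken on the
    logarithmic noise axis, where a log-spaced grid is uniform (a
    linear-axis difference would divide by the tiny spacings at the fine
    end and amplify estimation noise there).  Peak finding runs on the
    curvature magnitude normalized to 1 -- the sharp knee where the MI
    plateau gives way to decay is the curvature extremum regardless of
    its sign.  Peaks must exceed ``min_amplitude`` and have at least
    ``prominence`` prominence; the highest qualifying peak wins.
    """
    if curve.grid.size < 5:
        raise ValidationError("derivative rule needs >= 5 grid points")
    x = curve.grid[1:]  # drop the zero-noise anchor for the log axis
    u = np.log10(x)
    y = curve.mi_mean[1:]
    d2 = np.gradient(np.gradient(y, u), u)
    peak = np.max(np.abs(d2))
    diag: dict = {"raw_peak": float(peak)}
    # a straight line has zero curvature up to float noise; require the
    # peak curvature to be non-negligible on the curve's own scale before
    # normalizing, else noise is amplified into spurious peaks
    scale = np.ptp(y) / (u[-1] - u[0]) ** 2
    if peak <= 1e-6 * scale or scale == 0:
        return PrecisionEstimate(UNRESOLVED, "derivative", curve.grid, diag)
    d2n = np.abs(d2) / peak
    idxs, props = find_peaks(d2n, height=min_amplitude, prominence=prominence)
    # the outermost finite differences use one-sided boundary stencils;
    # a "peak" there is an edge artifact, and a genuine knee at the edge
    # of the tested range is unresolvable by construction
    interior = (idxs >= 3) & (idxs < d2n.size - 3)
    idxs, heights = idxs[interior], props["peak_heights"][interior]
    if idxs.size == 0:
        return PrecisionEstimate(UNRESOLVED, "derivative", curve.grid, diag)
    best = idxs[np.argmax(heights)]
    diag.update(peak_index=int(best) + 1,
                peak_height=float(d2n[best]))
    return PrecisionEstimate(float(x[best]), "derivative", curve.grid, diag)


def precision_twoline(curve: NoiseCurve, n_fit: int = 30) -> PrecisionEstimate:
    """Intersection of lines fit to the first/last ``n_fit`` non-zero levels.

    MI-vs-noise curves are examined on a logarithmic noise axis, where
    the low-noise plateau and the high-noise decay are each approximately
    linear; the lines are therefore fit in log10(r_c) and the returned
    precision is the noise width at their intersection.
    """
    x = np.log10(curve.grid[1:])
    y = curve.mi_mean[1:]
    if x.size < 2 * n_fit:
        raise ValidationError(
            f"two-line rule needs >= {2 * n_fit} non-zero noise levels, "
            f"got {x.size}")
    lo = np.polyfit(x[:n_fit], y[:n_fit], 1)
    hi = np.polyfit(x[-n_fit:], y[-n_fit:], 1)
    diag = {"low_line": [float(v) for v in lo],
            "high_line": [float(v) for v in hi]}
    if lo[0] == hi[0]:
        return PrecisionEstimate(UNRESOLVED, "two_line", curve.grid, diag)
    x_int = (hi[1] - lo[1]) / (lo[0] - hi[0])
    diag["intersection_log10"] = float(x_int)
    if not (x[0] <= x_int <= x[-1]):
        return PrecisionEstimate(UNRESOLVED, "two_line", curve.grid, diag)
    return PrecisionEstimate(float(10.0 ** x_int), "two_line", curve.grid,
                             diag)
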
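"""Validation-data generators with known ground truth.

Two dataset families mirror the structure of the real recordings:

* ``gaussian_pair`` -- one "spike time" per trial coupled to two motor
  PC scores through correlated Gaussians, the minimal testbed for MI
  estimation (the true MI has a closed form).
* ``moth_like`` -- variable per-trial spike counts within a wingbeat
  window, each spike time coupled to the motor scores, emulating a
  multi-spike flight muscle.

``fix_precision`` imposes a known ground-truth timing precision on any
spike matrix by rounding spike times to multiples of a chosen
resolution, enabling recovery experiments.  ``raw_flight_signal``
produces 10 kHz force/torque traces with known cycle boundaries for
exercising the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import SpikeMatrix, MotorScores, ValidationError

__all__ = [
    "GaussianPairSpec",
    "MothLikeSpec",
    "gaussian_pair",
    "moth_like",
    "fix_precision",
    "raw_flight_signal",
]


@dataclass
class GaussianPairSpec:
    """One correlated Gaussian 'spike time' per trial plus two PC scores.

    Defaults follow the validation setup: N = 2500 trials, mean 0,
    std 2 (ms for the time variable), with the time-score correlation
    ``rho`` swept between 0.5 and 0.9.
    """

    n: int = 2500
    rho: float = 0.9
    mu: float = 0.0
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError(f"|rho| must be < 1, got {self.rho}")
        if self.n < 10:
            raise ValidationError(f"n must be >= 10, got {self.n}")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


def gaussian_pair(spec: GaussianPairSpec) -> tuple[SpikeMatrix, MotorScores]:
    """Draw the Gaussian-pair dataset: time and both scores pairwise rho.

    A common latent factor z drives all three variables: the time is z
    itself and each score is rho*z + sqrt(1-rho^2)*noise, so
    corr(time, score_j) = rho while corr(score_1, score_2) = rho^2.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    e = rng.standard_normal((spec.n, 2))
    t = spec.mu + spec.sigma * z
    s = spec.mu + spec.sigma * (spec.rho * z[:, None]
                                + np.sqrt(1 - spec.rho ** 2) * e)
    spikes = SpikeMatrix.from_times(t[:, None])
    return spikes, MotorScores.from_array(s)


def gaussian_pair_true_mi(rho: float) -> float:
    """Closed-form MI (bits) between the time and both scores jointly.

    For the latent-factor construction the 3x3 correlation matrix is
    [[1, r, r], [r, 1, r^2], [r, r^2, 1]] and the Gaussian MI is
    -0.5 * log2(det C / det C_scores).
    """
    c = np.array([[1, rho, rho], [rho, 1, rho ** 2], [rho, rho ** 2, 1.0]])
    return float(-0.5 * np.log2(np.linalg.det(c)
                                / np.linalg.det(c[1:, 1:])))


@dataclass
class MothLikeSpec:
    """Multi-spike trials within a wingbeat window, timing coupled to output.

    ``count_probs`` maps per-trial spike count (support 1..6) to its
    probability; the default mixture is weighted toward 1-3 spikes as in
    single flight muscles.  Each spike time sits at a count-specific
    baseline phase inside the ~45 ms wingbeat window plus a Gaussian
    deviation of std ``timing_sd`` whose correlation with the (shared)
    motor drive is ``timing_rho``.
    """

    n: int = 2500
    count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05})
    timing_rho: float = 0.8
    timing_sd: float = 3.0
    window: tuple[float, float] = (0.0, 45.0)
    wingbeat_period: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.count_probs.values())
        if not np.isclose(total, 1.0):
            raise ValidationError(f"count_probs must sum to 1, got {total}")
        if any(c < 1 or c > 6 for c in self.count_probs):
            raise ValidationError("count support must be within 1..6")
        if self.window[0] >= self.window[1]:
            raise ValidationError("window bounds must be ordered")
        if not (-1.0 < self.timing_rho < 1.0):
            raise ValidationError("|timing_rho| must be < 1")


def moth_like(spec: MothLikeSpec) -> tuple[SpikeMatrix, MotorScores]:
    """Draw a moth-like dataset with count- and timing-coded information.

    Motor scores are standard normal.  Trial spike counts are drawn from
    ``count_probs`` independently of the scores (the count term of the
    decomposition is then near zero), and each spike time is its
    baseline phase plus timing_sd * (timing_rho * drive + residual),
    where the drive is the normalized sum of the two scores.
    """
    rng = np.random.default_rng(spec.seed)
    counts_support = np.array(sorted(spec.count_probs))
    probs = np.array([spec.count_probs[c] for c in counts_support])
    counts = rng.choice(counts_support, size=spec.n, p=probs)
    scores = rng.standard_normal((spec.n, 2))
    drive = scores.sum(axis=1) / np.sqrt(2.0)

    t0, t1 = spec.window
    span = t1 - t0
    max_count = int(counts.max())
    times = np.full((spec.n, max_count), np.nan)
    rho = spec.timing_rho
    for c in np.unique(counts):
        rows = np.flatnonzero(counts == c)
        # baseline phases spread evenly through the wingbeat window
        base = t0 + span * (np.arange(c) + 1) / (c + 1)
        resid = rng.standard_normal((rows.size, c))
        dev = spec.timing_sd * (rho * drive[rows, None]
                                + np.sqrt(1 - rho ** 2) * resid)
        times[rows, :c] = np.sort(base[None, :] + dev, axis=1)
    spikes = SpikeMatrix.from_times(times)
    return spikes, MotorScores.from_array(scores)


def fix_precision(spikes: SpikeMatrix, resolution: float) -> SpikeMatrix:
    """Round every spike time to the nearest multiple of ``resolution``.

    This imposes the resolution as a known ground-truth timing
    precision: no information can survive at finer scales.  Idempotent
    at a fixed resolution; the NaN pattern is unchanged.
    """
    if resolution <= 0:
        raise ValidationError(f"resolution must be > 0, got {resolution}")
    times = spikes.times.copy()
    mask = ~np.isnan(times)
    times[mask] = resolution * np.round(times[mask] / resolution)
    return spikes.with_times(times)


def raw_flight_signal(n_cycles: int, period_ms: float = 40.0,
                      noise_sd: float = 0.0, seed: int = 0,
                      fs_khz: float = 10.0):
    """Synthetic 10 kHz force/torque traces with known cycle boundaries.

    F_z is a periodic waveform with one dominant downward peak per cycle
    (plus Gaussian noise); tau_z varies cycle to cycle along exactly two
    latent waveforms, giving a known 2-D structure for the torque PCA.
    Returns ``(fz, tau, zero_points)`` where ``zero_points`` are the
    ground-truth sample indices of the downward F_z peaks.

    A warning is issued if the cycle frequency falls outside the
    5-35 Hz band-pass used for segmentation, where recovery degrades by
    design.
    """
    freq_hz = 1000.0 / period_ms
    if not (5.0 <= freq_hz <= 35.0):
        import warnings
        warnings.warn(f"cycle frequency {freq_hz:.1f} Hz outside the 5-35 Hz "
                      "segmentation passband", stacklevel=2)
    rng = np.random.default_rng(seed)
    samples_per_cycle = int(round(period_ms * fs_khz))
    n_samples = n_cycles * samples_per_cycle
    t = np.arange(n_samples)
    phase = 2 * np.pi * t / samples_per_cycle

    fz = -np.cos(phase)  # minimum (peak downward force) at each cycle start
    fz = fz + noise_sd * rng.standard_normal(n_samples)

    # two latent within-cycle torque waveforms with per-cycle weights
    w1 = np.sin(phase)
    w2 = np.sin(2 * phase + 0.7)
    a = np.repeat(rng.standard_normal(n_cycles), samples_per_cycle)
    b = np.repeat(rng.standard_normal(n_cycles), samples_per_cycle)
    tau = a * w1 + b * w2 + 0.01 * noise_sd * rng.standard_normal(n_samples)

    zero_points = np.arange(n_cycles) * samples_per_cycle
    return fz, tau, zero_points
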
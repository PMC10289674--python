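"""Cycle segmentation of periodic force traces and torque PCA.

Preprocessing from raw 10 kHz recordings to the trial-aligned
representations used by the estimators: the vertical force F_z is
band-pass filtered around the wingbeat frequency, the Hilbert analytic
phase defines a common zero point per cycle (at the peak downward
force), spikes are re-expressed as within-cycle times in ms, and the
per-cycle yaw-torque windows are reduced to two PC scores.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert
from sklearn.decomposition import PCA
from dataclasses import dataclass

from .datamodel import SpikeMatrix, MotorScores, ValidationError

__all__ = [
    "CycleSegmentation",
    "bandpass_fz",
    "segment_cycles",
    "torque_pca",
    "align_spikes",
]

FS_HZ = 10_000.0


@dataclass
class CycleSegmentation:
    """Per-cycle zero points (sample indices) and shortest-cycle length."""

    zero_points: np.ndarray
    L: int

    @property
    def n_cycles(self) -> int:
        return self.zero_points.size - 1  # full cycles between zero points

    def __post_init__(self) -> None:
        if np.any(np.diff(self.zero_points) <= 0):
            raise ValidationError("zero points must be strictly increasing")


def bandpass_fz(fz: np.ndarray, low_hz: float = 5.0, high_hz: float = 35.0,
                order: int = 8, fs_hz: float = FS_HZ) -> np.ndarray:
    """Zero-phase 8th-order Butterworth band-pass around the wingbeat band.

    Forward-backward application avoids the phase lag that would shift
    every cycle's zero point systematically.
    """
    fz = np.asarray(fz, dtype=float)
    sos = butter(order // 2, [low_hz, high_hz], btype="bandpass",
                 fs=fs_hz, output="sos")
    warmup = 3 * (2 * (order // 2) + 1)
    if fz.size <= 3 * warmup:
        raise ValidationError(f"trace too short to filter ({fz.size} samples)")
    return sosfiltfilt(sos, fz)


def segment_cycles(filtered_fz: np.ndarray,
                   target_phase: float = np.pi) -> CycleSegmentation:
    """Zero points where the analytic phase crosses ``target_phase`` + 2*pi*k.

    The default target is the phase of the waveform minimum (the peak
    downward force) for a signal whose fundamental is -cos.  Crossings
    are located on the unwrapped instantaneous phase and rounded to the
    nearest sample.
    """
    x = np.asarray(filtered_fz, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("constant signal: no cycles to segment")
    phase = np.unwrap(np.angle(hilbert(x)))
    # solve phase(t) = target + 2 pi k for every integer k in range
    k_lo = int(np.ceil((phase[0] - target_phase) / (2 * np.pi) - 1e-9))
    k_hi = int(np.floor((phase[-1] - target_phase) / (2 * np.pi) + 1e-9))
    zeros = []
    t = np.arange(x.size)
    for k in range(k_lo, k_hi + 1):
        level = target_phase + 2 * np.pi * k
        idx = np.searchsorted(phase, level)
        if idx == 0:
            zeros.append(0)
            continue
        if idx >= x.size:
            zeros.append(x.size - 1)
            continue
        # linear interpolation between bracketing samples, then round
        p0, p1 = phase[idx - 1], phase[idx]
        frac = 0.0 if p1 == p0 else (level - p0) / (p1 - p0)
        zeros.append(int(round(t[idx - 1] + frac)))
    zeros = np.unique(zeros)
    if zeros.size < 3:
        raise ValidationError("fewer than 3 cycles detected")
    gaps = np.diff(zeros)
    return CycleSegmentation(zero_points=zeros, L=int(gaps.min()))


def torque_pca(tau_z: np.ndarray, seg: CycleSegmentation
               ) -> tuple[MotorScores, np.ndarray, np.ndarray]:
    """Per-cycle torque windows (truncated to L samples) reduced to 2 PCs.

    Returns the N x 2 scores, the 2 x L loadings, and the explained
    variance ratios.  Loading signs are fixed so each loading's
    largest-magnitude element is positive, making score signs
    reproducible.
    """
    tau_z = np.asarray(tau_z, dtype=float)
    if seg.L < 2:
        raise ValidationError("shortest cycle too short for PCA")
    starts = seg.zero_points[:-1]
    usable = starts[starts + seg.L <= tau_z.size]
    windows = np.stack([tau_z[s:s + seg.L] for s in usable])
    pca = PCA(n_components=2)
    scores = pca.fit_transform(windows)
    loadings = pca.components_
    for j in range(2):
        peak = np.argmax(np.abs(loadings[j]))
        if loadings[j, peak] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return (MotorScores.from_array(scores), loadings,
            pca.explained_variance_ratio_)


def align_spikes(spike_samples: np.ndarray, seg: CycleSegmentation,
                 fs_khz: float = 10.0) -> SpikeMatrix:
    """Assign raw spike sample indices to cycles; times in ms from t = 0.

    Each spike falls in the cycle window [z_i, z_{i+1}); spikes before
    the first or after the last zero point are dropped (count logged).
    """
    import logging
    spike_samples = np.asarray(spike_samples)
    z = seg.zero_points
    cycle = np.searchsorted(z, spike_samples, side="right") - 1
    valid = (cycle >= 0) & (cycle < z.size - 1)
    dropped = int((~valid).sum())
    if dropped:
        logging.getLogger("spikeprecision").info(
            "%d spike(s) outside all cycle windows dropped", dropped)
    n_cycles = z.size - 1
    per_cycle: list[list[float]] = [[] for _ in range(n_cycles)]
    for s, c in zip(spike_samples[valid], cycle[valid]):
        per_cycle[c].append((s - z[c]) / fs_khz)
    max_count = max((len(p) for p in per_cycle), default=0)
    times = np.full((n_cycles, max(max_count, 1)), np.nan)
    for i, p in enumerate(per_cycle):
        times[i, :len(p)] = sorted(p)
    return SpikeMatrix.from_times(times, sample_resolution=1.0 / fs_khz)
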
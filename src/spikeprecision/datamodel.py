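"""Core domain types and delimited-text I/O.

The central representation is a trial-aligned spike matrix: one row per
cycle of a periodic motor behavior (a wing stroke), one column per
within-trial spike index, NaN-padded on the right where a trial has fewer
spikes than the maximum observed.  Motor output is represented per trial
as scores on the first two principal components of the within-cycle
output waveform.

All randomness in downstream estimators flows from the seed stored in
:class:`RunConfig` so that stochastic mutual-information estimates are
reproducible run to run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spikeprecision")

__all__ = [
    "SpikeMatrix",
    "MotorScores",
    "PairedDataset",
    "PrecisionEstimate",
    "RunConfig",
    "UNRESOLVED",
    "read_spike_matrix",
    "read_motor_scores",
    "write_spike_matrix",
    "write_motor_scores",
    "pair_dataset",
]

#: Sentinel returned by precision-selection rules when no threshold/peak
#: crossing exists within the tested noise or bin range.
UNRESOLVED = "unresolved"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class AlignmentError(ValidationError):
    """Raised when paired spike and motor tables disagree on trial count."""


def _normalize_rows(times: np.ndarray) -> tuple[np.ndarray, bool]:
    """Left-pack and ascending-sort the non-NaN entries of each row.

    ``np.sort`` places NaNs last in each row, which is exactly the
    left-packed ascending layout.  Returns the normalized matrix and
    whether any row needed reordering.
    """
    out = np.sort(times, axis=1)
    changed = not np.array_equal(out, times, equal_nan=True)
    return out, changed


@dataclass(frozen=True)
class SpikeMatrix:
    """NaN-padded matrix of within-trial spike times in milliseconds.

    Rows are trials (wing strokes); within each row the non-NaN entries
    occupy a left prefix and are sorted ascending.  ``counts[i]`` is the
    number of spikes in trial ``i`` and ``max_count`` the largest count
    observed (the number of columns).  ``sample_resolution`` records the
    temporal resolution of the source recording in ms per sample
    (0.1 ms for a 10 kHz acquisition).
    """

    times: np.ndarray
    counts: np.ndarray
    max_count: int
    sample_resolution: float = 0.1

    @classmethod
    def from_times(cls, times: np.ndarray, sample_resolution: float = 0.1,
                   _warn_on_sort: bool = True) -> "SpikeMatrix":
        times = np.asarray(times, dtype=float)
        if times.ndim == 1:
            times = times[:, None]
        if times.ndim != 2 or times.shape[0] == 0:
            raise ValidationError("spike matrix must be 2-D with at least one trial")
        if sample_resolution <= 0:
            raise ValidationError(f"sample_resolution must be > 0, got {sample_resolution}")
        finite_ok = np.isfinite(times) | np.isnan(times)
        if not np.all(finite_ok):
            raise ValidationError("spike times must be finite or NaN")
        norm, changed = _normalize_rows(times)
        if changed and _warn_on_sort:
            warnings.warn("spike rows were not sorted/left-packed; normalized", stacklevel=2)
        counts = np.sum(~np.isnan(norm), axis=1).astype(int)
        max_count = int(counts.max()) if counts.size else 0
        # drop all-NaN trailing columns so max_count == n columns
        norm = norm[:, :max(max_count, 1)]
        return cls(times=norm, counts=counts, max_count=max_count,
                   sample_resolution=float(sample_resolution))

    @property
    def n_trials(self) -> int:
        return self.times.shape[0]

    def with_times(self, times: np.ndarray) -> "SpikeMatrix":
        """Rebuild (revalidating) from a modified times matrix, keeping resolution."""
        return SpikeMatrix.from_times(times, self.sample_resolution, _warn_on_sort=False)

    def time_range(self) -> tuple[float, float]:
        """(t_min, t_max) over all observed spikes; errors if no spikes."""
        vals = self.times[~np.isnan(self.times)]
        if vals.size == 0:
            raise ValidationError("no spikes to bin")
        return float(vals.min()), float(vals.max())


@dataclass(frozen=True)
class MotorScores:
    """Per-trial scores on the first two motor-output principal components."""

    scores: np.ndarray

    @classmethod
    def from_array(cls, scores: np.ndarray) -> "MotorScores":
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 2:
            raise ValidationError(
                f"motor scores must be an N x 2 matrix, got shape {scores.shape}")
        if scores.shape[0] == 0:
            raise ValidationError("motor scores are empty")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("motor scores must be finite")
        return cls(scores=scores)

    @property
    def n_trials(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class PairedDataset:
    """Immutable pairing of a spike matrix with its motor scores."""

    spikes: SpikeMatrix
    motor: MotorScores

    @property
    def n_trials(self) -> int:
        return self.spikes.n_trials


def pair_dataset(spikes: SpikeMatrix, motor: MotorScores) -> PairedDataset:
    """Pair trial-aligned spike and motor tables, enforcing equal N."""
    if spikes.n_trials == 0 or motor.n_trials == 0:
        raise AlignmentError("empty dataset")
    if spikes.n_trials != motor.n_trials:
        raise AlignmentError(
            f"trial count mismatch: {spikes.n_trials} spike rows vs "
            f"{motor.n_trials} motor rows")
    return PairedDataset(spikes=spikes, motor=motor)


@dataclass
class PrecisionEstimate:
    """A spike-timing precision value in ms with provenance.

    ``value`` is the estimated precision in milliseconds, or the string
    ``"unresolved"`` when the selection rule found no qualifying
    crossing/peak. ``method`` names the selection rule, ``grid_or_bins``
    the noise grid (continuous rules) or bin range (discrete rule) it
    searched, and ``diagnostics`` holds rule-specific details such as the
    crossing index or fitted-line coefficients.
    """

    value: float | str
    method: str
    grid_or_bins: np.ndarray
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def resolved(self) -> bool:
        return not isinstance(self.value, str)


@dataclass
class RunConfig:
    """Parameters governing both estimation pipelines.

    Attributes
    ----------
    k : neighbor count for the KSG estimator (default 4).
    n_noise_reps : independent noise corruptions per noise level
        (default 150).
    noise_grid : ascending noise widths r_c in ms, starting at 0.  The
        default is 0 followed by 60 log-spaced levels from the 0.1 ms
        sampling resolution up to 32 ms.
    n_shuffles : label permutations for the shuffling bias correction.
    b_s_range : spike-word bin counts swept by the discrete method.
    b_m : equal-count partitions per motor PC (default 3, i.e. 9 states).
    seed : master RNG seed for every stochastic step.
    """

    k: int = 4
    n_noise_reps: int = 150
    noise_grid: np.ndarray = field(default_factory=lambda: default_noise_grid())
    n_shuffles: int = 10
    b_s_range: tuple[int, int] = (1, 70)
    b_m: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.noise_grid = np.asarray(self.noise_grid, dtype=float)
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.noise_grid.size == 0 or self.noise_grid[0] != 0.0:
            raise ValidationError("noise_grid must start at 0")
        if np.any(np.diff(self.noise_grid) <= 0) or np.any(self.noise_grid < 0):
            raise ValidationError("noise_grid must be ascending and non-negative")
        if self.n_shuffles < 10:
            raise ValidationError("n_shuffles must be >= 10")
        if self.b_m < 1:
            raise ValidationError("b_m must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A child generator for an independent named stream."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "noise_grid" in raw:
            raw["noise_grid"] = np.asarray(raw["noise_grid"], dtype=float)
        if "b_s_range" in raw:
            raw["b_s_range"] = tuple(raw["b_s_range"])
        return cls(**raw)

    def to_json(self, path: str) -> None:
        payload = asdict(self)
        payload["noise_grid"] = [float(x) for x in self.noise_grid]
        payload["b_s_range"] = list(self.b_s_range)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_noise_grid(n_levels: int = 60, r_min: float = 0.1,
                       r_max: float = 32.0) -> np.ndarray:
    """Zero plus ``n_levels`` log-spaced noise widths in ms.

    0.1 ms is the floor set by a 10 kHz sampling resolution; 60 non-zero
    levels are enough for the two-line precision rule, which fits the
    first and last 30 levels.
    """
    return np.concatenate([[0.0], np.geomspace(r_min, r_max, n_levels)])


# ---------------------------------------------------------------------------
# delimited-text readers/writers

def _read_table(path: str) -> pd.DataFrame:
    """Read a comma-separated table, detecting an optional header row."""
    probe = pd.read_csv(path, header=None, nrows=1)

    def _is_name(v) -> bool:
        if not isinstance(v, str):
            return False
        v = v.strip()
        if v == "" or v.lower() == "nan":
            return False
        try:
            float(v)
            return False
        except ValueError:
            return True

    # a header row is all names; a data row with one bad cell is not
    has_header = probe.iloc[0].apply(_is_name).all()
    df = pd.read_csv(path, header=0 if has_header else None,
                     float_precision="round_trip")
    return df


def read_spike_matrix(path: str, resolution: float = 0.1) -> SpikeMatrix:
    """Read a spike matrix from CSV: one row per trial, NaN/empty = absent."""
    if resolution <= 0:
        raise ValidationError(f"resolution must be > 0, got {resolution}")
    try:
        df = _read_table(path)
    except pd.errors.EmptyDataError:
        raise ValidationError("no trials in spike file") from None
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _locate_non_numeric(df)
        raise ValidationError(
            f"non-numeric cell at row {bad[0]}, column {bad[1]} of {path}") from exc
    if arr.shape[0] == 0:
        raise ValidationError("no trials in spike file")
    return SpikeMatrix.from_times(arr, sample_resolution=resolution)


def _locate_non_numeric(df: pd.DataFrame) -> tuple[int, int]:
    for i, row in df.iterrows():
        for j, v in enumerate(row):
            try:
                float(v)
            except (TypeError, ValueError):
                return int(i), int(j)
    return -1, -1


def read_motor_scores(path: str) -> MotorScores:
    """Read an N x 2 motor-score table from CSV (optional header row)."""
    try:
        df = _read_table(path)
    except pd.errors.EmptyDataError:
        raise ValidationError("no trials in motor-score file") from None
    if df.shape[1] != 2:
        raise ValidationError(
            f"motor-score file must have exactly 2 columns, got {df.shape[1]}")
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _locate_non_numeric(df)
        raise ValidationError(
            f"non-numeric cell at row {bad[0]}, column {bad[1]} of {path}") from exc
    return MotorScores.from_array(arr)


def write_spike_matrix(spikes: SpikeMatrix, path: str) -> None:
    pd.DataFrame(spikes.times).to_csv(path, header=False, index=False,
                                      float_format="%.17g")


def write_motor_scores(motor: MotorScores, path: str) -> None:
    pd.DataFrame(motor.scores, columns=["pc1", "pc2"]).to_csv(
        path, index=False, float_format="%.17g")
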
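"""Continuous and mixed discrete-continuous mutual-information estimation.

Implements the Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbor
estimator (algorithm 1: max-norm ball in the joint space, strict
inequality when counting marginal neighbors), a nearest-neighbor mixed
estimator for the information a discrete spike count carries about a
continuous motor output, and the count-conditioned decomposition

    I_total = I(count; M) + sum_i p(count = i) * I(times | count = i; M)

which isolates temporally encoded information from rate (count) coding.

All variables are standard scored before any distance comparison, so the
estimates are invariant to per-column affine rescaling.  Because the
estimator assumes continuous data, exact ties (which arise after
rounding spike times to a sampling grid) are broken by a deterministic
sub-resolution jitter, far below any physically meaningful timescale,
applied only inside distance computations.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

try:  # optional JIT acceleration of the marginal neighbor counting
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

from .datamodel import SpikeMatrix, MotorScores

__all__ = [
    "MIEstimate",
    "KnnDiagnostics",
    "standard_score",
    "ksg_mi",
    "mixed_mi_count",
    "timing_mi_decomposed",
    "knn_distance_diagnostics",
]

LN2 = np.log(2.0)
#: Relative amplitude of the deterministic tie-break jitter, in units of
#: the (unit, post-standard-scoring) column standard deviation.
TIE_JITTER = 1e-10
#: Below this sample count brute-force distance matrices beat a k-d tree.
BRUTE_FORCE_MAX_N = 200


@dataclass
class MIEstimate:
    """A mutual-information estimate in bits.

    ``per_count_terms`` is populated by the count-conditioned
    decomposition: a map from spike count to ``(mi_bits, weight)`` where
    the weight is the empirical probability of that count.  Counts whose
    class was too small for a stable conditional estimate appear with
    ``mi_bits = nan`` so their weight remains visible.
    """

    value: float
    k: int
    n: int
    per_count_terms: dict[int, tuple[float, float]] = field(default_factory=dict)


def standard_score(X: np.ndarray) -> np.ndarray:
    """Columnwise z-score; constant columns map to zero with a warning."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    if np.any(~nz):
        warnings.warn("constant column(s) standard-scored to zero", stacklevel=2)
    return out


def _column_jitter(Z: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic tie-break jitter for one standard-scored variable.

    Seeded from the run seed and a content hash of the variable, so the
    same variable receives the same jitter regardless of argument order
    (preserving the exact symmetry of the estimator in its arguments).
    """
    h = zlib.crc32(np.ascontiguousarray(Z).tobytes())
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, h]))
    return rng.uniform(-0.5, 0.5, size=Z.shape) * TIE_JITTER


def _shrink(eps: np.ndarray) -> np.ndarray:
    """Pull the count radius just inside the k-th-neighbor distance.

    The k-th joint neighbor often attains its max-norm distance in one
    marginal, placing it exactly on that marginal ball's boundary; the
    relative shrink (far above float rounding, far below the tie-break
    jitter) makes its strict exclusion deterministic in every counting
    path regardless of how the boundary comparison is rounded.
    """
    return eps * (1.0 - 1e-12)


def _count_within_1d(v: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Strictly-within-eps neighbor counts for a 1-D marginal (self excluded)."""
    r = _shrink(eps)
    order = np.sort(v)
    hi = np.searchsorted(order, v + r, side="left")
    lo = np.searchsorted(order, v - r, side="right")
    return hi - lo - 1


if _numba is not None:

    @_numba.njit
    def _scan_count(Y, eps):  # pragma: no cover - exercised via _count_within
        """Strict max-norm counts for points sorted by column 0."""
        n, d = Y.shape
        y0 = Y[:, 0]
        out = np.empty(n, np.int64)
        for i in range(n):
            e = eps[i]
            lo = np.searchsorted(y0, y0[i] - e, side="right")
            hi = np.searchsorted(y0, y0[i] + e, side="left")
            c = 0
            for j in range(lo, hi):
                ok = True
                for m in range(1, d):
                    if abs(Y[j, m] - Y[i, m]) >= e:
                        ok = False
                        break
                if ok:
                    c += 1
            out[i] = c - 1
        return out


def _count_within(M: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Strictly-within-eps max-norm neighbor counts (self excluded)."""
    if M.shape[1] == 1:
        return _count_within_1d(M[:, 0], eps)
    n = M.shape[0]
    r = _shrink(eps)
    if n <= BRUTE_FORCE_MAX_N:
        d = np.max(np.abs(M[:, None, :] - M[None, :, :]), axis=2)
        return (d < r[:, None]).sum(axis=1) - 1
    if _numba is not None:
        order = np.argsort(M[:, 0], kind="stable")
        counts = _scan_count(np.ascontiguousarray(M[order]),
                             np.ascontiguousarray(r[order]))
        out = np.empty(n, dtype=np.int64)
        out[order] = counts
        return out
    tree = cKDTree(M)
    return tree.query_ball_point(M, r, p=np.inf, return_length=True) - 1


def _knn_dist(Z: np.ndarray, k: int) -> np.ndarray:
    """Max-norm distance from each point to its k-th nearest neighbor."""
    n = Z.shape[0]
    if n <= BRUTE_FORCE_MAX_N:
        d = np.max(np.abs(Z[:, None, :] - Z[None, :, :]), axis=2)
        return np.partition(d, k, axis=1)[:, k]
    tree = cKDTree(Z)
    dist, _ = tree.query(Z, k=k + 1, p=np.inf)
    return dist[:, k]


def ksg_mi(X: np.ndarray, Y: np.ndarray, k: int = 4,
           tie_jitter_seed: int = 0) -> MIEstimate:
    """KSG (algorithm 1) mutual information between continuous X and Y, in bits.

    Both arguments are standard scored internally.  The estimate is
    psi(k) + psi(n) - <psi(n_x + 1) + psi(n_y + 1)> converted from nats,
    with n_x, n_y the numbers of marginal neighbors strictly inside the
    max-norm distance to the k-th joint-space neighbor.  Slightly
    negative values are reported unclipped (estimator noise around zero).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[1] == 0 or Y.shape[1] == 0:
        raise ValueError("X and Y must each have at least one column")
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= k:
        raise ValueError(f"need n > k; got n={n}, k={k}")

    Xz = standard_score(X)
    Yz = standard_score(Y)
    Xs = Xz + _column_jitter(Xz, tie_jitter_seed)
    Ys = Yz + _column_jitter(Yz, tie_jitter_seed)
    Z = np.hstack([Xs, Ys])

    eps = _knn_dist(Z, k)
    nx = _count_within(Xs, eps)
    ny = _count_within(Ys, eps)
    mi_nats = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return MIEstimate(value=float(mi_nats / LN2), k=k, n=n)


def mixed_mi_count(c: np.ndarray, Y: np.ndarray, k: int = 4,
                   tie_jitter_seed: int = 0) -> MIEstimate:
    """MI in bits between a discrete label and continuous Y.

    Nearest-neighbor scheme for mixed discrete-continuous pairs: for each
    point, the max-norm distance to its k-th neighbor among same-label
    points defines a ball, and the number of points of any label inside
    that ball enters a digamma average:

        I = psi(n) + psi(k) - <psi(n_label)> - <psi(m)>

    Labels with fewer than k+1 members cannot support the within-class
    search and are excluded with a warning.  The estimate is capped at
    the plugin entropy of the included labels (the information a label
    can carry is at most its entropy).
    """
    c = np.asarray(c)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = c.shape[0]
    labels, inverse, class_counts = np.unique(c, return_inverse=True,
                                              return_counts=True)
    if labels.size <= 1:
        return MIEstimate(value=0.0, k=k, n=n)

    usable = class_counts > k
    if not np.all(usable):
        warnings.warn(
            f"{int((~usable).sum())} label class(es) with <= k members "
            "excluded from mixed MI", stacklevel=2)
    keep = usable[inverse]
    if not np.any(keep):
        return MIEstimate(value=0.0, k=k, n=n)

    Yz = standard_score(Y)
    Ys = Yz + _column_jitter(Yz, tie_jitter_seed)
    Yk = Ys[keep]
    ck = inverse[keep]
    nk = Yk.shape[0]

    radius = np.empty(nk)
    label_n = np.empty(nk)
    for lab in np.unique(ck):
        mask = ck == lab
        pts = Yk[mask]
        radius[mask] = _knn_dist(pts, k)
        label_n[mask] = pts.shape[0]

    m = _count_within(Yk, radius) + 1  # include the point itself
    mi_nats = digamma(nk) + digamma(k) - np.mean(digamma(label_n)) - np.mean(digamma(m))
    # plugin entropy of the (included) label distribution bounds the MI
    probs = np.unique(ck, return_counts=True)[1] / nk
    h_label = float(-np.sum(probs * np.log(probs)))
    value = min(mi_nats, h_label) / LN2
    return MIEstimate(value=float(value), k=k, n=nk)


def _count_classes(spikes: SpikeMatrix):
    """Yield (count, trial-index array) for each observed spike count."""
    for count in np.unique(spikes.counts):
        yield int(count), np.flatnonzero(spikes.counts == count)


def timing_mi_decomposed(spikes: SpikeMatrix, motor: MotorScores, k: int = 4,
                         tie_jitter_seed: int = 0,
                         min_class_size: Optional[int] = None) -> MIEstimate:
    """Total MI between spiking and motor output, count/timing decomposed.

    Returns the count-code term plus, for each spike count i with enough
    trials, the count probability times the KSG MI between the n_i x i
    matrix of spike times and the corresponding motor scores.  Count
    classes smaller than max(k+2, 10) trials are excluded from the
    timing sum (too few points for a stable conditional estimate); their
    weight is still reported in ``per_count_terms`` with a NaN term.
    """
    if spikes.n_trials != motor.n_trials:
        raise ValueError("spikes and motor must be paired (equal N)")
    if min_class_size is None:
        min_class_size = max(k + 2, 10)

    count_term = mixed_mi_count(spikes.counts, motor.scores, k=k,
                                tie_jitter_seed=tie_jitter_seed)
    total = count_term.value
    n = spikes.n_trials
    per_count: dict[int, tuple[float, float]] = {}
    any_eligible = False
    for count, idx in _count_classes(spikes):
        weight = idx.size / n
        if count == 0:
            # trials without spikes carry no timing information
            per_count[count] = (0.0, weight)
            continue
        if idx.size < min_class_size:
            per_count[count] = (float("nan"), weight)
            continue
        times = spikes.times[idx, :count]
        est = ksg_mi(times, motor.scores[idx], k=k,
                     tie_jitter_seed=tie_jitter_seed)
        per_count[count] = (est.value, weight)
        total += weight * est.value
        any_eligible = True
    if not any_eligible:
        warnings.warn("no count class large enough for a timing term; "
                      "returning count term only", stacklevel=2)
    return MIEstimate(value=float(total), k=k, n=n, per_count_terms=per_count)


@dataclass
class KnnDiagnostics:
    """k-th-neighbor max-norm distance summaries per count class and noise level.

    ``median`` maps spike count -> array of median distances (standard-
    scored units) over the noise grid; ``quantiles`` holds the 25th/75th
    percentiles; ``delta_ms`` the difference from the zero-noise median
    converted back to milliseconds by multiplying by the mean standard
    deviation of that class's spike-time columns.
    """

    noise_grid: np.ndarray
    median: dict[int, np.ndarray]
    quantiles: dict[int, np.ndarray]
    delta_ms: dict[int, np.ndarray]


def knn_distance_diagnostics(spikes: SpikeMatrix, motor: MotorScores,
                             noise_grid, k: int = 4,
                             rng: Optional[np.random.Generator] = None,
                             tie_jitter_seed: int = 0) -> KnnDiagnostics:
    """Track how added uniform noise shifts k-NN distances per count class.

    For each spike-count class and each noise width, spike times are
    corrupted once, the joint (times, scores) space is standard scored,
    and the median k-th-neighbor max-norm distance recorded.  The change
    from the zero-noise median is also expressed in ms by undoing the
    standard scoring with the class's mean spike-time standard deviation.
    """
    from .continuous import corrupt_spikes  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(0)
    noise_grid = np.asarray(noise_grid, dtype=float)
    min_class = max(k + 2, 10)

    median: dict[int, np.ndarray] = {}
    quantiles: dict[int, np.ndarray] = {}
    delta_ms: dict[int, np.ndarray] = {}
    for count, idx in _count_classes(spikes):
        if count == 0 or idx.size < min_class:
            continue
        med = np.empty(noise_grid.size)
        qts = np.empty((noise_grid.size, 2))
        sds = np.empty(noise_grid.size)
        for g, r_c in enumerate(noise_grid):
            corrupted = corrupt_spikes(spikes, r_c, rng) if r_c > 0 else spikes
            times = corrupted.times[idx, :count]
            joint = np.hstack([times, motor.scores[idx]])
            Zs = standard_score(joint)
            Zs = Zs + _column_jitter(Zs, tie_jitter_seed)
            d = _knn_dist(Zs, k)
            med[g] = np.median(d)
            qts[g] = np.percentile(d, [25, 75])
            col_sd = times.std(axis=0, ddof=1)
            sds[g] = float(np.mean(col_sd)) if np.all(col_sd > 0) else float("nan")
        median[count] = med
        quantiles[count] = qts
        delta_ms[count] = (med - med[0]) * sds
    return KnnDiagnostics(noise_grid=noise_grid, median=median,
                          quantiles=quantiles, delta_ms=delta_ms)
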
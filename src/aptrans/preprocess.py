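"""Preprocessing for network training: zero-phase noise filtering,
population centering / max-normalization (with exact inversion), and AP
morphology features (APD90, max upstroke velocity, MDP, peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.signal import butter, filtfilt

from .simulator import UPSTROKE_DVDT_THRESHOLD

__all__ = [
    "NormStats",
    "zero_phase_filter",
    "fit_norm_stats",
    "normalize",
    "denormalize",
    "morphology_features",
    "MorphologyFeatures",
]

DEFAULT_CUTOFF_HZ = 100.0
DEFAULT_ORDER = 4
DEFAULT_FS_HZ = 1000.0  # 1-ms sampling


@dataclass
class NormStats:
    """Population centering/scaling statistics for one cell type.

    ``mean`` is the grand mean (mV) over every sample of every training
    trace of the cell type; ``scale`` is the maximum absolute centered
    value (mV) over the same set, so normalized training traces lie in
    [-1, 1].  Fit on training data only.
    """

    cell_type: str
    mean: float
    scale: float
    filter_cutoff_hz: float = DEFAULT_CUTOFF_HZ
    filter_order: int = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("normalization scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "mean": self.mean,
            "scale": self.scale,
            "filter_cutoff_hz": self.filter_cutoff_hz,
            "filter_order": self.filter_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(**d)


def zero_phase_filter(
    trace: np.ndarray,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    fs_hz: float = DEFAULT_FS_HZ,
) -> np.ndarray:
    """Low-pass Butterworth filter applied forward and backward.

    Forward-backward application cancels the filter's phase response, so
    repolarization timing (hence APD90) is preserved while high-frequency
    noise is removed.  Output length equals input length.
    """
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{fs_hz / 2} Hz"
        )
    v = np.asarray(trace, dtype=float)
    b, a = butter(order, cutoff_hz, fs=fs_hz)
    return filtfilt(b, a, v)


def _as_matrix(traces: Iterable[np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(t, dtype=float) for t in traces]
    if not arrs:
        raise ValueError("need at least one trace")
    return np.stack(arrs)


def fit_norm_stats(
    training_traces: Iterable[np.ndarray],
    cell_type: str,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> NormStats:
    """Grand mean and max-abs scale over the training traces of one cell type."""
    m = _as_matrix(training_traces)
    mean = float(m.mean())
    scale = float(np.abs(m - mean).max())
    if scale == 0:
        raise ValueError(
            "normalization scale undefined: traces are constant after centering"
        )
    return NormStats(cell_type=cell_type, mean=mean, scale=scale,
                     filter_cutoff_hz=cutoff_hz, filter_order=order)


def normalize(trace: np.ndarray, stats: NormStats, cell_type: str | None = None) -> np.ndarray:
    """(V - mean) / scale.  Training-set traces land in [-1, 1]; held-out
    traces may exceed that range, which is allowed."""
    if cell_type is not None and cell_type != stats.cell_type:
        raise ValueError(
            f"stats are for cell type {stats.cell_type!r}, got {cell_type!r}"
        )
    return (np.asarray(trace, dtype=float) - stats.mean) / stats.scale


def denormalize(trace: np.ndarray, stats: NormStats, cell_type: str | None = None) -> np.ndarray:
    """Exact inverse of :func:`normalize`."""
    if cell_type is not None and cell_type != stats.cell_type:
        raise ValueError(
            f"stats are for cell type {stats.cell_type!r}, got {cell_type!r}"
        )
    return np.asarray(trace, dtype=float) * stats.scale + stats.mean


class MorphologyFeatures(NamedTuple):
    apd90_ms: float
    vmax_mv_per_ms: float
    mdp_mv: float
    peak_mv: float


def morphology_features(trace: np.ndarray, dt: float = 1.0) -> MorphologyFeatures:
    """APD90, maximum upstroke velocity, MDP and peak of a single-AP window.

    The diastolic reference (MDP) is a robust minimum: the mean of the
    samples at or below the trace's 10th voltage percentile (in a
    single-AP window aligned 5 ms before the upstroke, the diastolic
    phase lies after repolarization; averaging removes the downward bias
    a pointwise minimum picks up from noise).  APD90 runs from the
    activation time — the interpolated upward crossing of the
    half-amplitude level on the upstroke, the standard marker that is
    insensitive to smoothing (a symmetric filter preserves the midpoint
    of an edge, whereas the maximum-dV/dt sample of a slow upstroke
    shifts) — to the interpolated downward crossing of
    ``peak - 0.9 * (peak - MDP)``.  On a noisy trace the repolarization
    may dither through that level, so the downward crossing is the
    median of the first crossing cluster (a clean trace has a single
    crossing, recovered exactly).  V_max is still the maximum dV/dt.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 3:
        raise ValueError("trace too short for morphology analysis")
    span = v.max() - v.min()
    if span < 1e-9:
        raise ValueError("flat trace: no action potential present")
    dvdt = np.diff(v) / dt
    up = int(np.argmax(dvdt))
    vmax = float(dvdt[up])
    low = v <= np.quantile(v, 0.1)
    mdp = float(v[low].mean())
    peak = float(v.max())
    level = peak - 0.9 * (peak - mdp)
    pk = int(np.argmax(v))
    # activation time: upward crossing of the half-amplitude level (last
    # one before the peak); fall back to the max-dV/dt sample if the
    # window starts above that level
    level50 = peak - 0.5 * (peak - mdp)
    rise = np.nonzero((v[:pk] < level50) & (v[1:pk + 1] >= level50))[0]
    if rise.size:
        i = int(rise[-1])
        t_start = (i + (level50 - v[i]) / (v[i + 1] - v[i])) * dt
    else:
        t_start = up * dt

    start = max(pk, up)
    seg = v[start:]
    down = np.nonzero((seg[:-1] >= level) & (seg[1:] < level))[0]
    if down.size == 0:
        raise ValueError(
            "incomplete repolarization: no APD90 crossing within the trace"
        )
    cluster = down[down - down[0] <= int(round(16.0 / dt))]
    times = [(start + i + (seg[i] - level) / (seg[i] - seg[i + 1])) * dt
             for i in cluster]
    t_cross = float(np.median(times))
    # a windowed trace that is still repolarizing at its end (falling
    # tail) never reached its true diastolic level: the apparent
    # crossing is an artifact of the truncated baseline
    tail = v[-min(40, v.size // 4):]
    if np.polyfit(np.arange(tail.size), tail, 1)[0] < -0.1 * dt:
        raise ValueError(
            "incomplete repolarization: trace is still falling at the "
            "end of the window"
        )
    return MorphologyFeatures(
        apd90_ms=t_cross - t_start,
        vmax_mv_per_ms=vmax,
        mdp_mv=mdp,
        peak_mv=peak,
    )
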
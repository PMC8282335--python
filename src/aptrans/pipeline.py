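"""Glue between the simulated population and the network: filtering,
normalization-statistics fitting on the training split, and array
preparation for training and evaluation."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .dataset import DatasetSplit
from .preprocess import NormStats, fit_norm_stats, normalize, zero_phase_filter

__all__ = ["prepare_data"]


def _stack(samples, which: str, filtered: bool, cutoff, order):
    out = []
    for s in samples:
        v = (s.input_trace if which == "input" else s.target_trace).voltage
        if filtered:
            v = zero_phase_filter(v, cutoff, order)
        out.append(v)
    return np.stack(out) if out else np.empty((0, 0))


def prepare_data(
    split: DatasetSplit,
    cutoff_hz: float = 100.0,
    order: int = 4,
    apply_filter: bool = True,
) -> dict:
    """Filter, fit per-cell-type normalization on the training split, and
    return normalized arrays for every split.

    Returns a dict with X_/Y_/labels_ arrays for train/val/test plus the
    fitted ``stats_immature`` and ``stats_adult``.
    """
    parts = {"train": split.training, "val": split.validation, "test": split.test}
    raw = {
        name: (
            _stack(ss, "input", apply_filter, cutoff_hz, order),
            _stack(ss, "target", apply_filter, cutoff_hz, order),
            np.array([s.label for s in ss], dtype=int),
        )
        for name, ss in parts.items()
    }
    window = raw["train"][0].shape[1]
    raw = {
        name: tuple(np.empty((0, window)) if a.ndim == 2 and a.size == 0 else a
                    for a in arrs)
        for name, arrs in raw.items()
    }
    stats_imm = fit_norm_stats(raw["train"][0], "immature", cutoff_hz, order)
    stats_adult = fit_norm_stats(raw["train"][1], "adult", cutoff_hz, order)
    data: dict = {"stats_immature": stats_imm, "stats_adult": stats_adult}
    for name, (X, Y, lab) in raw.items():
        data[f"X_{name}"] = normalize(X, stats_imm)
        data[f"Y_{name}"] = normalize(Y, stats_adult)
        data[f"labels_{name}"] = lab
    return data
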
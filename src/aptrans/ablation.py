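"""Ablation experiments: time-window feature ablation (zero out part of
the input sequence and retrain from scratch) and model ablation (drop the
second LSTM layer; drop the classification head).

Every ablation run reuses the intact run's data, seeds and configuration
and changes exactly one element; results are reported next to the intact
network's reference report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .metrics import EvalReport, evaluate
from .network import NetConfig, NetParams, init_params
from .training import TrainConfig, train

__all__ = [
    "AblationResult",
    "default_windows",
    "zero_window",
    "feature_ablation",
    "build_no_second_lstm_variant",
    "build_translation_only_variant",
    "train_and_evaluate",
    "locate_high_resistance_window",
]


@dataclass
class AblationResult:
    variant: str
    report: EvalReport
    reference: Optional[EvalReport] = None

    @property
    def delta_auroc(self) -> Optional[float]:
        if self.reference is None or self.report.auroc is None:
            return None
        return self.report.auroc - self.reference.auroc

    @property
    def delta_mse(self) -> Optional[float]:
        if self.reference is None:
            return None
        return self.report.mse - self.reference.mse


def default_windows(window: int = 701, step: int = 100) -> list[tuple[int, int]]:
    """Non-overlapping 100-ms windows; the final one absorbs the remainder
    (600-701 ms for the default sequence length)."""
    out = []
    lo = 0
    while lo < window:
        hi = min(lo + step, window)
        if window - hi < step:
            hi = window
        out.append((lo, hi))
        lo = hi
    return out


def zero_window(X: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Zero the normalized input inside [t_a, t_b) (zero = population mean)."""
    a, b = window
    if not (0 <= a < b <= X.shape[-1]):
        raise ValueError(f"window {window} outside the sequence or empty")
    out = np.array(X, dtype=float, copy=True)
    out[..., a:b] = 0.0
    return out


def train_and_evaluate(
    data: dict,
    net_config: NetConfig,
    train_config: TrainConfig,
    init_seed: int = 0,
) -> tuple[NetParams, EvalReport, list]:
    """Train from scratch on ``data`` and evaluate on its test split."""
    params = init_params(net_config, seed=init_seed)
    trained, history = train(data, params, train_config)
    report = evaluate(
        trained, data["X_test"], data["Y_test"],
        data["labels_test"] if net_config.include_classifier else None,
        data["stats_adult"],
    )
    return trained, report, history


def feature_ablation(
    data: dict,
    window: tuple[int, int],
    net_config: NetConfig,
    train_config: TrainConfig,
    reference: Optional[EvalReport] = None,
    init_seed: int = 0,
) -> AblationResult:
    """Zero a time window of every input (train/val/test), retrain from
    scratch with the same seeds/config, and evaluate on the ablated test
    inputs."""
    ablated = dict(data)
    for part in ("train", "val", "test"):
        ablated[f"X_{part}"] = zero_window(data[f"X_{part}"], window)
    _, report, _ = train_and_evaluate(ablated, net_config, train_config, init_seed)
    return AblationResult(
        variant=f"window[{window[0]},{window[1]})", report=report,
        reference=reference,
    )


def build_no_second_lstm_variant(net_config: NetConfig) -> NetConfig:
    """Same network with a single LSTM layer feeding the same heads."""
    return dc_replace(net_config, num_lstm_layers=1)


def build_translation_only_variant(net_config: NetConfig) -> NetConfig:
    """Network without the classification head; the loss reduces to the
    translation MSE alone."""
    return dc_replace(net_config, include_classifier=False)


def locate_high_resistance_window(
    voltage: np.ndarray,
    current: np.ndarray,
    windows: Optional[list] = None,
    dt: float = 1.0,
    cap: float = 1.0e4,
) -> tuple[int, int]:
    """Window containing the AP's high-membrane-resistance plateau phase.

    Scores each candidate window by the median |dV/dI| (capped) over its
    *plateau* samples — those above the diastolic voltage range — and
    returns the argmax.  During a high-resistance phase inward and
    outward currents balance (dI -> 0), so perturbations (I_Kr block,
    noise) produce their largest voltage effect.  Diastolic samples are
    excluded because a slowly depolarizing resting membrane also carries
    a near-constant current without being the phase of interest; windows
    that are mostly diastole are not eligible.
    """
    from .simulator import membrane_resistance_series

    v = np.asarray(voltage, dtype=float)
    r, _ = membrane_resistance_series(v, current, dt=dt, cap=cap)
    plateau = v > v.min() + 0.25 * (v.max() - v.min())
    wins = windows if windows is not None else default_windows(len(v))
    scores = []
    for a, b in wins:
        sel = plateau[a:b]
        if sel.mean() < 0.5:
            scores.append(-np.inf)
            continue
        scores.append(float(np.median(np.abs(r[a:b][sel]))))
    return wins[int(np.argmax(scores))]
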
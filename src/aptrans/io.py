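"""CSV readers/writers for AP populations, run manifests, and the
experimental-trace translation path."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import PairedSample
from .network import NetParams, forward_cached
from .preprocess import NormStats, normalize, denormalize, zero_phase_filter
from .simulator import (
    APTrace,
    DrugSpec,
    NETWORK_WINDOW,
    UPSTROKE_PRE_MS,
    detect_upstrokes,
)

__all__ = [
    "write_traces_csv",
    "read_ap_csv",
    "write_population",
    "read_population",
    "RunManifest",
    "translate_trace",
]

_META_COLS = ["id", "phenotype", "condition", "block_fraction",
              "cycle_length_ms", "seed"]


def _trace_row(i: int, trace: APTrace, condition: str) -> list:
    return [i, trace.phenotype, condition, trace.drug.block_fraction,
            trace.cycle_length_ms, trace.seed] + list(trace.voltage)


def write_traces_csv(path, traces: Sequence[APTrace],
                     conditions: Optional[Sequence[str]] = None) -> None:
    """One row per trace: metadata columns then v0..v{n-1} in mV at 1 ms."""
    conds = conditions if conditions is not None else [t.drug.mode for t in traces]
    n = len(traces[0].voltage)
    cols = _META_COLS + [f"v{j}" for j in range(n)]
    rows = [_trace_row(i, t, c) for i, (t, c) in enumerate(zip(traces, conds))]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_ap_csv(path, orientation: str = "auto", dt: float = 1.0) -> list[APTrace]:
    """Read AP traces from CSV.

    Accepts this package's own schema (metadata columns + v0..vN), a bare
    numeric matrix with traces as rows or as columns (auto-detected by
    which axis is longer, overridable via ``orientation`` in
    {"rows", "columns"}), and files with a leading time column in ms
    (used to infer the sampling step).
    """
    df = pd.read_csv(path)
    if set(_META_COLS).issubset(df.columns):
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        vcols.sort(key=lambda c: int(c[1:]))
        out = []
        for _, row in df.iterrows():
            frac = float(row["block_fraction"])
            cond = str(row["condition"])
            if cond == "simple_block":
                drug = DrugSpec(mode="simple_block", block_fraction=frac)
            elif cond in ("state_dependent",):
                drug = DrugSpec(mode="state_dependent")
            else:
                drug = DrugSpec()
            out.append(APTrace(
                voltage=row[vcols].to_numpy(dtype=float),
                dt_out=dt,
                phenotype=str(row["phenotype"]),
                drug=drug,
                cycle_length_ms=float(row["cycle_length_ms"]),
                seed=int(row["seed"]),
            ))
        return out

    # headerless / bare numeric layouts: re-read without a header if the
    # first row was numeric data
    try:
        first_numeric = all(
            isinstance(c, (int, float)) or str(c).replace(".", "", 1)
            .replace("-", "", 1).replace("e", "", 1).replace("+", "", 1).isdigit()
            for c in df.columns
        )
    except Exception:
        first_numeric = False
    if first_numeric:
        df = pd.read_csv(path, header=None)
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from e
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"missing/ragged value at row {i}, column {j} of {path}")

    # a monotonically increasing first column is a time axis
    t0 = mat[:, 0]
    if mat.shape[1] > 1 and np.all(np.diff(t0) > 0) and t0[0] in (0.0,) and mat.shape[0] > mat.shape[1]:
        step = float(np.median(np.diff(t0)))
        mat = mat[:, 1:].T  # remaining columns are traces
        return [APTrace(voltage=v, dt_out=step) for v in mat]

    if orientation == "auto":
        orientation = "rows" if mat.shape[1] >= mat.shape[0] else "columns"
    if orientation == "columns":
        mat = mat.T
    elif orientation != "rows":
        raise ValueError("orientation must be 'auto', 'rows' or 'columns'")
    return [APTrace(voltage=v, dt_out=dt) for v in mat]


def write_population(directory, samples: Sequence[PairedSample],
                     manifest: Optional[dict] = None) -> None:
    """Write a paired population as inputs.csv / targets.csv (+ labels in
    both) and an optional manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(samples[0].input_trace)
    cols = _META_COLS + ["label"] + [f"v{j}" for j in range(n)]
    for name, which in (("inputs.csv", "input_trace"), ("targets.csv", "target_trace")):
        rows = []
        for i, s in enumerate(samples):
            tr = getattr(s, which)
            rows.append([i, tr.phenotype, s.condition, s.block_fraction,
                         s.cycle_length_ms, s.seed, s.label] + list(tr.voltage))
        pd.DataFrame(rows, columns=cols).to_csv(directory / name, index=False)
    if manifest is not None:
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_population(directory) -> list[PairedSample]:
    directory = Path(directory)
    dfs = {name: pd.read_csv(directory / f"{name}.csv")
           for name in ("inputs", "targets")}
    vcols = [c for c in dfs["inputs"].columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    out = []
    for (_, ri), (_, rt) in zip(dfs["inputs"].iterrows(), dfs["targets"].iterrows()):
        cond = str(ri["condition"])
        frac = float(ri["block_fraction"])
        if cond == "simple_block":
            drug = DrugSpec(mode="simple_block", block_fraction=frac)
        elif cond == "state_dependent":
            drug = DrugSpec(mode="state_dependent")
        else:
            drug = DrugSpec()
        mk = lambda row, ph: APTrace(
            voltage=row[vcols].to_numpy(dtype=float), phenotype=ph, drug=drug,
            cycle_length_ms=float(row["cycle_length_ms"]), seed=int(row["seed"]))
        out.append(PairedSample(
            input_trace=mk(ri, "immature"),
            target_trace=mk(rt, "adult"),
            label=int(ri["label"]),
            condition=cond,
            cycle_length_ms=float(ri["cycle_length_ms"]),
            block_fraction=frac,
            seed=int(ri["seed"]),
        ))
    return out


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit with the same
    toolchain: config snapshot, master seed, population sizes, split
    membership, normalization statistics and the software version."""

    config: dict
    seed: int
    sizes: dict
    split_ids: dict
    norm_stats: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        d.pop("version", None)
        m = cls(**{k: d[k] for k in ("config", "seed", "sizes", "split_ids",
                                     "norm_stats")})
        return m


def _fit_to_window(v: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Crop/pad a raw trace to the 701-sample window at 1-ms steps.

    Longer traces are cropped to the final complete AP window (5 ms before
    the last usable upstroke); shorter traces are padded at the end with
    the trace's own diastolic (minimum) value.
    """
    if dt != 1.0:
        n_new = int(round(len(v) * dt))
        v = np.interp(np.arange(n_new), np.arange(len(v)) * dt, v)
    ups = detect_upstrokes(v)
    if len(ups) == 0:
        raise ValueError("no upstroke found in the trace; cannot window it")
    if len(v) >= NETWORK_WINDOW:
        tail = NETWORK_WINDOW - UPSTROKE_PRE_MS
        usable = [u for u in ups if u - UPSTROKE_PRE_MS >= 0 and u + tail <= len(v)]
        if usable:
            u = usable[-1]
            return v[u - UPSTROKE_PRE_MS:u - UPSTROKE_PRE_MS + NETWORK_WINDOW].copy()
        v = v[-NETWORK_WINDOW:]
        return v.copy()
    pad = np.full(NETWORK_WINDOW - len(v), float(np.min(v)))
    return np.concatenate([v, pad])


def translate_trace(
    raw_trace: np.ndarray,
    params: NetParams,
    stats_immature: NormStats,
    stats_adult: NormStats,
    dt: float = 1.0,
    apply_filter: bool = True,
) -> tuple[np.ndarray, Optional[float]]:
    """Translate a raw immature AP trace (mV) into an adult AP trace (mV).

    Pipeline: window to 701 samples -> zero-phase filter -> normalize with
    the *training* statistics -> network forward (dropout off) ->
    denormalize.  Also returns the drug probability (None for a
    translation-only network).
    """
    v = _fit_to_window(np.asarray(raw_trace, dtype=float), dt)
    if apply_filter:
        v = zero_phase_filter(v, stats_immature.filter_cutoff_hz,
                              stats_immature.filter_order)
    x = normalize(v, stats_immature)
    y, prob, _ = forward_cached(x, params, training=False)
    return denormalize(y, stats_adult), prob
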
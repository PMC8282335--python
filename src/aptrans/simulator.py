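"""Reduced ionic-model simulator for immature (iPSC-CM-like) and adult
ventricular action potentials.

The cell model is a Hodgkin–Huxley-style surrogate with seven currents

    I_Na, I_CaL, I_Kr, I_Ks, I_to, I_K1  and  I_f (immature phenotype only),

each of the form ``I_x = G_x * (gates) * (V - E_x)`` with two-gate kinetics
and Boltzmann steady states.  It is *not* a reproduction of any published
ionic model; its parameters are calibrated once, as packaged defaults, to a
qualitative morphology contract:

* the immature cell beats spontaneously (funny current + weak I_K1) with a
  maximum diastolic potential in [-80, -70] mV and a spontaneous cycle
  length near 982 ms;
* the adult cell is quiescent at a resting potential in [-92, -84] mV,
  fires 1:1 when paced, and has a faster upstroke and a shorter APD90 than
  the immature cell at a matched cycle length;
* APD90 increases monotonically with the fraction of I_Kr block.

Membrane voltage is integrated by Forward Euler at a fixed internal step
(default 0.01 ms) and resampled to a 1-ms output grid.  A stochastic noise
current is added to the membrane potential during the final ``noisy_beats``
paced beats as

    V_{t+dt} = V_t - I(V_t) * dt / Cm + xi * n * sqrt(dt),   n ~ N(0, 1)

with diffusion coefficient ``xi`` (default 0.3).  Drug block of I_Kr is
modelled either as a time-constant conductance scaling (``simple_block``)
or as a two-state open-channel binding scheme (``state_dependent``) whose
bound fraction b follows  db/dt = k_on*[D]*p_open*(1-b) - k_off*b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "IonicParams",
    "DrugSpec",
    "PacingProtocol",
    "NoiseSpec",
    "APTrace",
    "immature_params",
    "adult_params",
    "euler_noise_step",
    "apply_simple_block",
    "state_dependent_gkr_factor",
    "simulate_ap",
    "simulate_trace",
    "detect_upstrokes",
    "detect_cycle_length",
    "membrane_resistance_series",
    "SimulationError",
]

NETWORK_WINDOW = 701          # samples fed to the network (1 ms step)
UPSTROKE_PRE_MS = 5           # window starts 5 ms before the upstroke
UPSTROKE_DVDT_THRESHOLD = 5.0  # mV/ms, upstroke detector


class SimulationError(RuntimeError):
    """Raised when an integration blows up or a cell misbehaves."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class IonicParams:
    """Conductances (mS/uF), reversal potentials (mV) and gate constants.

    Gate steady states are Boltzmann functions 1/(1+exp((half-V)/k))
    (sign of ``k`` sets activation vs. inactivation); time constants are
    either fixed or a Boltzmann blend of two limits.
    """

    phenotype: str  # "immature" | "adult"
    Cm: float = 1.0  # uF/uF (currents are given per capacitance)

    # maximal conductances, mS/uF
    G_Na: float = 0.0
    G_CaL: float = 0.0
    G_Kr: float = 0.0
    G_Ks: float = 0.0
    G_to: float = 0.0
    G_K1: float = 0.0
    G_f: float = 0.0
    G_bg: float = 0.0  # linear background (pump/exchanger lump)

    # reversal potentials, mV
    E_Na: float = 65.0
    E_Ca: float = 60.0
    E_K: float = -91.0
    E_f: float = -22.0
    E_bg: float = -10.0

    # gate constants: (half, slope) pairs in mV; tau in ms
    m_half: float = -38.0
    m_k: float = 7.0
    tau_m: float = 0.12
    h_half: float = -72.0
    h_k: float = -6.0
    tau_h_lo: float = 9.0      # tau at hyperpolarized V
    tau_h_hi: float = 0.35     # tau at depolarized V
    d_half: float = -12.0
    d_k: float = 6.5
    tau_d: float = 1.8
    f_half: float = -26.0
    f_k: float = -6.5
    tau_f_lo: float = 35.0
    tau_f_hi: float = 110.0    # tau in the plateau range
    xr_half: float = -16.0
    xr_k: float = 7.5
    tau_xr: float = 320.0        # activation tau (depolarized)
    tau_xr_deact: float = 60.0   # deactivation tau (diastolic V)
    rkr_half: float = -8.0     # instantaneous I_Kr rectification
    rkr_k: float = -22.0
    xs_half: float = 2.0
    xs_k: float = 13.0
    tau_xs: float = 500.0        # activation tau (depolarized)
    tau_xs_deact: float = 80.0   # deactivation tau (diastolic V)
    rto_half: float = 5.0      # instantaneous I_to activation
    rto_k: float = 9.0
    s_half: float = -38.0
    s_k: float = -6.0
    tau_s: float = 25.0
    k1_half: float = -72.0     # instantaneous I_K1 gating
    k1_k: float = -9.0
    y_half: float = -78.0      # funny-current activation
    y_k: float = -7.0
    tau_y: float = 1100.0

    def __post_init__(self) -> None:
        for name in ("G_Na", "G_CaL", "G_Kr", "G_Ks", "G_to", "G_K1", "G_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.phenotype not in ("immature", "adult"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.Cm <= 0:
            raise ValueError("Cm must be > 0")

    def copy(self) -> "IonicParams":
        return replace(self)


@dataclass
class DrugSpec:
    """I_Kr drug condition.

    mode "none": drug-free.  mode "simple_block": G_Kr scaled by
    (1 - block_fraction), constant in time.  mode "state_dependent":
    open-channel binding at ``concentration`` ng/mL with rates ``k_on``
    (per ng/mL per ms) and ``k_off`` (per ms).
    """

    mode: str = "none"  # none | simple_block | state_dependent
    block_fraction: float = 0.0
    concentration: float = 0.0  # ng/mL
    k_on: float = 0.0           # 1/(ng/mL)/ms
    k_off: float = 0.0          # 1/ms

    def __post_init__(self) -> None:
        if self.mode not in ("none", "simple_block", "state_dependent"):
            raise ValueError(f"unknown drug mode {self.mode!r}")
        if self.mode == "simple_block" and not 0.0 <= self.block_fraction <= 0.5:
            raise ValueError("block_fraction must lie in [0, 0.5]")
        if self.mode == "state_dependent":
            if self.concentration < 0 or self.k_on < 0 or self.k_off < 0:
                raise ValueError("rates and concentration must be >= 0")

    @property
    def is_drugged(self) -> bool:
        return self.mode != "none"


# default state-dependent condition: 2.72 ng/mL of a potent hERG blocker.
# With the surrogate's open-probability duty cycle (~10-20 % of a beat),
# these rates accumulate use-dependent block across beats to an effective
# beat-averaged I_Kr reduction of roughly 20-30 %, i.e. an APD prolongation
# intermediate within the 1-50 % simple-block sweep.
DOFETILIDE_LIKE = DrugSpec(
    mode="state_dependent", concentration=2.72, k_on=2.0e-3, k_off=1.0e-3
)


@dataclass
class PacingProtocol:
    """Stimulation and recording schedule.

    For the spontaneously beating immature phenotype set
    ``stim_amplitude = 0``; ``cycle_length_ms`` then only sets the nominal
    duration of the conditioning / noisy recording segments.
    """

    stim_amplitude: float = 40.0  # uA/uF, depolarizing
    stim_duration_ms: float = 2.0
    cycle_length_ms: float = 982.0
    conditioning_beats: int = 12
    noisy_beats: int = 100

    def __post_init__(self) -> None:
        if self.noisy_beats < 1:
            raise ValueError("noisy_beats must be >= 1")
        if self.cycle_length_ms <= 0:
            raise ValueError("cycle_length_ms must be > 0")


@dataclass
class NoiseSpec:
    """Stochastic noise current: amplitude xi, time step and seed."""

    xi: float = 0.3
    dt: float = 1.0  # ms, step at which the update formula is quoted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class APTrace:
    """A voltage time series at a fixed sampling step with provenance."""

    voltage: np.ndarray          # mV
    dt_out: float = 1.0          # ms
    phenotype: str = ""
    drug: DrugSpec = field(default_factory=DrugSpec)
    cycle_length_ms: float = float("nan")
    seed: int = -1
    current: Optional[np.ndarray] = None  # total ionic current, uA/uF

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("APTrace voltage contains non-finite values")

    def __len__(self) -> int:
        return len(self.voltage)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.voltage)) * self.dt_out

    def is_valid_ap(self) -> bool:
        return bool(self.voltage.min() < -40.0 and self.voltage.max() > 0.0)


# ---------------------------------------------------------------------------
# packaged default parameter sets (calibrated once to the morphology contract)
# ---------------------------------------------------------------------------

def immature_params() -> IonicParams:
    """Spontaneously beating immature (iPSC-CM-like) cell.

    Calibrated to: spontaneous cycle length ~920-980 ms drug-free, MDP in
    [-80, -70] mV, slow upstroke (~10 mV/ms on the 1-ms grid), APD90
    ~320 ms, and a monotone APD/cycle-length prolongation under I_Kr
    block (with an all-or-none repolarization transition near 12 % block,
    a known behavior of cells with low repolarization reserve).
    """
    return IonicParams(
        phenotype="immature",
        G_Na=6.0,
        G_CaL=0.15,
        G_Kr=0.07,
        G_Ks=0.05,
        G_to=0.03,
        G_K1=0.26,
        G_f=0.008,
        G_bg=0.007,
        E_K=-86.0,
        E_bg=-30.0,
        m_half=-42.0,
        m_k=6.0,
        h_half=-66.0,
        h_k=-5.0,
        tau_h_lo=10.0,
        tau_h_hi=1.2,
        d_half=-20.0,
        d_k=5.0,
        tau_d=1.0,
        tau_f_lo=40.0,
        tau_f_hi=672.0,
        tau_xr=600.0,
        tau_xr_deact=25.0,
        tau_xs=840.0,
        tau_xs_deact=40.0,
        k1_half=-87.0,
        k1_k=-7.0,
        y_half=-75.0,
        y_k=-6.0,
        tau_y=900.0,
    )


def adult_params() -> IonicParams:
    """Quiescent adult ventricular cell (paced).

    Calibrated to: resting potential ~-91 mV, fast upstroke (>100 mV/ms),
    APD90 ~210 ms at a 982-ms cycle length with graded monotone
    prolongation under I_Kr block (to ~250 ms at 50 % block).
    """
    return IonicParams(
        phenotype="adult",
        G_Na=13.0,
        G_CaL=0.17,
        G_Kr=0.07,
        G_Ks=0.02,
        G_to=0.06,
        G_K1=0.65,
        G_f=0.0,
        m_half=-42.0,
        m_k=6.0,
        h_half=-66.0,
        h_k=-5.0,
        tau_h_lo=10.0,
        tau_h_hi=1.2,
        d_half=-20.0,
        d_k=5.0,
        tau_d=1.0,
        tau_f_lo=40.0,
        tau_f_hi=320.0,
        tau_xr=400.0,
        tau_xr_deact=25.0,
        tau_xs=700.0,
        tau_xs_deact=40.0,
        k1_half=-72.0,
        k1_k=-9.0,
    )


# ---------------------------------------------------------------------------
# elementary operations (exposed for direct use and testing)
# ---------------------------------------------------------------------------

def euler_noise_step(
    V_t: float, I_total: float, spec: NoiseSpec, n: float, Cm: float = 1.0
) -> float:
    """One Forward-Euler voltage update with additive Gaussian noise.

    Returns ``V_t - I(V_t)*dt/Cm + xi*n*sqrt(dt)`` where ``n`` is a
    standard-normal draw supplied by the caller's seeded RNG.
    """
    if not np.all(np.isfinite(V_t)):
        raise SimulationError(f"non-finite membrane voltage V_t = {V_t!r}")
    if not np.all(np.isfinite(I_total)):
        raise SimulationError(f"non-finite total current I_total = {I_total!r}")
    return V_t - I_total * spec.dt / Cm + spec.xi * n * math.sqrt(spec.dt)


def apply_simple_block(params: IonicParams, block_fraction: float) -> IonicParams:
    """Scale G_Kr by (1 - block_fraction); all other parameters untouched.

    A 1-50 % block sweep corresponds to G_Kr scale factors 0.99 down to
    0.50 in 0.01 decrements.
    """
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError(f"block_fraction {block_fraction} outside [0, 1]")
    out = params.copy()
    out.G_Kr = params.G_Kr * (1.0 - block_fraction)
    return out


def state_dependent_gkr_factor(
    open_probability: float,
    bound_fraction_prev: float,
    drug: DrugSpec,
    dt: float,
) -> tuple[float, float]:
    """One Forward-Euler step of the open-channel-block binding scheme.

    db/dt = k_on*[D]*p_open*(1-b) - k_off*b; the effective G_Kr multiplier
    is 1-b.  Returns (multiplier, next bound fraction).
    """
    if drug.mode != "state_dependent":
        raise ValueError("drug.mode must be 'state_dependent'")
    if not 0.0 <= open_probability <= 1.0:
        raise ValueError("open_probability outside [0, 1]")
    if not 0.0 <= bound_fraction_prev <= 1.0:
        raise ValueError("bound_fraction_prev outside [0, 1]")
    b = bound_fraction_prev
    db = drug.k_on * drug.concentration * open_probability * (1.0 - b) - drug.k_off * b
    b_next = min(max(b + dt * db, 0.0), 1.0)
    return 1.0 - b_next, b_next


# ---------------------------------------------------------------------------
# lookup tables and the numba kernel
# ---------------------------------------------------------------------------

_V_MIN, _V_MAX, _V_STEP = -150.0, 100.0, 0.05
_NGRID = int(round((_V_MAX - _V_MIN) / _V_STEP)) + 1

# table rows: inf/a pairs for the 8 ODE gates (a = dt/tau), then the two
# instantaneous gates
_GATES = ("m", "h", "d", "f", "xr", "xs", "s", "y")
_ROW_RKR = 16
_ROW_RTO = 17
_ROW_K1 = 18
_NROWS = 19


def _boltz(v: np.ndarray, half: float, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((half - v) / k))


def build_tables(p: IonicParams, dt: float) -> np.ndarray:
    """Precompute gate steady states and dt/tau on a voltage grid."""
    v = _V_MIN + _V_STEP * np.arange(_NGRID)
    t = np.empty((_NROWS, _NGRID))
    t[0] = _boltz(v, p.m_half, p.m_k)
    t[1] = dt / p.tau_m
    t[2] = _boltz(v, p.h_half, p.h_k)
    # tau_h: long at rest (recovery), shorter when depolarized (inactivation)
    w = _boltz(v, -45.0, 5.0)
    t[3] = dt / (p.tau_h_lo + w * (p.tau_h_hi - p.tau_h_lo))
    t[4] = _boltz(v, p.d_half, p.d_k)
    t[5] = dt / p.tau_d
    t[6] = _boltz(v, p.f_half, p.f_k)
    # tau_f: slow in the plateau voltage range, faster elsewhere
    bump = np.exp(-(((v + 15.0) / 22.0) ** 2))
    t[7] = dt / (p.tau_f_lo + bump * (p.tau_f_hi - p.tau_f_lo))
    t[8] = _boltz(v, p.xr_half, p.xr_k)
    wk = _boltz(v, -60.0, 6.0)  # 0 at diastolic V, 1 when depolarized
    t[9] = dt / (p.tau_xr_deact + wk * (p.tau_xr - p.tau_xr_deact))
    t[10] = _boltz(v, p.xs_half, p.xs_k)
    t[11] = dt / (p.tau_xs_deact + wk * (p.tau_xs - p.tau_xs_deact))
    t[12] = _boltz(v, p.s_half, p.s_k)
    t[13] = dt / p.tau_s
    t[14] = _boltz(v, p.y_half, p.y_k)
    t[15] = dt / p.tau_y
    t[_ROW_RKR] = _boltz(v, p.rkr_half, p.rkr_k)
    t[_ROW_RTO] = _boltz(v, p.rto_half, p.rto_k)
    t[_ROW_K1] = _boltz(v, p.k1_half, p.k1_k)
    return np.ascontiguousarray(t.T)


@njit(cache=True, fastmath=True)
def _kernel(
    V0, gates, b0, tables, cond, dt, n_steps,
    stim_amp, stim_dur_steps, cl_steps,
    drug_mode, kon_d, koff,
    noise, record_every, V_out, I_out, record_current,
):
    """Forward-Euler integration loop.

    cond = (G_Na, G_CaL, G_Kr, G_Ks, G_to, G_K1, G_f, E_Na, E_Ca, E_K,
    E_f, Cm, G_bg, E_bg).  Returns (status, final V, final b); status 0 = ok,
    1 = voltage blow-up (final V then holds the step index as a float).
    Records V (and optionally total ionic current) every ``record_every``
    steps, sampling *before* the step so V_out[0] is the initial state.
    """
    G_Na, G_CaL, G_Kr, G_Ks, G_to, G_K1, G_f = cond[0], cond[1], cond[2], cond[3], cond[4], cond[5], cond[6]
    E_Na, E_Ca, E_K, E_f, Cm = cond[7], cond[8], cond[9], cond[10], cond[11]
    G_bg, E_bg = cond[12], cond[13]
    inv_step = 1.0 / _V_STEP
    V = V0
    b = b0
    m, h, d, f, xr, xs, s, y = (
        gates[0], gates[1], gates[2], gates[3],
        gates[4], gates[5], gates[6], gates[7],
    )
    has_noise = noise.shape[0] > 0
    n_rec = V_out.shape[0]
    rec_count = 0
    rec_idx = 0
    cl_count = 0
    for step in range(n_steps):
        # table lookup with linear interpolation
        u = (V - _V_MIN) * inv_step
        if u < 0.0:
            u = 0.0
        elif u > _NGRID - 2:
            u = float(_NGRID - 2)
        i = int(u)
        w = u - i
        m_inf = tables[i, 0] + w * (tables[i + 1, 0] - tables[i, 0])
        a_m = tables[i, 1] + w * (tables[i + 1, 1] - tables[i, 1])
        h_inf = tables[i, 2] + w * (tables[i + 1, 2] - tables[i, 2])
        a_h = tables[i, 3] + w * (tables[i + 1, 3] - tables[i, 3])
        d_inf = tables[i, 4] + w * (tables[i + 1, 4] - tables[i, 4])
        a_d = tables[i, 5] + w * (tables[i + 1, 5] - tables[i, 5])
        f_inf = tables[i, 6] + w * (tables[i + 1, 6] - tables[i, 6])
        a_f = tables[i, 7] + w * (tables[i + 1, 7] - tables[i, 7])
        xr_inf = tables[i, 8] + w * (tables[i + 1, 8] - tables[i, 8])
        a_xr = tables[i, 9] + w * (tables[i + 1, 9] - tables[i, 9])
        xs_inf = tables[i, 10] + w * (tables[i + 1, 10] - tables[i, 10])
        a_xs = tables[i, 11] + w * (tables[i + 1, 11] - tables[i, 11])
        s_inf = tables[i, 12] + w * (tables[i + 1, 12] - tables[i, 12])
        a_s = tables[i, 13] + w * (tables[i + 1, 13] - tables[i, 13])
        y_inf = tables[i, 14] + w * (tables[i + 1, 14] - tables[i, 14])
        a_y = tables[i, 15] + w * (tables[i + 1, 15] - tables[i, 15])
        rkr = tables[i, _ROW_RKR] + w * (tables[i + 1, _ROW_RKR] - tables[i, _ROW_RKR])
        rto = tables[i, _ROW_RTO] + w * (tables[i + 1, _ROW_RTO] - tables[i, _ROW_RTO])
        k1 = tables[i, _ROW_K1] + w * (tables[i + 1, _ROW_K1] - tables[i, _ROW_K1])

        gkr_mult = 1.0
        if drug_mode == 2:
            p_open = xr * rkr
            b += dt * (kon_d * p_open * (1.0 - b) - koff * b)
            if b < 0.0:
                b = 0.0
            elif b > 1.0:
                b = 1.0
            gkr_mult = 1.0 - b

        I_Na = G_Na * m * m * m * h * (V - E_Na)
        I_CaL = G_CaL * d * f * (V - E_Ca)
        I_Kr = G_Kr * gkr_mult * xr * rkr * (V - E_K)
        I_Ks = G_Ks * xs * (V - E_K)
        I_to = G_to * rto * s * (V - E_K)
        I_K1 = G_K1 * k1 * (V - E_K)
        I_f = G_f * y * (V - E_f)
        I_bg = G_bg * (V - E_bg)
        I_ion = I_Na + I_CaL + I_Kr + I_Ks + I_to + I_K1 + I_f + I_bg

        if record_every > 0:
            if rec_count == 0 and rec_idx < n_rec:
                V_out[rec_idx] = V
                if record_current:
                    I_out[rec_idx] = I_ion
            rec_count += 1
            if rec_count == record_every:
                rec_count = 0
                rec_idx += 1

        I_stim = 0.0
        if stim_amp != 0.0 and cl_steps > 0:
            if cl_count < stim_dur_steps:
                I_stim = stim_amp
        cl_count += 1
        if cl_count == cl_steps:
            cl_count = 0

        V = V + dt * (-(I_ion) + I_stim) / Cm
        if has_noise:
            V += noise[step]
        if V > 200.0 or V < -200.0 or V != V:
            return 1, float(step), b

        m += a_m * (m_inf - m)
        h += a_h * (h_inf - h)
        d += a_d * (d_inf - d)
        f += a_f * (f_inf - f)
        xr += a_xr * (xr_inf - xr)
        xs += a_xs * (xs_inf - xs)
        s += a_s * (s_inf - s)
        y += a_y * (y_inf - y)

    gates[0], gates[1], gates[2], gates[3] = m, h, d, f
    gates[4], gates[5], gates[6], gates[7] = xr, xs, s, y
    return 0, V, b


def _cond_vector(p: IonicParams) -> np.ndarray:
    return np.array(
        [p.G_Na, p.G_CaL, p.G_Kr, p.G_Ks, p.G_to, p.G_K1, p.G_f,
         p.E_Na, p.E_Ca, p.E_K, p.E_f, p.Cm, p.G_bg, p.E_bg]
    )


def _initial_state(p: IonicParams) -> tuple[float, np.ndarray]:
    V0 = -76.0 if p.phenotype == "immature" else -88.0
    tables = build_tables(p, 1.0)  # dt irrelevant for inf rows
    u = (V0 - _V_MIN) / _V_STEP
    i = int(u)
    w = u - i
    gates = np.empty(8)
    for g, row in enumerate((0, 2, 4, 6, 8, 10, 12, 14)):
        gates[g] = tables[i, row] + w * (tables[i + 1, row] - tables[i, row])
    return V0, gates


# cache of post-conditioning states keyed by the full condition
_COND_CACHE: dict = {}


def _conditioning_key(p: IonicParams, drug: DrugSpec, protocol: PacingProtocol, dt: float):
    return (
        tuple(sorted(vars(p).items())),
        (drug.mode, drug.block_fraction, drug.concentration, drug.k_on, drug.k_off),
        (protocol.stim_amplitude, protocol.stim_duration_ms,
         round(protocol.cycle_length_ms, 6), protocol.conditioning_beats),
        dt,
    )


def clear_conditioning_cache() -> None:
    _COND_CACHE.clear()


def simulate_trace(
    params: IonicParams,
    protocol: PacingProtocol,
    drug: DrugSpec = DrugSpec(),
    noise: NoiseSpec = NoiseSpec(xi=0.0),
    seed: Optional[int] = None,
    dt_internal: float = 0.01,
    dt_out: float = 1.0,
    record_current: bool = False,
) -> APTrace:
    """Run conditioning then noisy beats; return the full noisy-phase trace.

    The returned trace spans ``noisy_beats * cycle_length_ms`` at ``dt_out``
    resolution.  Deterministic given ``seed`` (which overrides
    ``noise.seed`` when provided).
    """
    if dt_internal <= 0 or dt_internal > 0.01 + 1e-12:
        raise ValueError("internal step must be in (0, 0.01] ms")
    p = params
    if drug.mode == "simple_block":
        p = apply_simple_block(params, drug.block_fraction)
    drug_mode = {"none": 0, "simple_block": 1, "state_dependent": 2}[drug.mode]
    kon_d = drug.k_on * drug.concentration if drug_mode == 2 else 0.0
    koff = drug.k_off if drug_mode == 2 else 0.0

    tables = build_tables(p, dt_internal)
    cond = _cond_vector(p)
    cl_steps = int(round(protocol.cycle_length_ms / dt_internal))
    stim_steps = int(round(protocol.stim_duration_ms / dt_internal))
    stim_amp = protocol.stim_amplitude if p.phenotype == "adult" else 0.0
    if p.phenotype == "adult" and protocol.stim_amplitude == 0.0:
        stim_amp = 0.0  # explicitly quiescent run

    # conditioning (noise-free), cached per condition
    key = _conditioning_key(p, drug, protocol, dt_internal)
    if key in _COND_CACHE:
        V, gates, b = _COND_CACHE[key]
        gates = gates.copy()
    else:
        V, gates = _initial_state(p)
        b = 0.0
        n_cond = protocol.conditioning_beats * cl_steps
        empty = np.empty(0)
        dummy = np.empty(0)
        status, V, b = _kernel(
            V, gates, b, tables, cond, dt_internal, n_cond,
            stim_amp, stim_steps, cl_steps, drug_mode, kon_d, koff,
            empty, 0, dummy, dummy, False,
        )
        if status != 0:
            raise SimulationError(
                f"voltage blow-up during conditioning beat "
                f"{int(V * dt_internal / protocol.cycle_length_ms)}"
            )
        _COND_CACHE[key] = (V, gates.copy(), b)

    # noisy phase
    n_steps = protocol.noisy_beats * cl_steps
    record_every = int(round(dt_out / dt_internal))
    n_rec = n_steps // record_every
    V_out = np.empty(n_rec)
    I_out = np.empty(n_rec if record_current else 0)
    use_seed = noise.seed if seed is None else seed
    if noise.xi > 0:
        rng = np.random.default_rng(use_seed)
        scale = noise.xi * math.sqrt(dt_internal)
        noise_arr = rng.standard_normal(n_steps) * scale
    else:
        noise_arr = np.empty(0)
    status, V, b = _kernel(
        V, gates, b, tables, cond, dt_internal, n_steps,
        stim_amp, stim_steps, cl_steps, drug_mode, kon_d, koff,
        noise_arr, record_every, V_out, I_out, record_current,
    )
    if status != 0:
        beat = int(V * dt_internal / protocol.cycle_length_ms)
        raise SimulationError(f"voltage blow-up during noisy beat {beat}")
    return APTrace(
        voltage=V_out,
        dt_out=dt_out,
        phenotype=p.phenotype,
        drug=drug,
        cycle_length_ms=protocol.cycle_length_ms,
        seed=use_seed,
        current=I_out if record_current else None,
    )


def detect_upstrokes(
    voltage: np.ndarray,
    dt: float = 1.0,
    threshold: float = UPSTROKE_DVDT_THRESHOLD,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Indices of upstrokes: local maxima of dV/dt above ``threshold``.

    Crossings closer than ``refractory_ms`` to the previous upstroke are
    ignored; within each suprathreshold run the earliest sample attaining
    the maximum dV/dt is the marker.
    """
    v = np.asarray(voltage, dtype=float)
    dvdt = np.diff(v) / dt
    above = dvdt > threshold
    ups = []
    i = 0
    n = len(dvdt)
    refr = int(round(refractory_ms / dt))
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            seg = dvdt[i:j]
            marker = i + int(np.argmax(seg))
            if not ups or marker - ups[-1] >= refr:
                ups.append(marker)
            i = j
        else:
            i += 1
    return np.asarray(ups, dtype=int)


def detect_cycle_length(trace: APTrace) -> float:
    """Interval (ms) between the last two upstrokes of the trace."""
    ups = detect_upstrokes(trace.voltage, trace.dt_out)
    if len(ups) < 2:
        raise SimulationError(
            f"need >= 2 upstrokes to measure a cycle length, found {len(ups)}"
        )
    return float((ups[-1] - ups[-2]) * trace.dt_out)


def _crop_window(
    trace: APTrace, n_samples: int = NETWORK_WINDOW, pre_ms: float = UPSTROKE_PRE_MS
) -> tuple[np.ndarray, Optional[np.ndarray], float]:
    """Final complete beat window: ``pre_ms`` before the last usable upstroke.

    Returns (voltage window, current window or None, detected cycle length).
    """
    ups = detect_upstrokes(trace.voltage, trace.dt_out)
    if len(ups) < 2:
        raise SimulationError("trace has fewer than two upstrokes")
    pre = int(round(pre_ms / trace.dt_out))
    tail = n_samples - pre
    usable = [u for u in ups if u + tail <= len(trace.voltage) and u - pre >= 0]
    if not usable:
        raise SimulationError("no upstroke leaves room for a full window")
    u_last = usable[-1]
    prev = [u for u in ups if u < u_last]
    if not prev:
        raise SimulationError("no preceding upstroke to measure cycle length")
    cl = float((u_last - prev[-1]) * trace.dt_out)
    sl = slice(u_last - pre, u_last - pre + n_samples)
    cur = trace.current[sl] if trace.current is not None else None
    return trace.voltage[sl].copy(), None if cur is None else cur.copy(), cl


def simulate_ap(
    params: IonicParams,
    protocol: PacingProtocol,
    drug: DrugSpec = DrugSpec(),
    noise: NoiseSpec = NoiseSpec(xi=0.0),
    seed: Optional[int] = None,
    dt_internal: float = 0.01,
    record_current: bool = False,
) -> APTrace:
    """Simulate and return the final beat's 701-sample AP window.

    The window starts 5 ms before the last complete beat's upstroke; the
    trace metadata carries the *detected* last-beat cycle length (interval
    between the last two upstrokes), which for a spontaneous immature cell
    varies with the noise realization.
    """
    full = simulate_trace(
        params, protocol, drug, noise, seed=seed,
        dt_internal=dt_internal, record_current=record_current,
    )
    if params.phenotype == "immature":
        ups = detect_upstrokes(full.voltage, full.dt_out)
        if len(ups) < 2:
            raise SimulationError(
                "immature cell failed to beat spontaneously "
                f"(seed {full.seed}, {len(ups)} upstrokes detected)"
            )
    v, cur, cl = _crop_window(full)
    return APTrace(
        voltage=v,
        dt_out=full.dt_out,
        phenotype=full.phenotype,
        drug=full.drug,
        cycle_length_ms=cl,
        seed=full.seed,
        current=cur,
    )


def membrane_resistance_series(
    voltage: np.ndarray,
    total_current: np.ndarray,
    dt: float = 1.0,
    cap: float = 1.0e4,
    di_tolerance: float = 1.0e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise membrane resistance (dV/dt)/(dI/dt) via central differences.

    Where |dI| falls below ``di_tolerance`` the magnitude is capped at
    ``cap`` (the divergence dI -> 0, dV/dI -> inf made finite); the second
    return value flags capped samples.  Units are mV per (uA/uF), i.e.
    resistance normalized by membrane capacitance.
    """
    v = np.asarray(voltage, dtype=float)
    cur = np.asarray(total_current, dtype=float)
    if v.shape != cur.shape:
        raise ValueError(
            f"voltage and current lengths differ: {v.shape} vs {cur.shape}"
        )
    dv = np.gradient(v, dt)
    di = np.gradient(cur, dt)
    small = np.abs(di) < di_tolerance
    r = np.empty_like(dv)
    safe = ~small
    r[safe] = dv[safe] / di[safe]
    r[small] = np.sign(dv[small]) * cap
    r[small & (dv == 0)] = cap
    np.clip(r, -cap, cap, out=r)
    return r, small
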
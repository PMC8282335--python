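"""Population generation, immature-to-adult pairing at matched cycle
lengths, labeling, and the train/validation/test split.

A paired sample couples one immature AP window (the network input), the
adult AP window simulated at the *same* cycle length (the regression
target), and a binary drug label (0 = drug-free, 1 = drugged).  The
default design is a population of 208 drug-free pairs, 250
simple-block pairs (a 1-50 % I_Kr block sweep in 1 % steps with five
noise-seeded beating rates per level), and 300 state-dependent-block
pairs, 758 in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import simulator as sim
from .simulator import (
    APTrace,
    DrugSpec,
    DOFETILIDE_LIKE,
    IonicParams,
    NoiseSpec,
    PacingProtocol,
    SimulationError,
)

__all__ = [
    "PairedSample",
    "DatasetSplit",
    "PopulationConfig",
    "enumerate_conditions",
    "build_population",
    "split_dataset",
]


@dataclass
class PairedSample:
    """(immature input, adult target, drug label) at a matched cycle length."""

    input_trace: APTrace      # immature, 701 samples
    target_trace: APTrace     # adult, 701 samples
    label: int                # 0 drug-free, 1 drugged
    condition: str            # drug_free | simple_block | state_dependent
    cycle_length_ms: float
    block_fraction: float = 0.0
    seed: int = -1

    def __post_init__(self) -> None:
        if len(self.input_trace) != len(self.target_trace):
            raise ValueError("input and target traces must have equal length")
        if self.input_trace.dt_out != self.target_trace.dt_out:
            raise ValueError("input and target sampling steps differ")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if (self.condition == "drug_free") != (self.label == 0):
            raise ValueError("condition tag inconsistent with label")


@dataclass
class DatasetSplit:
    training: list
    validation: list
    test: list
    seed: int = 0
    ratios: tuple = (0.7, 0.1, 0.2)

    def counts_by_condition(self) -> dict:
        out = {}
        for name, part in (("training", self.training),
                           ("validation", self.validation),
                           ("test", self.test)):
            c: dict = {}
            for s in part:
                c[s.condition] = c.get(s.condition, 0) + 1
            out[name] = c
        return out

    def __iter__(self):
        return iter((self.training, self.validation, self.test))


@dataclass
class PopulationConfig:
    """Study-design knobs for :func:`build_population`.

    Defaults reproduce the full population: 208 drug-free samples, a
    1-50 % block sweep in 1 % increments with 5 rates (noise seeds) per
    level (250 samples), and 300 state-dependent samples.
    """

    n_drug_free: int = 208
    block_min: float = 0.01
    block_max: float = 0.50
    block_step: float = 0.01
    rates_per_level: int = 5
    n_state_dependent: int = 300
    state_drug: DrugSpec = field(default_factory=lambda: DOFETILIDE_LIKE)
    noise_xi: float = 0.3
    noisy_beats: int = 100
    conditioning_beats: int = 12
    window: int = sim.NETWORK_WINDOW

    def block_levels(self) -> list[float]:
        n = int(round((self.block_max - self.block_min) / self.block_step)) + 1
        return [round(self.block_min + i * self.block_step, 10) for i in range(n)]

    @property
    def n_simple_block(self) -> int:
        return len(self.block_levels()) * self.rates_per_level

    @property
    def total(self) -> int:
        return self.n_drug_free + self.n_simple_block + self.n_state_dependent


def enumerate_conditions(config: PopulationConfig, seed: int) -> list[dict]:
    """Deterministic plan of every sample to simulate.

    Per-sample RNG seeds are drawn from a generator seeded with the master
    seed, so the plan (and hence the population) is reproducible.
    """
    rng = np.random.default_rng(seed)
    plan: list[dict] = []
    for i in range(config.n_drug_free):
        plan.append({
            "condition": "drug_free", "label": 0, "block_fraction": 0.0,
            "seed": int(rng.integers(0, 2**31 - 1)),
        })
    for level in config.block_levels():
        for _ in range(config.rates_per_level):
            plan.append({
                "condition": "simple_block", "label": 1,
                "block_fraction": float(level),
                "seed": int(rng.integers(0, 2**31 - 1)),
            })
    for i in range(config.n_state_dependent):
        plan.append({
            "condition": "state_dependent", "label": 1, "block_fraction": 0.0,
            "seed": int(rng.integers(0, 2**31 - 1)),
        })
    return plan


def _drug_for(entry: dict, config: PopulationConfig) -> DrugSpec:
    if entry["condition"] == "drug_free":
        return DrugSpec()
    if entry["condition"] == "simple_block":
        return DrugSpec(mode="simple_block", block_fraction=entry["block_fraction"])
    return config.state_drug


def build_pair(
    entry: dict,
    config: PopulationConfig,
    immature: Optional[IonicParams] = None,
    adult: Optional[IonicParams] = None,
) -> PairedSample:
    """Simulate one immature trace and its adult partner at the matched
    last-beat cycle length."""
    imm = immature if immature is not None else sim.immature_params()
    ad = adult if adult is not None else sim.adult_params()
    drug = _drug_for(entry, config)
    noise = NoiseSpec(xi=config.noise_xi)
    prot_imm = PacingProtocol(
        stim_amplitude=0.0,
        cycle_length_ms=982.0,
        conditioning_beats=config.conditioning_beats,
        noisy_beats=config.noisy_beats,
    )
    try:
        imm_trace = sim.simulate_ap(imm, prot_imm, drug=drug, noise=noise,
                                    seed=entry["seed"])
        cl = imm_trace.cycle_length_ms
        prot_ad = PacingProtocol(
            cycle_length_ms=cl,
            conditioning_beats=config.conditioning_beats,
            noisy_beats=config.noisy_beats,
        )
        # adult partner uses a distinct (derived) noise seed
        ad_trace = sim.simulate_ap(ad, prot_ad, drug=drug, noise=noise,
                                   seed=entry["seed"] + 1)
    except SimulationError as e:
        raise SimulationError(
            f"simulation failed for condition={entry['condition']} "
            f"block={entry['block_fraction']} seed={entry['seed']}: {e}"
        ) from e
    return PairedSample(
        input_trace=imm_trace,
        target_trace=ad_trace,
        label=entry["label"],
        condition=entry["condition"],
        cycle_length_ms=cl,
        block_fraction=entry["block_fraction"],
        seed=entry["seed"],
    )


def build_population(
    config: Optional[PopulationConfig] = None,
    seed: int = 0,
    immature: Optional[IonicParams] = None,
    adult: Optional[IonicParams] = None,
    progress: bool = False,
) -> list[PairedSample]:
    """Simulate the full paired population defined by ``config``."""
    cfg = config if config is not None else PopulationConfig()
    plan = enumerate_conditions(cfg, seed)
    samples = []
    iterator = plan
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(plan, desc="population")
        except ImportError:  # pragma: no cover
            pass
    for entry in iterator:
        samples.append(build_pair(entry, cfg, immature=immature, adult=adult))
    return samples


def _allocate(n: int, ratios: Sequence[float]) -> list[int]:
    """Floor-then-distribute-remainder allocation of n items to ratios."""
    floors = [int(np.floor(n * r)) for r in ratios]
    rem = n - sum(floors)
    # hand remaining items to the largest fractional parts (ties: later
    # split, so leftovers favor the held-out sets)
    fracs = [(n * r) - f for r, f in zip(ratios, floors)]
    order = sorted(range(len(ratios)), key=lambda i: (-fracs[i], -i))
    for i in order[:rem]:
        floors[i] += 1
    return floors


def split_dataset(
    samples: Sequence[PairedSample],
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffled split stratified by condition.

    Within each condition the samples are shuffled with the seeded RNG and
    allocated to training/validation/test by floor-then-remainder counts,
    so each condition's proportion is preserved to within one sample per
    split.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    by_cond: dict[str, list] = {}
    for s in samples:
        by_cond.setdefault(s.condition, []).append(s)
    for cond, group in by_cond.items():
        if not group:
            raise ValueError(f"empty condition class {cond!r}")
    parts: tuple[list, list, list] = ([], [], [])
    for cond in sorted(by_cond):
        group = list(by_cond[cond])
        idx = rng.permutation(len(group))
        counts = _allocate(len(group), ratios)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(group[i] for i in idx[start:start + c])
            start += c
    train, val, test = parts
    return DatasetSplit(training=train, validation=val, test=test,
                        seed=seed, ratios=tuple(ratios))
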
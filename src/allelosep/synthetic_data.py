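"""Generative model for target-neighbor mixed-culture experiments.

Raw per-plant data behind published mixed-culture tables are rarely
available, so this module simulates them from a known truth: each species ×
trait has a monoculture baseline performance, and a neighbor imposes a
fractional competition effect ``c`` (resource-mediated) and an allelopathy
effect ``a`` (chemically mediated).  Expected performances per arm:

===================  =========================  ==========================
arm                  additive model             multiplicative model
===================  =========================  ==========================
monoculture          b                          b
mixed                b·(1 − c − a)              b·(1 − c)·(1 − a)
residual_solution    b·(1 − a)                  b·(1 − a)
===================  =========================  ==========================

The residual-solution arm keeps the chemicals but removes the competitor,
mirroring the nutrient-replenished bioassay; under the additive model the
TB/AE/RC pipeline is exactly identifiable: TB = 100(c + a), AE = 100a,
RC = 100c.  Measurement noise is multiplicative lognormal per plant with a
configurable coefficient of variation (additive Gaussian available);
effects are endpoint multipliers — no growth dynamics are modeled.

Each (species, arm, replicate) gets its own random stream derived from the
master seed by stable hashing, so adding an arm never perturbs the draws of
existing arms.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DesignSpec, EXPERIMENT2_DESIGN, NO_PARTNER, TraitObservation
from .decomposition import decomposition_from_observations

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "config_from_dict",
    "design_from_dict",
    "expected_performance",
    "simulate_competition_experiment",
    "simulate_decomposition_experiment",
    "parameter_recovery_study",
    "default_recovery_config",
    "multiplicative_rc_mismatch",
]


class ConfigError(ValueError):
    """A simulation configuration violates a generative-model invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for a simulated mixed-culture experiment.

    ``baseline`` maps (species, trait) to the expected monoculture
    performance in trait units; ``competition`` and ``allelopathy`` map
    (receiver, donor) to fractional reductions (negative = facilitation);
    pairs absent from either map default to 0.  ``noise_cv`` is the
    per-plant coefficient of variation of the measurement noise.
    """

    baseline: Mapping[tuple[str, str], float]
    competition: Mapping[tuple[str, str], float] = field(default_factory=dict)
    allelopathy: Mapping[tuple[str, str], float] = field(default_factory=dict)
    interference_model: str = "additive"
    noise_model: str = "lognormal"
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interference_model not in ("additive", "multiplicative"):
            raise ConfigError(f"unknown interference_model {self.interference_model!r}")
        if self.noise_model not in ("lognormal", "normal"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.baseline:
            raise ConfigError("baseline map is empty")
        for key, b in self.baseline.items():
            if b <= 0:
                raise ConfigError(f"baseline for {key} must be > 0, got {b}")
        pairs = set(self.competition) | set(self.allelopathy)
        for pair in pairs:
            c = self.competition.get(pair, 0.0)
            a = self.allelopathy.get(pair, 0.0)
            if self.interference_model == "additive":
                if c + a >= 1:
                    raise ConfigError(
                        f"additive model needs c + a < 1 for {pair}, got {c} + {a}"
                    )
            elif c >= 1 or a >= 1:
                raise ConfigError(
                    f"multiplicative model needs c < 1 and a < 1 for {pair}"
                )

    def effects(self, receiver: str, donor: str) -> tuple[float, float]:
        return (
            self.competition.get((receiver, donor), 0.0),
            self.allelopathy.get((receiver, donor), 0.0),
        )


def _nested_to_pairs(nested: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, str], float]:
    return {(outer, inner): float(v)
            for outer, m in nested.items() for inner, v in m.items()}


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a config from the nested-mapping form used in YAML/JSON files.

    Expected keys: ``baseline: {species: {trait: value}}``,
    ``competition`` / ``allelopathy``: ``{receiver: {donor: effect}}``, plus
    the scalar fields of :class:`SimulationConfig`.
    """
    return SimulationConfig(
        baseline=_nested_to_pairs(d["baseline"]),
        competition=_nested_to_pairs(d.get("competition", {})),
        allelopathy=_nested_to_pairs(d.get("allelopathy", {})),
        interference_model=d.get("interference_model", "additive"),
        noise_model=d.get("noise_model", "lognormal"),
        noise_cv=float(d.get("noise_cv", 0.05)),
        n_replicates=int(d.get("n_replicates", 3)),
        seed=int(d.get("seed", 0)),
    )


def design_from_dict(d: Mapping) -> DesignSpec:
    return DesignSpec(
        target_species=d["target_species"],
        neighbor_species=d["neighbor_species"],
        target_count=int(d["target_count"]),
        neighbor_count=int(d["neighbor_count"]),
    )


def expected_performance(
    config: SimulationConfig, species: str, trait: str, arm: str, partner: str
) -> float:
    """Noise-free expected trait value for one arm of the design."""
    b = config.baseline[(species, trait)]
    if arm == "monoculture":
        return b
    c, a = config.effects(species, partner)
    if arm == "mixed":
        if config.interference_model == "additive":
            return b * (1.0 - c - a)
        return b * (1.0 - c) * (1.0 - a)
    if arm == "residual_solution":
        return b * (1.0 - a)
    raise ConfigError(f"unknown arm {arm!r}")


def _stream(config: SimulationConfig, species: str, arm: str, replicate: int) -> np.random.Generator:
    key = zlib.crc32(f"{species}|{arm}|{replicate}".encode())
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _noise_factors(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    cv = config.noise_cv
    if cv == 0:
        return np.ones(n)
    if config.noise_model == "lognormal":
        # unit-mean lognormal with the requested CV
        sigma2 = math.log1p(cv * cv)
        return np.exp(rng.normal(-sigma2 / 2, math.sqrt(sigma2), size=n))
    return np.maximum(rng.normal(1.0, cv, size=n), 0.0)


def _simulate_arm(
    config: SimulationConfig,
    experiment_id: str,
    species: str,
    arm: str,
    partner: str,
    n_plants: int,
    traits: Sequence[str],
) -> list[TraitObservation]:
    out: list[TraitObservation] = []
    for rep in range(1, config.n_replicates + 1):
        rng = _stream(config, species, arm, rep)
        for trait in traits:
            mu = expected_performance(config, species, trait, arm, partner)
            values = mu * _noise_factors(config, rng, n_plants)
            out.extend(
                TraitObservation(
                    experiment_id=experiment_id,
                    species=species,
                    arm=arm,
                    partner_species=partner,
                    replicate_id=f"basin{rep}",
                    plant_id=f"{species}-{arm}-{rep}-{i + 1}",
                    trait=trait,
                    value=float(v),
                )
                for i, v in enumerate(values)
            )
    return out


def _species_traits(config: SimulationConfig, species: str) -> list[str]:
    traits = [t for (s, t) in config.baseline if s == species]
    if not traits:
        raise ConfigError(f"no baseline traits for species {species!r}")
    return traits


def simulate_competition_experiment(
    config: SimulationConfig, design: DesignSpec
) -> list[TraitObservation]:
    """Per-plant data for the competition-intensity experiment.

    Three arms: monoculture of each species (its own plant count) and the
    mixed culture with both species in one basin.  Deterministic given
    ``config.seed``.
    """
    target, neighbor = design.target_species, design.neighbor_species
    obs: list[TraitObservation] = []
    obs += _simulate_arm(config, "exp1", target, "monoculture", NO_PARTNER,
                         design.target_count, _species_traits(config, target))
    obs += _simulate_arm(config, "exp1", target, "mixed", neighbor,
                         design.target_count, _species_traits(config, target))
    if design.neighbor_count > 0:
        obs += _simulate_arm(config, "exp1", neighbor, "monoculture", NO_PARTNER,
                             design.neighbor_count, _species_traits(config, neighbor))
        obs += _simulate_arm(config, "exp1", neighbor, "mixed", target,
                             design.neighbor_count, _species_traits(config, neighbor))
    return obs


def simulate_decomposition_experiment(
    config: SimulationConfig, design: DesignSpec = EXPERIMENT2_DESIGN
) -> list[TraitObservation]:
    """Per-plant data for the two-step TB/AE bioassay.

    The receiver (the design's neighbor species) appears in three arms:
    monoculture control, mixed culture with the donor, and monoculture in
    the donor mixture's residual solution (competition removed, chemicals
    retained).  Donor plants in the mixed arm are also emitted.
    """
    donor, receiver = design.target_species, design.neighbor_species
    obs: list[TraitObservation] = []
    r_traits = _species_traits(config, receiver)
    obs += _simulate_arm(config, "exp2", receiver, "monoculture", NO_PARTNER,
                         design.neighbor_count, r_traits)
    obs += _simulate_arm(config, "exp2", receiver, "mixed", donor,
                         design.neighbor_count, r_traits)
    obs += _simulate_arm(config, "exp2", receiver, "residual_solution", donor,
                         design.neighbor_count, r_traits)
    obs += _simulate_arm(config, "exp2", donor, "mixed", receiver,
                         design.target_count, _species_traits(config, donor))
    return obs


def default_recovery_config(
    c: float = 0.2,
    a: float = 0.3,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    interference_model: str = "additive",
    seed: int = 0,
) -> SimulationConfig:
    """Single-trait donor→receiver configuration used by the recovery study.

    Baselines mimic the hydroponic root-length scale (receiver ≈ 7.3 cm,
    donor ≈ 8.7 cm).
    """
    return SimulationConfig(
        baseline={("BYG", "RL"): 7.32, ("PI", "RL"): 8.73},
        competition={("BYG", "PI"): c},
        allelopathy={("BYG", "PI"): a},
        interference_model=interference_model,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
    )


def _generative_truth(config: SimulationConfig, receiver: str, donor: str) -> dict[str, float]:
    c, a = config.effects(receiver, donor)
    if config.interference_model == "additive":
        tb = 100.0 * (c + a)
    else:
        tb = 100.0 * (1.0 - (1.0 - c) * (1.0 - a))
    ae = 100.0 * a
    return {
        "tb": tb,
        "ae": ae,
        "rc": tb - ae,
        "ae_share": 100.0 * ae / tb if tb != 0 else float("nan"),
    }


def multiplicative_rc_mismatch(c: float, a: float) -> float:
    """Relative RC shortfall when multiplicative data meet the additive split.

    Under the multiplicative model the subtraction RC = TB − AE recovers
    100·c·(1 − a) instead of 100·c; the relative mismatch against the total
    interference is c·a / (c + a − c·a).
    """
    return c * a / (c + a - c * a)


def parameter_recovery_study(
    configs: Sequence[SimulationConfig],
    n_runs: int,
    seed: int = 0,
    design: DesignSpec = EXPERIMENT2_DESIGN,
) -> pd.DataFrame:
    """Simulate → summarize → decompose repeatedly and score recovery.

    For each configuration, runs the full two-step bioassay pipeline
    ``n_runs`` times with independent seeds derived from ``seed``, and
    reports mean, bias and RMSE of recovered TB, AE, RC and AE share
    against the generative truth.  Per-run pipeline failures are counted,
    not fatal.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    donor, receiver = design.target_species, design.neighbor_species
    rows = []
    master = np.random.SeedSequence(seed)
    for cfg_idx, config in enumerate(configs):
        run_seeds = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(cfg_idx,)
        ).generate_state(n_runs) & 0x7FFFFFFF
        truth = _generative_truth(config, receiver, donor)
        recovered: dict[str, list[float]] = {k: [] for k in truth}
        failures = 0
        for run_seed in run_seeds:
            run_cfg = replace(config, seed=int(run_seed))
            try:
                obs = simulate_decomposition_experiment(run_cfg, design)
                table = decomposition_from_observations(obs, receiver_species=receiver)
                # single-trait pipelines yield one row per donor; average if several
                sub = table.to_frame()
                sub = sub[sub["donor"] == donor]
                for key in recovered:
                    recovered[key].append(float(sub[key].mean()))
            except Exception:
                failures += 1
        row: dict[str, object] = {
            "interference_model": config.interference_model,
            "noise_cv": config.noise_cv,
            "n_replicates": config.n_replicates,
            "c": config.effects(receiver, donor)[0],
            "a": config.effects(receiver, donor)[1],
            "n_runs": n_runs,
            "n_failures": failures,
        }
        for key, vals in recovered.items():
            arr = np.asarray(vals)
            row[f"{key}_truth"] = truth[key]
            row[f"{key}_mean"] = float(arr.mean()) if arr.size else float("nan")
            row[f"{key}_bias"] = (
                float(arr.mean() - truth[key]) if arr.size else float("nan")
            )
            row[f"{key}_rmse"] = (
                float(np.sqrt(np.mean((arr - truth[key]) ** 2)))
                if arr.size
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
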
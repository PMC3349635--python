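"""Domain types, tidy-file I/O and packaged reference tables.

The unit of raw data is one measured trait value for one plant
(:class:`TraitObservation`); the unit the interference indices consume is a
group mean ± SE over replicate basins (:class:`GroupSummary`).  Data travel
as tidy UTF-8 CSV with the header::

    experiment_id,species,arm,partner_species,replicate_id,plant_id,trait,value

Arms are ``monoculture`` (plain control), ``mixed`` (focal grown with a
partner species) and ``residual_solution`` (focal grown alone in the
nutrient-replenished medium recovered from a partner's mixed culture).
Traits are ``RL`` (root length, cm), ``PH`` (plant height, cm) and ``DW``
(plant dry weight, g/plant).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "TRAITS",
    "NO_PARTNER",
    "TraitObservation",
    "GroupSummary",
    "DesignSpec",
    "SchemaError",
    "ValidationError",
    "read_observations",
    "write_observations",
    "observations_to_frame",
    "summarize_groups",
    "summaries_to_frame",
    "get_summary",
    "load_paper_fixture",
]

logger = logging.getLogger(__name__)

ARMS = ("monoculture", "mixed", "residual_solution")
TRAITS = {"RL": "root length (cm)", "PH": "plant height (cm)", "DW": "dry weight (g/plant)"}
NO_PARTNER = "none"

CSV_COLUMNS = [
    "experiment_id",
    "species",
    "arm",
    "partner_species",
    "replicate_id",
    "plant_id",
    "trait",
    "value",
]


class SchemaError(ValueError):
    """A tidy file does not match the expected header/schema."""


class ValidationError(ValueError):
    """A row or field violates a domain invariant."""


@dataclass(frozen=True)
class TraitObservation:
    """One measured trait value for one plant in one arm/replicate.

    ``partner_species`` is the other species in the mixture, or the donor of
    the residual solution; ``"none"`` for plain monoculture controls.
    """

    experiment_id: str
    species: str
    arm: str
    partner_species: str
    replicate_id: str
    plant_id: str
    trait: str
    value: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.trait not in TRAITS:
            raise ValidationError(
                f"unknown trait {self.trait!r}; expected one of {sorted(TRAITS)}"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"trait value must be finite and >= 0, got {self.value!r}"
            )
        if self.arm == "monoculture" and self.partner_species != NO_PARTNER:
            raise ValidationError(
                "monoculture observations must have partner_species='none', "
                f"got {self.partner_species!r}"
            )
        if self.arm != "monoculture":
            if self.partner_species == NO_PARTNER:
                raise ValidationError(f"arm {self.arm!r} requires a partner species")
            if self.partner_species == self.species:
                raise ValidationError("partner_species must differ from species")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SE over experimental units for one (species, arm, partner, trait) cell."""

    species: str
    arm: str
    partner_species: str
    trait: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be >= 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.species, self.arm, self.partner_species, self.trait)


@dataclass(frozen=True)
class DesignSpec:
    """Sowing design of a target-neighbor mixed-culture basin.

    Sowing proportions default to ``count / (target_count + neighbor_count)``
    and feed the generalized competitive-ratio correction for unequal
    densities.
    """

    target_species: str
    neighbor_species: str
    target_count: int
    neighbor_count: int
    sown_proportion_target: float | None = None
    sown_proportion_neighbor: float | None = None
    solution_volume_l: float = 10.0
    duration_days: int = 7

    def __post_init__(self) -> None:
        if self.target_count <= 0 or self.neighbor_count < 0:
            raise ValidationError("target_count must be > 0 and neighbor_count >= 0")
        if self.solution_volume_l <= 0 or self.duration_days <= 0:
            raise ValidationError("solution volume and duration must be positive")

    @property
    def proportions(self) -> tuple[float, float]:
        """(z_target, z_neighbor) sowing proportions."""
        if self.sown_proportion_target is not None and self.sown_proportion_neighbor is not None:
            return (self.sown_proportion_target, self.sown_proportion_neighbor)
        total = self.target_count + self.neighbor_count
        if total == 0:
            raise ValidationError("design has no plants")
        return (self.target_count / total, self.neighbor_count / total)


# Experiment 1: 20 target + 20 neighbor seedlings per 10-L basin, 7 days.
EXPERIMENT1_DESIGN = DesignSpec("PI", "BYG", target_count=20, neighbor_count=20)
# Experiment 2: 20 rice (donor) + 10 barnyardgrass (receiver) per basin.
EXPERIMENT2_DESIGN = DesignSpec("PI", "BYG", target_count=20, neighbor_count=10)


def read_observations(path) -> list[TraitObservation]:
    """Read tidy per-plant observations from CSV, validating every row.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (with the 1-based data row number) for a bad
    value; row order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    observations: list[TraitObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            value = float(getattr(row, "value"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: non-numeric value {row.value!r}") from exc
        try:
            observations.append(
                TraitObservation(
                    experiment_id=str(row.experiment_id),
                    species=str(row.species),
                    arm=str(row.arm),
                    partner_species=str(row.partner_species),
                    replicate_id=str(row.replicate_id),
                    plant_id=str(row.plant_id),
                    trait=str(row.trait),
                    value=value,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    logger.info("read %d observations from %s", len(observations), path)
    return observations


def observations_to_frame(observations: Iterable[TraitObservation]) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in observations], columns=CSV_COLUMNS)


def write_observations(observations: Iterable[TraitObservation], path) -> None:
    """Write observations in the tidy CSV schema (inverse of :func:`read_observations`)."""
    observations_to_frame(observations).to_csv(path, index=False)


def summarize_groups(
    observations: Sequence[TraitObservation],
    unit: Literal["basin_mean", "plant"] = "basin_mean",
) -> list[GroupSummary]:
    """Collapse per-plant observations to mean ± SE per (species, arm, partner, trait).

    With ``unit="basin_mean"`` (default) plants are first averaged within each
    replicate basin and the SE is taken over basin means (basins are the
    randomized units, typically n = 3).  With ``unit="plant"`` every plant is
    an experimental unit.  A cell with a single unit gets se = 0 and a warning.
    """
    if unit not in ("basin_mean", "plant"):
        raise ValueError(f"unknown unit {unit!r}")
    df = observations_to_frame(observations)
    if df.empty:
        warnings.warn("no observations to summarize", stacklevel=2)
        return []
    keys = ["species", "arm", "partner_species", "trait"]
    if unit == "basin_mean":
        units = df.groupby(keys + ["replicate_id"], sort=False)["value"].mean().reset_index()
    else:
        units = df
    out: list[GroupSummary] = []
    for key, grp in units.groupby(keys, sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        if n == 1:
            warnings.warn(
                f"cell {key} has a single experimental unit; se reported as 0",
                stacklevel=2,
            )
            se = 0.0
        else:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
        out.append(GroupSummary(*key, mean=float(np.mean(vals)), se=se, n=n))
    return out


def summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(s) for s in summaries],
        columns=["species", "arm", "partner_species", "trait", "mean", "se", "n"],
    )


def get_summary(
    summaries: Iterable[GroupSummary],
    species: str,
    arm: str,
    partner_species: str,
    trait: str,
) -> GroupSummary:
    """Look up one summary cell; KeyError names the missing (species, arm, partner, trait)."""
    for s in summaries:
        if s.key == (species, arm, partner_species, trait):
            return s
    raise KeyError(f"no summary for species={species} arm={arm} partner={partner_species} trait={trait}")


_FIXTURES = {
    "table1_means": "table1_means.csv",
    "table3_ir": "table3_ir.csv",
    "table2_printed": "table2_printed.csv",
}


def _fixture_path(filename: str):
    return resources.files("allelosep.fixtures").joinpath(filename)


def load_paper_fixture(name: str):
    """Load a packaged reference table.

    ``table1_means`` returns the mixed-culture group means ± SE as a list of
    :class:`GroupSummary` (the inputs of the competition indices);
    ``table3_ir`` returns a DataFrame of total-biointerference and
    allelopathic-effect inhibitory rates per donor × trait;
    ``table2_printed`` returns the published competition-index values (as
    strings, preserving printed precision) used by the reproduction check.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    path = _fixture_path(_FIXTURES[name])
    if name == "table1_means":
        df = pd.read_csv(path)
        return [
            GroupSummary(
                species=r.species,
                arm=r.arm,
                partner_species=r.partner_species,
                trait=r.trait,
                mean=float(r.mean),
                se=float(r.se),
                n=int(r.n),
            )
            for r in df.itertuples(index=False)
        ]
    if name == "table2_printed":
        return pd.read_csv(path, dtype={"printed": str})
    return pd.read_csv(path)
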
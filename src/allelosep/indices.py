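"""Pairwise plant-interference indices: RCI, RNE, CR and IR.

All four statistics compare the performance of a focal plant grown with a
neighbor (``P_mix``) against its monoculture control (``P_mono``), where
performance is any positive endpoint trait (root length, height, dry mass):

* RCI, relative competition intensity: ``(P_mono − P_mix) / P_mono``.
  Positive = inhibition by the neighbor, negative = facilitation; unbounded
  below, ≤ 1 above.
* RNE, relative neighbor effect: ``(P_mono − P_mix) / max(P_mono, P_mix)``.
  Same sign as RCI but symmetric around zero and bounded in [−1, 1].
* CR, competitive ratio (Willey & Rao): the ratio of the two species'
  relative yields, optionally corrected by the inverse ratio of sowing
  proportions.  By construction CR(a over b) × CR(b over a) = 1; CR > 1
  means one focal plant is worth more than one neighbor plant.
* IR, inhibitory rate: ``(1 − treatment/control) × 100`` in percent; equals
  100 × RCI when control/treatment are the monoculture/mixture pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import DesignSpec, GroupSummary, get_summary

__all__ = [
    "UndefinedIndexError",
    "MissingCellError",
    "IndexValue",
    "IndexTable",
    "relative_competition_intensity",
    "relative_neighbor_effect",
    "competitive_ratio",
    "inhibitory_rate",
    "compute_index_table",
]

#: display rounding, decimal places per index kind (half-even)
DISPLAY_DECIMALS = {"RCI": 4, "RNE": 4, "CR": 4, "IR": 2}

RECIPROCITY_TOL = 1e-9


class UndefinedIndexError(ValueError):
    """An index is undefined for the given performances (e.g. dead control)."""


class MissingCellError(KeyError):
    """A required (species, arm, trait) summary cell is absent."""


def relative_competition_intensity(p_mono: float, p_mix: float) -> float:
    """RCI = (P_mono − P_mix)/P_mono; positive = inhibition, negative = facilitation."""
    if p_mono <= 0:
        raise UndefinedIndexError(f"RCI undefined for monoculture performance {p_mono}")
    if p_mix < 0:
        raise UndefinedIndexError(f"mixture performance must be >= 0, got {p_mix}")
    return (p_mono - p_mix) / p_mono


def relative_neighbor_effect(p_mono: float, p_mix: float) -> float:
    """RNE = (P_mono − P_mix)/max(P_mono, P_mix); bounded in [−1, 1].

    Equals RCI whenever P_mono ≥ P_mix; under facilitation the larger mixture
    performance becomes the denominator, which is what symmetrizes the index.
    """
    if p_mono < 0 or p_mix < 0:
        raise UndefinedIndexError("performances must be >= 0")
    p_max = max(p_mono, p_mix)
    if p_max == 0:
        raise UndefinedIndexError("RNE undefined when both performances are 0")
    return (p_mono - p_mix) / p_max


def competitive_ratio(
    focal_mono: float,
    focal_mix: float,
    partner_mono: float,
    partner_mix: float,
    z_focal: float = 0.5,
    z_partner: float = 0.5,
) -> float:
    """Competitive ratio of the focal species over its partner.

    ``[(focal_mix/focal_mono) / (partner_mix/partner_mono)] × (z_partner/z_focal)``
    where z are sowing proportions (equal by default, factor 1).  Swapping
    focal and partner returns the exact reciprocal.
    """
    for name, v in (
        ("focal_mono", focal_mono),
        ("focal_mix", focal_mix),
        ("partner_mono", partner_mono),
        ("partner_mix", partner_mix),
    ):
        if v <= 0:
            raise UndefinedIndexError(f"CR requires positive performances; {name}={v}")
    if not (0 < z_focal < 1 and 0 < z_partner < 1):
        raise UndefinedIndexError("sowing proportions must lie in (0, 1)")
    return ((focal_mix / focal_mono) / (partner_mix / partner_mono)) * (z_partner / z_focal)


def inhibitory_rate(control: float, treatment: float) -> float:
    """IR = (1 − treatment/control) × 100, in percent; negative = stimulation."""
    if control <= 0:
        raise UndefinedIndexError(f"IR undefined for control {control}")
    if treatment < 0:
        raise UndefinedIndexError(f"treatment must be >= 0, got {treatment}")
    return (1.0 - treatment / control) * 100.0


@dataclass(frozen=True)
class IndexValue:
    index_kind: str  # RCI | RNE | CR | IR
    focal_species: str
    partner_species: str
    trait: str
    value: float


class IndexTable:
    """Interference indices for every (focal, partner, trait) of a mixed culture.

    Stores full-precision values; rounding (4 dp half-even for RCI/RNE/CR,
    2 dp for IR) is applied only on display/serialization.
    """

    def __init__(self, values: Sequence[IndexValue]):
        self.values = list(values)
        self._by_key = {
            (v.focal_species, v.partner_species, v.trait, v.index_kind): v.value
            for v in self.values
        }
        self._check_reciprocity()

    def _check_reciprocity(self) -> None:
        for (focal, partner, trait, kind), value in self._by_key.items():
            if kind != "CR":
                continue
            recip = self._by_key.get((partner, focal, trait, "CR"))
            if recip is not None and abs(value * recip - 1.0) > RECIPROCITY_TOL:
                raise AssertionError(
                    f"CR reciprocity violated for ({focal},{partner},{trait}): "
                    f"{value} × {recip} != 1"
                )

    def value(self, focal: str, partner: str, trait: str, kind: str) -> float:
        key = (focal, partner, trait, kind)
        if key not in self._by_key:
            raise MissingCellError(f"no {kind} for focal={focal} partner={partner} trait={trait}")
        return self._by_key[key]

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "focal": v.focal_species,
                    "partner": v.partner_species,
                    "trait": v.trait,
                    "index": v.index_kind,
                    "value": v.value,
                }
                for v in self.values
            ]
        )
        if rounded:
            df["value"] = [
                round(val, DISPLAY_DECIMALS[kind])
                for val, kind in zip(df["value"], df["index"])
            ]
        return df

    def to_csv(self, path, rounded: bool = True) -> None:
        self.to_frame(rounded=rounded).to_csv(path, index=False)

    def to_markdown(self) -> str:
        """Wide markdown layout: one row per (focal, partner), indices × traits as columns."""
        df = self.to_frame(rounded=True)
        wide = df.pivot_table(
            index=["focal", "partner"], columns=["index", "trait"], values="value"
        )
        wide.columns = [f"{k} {t}" for k, t in wide.columns]
        return wide.reset_index().to_markdown(index=False)


def compute_index_table(
    summaries: Iterable[GroupSummary],
    design: DesignSpec | None = None,
) -> IndexTable:
    """Assemble RCI, RNE and CR for every mixed-culture pair in the summaries.

    Pairs are discovered from the ``mixed`` arm; each focal species needs a
    plain monoculture control and its partner needs the reciprocal mixed and
    monoculture cells.  Sowing proportions come from ``design`` when given
    (matched by species, either orientation), else equal proportions.
    """
    summaries = list(summaries)
    mixed = [s for s in summaries if s.arm == "mixed"]
    if not mixed:
        raise MissingCellError("no mixed-arm summaries; nothing to index")

    def _cell(species: str, arm: str, partner: str, trait: str) -> GroupSummary:
        try:
            return get_summary(summaries, species, arm, partner, trait)
        except KeyError as exc:
            raise MissingCellError(str(exc)) from exc

    def _proportions(focal: str, partner: str) -> tuple[float, float]:
        if design is None:
            return (0.5, 0.5)
        z_t, z_n = design.proportions
        if (focal, partner) == (design.target_species, design.neighbor_species):
            return (z_t, z_n)
        if (focal, partner) == (design.neighbor_species, design.target_species):
            return (z_n, z_t)
        return (0.5, 0.5)

    values: list[IndexValue] = []
    for s in mixed:
        focal, partner, trait = s.species, s.partner_species, s.trait
        focal_mono = _cell(focal, "monoculture", "none", trait)
        partner_mono = _cell(partner, "monoculture", "none", trait)
        partner_mix = _cell(partner, "mixed", focal, trait)
        z_f, z_p = _proportions(focal, partner)
        values.append(
            IndexValue("RCI", focal, partner, trait,
                       relative_competition_intensity(focal_mono.mean, s.mean))
        )
        values.append(
            IndexValue("RNE", focal, partner, trait,
                       relative_neighbor_effect(focal_mono.mean, s.mean))
        )
        values.append(
            IndexValue("CR", focal, partner, trait,
                       competitive_ratio(focal_mono.mean, s.mean,
                                         partner_mono.mean, partner_mix.mean,
                                         z_focal=z_f, z_partner=z_p))
        )
    return IndexTable(values)
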
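"""Split total biointerference into allelopathic effect and resource competition.

The two-step bioassay measures, on the receiver species (barnyardgrass):

* TB — the inhibitory rate of the mixed-culture arm against the receiver's
  monoculture control: everything the donor does to the receiver.
* AE — the inhibitory rate of the receiver grown alone in the donor
  mixture's *residual solution* (nutrients replenished to standard Hoagland
  levels) against a fresh-solution control: only the released chemicals act.

Resource competition is then the remainder, RC = TB − AE, and the
allelopathic share of interference is AE/TB.  Negative RC (AE measured
larger than TB) is reported and flagged, not clamped — net facilitation is a
legitimate outcome of the framework.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import GroupSummary, TraitObservation, observations_to_frame
from .indices import inhibitory_rate

__all__ = [
    "PairingError",
    "DecompositionResult",
    "DecompositionTable",
    "total_biointerference",
    "allelopathic_effect",
    "decompose",
    "reproduce_decomposition_table",
    "decomposition_from_observations",
]


class PairingError(ValueError):
    """Control and treatment summaries do not form a valid bioassay pair."""


def _check_pair(control: GroupSummary, treatment: GroupSummary, treatment_arm: str) -> None:
    if control.species != treatment.species or control.trait != treatment.trait:
        raise PairingError(
            f"control {control.key} and treatment {treatment.key} must share "
            "species and trait"
        )
    if control.arm != "monoculture":
        raise PairingError(f"control arm must be monoculture, got {control.arm!r}")
    if treatment.arm != treatment_arm:
        raise PairingError(
            f"treatment arm must be {treatment_arm!r}, got {treatment.arm!r}"
        )


def total_biointerference(
    receiver_mono_control: GroupSummary, receiver_mixed: GroupSummary
) -> float:
    """TB in percent: IR of the receiver's mixed arm against its monoculture control."""
    _check_pair(receiver_mono_control, receiver_mixed, "mixed")
    return inhibitory_rate(receiver_mono_control.mean, receiver_mixed.mean)


def allelopathic_effect(
    receiver_control_fresh: GroupSummary,
    receiver_in_residual: GroupSummary,
    nutrients_replenished: bool = True,
) -> float:
    """AE in percent: IR of the residual-solution arm against the fresh-solution control.

    ``nutrients_replenished`` records the design assumption that N, P and K in
    the residual solution were restored to standard levels before the assay;
    if False, AE is confounded with nutrient depletion and a warning is raised.
    """
    _check_pair(receiver_control_fresh, receiver_in_residual, "residual_solution")
    if not nutrients_replenished:
        warnings.warn(
            "residual solution nutrients not replenished: AE is confounded "
            "with nutrient depletion",
            stacklevel=2,
        )
    ae = inhibitory_rate(receiver_control_fresh.mean, receiver_in_residual.mean)
    if ae < 0:
        warnings.warn(
            f"stimulatory residual solution (AE = {ae:.2f}% < 0)", stacklevel=2
        )
    return ae


@dataclass(frozen=True)
class DecompositionResult:
    """TB/AE/RC decomposition for one donor → receiver trait.

    ``rc = tb − ae`` holds identically; ``ae_share`` is 100·AE/TB in percent
    (NaN and flagged when TB = 0).  ``flags`` collects data-quality notes
    (negative RC, undefined share).
    """

    donor_species: str
    receiver_species: str
    trait: str
    tb: float
    ae: float
    rc: float
    ae_share: float
    se_tb: float = float("nan")
    se_ae: float = float("nan")
    flags: tuple[str, ...] = ()


def decompose(
    tb: float,
    ae: float,
    donor_species: str = "",
    receiver_species: str = "",
    trait: str = "",
    se_tb: float = float("nan"),
    se_ae: float = float("nan"),
) -> DecompositionResult:
    """RC = TB − AE and the allelopathic share AE/TB, with sign/zero flags."""
    if not (math.isfinite(tb) and math.isfinite(ae)):
        raise ValueError("tb and ae must be finite percentages")
    rc = tb - ae
    flags: list[str] = []
    if tb == 0:
        share = float("nan")
        if ae != 0:
            flags.append("share_undefined_zero_tb")
    else:
        share = 100.0 * ae / tb
    if rc < 0:
        flags.append("negative_rc")
    return DecompositionResult(
        donor_species,
        receiver_species,
        trait,
        tb=tb,
        ae=ae,
        rc=rc,
        ae_share=share,
        se_tb=se_tb,
        se_ae=se_ae,
        flags=tuple(flags),
    )


class DecompositionTable:
    """TB, AE, RC and AE/TB per donor × trait; serializes to CSV and stacked bars."""

    def __init__(self, results: Sequence[DecompositionResult]):
        self.results = list(results)

    def result(self, donor: str, trait: str) -> DecompositionResult:
        for r in self.results:
            if r.donor_species == donor and r.trait == trait:
                return r
        raise KeyError(f"no decomposition for donor={donor} trait={trait}")

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "donor": r.donor_species,
                    "receiver": r.receiver_species,
                    "trait": r.trait,
                    "tb": r.tb,
                    "ae": r.ae,
                    "rc": r.rc,
                    "ae_share": r.ae_share,
                    "flags": ";".join(r.flags),
                }
                for r in self.results
            ]
        )
        if rounded:
            for col in ("tb", "ae", "rc", "ae_share"):
                df[col] = df[col].round(2)
        return df

    def to_csv(self, path, rounded: bool = True) -> None:
        self.to_frame(rounded=rounded).to_csv(path, index=False)

    def plot_stacked(self, path) -> None:
        """Stacked-bar decomposition per donor: total bar = RC (shaded) + AE (open)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        donors = list(dict.fromkeys(df["donor"]))
        fig, axes = plt.subplots(
            1, len(donors), figsize=(4 * len(donors), 3.5), squeeze=False, sharey=True
        )
        for ax, donor in zip(axes[0], donors):
            sub = df[df["donor"] == donor]
            x = np.arange(len(sub))
            ax.bar(x, sub["rc"], color="0.6", edgecolor="black", label="RC")
            ax.bar(x, sub["ae"], bottom=sub["rc"], color="white",
                   edgecolor="black", label="AE")
            ax.set_xticks(x, sub["trait"])
            ax.set_title(f"{donor} on {sub['receiver'].iloc[0]}")
            ax.set_ylabel("Inhibitory rate (%)")
        axes[0, -1].legend()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def reproduce_decomposition_table(source) -> DecompositionTable:
    """Build the decomposition table from printed TB/AE rates or raw observations.

    ``source`` is either a DataFrame with columns
    ``donor,receiver,trait,tb,tb_se,ae,ae_se`` (the shipped fixture shape) or
    a collection of :class:`TraitObservation` from a two-step bioassay, in
    which case TB/AE and their SEs are computed from per-replicate basins.
    """
    if isinstance(source, pd.DataFrame):
        required = {"donor", "receiver", "trait", "tb", "ae"}
        missing = required - set(source.columns)
        if missing:
            raise PairingError(f"fixture frame missing columns {sorted(missing)}")
        results = [
            decompose(
                float(r.tb),
                float(r.ae),
                donor_species=r.donor,
                receiver_species=r.receiver,
                trait=r.trait,
                se_tb=float(getattr(r, "tb_se", float("nan"))),
                se_ae=float(getattr(r, "ae_se", float("nan"))),
            )
            for r in source.itertuples(index=False)
        ]
        return DecompositionTable(results)
    return decomposition_from_observations(source)


def _replicate_ir(control: pd.DataFrame, treatment: pd.DataFrame) -> tuple[float, float]:
    """Mean and SE of per-replicate inhibitory rates.

    Basin means are paired by sorted replicate index (treatment basin i vs
    control basin i); the mean IR is computed from the grand means (the path
    validated against the printed tables) and the SE from the paired
    per-replicate IRs.
    """
    c_means = control.groupby("replicate_id")["value"].mean().sort_index()
    t_means = treatment.groupby("replicate_id")["value"].mean().sort_index()
    ir_mean = inhibitory_rate(float(c_means.mean()), float(t_means.mean()))
    k = min(len(c_means), len(t_means))
    if k < 2:
        return ir_mean, 0.0
    per_rep = [
        inhibitory_rate(float(c), float(t))
        for c, t in zip(c_means.iloc[:k], t_means.iloc[:k])
    ]
    se = float(np.std(per_rep, ddof=1) / math.sqrt(k))
    return ir_mean, se


def decomposition_from_observations(
    observations: Iterable[TraitObservation],
    receiver_species: str | None = None,
) -> DecompositionTable:
    """Compute TB, AE and the decomposition from raw two-step bioassay data.

    Requires, for the receiver species, a monoculture control arm plus mixed
    and residual-solution arms against each donor.  Raises
    :class:`PairingError` naming any missing (donor, trait) arm.
    """
    df = observations_to_frame(observations)
    if df.empty:
        raise PairingError("no observations supplied")
    if receiver_species is None:
        residual = df[df["arm"] == "residual_solution"]
        if residual.empty:
            raise PairingError("no residual_solution arm; cannot identify the receiver")
        receivers = residual["species"].unique()
        if len(receivers) != 1:
            raise PairingError(f"ambiguous receiver species {sorted(receivers)}")
        receiver_species = receivers[0]
    rec = df[df["species"] == receiver_species]
    control = rec[(rec["arm"] == "monoculture")]
    if control.empty:
        raise PairingError(f"no monoculture control for receiver {receiver_species}")
    donors = sorted(
        set(rec.loc[rec["arm"] != "monoculture", "partner_species"])
    )
    results: list[DecompositionResult] = []
    for donor in donors:
        for trait in sorted(rec["trait"].unique()):
            c = control[control["trait"] == trait]
            mixed = rec[(rec["arm"] == "mixed") & (rec["partner_species"] == donor)
                        & (rec["trait"] == trait)]
            resid = rec[(rec["arm"] == "residual_solution")
                        & (rec["partner_species"] == donor) & (rec["trait"] == trait)]
            missing = [
                name
                for name, part in (("monoculture", c), ("mixed", mixed),
                                   ("residual_solution", resid))
                if part.empty
            ]
            if missing:
                raise PairingError(
                    f"donor {donor}, trait {trait}: missing arm(s) {missing}"
                )
            tb, se_tb = _replicate_ir(c, mixed)
            ae, se_ae = _replicate_ir(c, resid)
            results.append(
                decompose(tb, ae, donor_species=donor,
                          receiver_species=receiver_species, trait=trait,
                          se_tb=se_tb, se_ae=se_ae)
            )
    return DecompositionTable(results)
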
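"""One-way ANOVA and (protected) LSD pairwise comparisons at the 5% level.

Classical fixed-effects decomposition: F = MS_between / MS_within with p
from the F distribution, followed by Fisher's least significant difference

    LSD(i, j) = t(1 − α/2, df_error) · sqrt(MSE · (1/n_i + 1/n_j))

with a pair flagged significant iff |mean_i − mean_j| > LSD.  With
``protected=True`` (default) no pair is flagged unless the omnibus F test is
itself significant at α, which controls the familywise type-I error.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsufficientReplicationError",
    "PairwiseComparison",
    "ComparisonResult",
    "one_way_anova",
    "lsd_pairwise",
    "comparisons_to_frame",
]


class InsufficientReplicationError(ValueError):
    """A group has fewer than two replicate values."""


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    diff: float  # mean_a − mean_b
    lsd: float  # threshold in trait units
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    levels: tuple[str, ...]
    means: tuple[float, ...]
    ns: tuple[int, ...]
    f_statistic: float
    p_value: float
    mse: float
    error_df: int
    pairwise: tuple[PairwiseComparison, ...] = ()


def _validate_groups(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None
) -> tuple[list[np.ndarray], list[str]]:
    if len(groups) < 2:
        raise InsufficientReplicationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise InsufficientReplicationError(
                f"group {i} has {a.size} value(s); need >= 2 per group"
            )
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    elif len(labels) != len(arrays):
        raise ValueError("labels must match the number of groups")
    return arrays, list(labels)


def one_way_anova(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> ComparisonResult:
    """Fixed-effects one-way ANOVA over ≥ 2 groups of replicate values.

    Degenerate inputs are handled explicitly: zero within-group variance with
    distinct means gives F = inf, p = 0 (with a warning); identical groups
    give F = 0, p = 1.
    """
    arrays, labels = _validate_groups(groups, labels)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        if ms_between == 0.0:
            f, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance with distinct means; F is infinite",
                stacklevel=2,
            )
            f, p = math.inf, 0.0
    else:
        f = ms_between / mse
        p = float(stats.f.sf(f, df_between, df_within))
    return ComparisonResult(
        levels=tuple(labels),
        means=tuple(float(a.mean()) for a in arrays),
        ns=tuple(int(a.size) for a in arrays),
        f_statistic=float(f),
        p_value=float(p),
        mse=float(mse),
        error_df=int(df_within),
    )


def lsd_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    protected: bool = True,
) -> ComparisonResult:
    """LSD comparisons for every pair of groups, optionally gated on the omnibus F.

    Returns the omnibus :class:`ComparisonResult` with ``pairwise`` filled in.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    omnibus = one_way_anova(groups, labels)
    gate_open = (not protected) or (omnibus.p_value < alpha)
    t_crit = float(stats.t.ppf(1 - alpha / 2, omnibus.error_df))
    pairs: list[PairwiseComparison] = []
    for i, j in itertools.combinations(range(len(omnibus.levels)), 2):
        lsd = t_crit * math.sqrt(omnibus.mse * (1 / omnibus.ns[i] + 1 / omnibus.ns[j]))
        diff = omnibus.means[i] - omnibus.means[j]
        sig = gate_open and abs(diff) > lsd
        pairs.append(
            PairwiseComparison(omnibus.levels[i], omnibus.levels[j], diff, lsd, sig)
        )
    return ComparisonResult(
        levels=omnibus.levels,
        means=omnibus.means,
        ns=omnibus.ns,
        f_statistic=omnibus.f_statistic,
        p_value=omnibus.p_value,
        mse=omnibus.mse,
        error_df=omnibus.error_df,
        pairwise=tuple(pairs),
    )


def comparisons_to_frame(result: ComparisonResult, trait: str = "") -> pd.DataFrame:
    """Pairwise flags as a tidy frame (trait, group_a, group_b, diff, lsd, significant)."""
    return pd.DataFrame(
        [
            {
                "trait": trait,
                "group_a": p.group_a,
                "group_b": p.group_b,
                "diff": p.diff,
                "lsd": p.lsd,
                "significant": p.significant,
            }
            for p in result.pairwise
        ]
    )
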
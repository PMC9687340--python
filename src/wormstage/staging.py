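"""Relative-lifespan staging: 25 fine classes, 6 merged groups, 80/20 split.

An individual photographed on ``day`` of a realized ``lifespan`` is assigned
to one of 25 bins each covering 4 % of that lifespan; bins are left-open /
right-closed, so a relative age of exactly 32 % falls in class 8 and
33.33 % in class 9. Fine classes are merged into six coarse groups
(1–5, 6–9, 10–13, 14–17, 18–21, 22–25) — an early/middle/late split with two
groups per period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_FINE = 25
N_GROUPS = 6

# Group g covers fine classes (edge[g-1], edge[g]]
_GROUP_EDGES = (0, 5, 9, 13, 17, 21, 25)


@dataclass(frozen=True)
class StageLabel:
    """A fine class in 1–25 paired with its merged group in 1–6."""

    fine: int
    group: int

    def __post_init__(self) -> None:
        if not 1 <= self.fine <= N_FINE:
            raise ValueError(f"fine class {self.fine} outside [1, {N_FINE}]")
        if self.group != merge_to_group(self.fine):
            raise ValueError(
                f"group {self.group} inconsistent with fine class {self.fine}"
            )


def assign_fine_class(day: float, lifespan: float) -> int:
    """Assign the fine relative-lifespan class for an image.

    Parameters
    ----------
    day : number of days since adulthood, ``0 <= day <= lifespan``.
    lifespan : the individual's realized lifespan in days, ``> 0``.

    Returns
    -------
    int
        ``ceil(25 * day / lifespan)`` clamped to ``[1, 25]``; day 0 maps to
        class 1. E.g. day 5 of a 15-day lifespan -> class 9.
    """
    if lifespan <= 0:
        raise ValueError(f"lifespan must be positive, got {lifespan}")
    if day < 0 or day > lifespan:
        raise ValueError(f"day {day} outside [0, lifespan={lifespan}]")
    fine = math.ceil(N_FINE * day / lifespan)
    return min(max(fine, 1), N_FINE)


def merge_to_group(fine: int) -> int:
    """Merge a fine class 1–25 into its coarse group 1–6."""
    if not 1 <= fine <= N_FINE:
        raise ValueError(f"fine class {fine} outside [1, {N_FINE}]")
    for g in range(1, N_GROUPS + 1):
        if fine <= _GROUP_EDGES[g]:
            return g
    raise AssertionError("unreachable")


def stage_label(day: float, lifespan: float) -> StageLabel:
    """Full stage label (fine + group) for an image."""
    fine = assign_fine_class(day, lifespan)
    return StageLabel(fine=fine, group=merge_to_group(fine))


def split_dataset(
    manifest: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    group_column: str = "stage_group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of an image manifest.

    Within each coarse group the rows are shuffled with ``seed`` and
    ``round(train_fraction * group_size)`` of them (round-half-up) go to the
    training partition; the remainder go to test. Groups with fewer than two
    rows are assigned entirely to train with a warning.

    Returns ``(train, test)`` data frames preserving the input schema.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")

    rng = np.random.default_rng(seed)
    train_parts: list[pd.DataFrame] = []
    test_parts: list[pd.DataFrame] = []
    for _, block in manifest.groupby(group_column, sort=True):
        order = rng.permutation(len(block))
        block = block.iloc[order]
        if len(block) < 2:
            warnings.warn(
                f"stage group with {len(block)} image(s): assigned to train",
                stacklevel=2,
            )
            train_parts.append(block)
            continue
        # round-half-up so a 0.5 residual favors train
        n_train = int(math.floor(train_fraction * len(block) + 0.5))
        n_train = min(max(n_train, 1), len(block) - 1)
        train_parts.append(block.iloc[:n_train])
        test_parts.append(block.iloc[n_train:])

    train = pd.concat(train_parts).reset_index(drop=True)
    test = (
        pd.concat(test_parts).reset_index(drop=True)
        if test_parts
        else manifest.iloc[0:0].copy()
    )
    return train, test
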
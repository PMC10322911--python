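"""Freezing-based fear-extinction metrics.

Fear reduction on an extinction day is the first 5-tone block's freezing
expressed as a percentage of the post-conditioning CS+ test freezing
(% reduction = first_block × 100 / test); remission is the first day
with reduction strictly below 20%, within at most 7 days (animals that
never reach it are censored at day 7). Δ freezing is the signed
difference (probe − test CS+) in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BehaviorConfig
from .errors import InvalidConfigError
from .synth import FreezingDataset

NOT_ACHIEVED = -1  # sentinel for remission not reached within max days


@dataclass
class RemissionResult:
    """Per-animal extinction summary."""

    animal_id: str
    group: str
    reductions_pct: tuple[float, ...]  # first-block reduction per session
    remission_day: int                 # 1-based, or NOT_ACHIEVED
    censored: bool                     # True when not achieved within max days
    delta_freezing: float              # remote probe − test CS+, points

    @property
    def sessions_to_remission(self) -> int:
        """Remission day, censored animals counted at the maximum day."""
        return self.remission_day if not self.censored else len(self.reductions_pct)


def block_average(tone_freezing: np.ndarray, block_size: int = 5) -> np.ndarray:
    """Means of consecutive non-overlapping tone blocks."""
    x = np.asarray(tone_freezing, dtype=float)
    if x.ndim != 1 or x.size == 0 or x.size % block_size != 0:
        raise InvalidConfigError(
            f"tone count {x.size} not divisible by block size {block_size}")
    return x.reshape(-1, block_size).mean(axis=1)


def freezing_reduction(first_block_freezing: float,
                       test_cs_freezing: float) -> float:
    """First-block freezing as % of the post-conditioning test level."""
    if test_cs_freezing <= 0:
        raise InvalidConfigError(
            "test CS+ freezing must be positive (undefined baseline)")
    if first_block_freezing < 0:
        raise InvalidConfigError("freezing must be >= 0")
    return first_block_freezing * 100.0 / test_cs_freezing


def remission_day(daily_first_block: np.ndarray, test_cs_freezing: float,
                  config: BehaviorConfig | None = None) -> int:
    """First day whose reduction is strictly below the remission threshold.

    Returns :data:`NOT_ACHIEVED` when no day within ``max_extinction_days``
    qualifies.
    """
    config = config or BehaviorConfig()
    config.validate()
    blocks = np.asarray(daily_first_block, dtype=float)
    if not 1 <= blocks.size <= config.max_extinction_days:
        raise InvalidConfigError(
            f"expected 1–{config.max_extinction_days} sessions, got {blocks.size}")
    for day, fb in enumerate(blocks, start=1):
        if freezing_reduction(fb, test_cs_freezing) < config.remission_threshold_pct:
            return day
    return NOT_ACHIEVED


def delta_freezing(probe_freezing: float, test_cs_freezing: float) -> float:
    """Signed change in freezing (percentage points) relative to test CS+."""
    for v in (probe_freezing, test_cs_freezing):
        if not 0 <= v <= 100:
            raise InvalidConfigError("freezing percentages must be in [0, 100]")
    return probe_freezing - test_cs_freezing


def summarize_dataset(dataset: FreezingDataset,
                      config: BehaviorConfig | None = None
                      ) -> list[RemissionResult]:
    """Score every animal in a freezing dataset.

    Sessions after the remission day are ignored (training stopped at
    remission); the Δ-freezing probe is the remote test block.
    """
    config = config or BehaviorConfig()
    config.validate()
    probes = dataset.probes.set_index("animal_id")
    results = []
    for _, row in dataset.animals.iterrows():
        mat = dataset.animal_matrix(row.animal_id)
        n_days = min(mat.shape[0], config.max_extinction_days)
        first_blocks = np.array([
            block_average(mat[d], config.block_size)[0] for d in range(n_days)])
        day = remission_day(first_blocks, row.test_cs_freezing, config)
        if day != NOT_ACHIEVED:
            first_blocks = first_blocks[:day]  # training stops at remission
        reductions = tuple(freezing_reduction(fb, row.test_cs_freezing)
                           for fb in first_blocks)
        results.append(RemissionResult(
            animal_id=row.animal_id, group=row.group,
            reductions_pct=reductions,
            remission_day=day, censored=day == NOT_ACHIEVED,
            delta_freezing=delta_freezing(
                float(probes.loc[row.animal_id, "remote_pct"]),
                float(row.test_cs_freezing))))
    return results


def group_summary(results: list[RemissionResult]) -> pd.DataFrame:
    """Median sessions-to-remission and Δ freezing per group."""
    df = pd.DataFrame({
        "group": [r.group for r in results],
        "sessions_to_remission": [r.sessions_to_remission for r in results],
        "censored": [r.censored for r in results],
        "delta_freezing": [r.delta_freezing for r in results],
    })
    return (df.groupby("group")
            .agg(n=("group", "size"),
                 median_sessions=("sessions_to_remission", "median"),
                 n_censored=("censored", "sum"),
                 median_delta_freezing=("delta_freezing", "median"))
            .reset_index())
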
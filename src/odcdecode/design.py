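"""Block-design timing for ocular dominance column (ODC) mapping runs.

The reference acquisition is a 270 s run at TR 3 s (90 volumes): a 15 s
baseline at the start and end, and eight 30 s stimulation blocks in between,
four per eye, in pseudorandomized order.  VASO sessions acquire interleaved
blood-nulled / not-nulled volume pairs at an effective TR of 5 s; after
BOLD-contamination correction they are analyzed on the same 3 s grid.

Retinotopic mapping runs (used only for their timing arithmetic here) present
8.25 cycles of a rotating wedge (64 s cycle, 552 s run) or an expanding /
contracting ring (32 s cycle, 288 s run) with 12 s baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
BASELINE = "baseline"

#: number of initial volumes discarded from every stimulation block to omit
#: hemodynamic transients
N_TRANSIENT_VOLUMES = 2


@dataclass(frozen=True)
class RunDesign:
    """Timing of a single block-design run.

    Parameters
    ----------
    tr_s : float
        Repetition time of the analysis grid in seconds.
    n_volumes : int
        Volumes per run on that grid.
    baseline_s : float
        Duration of the leading and trailing baseline periods.
    block_s : float
        Duration of one stimulation block.
    block_conditions : tuple of str
        Ordered eye labels (``"left"`` / ``"right"``) of the blocks.
    n_runs : int
        Runs per session.
    vaso_pairing : bool
        If set, raw volumes are acquired as (nulled, not-nulled) pairs at an
        effective TR of ``vaso_effective_tr_s`` and later resampled onto the
        ``tr_s`` grid.
    """

    tr_s: float = 3.0
    n_volumes: int = 90
    baseline_s: float = 15.0
    block_s: float = 30.0
    block_conditions: tuple = (LEFT, RIGHT) * 4
    n_runs: int = 10
    vaso_pairing: bool = False
    vaso_effective_tr_s: float = 5.0

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        total = 2 * self.baseline_s + self.block_s * len(self.block_conditions)
        if not np.isclose(total, self.tr_s * self.n_volumes):
            raise ValueError(
                f"design timing inconsistent: 2*{self.baseline_s} + "
                f"{len(self.block_conditions)}*{self.block_s} != "
                f"{self.tr_s}*{self.n_volumes}"
            )
        n_left = sum(c == LEFT for c in self.block_conditions)
        n_right = sum(c == RIGHT for c in self.block_conditions)
        if n_left != n_right:
            raise ValueError("unequal number of left and right blocks")
        if any(c not in (LEFT, RIGHT) for c in self.block_conditions):
            raise ValueError("block conditions must be 'left' or 'right'")

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_volumes

    @property
    def n_blocks(self) -> int:
        return len(self.block_conditions)

    def block_onsets(self) -> np.ndarray:
        """Onset time in seconds of every stimulation block."""
        return self.baseline_s + self.block_s * np.arange(self.n_blocks)

    def volume_times(self) -> np.ndarray:
        return self.tr_s * np.arange(self.n_volumes)

    def volume_conditions(self) -> np.ndarray:
        """Condition label per volume ('left' | 'right' | 'baseline')."""
        labels = np.full(self.n_volumes, BASELINE, dtype=object)
        t = self.volume_times()
        for onset, cond in zip(self.block_onsets(), self.block_conditions):
            labels[(t >= onset) & (t < onset + self.block_s)] = cond
        return labels

    def volume_block_index(self) -> np.ndarray:
        """Block index per volume (-1 for baseline volumes)."""
        idx = np.full(self.n_volumes, -1, dtype=int)
        t = self.volume_times()
        for b, onset in enumerate(self.block_onsets()):
            idx[(t >= onset) & (t < onset + self.block_s)] = b
        return idx

    def retained_mask(self) -> np.ndarray:
        """Volumes kept for decoding and PSC: all stimulation volumes except
        the first ``N_TRANSIENT_VOLUMES`` of every block."""
        block = self.volume_block_index()
        keep = block >= 0
        for b in range(self.n_blocks):
            in_block = np.flatnonzero(block == b)
            keep[in_block[:N_TRANSIENT_VOLUMES]] = False
        return keep

    def baseline_mask(self, drop_post_block: int = N_TRANSIENT_VOLUMES) -> np.ndarray:
        """Baseline volumes, excluding the first ``drop_post_block`` volumes
        after each block ends (mirror of the stimulation transient rule)."""
        block = self.volume_block_index()
        base = block < 0
        # drop the first volumes of any baseline period that follows a block
        t = self.volume_times()
        for onset in self.block_onsets():
            end = onset + self.block_s
            after = np.flatnonzero(base & (t >= end))
            # only volumes immediately following this block's end
            after = after[t[after] < end + drop_post_block * self.tr_s]
            base[after] = False
        return base

    def events_frame(self, include_baseline: bool = True) -> pd.DataFrame:
        """Events table with columns onset, duration, trial_type (seconds)."""
        rows = []
        if include_baseline:
            rows.append((0.0, self.baseline_s, BASELINE))
        for onset, cond in zip(self.block_onsets(), self.block_conditions):
            rows.append((float(onset), self.block_s, cond))
        if include_baseline:
            rows.append((self.duration_s - self.baseline_s, self.baseline_s, BASELINE))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])

    def with_conditions(self, conditions: Sequence[str]) -> "RunDesign":
        return replace(self, block_conditions=tuple(conditions))


def pseudorandom_conditions(seed: int) -> tuple:
    """Pseudorandomized order of four left and four right blocks."""
    rng = np.random.default_rng(seed)
    conds = np.array([LEFT] * 4 + [RIGHT] * 4, dtype=object)
    return tuple(rng.permutation(conds))


def odc_run_design(seed: int | None = None, **kwargs) -> RunDesign:
    """The reference ODC run (270 s, TR 3 s, 8 blocks), optionally with a
    seeded pseudorandom block order."""
    d = RunDesign(**kwargs)
    if seed is not None:
        d = d.with_conditions(pseudorandom_conditions(seed))
    return d


def session_designs(n_runs: int = 10, seed: int = 0, **kwargs) -> list:
    """One RunDesign per run with independent pseudorandom block orders."""
    ss = np.random.SeedSequence(seed)
    return [odc_run_design(seed=int(s.generate_state(1)[0] % (2**31)), n_runs=n_runs, **kwargs)
            for s in ss.spawn(n_runs)]


@dataclass(frozen=True)
class RetinotopyDesign:
    """Timing of a phase-encoded retinotopy run."""

    cycle_period_s: float
    n_cycles: float = 8.25
    baseline_s: float = 12.0
    tr_s: float = 2.0

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.cycle_period_s + 2 * self.baseline_s

    @property
    def highpass_cutoff_hz(self) -> float:
        """High-pass cutoff = 1 / (3 x stimulus cycle period)."""
        return 1.0 / (3.0 * self.cycle_period_s)


def wedge_design() -> RetinotopyDesign:
    """Rotating wedge: 64 s cycles, 552 s run."""
    return RetinotopyDesign(cycle_period_s=64.0)


def ring_design() -> RetinotopyDesign:
    """Expanding/contracting ring: 32 s cycles, 288 s run."""
    return RetinotopyDesign(cycle_period_s=32.0)
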
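"""Experimental design: blocks, factor crossings, and randomization.

The experiment crosses gravity multiplier, initial vertical velocity
(4.5 / 6 m/s), initial horizontal velocity (3 / 4 m/s) and occlusion
category (short / long).  Three main blocks of 320 trials cover the
five upright gravities (0.7-1.3 g, 8 repetitions per cell per block);
one inversion block of 384 trials covers {1 g, -1 g} at 24 repetitions
per cell; a 48-trial training block presents every combination once.
Each subject therefore completes 960 + 384 = 1344 experimental trials.
Block order is counterbalanced: half the subjects get the inversion
block first, half last.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import LONG_OCCLUSION, SHORT_OCCLUSION

MAIN_GRAVITIES = (0.7, 0.85, 1.0, 1.15, 1.3)
INVERSION_GRAVITIES = (1.0, -1.0)
ALL_GRAVITIES = (0.7, 0.85, 1.0, 1.15, 1.3, -1.0)
V_VERTICAL = (4.5, 6.0)
V_HORIZONTAL = (3.0, 4.0)
OCC_CATEGORIES = ("short", "long")

MAIN_REPS = 8
INVERSION_REPS = 24
N_MAIN_BLOCKS = 3

_OCC_BOUNDS = {"short": SHORT_OCCLUSION, "long": LONG_OCCLUSION}


class DesignError(ValueError):
    """Invalid design request."""


@dataclass(frozen=True)
class TrialCondition:
    """Factor levels of one trial."""

    block_id: int
    block_type: str  # 'main' | 'inversion' | 'training'
    gravity_mult: float
    v_xi: float
    v_yi: float
    occ_category: str
    occ_fraction: float
    rep_index: int
    trial_index: int = -1

    def __post_init__(self) -> None:
        lo, hi = _OCC_BOUNDS[self.occ_category]
        if not lo <= self.occ_fraction <= hi:
            raise DesignError(
                f"occ_fraction {self.occ_fraction} outside {self.occ_category} "
                f"bounds [{lo}, {hi}]")


@dataclass
class ExperimentPlan:
    """One subject's full trial sequence."""

    subject_id: str
    block_order: tuple[str, ...]
    trials: list[TrialCondition]
    seed: int
    training: list[TrialCondition] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(tc) for tc in self.training + self.trials]
        return pd.DataFrame(rows)


def _draw_fraction(rng: np.random.Generator, category: str) -> float:
    lo, hi = _OCC_BOUNDS[category]
    return float(rng.uniform(lo, hi))


def _build_block(gravities, reps, block_type, block_id, seed) -> list[TrialCondition]:
    rng = np.random.default_rng(seed)
    cells = list(itertools.product(gravities, V_VERTICAL, V_HORIZONTAL,
                                   OCC_CATEGORIES))
    pool = [(cell, rep) for cell in cells for rep in range(reps)]
    order = rng.permutation(len(pool))
    out = []
    for i in order:
        (gm, vy, vx, occ), rep = pool[i]
        out.append(TrialCondition(
            block_id=block_id, block_type=block_type, gravity_mult=gm,
            v_xi=vx, v_yi=vy, occ_category=occ,
            occ_fraction=_draw_fraction(rng, occ), rep_index=rep))
    return out


def build_main_block(seed: int, block_id: int = 0) -> list[TrialCondition]:
    """One main block: 5 gravities x 2 x 2 x 2 x 8 reps = 320 trials, shuffled."""
    return _build_block(MAIN_GRAVITIES, MAIN_REPS, "main", block_id, seed)


def build_inversion_block(seed: int, block_id: int = 0) -> list[TrialCondition]:
    """The 1 g / -1 g block: 2 x 2 x 2 x 2 x 24 reps = 384 trials, shuffled."""
    return _build_block(INVERSION_GRAVITIES, INVERSION_REPS, "inversion",
                        block_id, seed)


def build_training_block(seed: int, block_id: int = 0) -> list[TrialCondition]:
    """Training: each of the 6 x 2 x 2 x 2 = 48 combinations exactly once."""
    return _build_block(ALL_GRAVITIES, 1, "training", block_id, seed)


def build_experiment(subject_id: str, inversion_first: bool, seed: int) -> ExperimentPlan:
    """Assemble a subject's plan: training, then 4 experimental blocks.

    The inversion block comes first or last among the experimental
    blocks according to ``inversion_first``; trial indices run over the
    experimental trials only (1344 in total).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    training = build_training_block(seeds[0], block_id=0)
    mains = [build_main_block(seeds[1 + i], block_id=0) for i in range(N_MAIN_BLOCKS)]
    inversion = build_inversion_block(seeds[4], block_id=0)
    if inversion_first:
        blocks = [inversion] + mains
        order = ("inversion", "main", "main", "main")
    else:
        blocks = mains + [inversion]
        order = ("main", "main", "main", "inversion")

    trials: list[TrialCondition] = []
    idx = 0
    for b_id, block in enumerate(blocks, start=1):
        for tc in block:
            trials.append(TrialCondition(
                block_id=b_id, block_type=tc.block_type,
                gravity_mult=tc.gravity_mult, v_xi=tc.v_xi, v_yi=tc.v_yi,
                occ_category=tc.occ_category, occ_fraction=tc.occ_fraction,
                rep_index=tc.rep_index, trial_index=idx))
            idx += 1
    return ExperimentPlan(subject_id=subject_id, block_order=order,
                          trials=trials, seed=seed, training=training)
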
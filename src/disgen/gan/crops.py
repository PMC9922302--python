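"""Crop-length assignment and per-epoch balancing.

Each discriminator accepts a single crop length; every training sequence is
mapped to the nearest length in the plan (ties to the smaller value), then
each length's pool is topped up to exactly ``c_max`` assignments by randomly
re-sampling sequences, so all discriminators see the same amount of data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..ensembles_io import ResidueSequence


@dataclass
class CropPlan:
    lengths: Tuple[int, ...] = (20, 50, 80, 110)
    c_max: int = 1070
    n_frames: int = 1750

    @property
    def frames_per_epoch(self) -> int:
        return len(self.lengths) * self.c_max * self.n_frames


def nearest_crop_length(L: int, lengths: Sequence[int]) -> int:
    """Nearest plan length, ties to the smaller value."""
    if L < min(lengths):
        raise ValueError(f"sequence length {L} below smallest crop length {min(lengths)}")
    return min(lengths, key=lambda c: (abs(L - c), c))


def assign_crops(
    sequences: Sequence[ResidueSequence],
    plan: CropPlan,
    seed: int,
) -> Dict[int, List[ResidueSequence]]:
    """One epoch's sequence-to-crop-length assignment, balanced to ``c_max``.

    Sequences whose length equals a plan value keep it; others go to the
    nearest value (tie -> smaller).  Random re-sampling then tops each length
    up to exactly ``c_max``; raises if a length already exceeds ``c_max``.
    """
    rng = np.random.default_rng(seed)
    assignment: Dict[int, List[ResidueSequence]] = {c: [] for c in plan.lengths}
    for seq in sequences:
        L = len(seq)
        if L in assignment:
            assignment[L].append(seq)
        else:
            assignment[nearest_crop_length(L, plan.lengths)].append(seq)
    for c, members in assignment.items():
        if len(members) > plan.c_max:
            raise ValueError(
                f"crop length {c} has {len(members)} sequences, exceeding c_max={plan.c_max}"
            )
    pool = [s for s in sequences]
    for c in plan.lengths:
        fitting = [s for s in pool if len(s) >= c] or pool
        while len(assignment[c]) < plan.c_max:
            assignment[c].append(fitting[rng.integers(len(fitting))])
    return assignment


def crop_frames(xyz: np.ndarray, onehot: np.ndarray, crop_len: int,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Random contiguous crops: each frame gets its own start offset.

    Returns cropped coordinates (N, crop_len, 3) and per-frame one-hot
    (N, crop_len, 20).
    """
    N, L, _ = xyz.shape
    if crop_len > L:
        raise ValueError(f"crop length {crop_len} exceeds sequence length {L}")
    starts = rng.integers(0, L - crop_len + 1, size=N)
    idx = starts[:, None] + np.arange(crop_len)[None, :]
    cropped = xyz[np.arange(N)[:, None], idx]
    oh = onehot[idx]
    return cropped, oh
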
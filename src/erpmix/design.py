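"""Experimental design generation.

The experiment is a 2 (Type: intact vs. scrambled) x 2 (Category: face vs.
house) x 2 (Duration: 33 vs. 216 ms) within-subject design delivered in four
blocks.  Blocks 1-2 (the first half) contain only 33 ms presentations: every
intact stimulus appears three times and every scrambled stimulus once per
block.  In blocks 3-4 every stimulus appears once at each duration.  At the
canonical size (40 stimuli per category) each block holds exactly 320 trials,
each intact stimulus is seen 8x at 33 ms and 2x at 216 ms, and each scrambled
stimulus 4x at 33 ms and 2x at 216 ms.

``n_stimuli_per_category`` scales the whole design down proportionally while
preserving the repetition structure; the default reproduces the canonical
design exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "participant_id",
    "block",
    "half",
    "trial_index",
    "stimulus_id",
    "category",
    "type",
    "duration",
]

DURATION_SHORT = 33
DURATION_LONG = 216


def _block_plan(n_per_cat: int) -> dict[int, list[tuple[int, str, str, int]]]:
    """Unordered trial composition of each block.

    Stimulus ids 1..n_per_cat are faces, n_per_cat+1..2*n_per_cat houses; the
    scrambled version of a stimulus shares its id (Type distinguishes them).
    """
    faces = list(range(1, n_per_cat + 1))
    houses = list(range(n_per_cat + 1, 2 * n_per_cat + 1))
    intact = [(s, "face", "intact") for s in faces] + [
        (s, "house", "intact") for s in houses
    ]
    scrambled = [(s, "face", "scrambled") for s in faces] + [
        (s, "house", "scrambled") for s in houses
    ]

    first_half = (
        [(s, c, t, DURATION_SHORT) for (s, c, t) in intact for _ in range(3)]
        + [(s, c, t, DURATION_SHORT) for (s, c, t) in scrambled]
    )
    second_half = [
        (s, c, t, d)
        for (s, c, t) in intact + scrambled
        for d in (DURATION_SHORT, DURATION_LONG)
    ]
    return {1: first_half, 2: first_half, 3: second_half, 4: second_half}


def build_design(
    n_participants: int,
    seed: int,
    n_stimuli_per_category: int = 40,
) -> pd.DataFrame:
    """Generate the per-trial design table for ``n_participants``.

    Within-block trial order is an independent seeded permutation per
    participant and block; the table is deterministic given ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_stimuli_per_category < 1:
        raise ValueError("n_stimuli_per_category must be >= 1")

    plan = _block_plan(n_stimuli_per_category)
    streams = np.random.SeedSequence(seed).spawn(n_participants)

    rows: list[tuple] = []
    for p_idx in range(n_participants):
        pid = p_idx + 1
        rng = np.random.default_rng(streams[p_idx])
        for block in (1, 2, 3, 4):
            trials = plan[block]
            order = rng.permutation(len(trials))
            half = 1 if block <= 2 else 2
            for trial_index, k in enumerate(order, start=1):
                s, c, t, d = trials[k]
                rows.append((pid, block, half, trial_index, s, c, t, d))

    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return df


def validate_design(design: pd.DataFrame, n_stimuli_per_category: int = 40) -> None:
    """Raise ``ValueError`` if the design violates its structural invariants."""
    n = n_stimuli_per_category
    block_size = 8 * n
    for (pid, block), g in design.groupby(["participant_id", "block"]):
        if len(g) != block_size:
            raise ValueError(
                f"participant {pid} block {block}: {len(g)} trials, "
                f"expected {block_size}"
            )
    first = design[design["block"] <= 2]
    if (first["duration"] != DURATION_SHORT).any():
        raise ValueError("first-half blocks must contain only 33 ms trials")

    counts = (
        design.groupby(["participant_id", "type", "stimulus_id", "duration"])
        .size()
        .unstack("duration", fill_value=0)
    )
    expected = {
        "intact": {DURATION_SHORT: 8, DURATION_LONG: 2},
        "scrambled": {DURATION_SHORT: 4, DURATION_LONG: 2},
    }
    for (pid, typ, sid), row in counts.iterrows():
        for dur, want in expected[typ].items():
            if row.get(dur, 0) != want:
                raise ValueError(
                    f"participant {pid} {typ} stimulus {sid}: "
                    f"{row.get(dur, 0)} trials at {dur} ms, expected {want}"
                )
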
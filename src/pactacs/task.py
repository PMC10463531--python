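"""Computerized dynamic-visual-acuity (DVA) task design and scoring.

Each session presents a moving Landolt C whose gap points up, down,
left or right (4-alternative forced choice).  The design is the full
factorial of speed (200-700 deg/s in steps of 100), movement direction
(two), gap direction (four) and optotype size (3, 4, 5 minimum angles
of resolution) — 144 trials — shuffled per session, with inter-stimulus
intervals drawn uniformly from 1.5-2.5 s.

Stimulus rendering parameters (240 Hz display, 70 cm viewing distance,
+/-10 deg sweep) are carried as schedule metadata only; the analysis
consumes trial factors and correctness, not pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPEEDS = (200, 300, 400, 500, 600, 700)  # deg/s
MOVE_DIRS = ("LR", "RL")
GAP_DIRS = ("up", "down", "left", "right")
SIZES = (3, 4, 5)  # minimum angle of resolution (MAR)
ISI_RANGE = (1.5, 2.5)  # s
SESSIONS = ("pre", "post0", "post10")
CHANCE_LEVEL = 0.25

#: fixed rendering metadata (not used computationally)
DISPLAY_META = {"refresh_hz": 240, "viewing_distance_cm": 70, "sweep_deg": (-10, 10)}


@dataclass
class TrialSchedule:
    """One session's ordered trial list with onsets."""

    trials: pd.DataFrame  # columns: onset_s, duration_s, isi_s, speed, move_dir, gap_dir, size
    session_label: str
    seed: int
    meta: dict = field(default_factory=lambda: dict(DISPLAY_META))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_tsv(self, path: str | Path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)


def build_schedule(session_label: str, seed: int) -> TrialSchedule:
    """Enumerate the 6x2x4x3 factorial once, shuffle by *seed*, and draw
    ISIs uniform on [1.5, 2.5] s; onsets are cumulated session times."""
    if session_label not in SESSIONS:
        raise ValueError(f"unknown session label: {session_label!r}")
    rng = np.random.default_rng(seed)
    grid = [
        (sp, mv, gp, sz)
        for sp in SPEEDS
        for mv in MOVE_DIRS
        for gp in GAP_DIRS
        for sz in SIZES
    ]
    order = rng.permutation(len(grid))
    rows = pd.DataFrame(
        [grid[i] for i in order], columns=["speed", "move_dir", "gap_dir", "size"]
    )
    rows["isi_s"] = rng.uniform(*ISI_RANGE, size=len(rows))
    sweep = DISPLAY_META["sweep_deg"][1] - DISPLAY_META["sweep_deg"][0]
    rows["duration_s"] = sweep / rows["speed"]
    # stimulus onset follows the preceding fixation (ISI)
    rows["onset_s"] = (
        rows["isi_s"].cumsum() + rows["duration_s"].cumsum() - rows["duration_s"]
    )
    cols = ["onset_s", "duration_s", "isi_s", "speed", "move_dir", "gap_dir", "size"]
    return TrialSchedule(trials=rows[cols], session_label=session_label, seed=seed)


def score(schedule: TrialSchedule, responses) -> dict:
    """Score 4-AFC responses against the schedule's gap directions.

    Returns overall accuracy and accuracy per optotype size (proportions
    in [0, 1]).
    """
    responses = list(responses)
    if len(responses) != schedule.n_trials:
        raise ValueError(
            f"{len(responses)} responses for {schedule.n_trials} trials"
        )
    correct = np.asarray(responses) == schedule.trials["gap_dir"].to_numpy()
    out = {"overall": float(correct.mean())}
    for sz in SIZES:
        mask = (schedule.trials["size"] == sz).to_numpy()
        # NaN for a size absent from a (subsampled) schedule
        out[f"size{sz}"] = float(correct[mask].mean()) if mask.any() else float("nan")
    out["correct"] = correct
    return out


def response_table(schedule: TrialSchedule, responses) -> pd.DataFrame:
    """Per-trial response/correctness table (one row per scheduled trial)."""
    rec = score(schedule, responses)
    df = schedule.trials.copy()
    df["response"] = list(responses)
    df["correct"] = rec["correct"]
    return df


def screen_exclusions(accuracy: pd.DataFrame, chance: float = CHANCE_LEVEL) -> pd.DataFrame:
    """Flag size-specific analyses of subjects who never beat chance.

    *accuracy* is long-form with columns ``subject, condition, session,
    size, accuracy``.  A (subject, size) pair is excluded when that
    size's accuracy is below *chance* in **all three** sessions of any
    one stimulation condition; subjects with incomplete sessions are
    flagged ``incomplete`` instead of excluded.
    """
    out = []
    for (subj, size), grp in accuracy.groupby(["subject", "size"]):
        excluded, incomplete = False, False
        for _, cond_grp in grp.groupby("condition"):
            got = set(cond_grp["session"])
            if not set(SESSIONS) <= got:
                incomplete = True
                continue
            if (cond_grp["accuracy"] < chance).all():
                excluded = True
        out.append(
            {"subject": subj, "size": size, "excluded": excluded, "incomplete": incomplete}
        )
    return pd.DataFrame(out)
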
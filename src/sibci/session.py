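"""Session planning: block/trial schedule of an imagery recording.

A session consists of ``n_blocks`` blocks; within each block every task
appears exactly ``trials_per_task_per_block`` times in a freshly shuffled
order.  Each trial is blank (uniform 0.5-1.5 s) -> "Ready!" (0.5 s) ->
"GO!" (0.5 s) -> imagery (4 s); the event marker sits on the first sample
of the imagery window, with integer codes 1..n_tasks in task order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, ProtocolConfig

#: Continuous-recording padding before the first and after the last trial.
EDGE_PAD_S = 2.0


@dataclass(frozen=True)
class SessionPlan:
    """Trial schedule: one row per trial, onsets in samples at protocol fs."""

    trials: pd.DataFrame  # columns: block, within_block, task, code, onset_sample, blank_s
    fs: float
    n_samples: int
    marker_codes: dict[str, int]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def task_counts(self) -> pd.Series:
        return self.trials["task"].value_counts()


def make_session_plan(cfg: ProtocolConfig, seed: int) -> SessionPlan:
    """Draw a deterministic session plan for the given protocol and seed.

    Onsets are strictly increasing; per-block task counts are exact; the
    within-block order is an independent shuffle per block.
    """
    rng = np.random.default_rng(seed)
    codes = {task: i + 1 for i, task in enumerate(cfg.task_names)}

    rows = []
    t = EDGE_PAD_S
    lo, hi = cfg.blank_range_s
    for block in range(cfg.n_blocks):
        order = np.repeat(np.arange(cfg.n_tasks), cfg.trials_per_task_per_block)
        rng.shuffle(order)
        for within, task_idx in enumerate(order):
            blank = float(rng.uniform(lo, hi))
            onset_t = t + blank + cfg.ready_s + cfg.go_s
            task = cfg.task_names[task_idx]
            rows.append(
                {
                    "block": block,
                    "within_block": within,
                    "task": task,
                    "code": codes[task],
                    "onset_sample": int(round(onset_t * cfg.fs)),
                    "blank_s": blank,
                }
            )
            t = onset_t + cfg.task_s

    trials = pd.DataFrame(rows)
    if not np.all(np.diff(trials["onset_sample"]) > 0):
        raise ConfigError("trial onsets are not strictly increasing; fs too low for timing")
    n_samples = int(round((t + EDGE_PAD_S) * cfg.fs))
    return SessionPlan(trials=trials, fs=cfg.fs, n_samples=n_samples, marker_codes=codes)
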
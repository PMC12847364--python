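"""Preprocessing: downsample, average re-reference, epoch, baseline-correct.

The stage order is fixed (resample -> re-reference -> epoch -> baseline)
and deliberately lightweight: no artifact rejection, no ICA, no channel
interpolation.  Epochs span -0.5 .. 4.0 s around imagery onset (half-open
sample window, onset at t = 0), 1125 samples at the 250 Hz working rate.
Baseline correction subtracts the mean of the *whole* epoch per trial and
channel; subtracting only the pre-onset mean is available as a clearly
non-default option.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import AnalysisConfig, TASK_NAMES
from .io import RawSession
from .session import SessionPlan
from .simulate import SubjectiveData


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples with per-trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    fs: float
    window_s: tuple[float, float]  # [t_start, t_end) relative to onset
    trials: pd.DataFrame  # columns: task, and optionally block, self_eval
    participant_id: str = "P01"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def labels(self) -> np.ndarray:
        return self.trials["task"].to_numpy()

    def select_tasks(self, tasks) -> "EpochSet":
        mask = self.trials["task"].isin(list(tasks)).to_numpy()
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            window_s=self.window_s,
            trials=self.trials.loc[mask].reset_index(drop=True),
            participant_id=self.participant_id,
        )

    def select_trials(self, index) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            fs=self.fs,
            window_s=self.window_s,
            trials=self.trials.iloc[index].reset_index(drop=True),
            participant_id=self.participant_id,
        )

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if len(self.trials) != self.n_trials:
            raise ValueError("trial metadata length mismatch")
        t0, t1 = self.window_s
        expected = int(round((t1 - t0) * self.fs))
        if self.n_samples != expected:
            raise ValueError(f"n_samples {self.n_samples} != round(window * fs) = {expected}")
        unknown = set(self.trials["task"]) - set(TASK_NAMES)
        if unknown:
            raise ValueError(f"unknown task label(s): {sorted(unknown)}")


def resample(raw: RawSession, target_fs: float) -> RawSession:
    """Polyphase anti-aliased downsampling; event indices rescale with the rate.

    ``target_fs == raw.fs`` is an exact identity.  Upsampling is out of
    scope and rejected.  Event samples are rescaled by the rational rate
    ratio with round-half-even.
    """
    if target_fs > raw.fs:
        raise ValueError(f"upsampling {raw.fs} -> {target_fs} Hz is not supported")
    if target_fs == raw.fs:
        return raw
    ratio = Fraction(target_fs / raw.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    if abs(up / down - target_fs / raw.fs) > 1e-9:
        raise ValueError("resampling ratio is not rational within tolerance")
    data = sps.resample_poly(raw.data, up, down, axis=1)
    events = raw.events.copy()
    # np.round is round-half-even, keeping rescaled onsets unbiased.
    events["onset_sample"] = np.round(
        events["onset_sample"].to_numpy() * (up / down)
    ).astype(int)
    return RawSession(
        data=data,
        fs=target_fs,
        channel_names=list(raw.channel_names),
        events=events,
        participant_id=raw.participant_id,
        provenance={**raw.provenance, "resampled_from": raw.fs},
    )


def rereference_average(raw: RawSession) -> RawSession:
    """Subtract the instantaneous mean across all channels from every channel."""
    if raw.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = raw.data - raw.data.mean(axis=0, keepdims=True)
    return RawSession(
        data=data,
        fs=raw.fs,
        channel_names=list(raw.channel_names),
        events=raw.events,
        participant_id=raw.participant_id,
        provenance={**raw.provenance, "reference": "average"},
    )


def extract_epochs(
    raw: RawSession,
    window_s: tuple[float, float] = (-0.5, 4.0),
    plan: SessionPlan | None = None,
    subjective: SubjectiveData | None = None,
) -> EpochSet:
    """Cut one epoch per event over the half-open window [t_start, t_end).

    Sample window: ``[onset + round(t_start*fs), onset + round(t_end*fs))``.
    Per-trial block indices and self-evaluation categories are joined from
    the session plan and subjective data when provided (matched by trial
    order, which both share with the event list).
    """
    t0, t1 = window_s
    if t1 <= t0:
        raise ValueError(f"empty epoch window {window_s}")
    fs = raw.fs
    off0, off1 = int(round(t0 * fs)), int(round(t1 * fs))
    onsets = raw.events["onset_sample"].to_numpy()
    starts, stops = onsets + off0, onsets + off1
    bad = np.flatnonzero((starts < 0) | (stops > raw.n_samples))
    if bad.size:
        raise ValueError(f"epoch window out of recording bounds for trial(s) {bad.tolist()}")

    data = np.stack([raw.data[:, a:b] for a, b in zip(starts, stops)])
    trials = pd.DataFrame({"task": raw.events["label"].to_list()})
    if plan is not None:
        if len(plan) != len(trials):
            raise ValueError("session plan trial count does not match events")
        if list(plan.trials["task"]) != list(trials["task"]):
            raise ValueError("session plan task order does not match events")
        trials["block"] = plan.trials["block"].to_numpy()
    if subjective is not None:
        if len(subjective.self_eval) != len(trials):
            raise ValueError("subjective self_eval length does not match events")
        trials["self_eval"] = subjective.self_eval.to_numpy()

    epochs = EpochSet(
        data=data,
        fs=fs,
        window_s=(t0, t1),
        trials=trials,
        participant_id=raw.participant_id,
    )
    epochs.validate()
    return epochs


def baseline_correct(epochs: EpochSet, prestim_only: bool = False) -> EpochSet:
    """Per trial and channel, subtract the mean over the full epoch window.

    ``prestim_only=True`` subtracts the pre-onset (t < 0) mean instead — a
    conventional baseline, provided as an explicit deviation from the
    default whole-epoch rule.
    """
    if prestim_only:
        t0, _ = epochs.window_s
        n_pre = int(round(-t0 * epochs.fs))
        if n_pre < 1:
            raise ValueError("prestim baseline requires a pre-onset segment")
        mean = epochs.data[:, :, :n_pre].mean(axis=2, keepdims=True)
    else:
        mean = epochs.data.mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


def preprocess(
    raw: RawSession,
    analysis: AnalysisConfig | None = None,
    plan: SessionPlan | None = None,
    subjective: SubjectiveData | None = None,
) -> EpochSet:
    """Full stage: resample -> average reference -> epoch -> baseline."""
    analysis = analysis or AnalysisConfig()
    raw = resample(raw, analysis.target_fs)
    raw = rereference_average(raw)
    epochs = extract_epochs(raw, analysis.epoch_window_s, plan=plan, subjective=subjective)
    return baseline_correct(epochs, prestim_only=analysis.prestim_baseline)
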
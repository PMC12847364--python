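"""EEG containers and file I/O.

``RawSession`` is the continuous-recording container shared by the
simulator and the preprocessing stage.  On disk it maps to a BrainVision
triplet (``.vhdr``/``.vmrk``/``.eeg``) in exactly one dialect —
multiplexed IEEE float32, microvolt resolution 1.0 — which makes the
write -> read round trip bit-exact at float32 precision.  Any other
dialect is rejected loudly rather than half-supported.

Events are additionally written to a plain TSV (onset_sample, code,
label) and subjective data to one TSV per participant.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file is not in the supported BrainVision dialect."""


@dataclass
class RawSession:
    """Continuous multichannel EEG: channels x samples in microvolts."""

    data: np.ndarray  # (n_channels, n_samples) float
    fs: float
    channel_names: list[str]
    events: pd.DataFrame  # columns: onset_sample, code, label
    participant_id: str = "P01"
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        ev = self.events
        if len(ev) > 0:
            if not ev["onset_sample"].is_monotonic_increasing:
                raise ValueError("events must be sorted by onset_sample")
            if int(ev["onset_sample"].max()) >= self.n_samples:
                raise ValueError("event onset beyond end of recording")


def make_events(onsets, codes, labels) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_sample": np.asarray(onsets, dtype=int),
            "code": np.asarray(codes, dtype=int),
            "label": list(labels),
        }
    )


# --------------------------------------------------------------------------
# BrainVision triplet (single dialect: MULTIPLEXED / IEEE_FLOAT_32 / uV)
# --------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by sibci

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_HEADER = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,0
"""


def write_brainvision(raw: RawSession, basepath) -> tuple[str, str, str]:
    """Write ``basepath{.vhdr,.vmrk,.eeg}``; returns the three paths.

    One marker line per event (type ``Stimulus``, description ``S<code>``,
    1-based position), preceded by the conventional New Segment marker.
    """
    raw.validate()
    basepath = os.fspath(basepath)
    stem = os.path.basename(basepath)
    vhdr, vmrk, eeg = (basepath + ext for ext in (".vhdr", ".vmrk", ".eeg"))

    # SamplingInterval is in microseconds; keep fractional values exact enough
    # for round trip (formatted with repr-level precision).
    interval = 1e6 / raw.fs
    interval_str = f"{interval:.10g}"
    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(raw.channel_names)
    )
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write(
            _VHDR_TEMPLATE.format(
                stem=stem,
                n_channels=raw.n_channels,
                sampling_interval=interval_str,
                channel_lines=channel_lines,
            )
        )
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write(_VMRK_HEADER.format(stem=stem))
        for i, ev in enumerate(raw.events.itertuples(index=False)):
            # BrainVision marker positions are 1-based sample indices.
            fh.write(
                f"Mk{i + 2}=Stimulus,S{int(ev.code):3d},{int(ev.onset_sample) + 1},1,0\n"
            )
    raw.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr, vmrk, eeg


def _parse_ini(path) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            m = re.match(r"\[(.+)\]$", line)
            if m:
                current = sections.setdefault(m.group(1), {})
                continue
            if current is not None and "=" in line:
                key, val = line.split("=", 1)
                current[key.strip()] = val.strip()
    return sections


def read_brainvision(header_path, label_map: dict[int, str] | None = None) -> RawSession:
    """Read a BrainVision triplet written in the supported dialect.

    Parameters
    ----------
    header_path : path to the ``.vhdr`` file.
    label_map : optional mapping of marker codes to task labels; codes
        absent from the map keep ``S<code>`` as their label.
    """
    header_path = os.fspath(header_path)
    base_dir = os.path.dirname(header_path)
    ini = _parse_ini(header_path)
    common = ini.get("Common Infos", {})
    binary = ini.get("Binary Infos", {})

    fmt = common.get("DataFormat", "BINARY")
    orient = common.get("DataOrientation", "MULTIPLEXED")
    binfmt = binary.get("BinaryFormat", "")
    if fmt != "BINARY" or orient != "MULTIPLEXED" or binfmt != "IEEE_FLOAT_32":
        raise FormatError(
            f"unsupported BrainVision dialect: DataFormat={fmt}, "
            f"DataOrientation={orient}, BinaryFormat={binfmt}; "
            "only BINARY/MULTIPLEXED/IEEE_FLOAT_32 is supported"
        )
    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    channel_names = []
    for i in range(n_channels):
        entry = ini.get("Channel Infos", {}).get(f"Ch{i + 1}")
        if entry is None:
            raise FormatError(f"missing channel entry Ch{i + 1} in header")
        channel_names.append(entry.split(",")[0])

    eeg_path = os.path.join(base_dir, common["DataFile"])
    vmrk_path = os.path.join(base_dir, common["MarkerFile"])
    for p in (eeg_path, vmrk_path):
        if not os.path.exists(p):
            raise IOError(f"companion file not found: {p}")

    flat = np.fromfile(eeg_path, dtype="<f4")
    if flat.size % n_channels != 0:
        n_full = flat.size // n_channels
        raise FormatError(
            f"truncated binary file {eeg_path}: {flat.size} values is not a "
            f"multiple of {n_channels} channels (expected {(n_full + 1) * n_channels} "
            f"values for {n_full + 1} samples, found {flat.size})"
        )
    data = flat.reshape(-1, n_channels).T.astype(np.float64)

    onsets, codes, labels = [], [], []
    for key, val in _parse_ini(vmrk_path).get("Marker Infos", {}).items():
        parts = val.split(",")
        if len(parts) < 3 or parts[0] != "Stimulus":
            continue
        code = int(parts[1].lstrip("S").strip())
        onset = int(parts[2]) - 1
        onsets.append(onset)
        codes.append(code)
        labels.append((label_map or {}).get(code, parts[1].strip()))
    events = make_events(onsets, codes, labels)

    raw = RawSession(
        data=data,
        fs=fs,
        channel_names=channel_names,
        events=events,
        provenance={"source": header_path},
    )
    raw.validate()
    return raw


# --------------------------------------------------------------------------
# Plain-text sidecars
# --------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_epochs(epochs, basepath) -> tuple[str, str]:
    """Serialize an EpochSet as a binary array + TSV metadata sidecar."""
    basepath = os.fspath(basepath)
    npy, tsv = basepath + ".npy", basepath + ".tsv"
    np.save(npy, epochs.data)
    meta = epochs.trials.copy()
    meta.attrs = {}
    meta.to_csv(tsv, sep="\t", index=False)
    with open(basepath + ".json", "w") as fh:
        import json

        json.dump(
            {
                "fs": epochs.fs,
                "window_s": list(epochs.window_s),
                "participant_id": epochs.participant_id,
            },
            fh,
        )
    return npy, tsv


def read_epochs(basepath):
    from .preprocess import EpochSet

    basepath = os.fspath(basepath)
    data = np.load(basepath + ".npy")
    trials = pd.read_csv(basepath + ".tsv", sep="\t")
    import json

    with open(basepath + ".json") as fh:
        meta = json.load(fh)
    return EpochSet(
        data=data,
        fs=meta["fs"],
        window_s=tuple(meta["window_s"]),
        trials=trials,
        participant_id=meta["participant_id"],
    )
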
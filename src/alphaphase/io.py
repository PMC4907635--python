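"""On-disk containers: epoched EEG with a JSON sidecar, trial tables as CSV.

An EpochSet is channels x trials x samples of voltages (µV) with sampling
rate, channel labels and the sample index of first-LED onset.  It is stored
as a raw ``.npy`` array next to a ``.json`` sidecar carrying the metadata
(fs, channel_names, t0_offset_samples, units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Documented trial-table column schema (one row per trial).
TRIAL_COLUMNS = (
    "participant",   # int
    "trial",         # 0-based presentation order
    "validity",      # "valid" | "invalid" (cue matched target side?)
    "synchrony",     # "async" | "simul"
    "cue_side",      # "left" | "right"
    "target_side",   # "left" | "right"
    "leading_led",   # "top" | "bottom" (async trials; "" otherwise)
    "soa_ms",        # stimulus onset asynchrony (0 for simultaneous)
    "response",      # "async" | "simul"
    "correct",       # bool
    "rt_ms",         # response time
)


@dataclass
class EpochSet:
    """Channels x trials x samples voltage array with timing metadata."""

    data: np.ndarray            # (n_channels, n_trials, n_samples), µV
    fs: float
    channel_names: tuple
    onset_index: int            # sample of first-LED onset in every record

    def __post_init__(self):
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be 3-D")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")

    @property
    def times(self):
        """Seconds relative to first-LED onset."""
        n = self.data.shape[-1]
        return (np.arange(n) - self.onset_index) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def pick(self, names) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(self.data[idx], self.fs, tuple(names), self.onset_index)


def save_epochset(es: EpochSet, path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), es.data)
    sidecar = {
        "fs": es.fs,
        "channel_names": list(es.channel_names),
        "t0_offset_samples": es.onset_index,
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_epochset(path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npy"))
    return EpochSet(data=data, fs=meta["fs"],
                    channel_names=tuple(meta["channel_names"]),
                    onset_index=meta["t0_offset_samples"])


def save_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False,
                       dtype={"leading_led": str})


def save_artifact_windows(rows, path) -> None:
    """rows: iterable of (record_id, channel, start, stop, source)."""
    df = pd.DataFrame(rows, columns=["record_id", "channel",
                                     "start_sample", "end_sample", "source"])
    df.to_csv(path, index=False)
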
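"""Recording containers, channel maps, epochs, and bipolar derivation.

Continuous multichannel voltage is held in a :class:`Recording` (channels x
time, microvolts) with condition epochs expressed in seconds from recording
start, half-open ``[start, end)``.  Channels are mapped to anatomical
structures via a :class:`ChannelMap`; within-structure electrode pairs are
differenced to form bipolar LFP traces that reject volume-conducted
common-mode signals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

#: Default structure vocabulary (11 forebrain groups).
STRUCTURES = (
    "amyg", "dStr", "OC", "OFC", "PC", "mPFC", "M1", "S1", "thal", "vHipp", "vStr",
)

HEMISPHERES = ("lesioned", "intact")


@dataclass
class Recording:
    """Continuous multichannel recording with condition epochs.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Unique channel identifiers, one per row of ``samples``.
    epochs : DataFrame with columns (label, start_s, end_s)
        Condition epochs, half-open intervals in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str]
    epochs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["label", "start_s", "end_s"]))
    session: str = ""
    animal: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be positive and finite")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match samples rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        dur = self.duration_s
        for _, row in self.epochs.iterrows():
            if not (0 <= row.start_s < row.end_s <= dur + 1e-9):
                raise ValueError(
                    f"epoch {row.label!r} [{row.start_s}, {row.end_s}) outside "
                    f"recording [0, {dur:g})")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.attrs["fs"] = self.fs
            f.attrs["session"] = self.session
            f.attrs["animal"] = self.animal
            f.create_dataset("channels", data=np.array(self.channel_ids, dtype="S"))
            ep = f.create_group("epochs")
            ep.create_dataset("label", data=self.epochs["label"].to_numpy(dtype="S"))
            ep.create_dataset("start_s", data=self.epochs["start_s"].to_numpy(float))
            ep.create_dataset("end_s", data=self.epochs["end_s"].to_numpy(float))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Recording":
        with h5py.File(path, "r") as f:
            epochs = pd.DataFrame({
                "label": [s.decode() for s in f["epochs/label"][()]],
                "start_s": f["epochs/start_s"][()],
                "end_s": f["epochs/end_s"][()],
            })
            return cls(
                samples=f["samples"][()],
                fs=float(f.attrs["fs"]),
                channel_ids=[s.decode() for s in f["channels"][()]],
                epochs=epochs,
                session=str(f.attrs.get("session", "")),
                animal=str(f.attrs.get("animal", "")),
            )


@dataclass
class ChannelMap:
    """channel_id -> (structure, hemisphere, animal, session)."""

    table: pd.DataFrame  # columns: channel_id, structure, hemisphere, animal, session
    vocabulary: tuple[str, ...] = STRUCTURES

    def __post_init__(self) -> None:
        required = {"channel_id", "structure", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"channel map missing columns: {sorted(missing)}")
        bad = set(self.table["structure"]) - set(self.vocabulary)
        if bad:
            raise ValueError(
                f"structures {sorted(bad)} not in vocabulary {self.vocabulary}")
        bad_h = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_h:
            raise ValueError(f"hemispheres {sorted(bad_h)} not in {HEMISPHERES}")
        if self.table["channel_id"].duplicated().any():
            raise ValueError("duplicate channel_id in channel map")

    def lookup(self, channel_id: str) -> tuple[str, str]:
        row = self.table.loc[self.table["channel_id"] == channel_id]
        if row.empty:
            raise KeyError(f"channel {channel_id!r} not in map")
        return str(row["structure"].iloc[0]), str(row["hemisphere"].iloc[0])

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Channels grouped by (structure, hemisphere), sorted by id."""
        out: dict[tuple[str, str], list[str]] = {}
        for (s, h), sub in self.table.groupby(["structure", "hemisphere"]):
            out[(str(s), str(h))] = sorted(sub["channel_id"].tolist())
        return out

    @classmethod
    def from_csv(cls, path: str | Path, vocabulary: tuple[str, ...] = STRUCTURES
                 ) -> "ChannelMap":
        return cls(pd.read_csv(path, dtype=str), vocabulary=vocabulary)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class BipolarSet:
    """Bipolar LFP traces derived from within-structure electrode pairs.

    ``signals[(structure, hemisphere, pair_id)]`` is the difference trace
    ``channel_a - channel_b``; ``pairs`` records which channels built it.
    """

    signals: dict[tuple[str, str, int], np.ndarray]
    pairs: dict[tuple[str, str, int], tuple[str, str]]
    fs: float

    def keys_for(self, structure: str, hemisphere: str | None = None
                 ) -> list[tuple[str, str, int]]:
        return [k for k in self.signals
                if k[0] == structure and (hemisphere is None or k[1] == hemisphere)]

    @property
    def structures(self) -> list[tuple[str, str]]:
        return sorted({(s, h) for (s, h, _) in self.signals})


def bipolar_derive(recording: Recording, channel_map: ChannelMap,
                   pairing_policy: str = "adjacent") -> BipolarSet:
    """Difference within-structure electrode pairs into bipolar LFP traces.

    ``adjacent`` (default) sorts channels by id within each (structure,
    hemisphere) group and pairs consecutive ones, using each channel at most
    once; ``all`` forms every within-group combination (for electrode-level
    coupling analyses).  Groups with a single channel are skipped with a
    warning — a bipolar trace needs two electrodes.
    """
    if pairing_policy not in ("adjacent", "all"):
        raise ValueError("pairing_policy must be 'adjacent' or 'all'")
    signals: dict[tuple[str, str, int], np.ndarray] = {}
    pairs: dict[tuple[str, str, int], tuple[str, str]] = {}
    for (structure, hemi), chans in channel_map.groups().items():
        chans = [c for c in chans if c in recording.channel_ids]
        if len(chans) < 2:
            if chans:
                warnings.warn(
                    f"structure {structure}/{hemi} has a single channel; "
                    "skipped (no bipolar pair possible)")
            continue
        if pairing_policy == "adjacent":
            combos = [(chans[i], chans[i + 1]) for i in range(0, len(chans) - 1, 2)]
        else:
            combos = [(a, b) for i, a in enumerate(chans) for b in chans[i + 1:]]
        for pid, (a, b) in enumerate(combos):
            signals[(structure, hemi, pid)] = recording.channel(a) - recording.channel(b)
            pairs[(structure, hemi, pid)] = (a, b)
    return BipolarSet(signals=signals, pairs=pairs, fs=recording.fs)


def extract_epoch(recording: Recording, label: str) -> Recording:
    """Slice a recording to one condition epoch, sample-accurate ``[start, end)``."""
    sub = recording.epochs.loc[recording.epochs["label"] == label]
    if sub.empty:
        available = recording.epochs["label"].tolist()
        raise KeyError(f"epoch {label!r} not found; available: {available}")
    row = sub.iloc[0]
    i0 = int(np.floor(row.start_s * recording.fs))
    i1 = int(np.floor(row.end_s * recording.fs))
    return Recording(
        samples=recording.samples[:, i0:i1],
        fs=recording.fs,
        channel_ids=list(recording.channel_ids),
        epochs=pd.DataFrame({"label": [label], "start_s": [0.0],
                             "end_s": [(i1 - i0) / recording.fs]}),
        session=recording.session,
        animal=recording.animal,
    )


def downsample(signal: np.ndarray, fs_in: float, fs_out: float = 2000.0,
               max_denominator: int = 1000) -> np.ndarray:
    """Anti-alias filtered rational-ratio downsampling (polyphase)."""
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")
    if fs_out == fs_in:
        return np.asarray(signal, dtype=np.float64)
    ratio = Fraction(fs_out / fs_in).limit_denominator(max_denominator)
    if abs(float(ratio) - fs_out / fs_in) > 1e-12:
        raise ValueError(
            f"fs_in/fs_out ratio {fs_in}/{fs_out} is not rational within "
            f"denominator {max_denominator}")
    return sps.resample_poly(np.asarray(signal, dtype=np.float64),
                             ratio.numerator, ratio.denominator, axis=-1)


def read_epochs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df[["label", "start_s", "end_s"]]


def write_ledger_json(ledger_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ledger_dict, indent=2, default=float))
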
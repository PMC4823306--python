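"""Recording, profile and feature-table import/export.

Recordings travel as HDF5 (signal matrix + attributes) with the event table
embedded as UTF-8 TSV; profiles and stimulation configs as flat JSON.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json

import h5py
import numpy as np
import pandas as pd

from .lockin import FeatureSet
from .simulate import Recording, SubjectProfile
from .stimulation import StimulationConfig

__all__ = [
    "save_recording",
    "load_recording",
    "save_profile",
    "load_profile",
    "save_config",
    "load_config",
    "write_feature_table",
    "read_feature_table",
]


def save_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip")
        f.attrs["sample_rate"] = recording.sample_rate
        f.attrs["channel_labels"] = list(recording.channel_labels)
        buf = _io.StringIO()
        recording.events.to_csv(buf, sep="\t", index=False)
        f.create_dataset("events_tsv", data=buf.getvalue())


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["sample_rate"])
        labels = tuple(
            lab.decode() if isinstance(lab, bytes) else str(lab)
            for lab in f.attrs["channel_labels"]
        )
        events = pd.read_csv(_io.StringIO(f["events_tsv"][()].decode()), sep="\t")
    return Recording(data, fs, labels, events)


def _dump_dataclass(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(obj), fh, indent=2, default=list)


def save_profile(profile: SubjectProfile, path) -> None:
    _dump_dataclass(profile, path)


def load_profile(path) -> SubjectProfile:
    with open(path) as fh:
        raw = json.load(fh)
    if "blocking_window" in raw:
        raw["blocking_window"] = tuple(raw["blocking_window"])
    return SubjectProfile(**raw)


def save_config(config: StimulationConfig, path) -> None:
    _dump_dataclass(config, path)


def load_config(path) -> StimulationConfig:
    with open(path) as fh:
        return StimulationConfig(**json.load(fh))


def write_feature_table(features: FeatureSet, path) -> None:
    features.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_feature_table(path, group: str = "features") -> FeatureSet:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c not in ("trial_id", "class_label")]
    return FeatureSet(
        df[names].to_numpy(float),
        df["class_label"].to_numpy(),
        names,
        group,
        df["trial_id"].to_numpy(),
    )
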
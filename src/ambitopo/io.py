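"""HDF5/CSV/JSON persistence for every pipeline stage.

Epoch container layout::

    /subject_<k>/data      float64 (trial, channel, sample)
    /subject_<k>/labels    bytes   (trial,)  b"LA"/b"HA"
    attrs: fs, window, channels  (identical across subjects)

ERSP and topogram stacks follow the same per-subject grouping with axis
attributes, so each stage's output is a valid input of the next.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .spectral import ERSPArray
from .synthetic import EpochSet
from .topomap import TopogramStack


def _s(x) -> str:
    """h5py may hand back bytes or str depending on storage; normalize."""
    return x.decode() if isinstance(x, bytes) else str(x)


def save_epochs(path, epoch_sets: list[EpochSet]) -> None:
    with h5py.File(path, "w") as f:
        first = epoch_sets[0]
        f.attrs["fs"] = first.fs
        f.attrs["window"] = list(first.window)
        f.attrs["channels"] = [c.encode() for c in first.channels]
        for ep in epoch_sets:
            g = f.create_group(f"subject_{ep.subject_id}")
            g.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
            g.create_dataset("labels", data=np.array([l.encode() for l in ep.labels]))


def load_epochs(path) -> list[EpochSet]:
    out = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        window = tuple(float(x) for x in f.attrs["window"])
        channels = tuple(_s(c) for c in f.attrs["channels"])
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            out.append(EpochSet(
                subject_id=int(name.split("_")[1]), channels=channels, fs=fs,
                window=window, data=g["data"][()],
                labels=np.array([_s(l) for l in g["labels"][()]])))
    return out


def save_ersp(path, ersps: list[ERSPArray], subject_ids: list[int]) -> None:
    with h5py.File(path, "w") as f:
        first = ersps[0]
        f.attrs["channels"] = [c.encode() for c in first.channels]
        f.attrs["freqs"] = first.freqs
        f.attrs["times"] = first.times
        for sid, e in zip(subject_ids, ersps):
            g = f.create_group(f"subject_{sid}")
            g.create_dataset("data", data=e.data, compression="gzip", compression_opts=1)
            g.attrs["level"] = e.level
            g.attrs["condition"] = e.condition
            if e.labels is not None:
                g.create_dataset("labels", data=np.array([l.encode() for l in e.labels]))


def load_ersp(path) -> tuple[list[ERSPArray], list[int]]:
    ersps, sids = [], []
    with h5py.File(path, "r") as f:
        channels = tuple(_s(c) for c in f.attrs["channels"])
        freqs = np.asarray(f.attrs["freqs"], float)
        times = np.asarray(f.attrs["times"], float)
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            labels = None
            if "labels" in g:
                labels = np.array([_s(l) for l in g["labels"][()]])
            ersps.append(ERSPArray(
                data=g["data"][()], channels=channels, freqs=freqs.copy(),
                times=times.copy(), level=str(g.attrs["level"]),
                condition=str(g.attrs["condition"]), labels=labels))
            sids.append(int(name.split("_")[1]))
    return ersps, sids


def save_stacks(path, stacks: list[TopogramStack]) -> None:
    with h5py.File(path, "w") as f:
        meta = stacks[0].render_meta
        f.attrs["render_meta"] = json.dumps(meta)
        for s in stacks:
            g = f.create_group(f"subject_{s.subject_id}")
            g.create_dataset("images", data=s.images.astype(np.float32),
                             compression="gzip", compression_opts=1)
            g.create_dataset("labels", data=np.array([l.encode() for l in s.labels]))


def load_stacks(path) -> list[TopogramStack]:
    out = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["render_meta"])
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            out.append(TopogramStack(
                subject_id=int(name.split("_")[1]),
                images=g["images"][()].astype(float),
                labels=np.array([_s(l) for l in g["labels"][()]]),
                render_meta=dict(meta)))
    return out


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
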
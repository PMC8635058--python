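"""Electrode montage handling: 2-D scalp projection and channel neighborhoods.

The study cap has 31 channels; here a standard 10-10 subset is used, with
3-D positions taken from MNE's ``standard_1020`` template and flattened to
the plane by an azimuthal-equidistant projection about the best-fit head
sphere (nose toward +y).  All downstream geometry — topogram interpolation
and the spatial channel-neighbor graph of the cluster test — runs on these
2-D coordinates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default 31-channel cap (standard 10-10 names)
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
)


@dataclass(frozen=True)
class Montage:
    """2-D electrode layout on the unit head disc (nose at +y)."""

    channels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), max radius scaled to 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) < 1e-9:
            raise ValueError("duplicate electrode coordinates in montage")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, names) -> np.ndarray:
        """Channel indices for a list of names (raises on unknown names)."""
        lut = {c: i for i, c in enumerate(self.channels)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as e:  # pragma: no cover - message clarity only
            raise KeyError(f"channel {e.args[0]!r} not in montage") from None

    def subset(self, names) -> "Montage":
        idx = self.index(names)
        return Montage(tuple(names), self.positions[idx])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.channels).encode())
        h.update(np.ascontiguousarray(self.positions.round(9)).tobytes())
        return h.hexdigest()[:16]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"name": self.channels,
             "x": self.positions[:, 0], "y": self.positions[:, 1]}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        df = pd.read_csv(path)
        return cls(tuple(df["name"]), df[["x", "y"]].to_numpy(float))


def _fit_sphere(xyz: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: returns (center, radius)."""
    A = np.c_[2.0 * xyz, np.ones(len(xyz))]
    b = (xyz ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def make_standard_montage(channels=DEFAULT_CHANNELS) -> Montage:
    """Build the default montage from MNE's standard_1020 template.

    3-D positions are projected azimuthal-equidistantly: planar radius is
    proportional to the inclination angle from the vertex, azimuth kept,
    then rescaled so the outermost electrode sits at radius 1.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in ch_pos]
    if missing:
        raise KeyError(f"channels absent from standard_1020: {missing}")
    xyz = np.array([ch_pos[c] for c in channels], dtype=float)
    center, _ = _fit_sphere(xyz)
    v = xyz - center
    r = np.linalg.norm(v, axis=1)
    incl = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))  # 0 at vertex
    azim = np.arctan2(v[:, 1], v[:, 0])                # +y = nose
    plane = np.c_[incl * np.cos(azim), incl * np.sin(azim)]
    plane /= np.max(np.linalg.norm(plane, axis=1))
    return Montage(tuple(channels), plane)


@dataclass(frozen=True)
class NeighborGraph:
    """Spatial channel adjacency (symmetric, irreflexive).

    Frequency/time adjacency of the cluster test is implicit (±1 bin) and
    not part of this graph.
    """

    channels: tuple[str, ...]
    adjacency: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        for c, nbrs in self.adjacency.items():
            if c in nbrs:
                raise ValueError(f"self-neighborhood at {c}")
            for n in nbrs:
                if c not in self.adjacency.get(n, frozenset()):
                    raise ValueError(f"asymmetric adjacency {c}<->{n}")

    def neighbor_indices(self, channels=None) -> list[np.ndarray]:
        """Per-channel neighbor index arrays in the given channel order."""
        chs = tuple(channels) if channels is not None else self.channels
        lut = {c: i for i, c in enumerate(chs)}
        out = []
        for c in chs:
            nbrs = [lut[n] for n in self.adjacency[c] if n in lut]
            out.append(np.array(sorted(nbrs), dtype=int))
        return out

    def degrees(self) -> np.ndarray:
        return np.array([len(self.adjacency[c]) for c in self.channels])

    def edge_pairs(self, channels=None) -> np.ndarray:
        """(n_edges, 2) undirected index pairs, each edge once (i < j)."""
        chs = tuple(channels) if channels is not None else self.channels
        lut = {c: i for i, c in enumerate(chs)}
        pairs = set()
        for c in chs:
            for n in self.adjacency[c]:
                if n in lut:
                    i, j = lut[c], lut[n]
                    pairs.add((min(i, j), max(i, j)))
        if not pairs:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(pairs), dtype=int)


def build_neighbor_graph(montage: Montage, max_distance: float = 0.5) -> NeighborGraph:
    """Channels within ``max_distance`` (unit-disc coordinates) are neighbors.

    The default threshold yields a median degree of about 4-6 on the
    standard 31-channel cap, the conventional density for sensor-space
    cluster statistics.
    """
    pos = montage.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = {}
    for i, c in enumerate(montage.channels):
        nbrs = frozenset(montage.channels[j] for j in np.flatnonzero(d[i] <= max_distance))
        if not nbrs:
            raise ValueError(f"channel {c} has no spatial neighbor at threshold {max_distance}")
        adj[c] = nbrs
    return NeighborGraph(montage.channels, adj)
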
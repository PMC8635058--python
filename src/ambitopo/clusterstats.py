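"""Cluster-based permutation contrast of ERSP between conditions.

The paired contrast runs over (channel, frequency, time) triplets of
subject-mean ERSP: an elementwise paired t-test, a two-tailed p = 0.01
threshold, a spatial min-neighbor criterion, connected-component grouping
(channel adjacency from the montage, +-1 bin on the frequency and time
axes, no diagonal steps, polarities separate), summed rectified t as the
cluster mass, and a per-polarity max-mass permutation null obtained by
sign-flipping the within-subject condition difference.  A cluster is
declared significant when its permutation p-value is below 0.025 per tail
(family-wise alpha 0.05 two-tailed).

Sign-flipping subjects — not trials — is the exchangeability unit because
the test contrasts paired subject means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .montage import NeighborGraph

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A connected suprathreshold set of (channel, freq_bin, time_bin) triplets."""

    members: np.ndarray          # (k, 3) int array of (ch, f, t) bins
    polarity: str                # "positive" | "negative"
    mass: float                  # summed |t| over members
    p_value: float | None = None
    significant: bool | None = None
    f_bounds: tuple[float, float] | None = None
    t_bounds: tuple[float, float] | None = None
    channel_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int).reshape(-1, 3)
        if self.members.shape[0] == 0:
            raise ValueError("empty cluster")
        if self.mass <= 0:
            raise ValueError("cluster mass must be positive")

    @property
    def size(self) -> int:
        return self.members.shape[0]

    def to_dict(self) -> dict:
        return {
            "polarity": self.polarity,
            "size": int(self.size),
            "mass": float(self.mass),
            "p_value": None if self.p_value is None else float(self.p_value),
            "significant": self.significant,
            "f_bounds": None if self.f_bounds is None else list(map(float, self.f_bounds)),
            "t_bounds": None if self.t_bounds is None else list(map(float, self.t_bounds)),
            "channels": None if self.channel_set is None else list(self.channel_set),
        }


def paired_t_map(ersp_ha: np.ndarray, ersp_la: np.ndarray) -> np.ndarray:
    """Elementwise paired t over subjects: t = mean(d) / (sd(d)/sqrt(N)).

    Inputs are (n_subjects, ...) arrays of subject-mean ERSP aligned on all
    trailing axes; df = N - 1.  Triplets with zero difference variance get
    t = 0 (degenerate; logged).
    """
    ha = np.asarray(ersp_ha, dtype=float)
    la = np.asarray(ersp_la, dtype=float)
    if ha.shape != la.shape:
        raise ValueError("HA and LA arrays must be aligned")
    n = ha.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    d = ha - la
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    bad = sd == 0
    if np.any(bad):
        logger.warning("zero-variance differences at %d triplet(s); t set to 0",
                       int(bad.sum()))
        t = np.where(bad, 0.0, t)
    return t


def t_threshold(df: int, alpha: float = 0.01) -> float:
    """|t| threshold for a two-tailed elementwise test at ``alpha``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(t_dist.ppf(1.0 - alpha / 2.0, df))


@dataclass(frozen=True)
class ClusterSettings:
    """All knobs of the cluster-forming step (shared by observed and null)."""

    alpha: float = 0.01
    cluster_alpha: float = 0.025
    min_channel_neighbors: int = 2
    n_perm: int = 2000


def _neighbor_filter(mask: np.ndarray, neighbor_idx: list[np.ndarray],
                     min_neighbors: int) -> np.ndarray:
    """Keep suprathreshold samples with >= min_neighbors suprathreshold
    spatial channel-neighbors at the same (frequency, time) bin."""
    if min_neighbors <= 0:
        return mask
    counts = np.zeros(mask.shape, dtype=int)
    for i, nbr in enumerate(neighbor_idx):
        if len(nbr):
            counts[i] = mask[nbr].sum(axis=0)
    return mask & (counts >= min_neighbors)


def _component_labels(mask: np.ndarray, edge_pairs: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of the True voxels of ``mask`` (C, F, T).

    Adjacency: +-1 bin along frequency and time, and montage channel edges
    at identical (f, t); no diagonal connections.  Returns (labels over
    active voxels in flat order, n_components) where ``labels`` aligns with
    ``np.flatnonzero(mask)``.
    """
    C, F, T = mask.shape
    active = np.flatnonzero(mask)
    k = active.size
    if k == 0:
        return np.empty(0, dtype=int), 0
    flat = mask.reshape(-1)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []

    def add_edges(a_idx: np.ndarray, b_idx: np.ndarray) -> None:
        both = flat[a_idx] & flat[b_idx]
        rows.append(a_idx[both])
        cols.append(b_idx[both])

    lin = np.arange(C * F * T).reshape(C, F, T)
    # time axis
    add_edges(lin[:, :, :-1].ravel(), lin[:, :, 1:].ravel())
    # frequency axis
    add_edges(lin[:, :-1, :].ravel(), lin[:, 1:, :].ravel())
    # channel edges
    if len(edge_pairs):
        ft = lin[0].ravel()  # (F*T,) offsets within one channel
        a = (edge_pairs[:, 0:1] * F * T + ft[None, :]).ravel()
        b = (edge_pairs[:, 1:2] * F * T + ft[None, :]).ravel()
        add_edges(a, b)

    r = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    ri = np.searchsorted(active, r)
    ci = np.searchsorted(active, c)
    g = sparse.coo_matrix((np.ones(len(ri), dtype=np.int8), (ri, ci)), shape=(k, k))
    n_comp, labels = connected_components(g, directed=False)
    return labels, n_comp


def threshold_and_cluster(
    t_map: np.ndarray,
    df: int,
    graph: NeighborGraph,
    channels: tuple[str, ...] | None = None,
    alpha: float = 0.01,
    min_channel_neighbors: int = 2,
) -> list[Cluster]:
    """Form positive and negative clusters from a (C, F, T) t-map.

    Returns clusters of both polarities sorted by descending mass (empty
    list when nothing survives thresholding).
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3:
        raise ValueError("t_map must be (channels, freqs, times)")
    chs = tuple(channels) if channels is not None else graph.channels
    if t_map.shape[0] != len(chs):
        raise ValueError("t_map channel axis does not match channel list")
    thr = t_threshold(df, alpha)
    nbr_idx = graph.neighbor_indices(chs)
    edges = graph.edge_pairs(chs)

    out: list[Cluster] = []
    for polarity, mask in (("positive", t_map >= thr), ("negative", t_map <= -thr)):
        mask = _neighbor_filter(mask, nbr_idx, min_channel_neighbors)
        labels, n_comp = _component_labels(mask, edges)
        if n_comp == 0:
            continue
        active = np.flatnonzero(mask)
        tri = np.column_stack(np.unravel_index(active, t_map.shape))
        masses = np.bincount(labels, weights=np.abs(t_map.reshape(-1)[active]),
                             minlength=n_comp)
        for comp in range(n_comp):
            sel = labels == comp
            out.append(Cluster(members=tri[sel], polarity=polarity,
                               mass=float(masses[comp])))
    out.sort(key=lambda cl: cl.mass, reverse=True)
    return out


def _max_masses_for_signs(d_flat: np.ndarray, signs: np.ndarray, shape: tuple,
                          df: int, thr: float, nbr_idx, edges,
                          min_channel_neighbors: int) -> np.ndarray:
    """Per-polarity max cluster mass for each sign-flip row of ``signs``.

    ``d_flat`` is (N, V) subject differences; the per-permutation t-map is
    mean(s*d)/se(s*d), where the second moment of s*d equals that of d, so
    only the mean depends on the signs.

    Returns (P, 2) array of (max positive mass, max negative mass).
    """
    n = d_flat.shape[0]
    q = (d_flat**2).sum(axis=0) / n                      # second moment, flip-invariant
    out = np.empty((len(signs), 2))
    for p, s in enumerate(signs):
        m = (s @ d_flat) / n
        var = (q - m**2) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0).reshape(shape)
        for col, mask in ((0, t >= thr), (1, t <= -thr)):
            mask = _neighbor_filter(mask, nbr_idx, min_channel_neighbors)
            labels, n_comp = _component_labels(mask, edges)
            if n_comp == 0:
                out[p, col] = 0.0
                continue
            active = np.flatnonzero(mask)
            masses = np.bincount(labels, weights=np.abs(t.reshape(-1)[active]),
                                 minlength=n_comp)
            out[p, col] = masses.max()
    return out


def permutation_null(
    ersp_ha: np.ndarray,
    ersp_la: np.ndarray,
    graph: NeighborGraph,
    channels: tuple[str, ...] | None = None,
    settings: ClusterSettings | None = None,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> dict[str, np.ndarray]:
    """Null distribution of the per-polarity maximum cluster mass.

    Each permutation flips the HA/LA assignment independently per subject
    (equivalently the sign of the subject difference), recomputes the
    t-map, re-clusters with identical settings, and records the maximum
    cluster mass of each polarity (0 when no cluster forms).  With
    ``exhaustive=True`` all 2^N sign patterns are enumerated instead of
    Monte-Carlo sampling (identity included).
    """
    settings = settings or ClusterSettings()
    if settings.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ha = np.asarray(ersp_ha, float)
    la = np.asarray(ersp_la, float)
    if ha.shape != la.shape or ha.ndim != 4:
        raise ValueError("expected aligned (subjects, channels, freqs, times) arrays")
    n, C, F, T = ha.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    chs = tuple(channels) if channels is not None else graph.channels
    d_flat = (ha - la).reshape(n, -1)
    thr = t_threshold(n - 1, settings.alpha)
    nbr_idx = graph.neighbor_indices(chs)
    edges = graph.edge_pairs(chs)

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to 20 subjects")
        signs = np.array([[1 - 2 * ((i >> b) & 1) for b in range(n)]
                          for i in range(2**n)], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(settings.n_perm, n))
    mm = _max_masses_for_signs(d_flat, signs, (C, F, T), n - 1, thr,
                               nbr_idx, edges, settings.min_channel_neighbors)
    return {"positive": mm[:, 0], "negative": mm[:, 1], "exhaustive": exhaustive}


def cluster_p_values(observed: list[Cluster], null_max_mass: dict[str, np.ndarray],
                     cluster_alpha: float = 0.025) -> list[Cluster]:
    """Attach permutation p-values (per-polarity tail) and significance flags.

    Monte-Carlo p uses the +1-corrected counting rule
    p = (1 + #{null >= mass}) / (1 + n_perm), so p > 0 always; exhaustive
    nulls contain the identity relabeling and use the plain proportion.
    """
    exhaustive = bool(null_max_mass.get("exhaustive", False))
    for cl in observed:
        null = np.asarray(null_max_mass[cl.polarity], dtype=float)
        if null.size == 0:
            raise ValueError("empty null distribution")
        # tolerance absorbs float noise between the observed and the
        # identity-permutation arithmetic paths
        tol = 1e-8 * (1.0 + cl.mass)
        ge = int(np.sum(null >= cl.mass - tol))
        if exhaustive:
            p = ge / null.size
        else:
            p = (1 + ge) / (1 + null.size)
        cl.p_value = float(p)
        cl.significant = bool(p < cluster_alpha)
    return observed


def extract_bounds(cluster: Cluster, freq_axis: np.ndarray, time_axis: np.ndarray,
                   channels: tuple[str, ...]) -> Cluster:
    """Fill in [f1, f2] Hz, [t1, t2] s, and the member channel set."""
    freq_axis = np.asarray(freq_axis, float)
    time_axis = np.asarray(time_axis, float)
    fbins = cluster.members[:, 1]
    tbins = cluster.members[:, 2]
    cluster.f_bounds = (float(freq_axis[fbins.min()]), float(freq_axis[fbins.max()]))
    cluster.t_bounds = (float(time_axis[tbins.min()]), float(time_axis[tbins.max()]))
    cbins = np.unique(cluster.members[:, 0])
    cluster.channel_set = tuple(channels[i] for i in cbins)
    return cluster


def cluster_permutation_test(
    ersp_ha: np.ndarray,
    ersp_la: np.ndarray,
    graph: NeighborGraph,
    freqs: np.ndarray,
    times: np.ndarray,
    channels: tuple[str, ...] | None = None,
    settings: ClusterSettings | None = None,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[list[Cluster], dict[str, np.ndarray]]:
    """Full contrast: observed clusters with p-values, bounds, and the null.

    Inputs are (subjects, channels, freqs, times) arrays of subject-mean
    ERSP (post-stimulus segment).  Returns clusters sorted by descending
    mass plus the per-polarity max-mass null distribution.
    """
    settings = settings or ClusterSettings()
    chs = tuple(channels) if channels is not None else graph.channels
    n = np.asarray(ersp_ha).shape[0]
    t_map = paired_t_map(ersp_ha, ersp_la)
    observed = threshold_and_cluster(t_map, n - 1, graph, chs,
                                     alpha=settings.alpha,
                                     min_channel_neighbors=settings.min_channel_neighbors)
    null = permutation_null(ersp_ha, ersp_la, graph, chs, settings,
                            seed=seed, exhaustive=exhaustive)
    observed = cluster_p_values(observed, null, settings.cluster_alpha)
    for cl in observed:
        extract_bounds(cl, freqs, times, chs)
    return observed, null


def clusters_to_json(clusters: list[Cluster]) -> list[dict]:
    return [cl.to_dict() for cl in clusters]


def clusters_to_table(clusters: list[Cluster]) -> "pd.DataFrame":
    """BED-like TSV-ready table: cluster_id, polarity, f1, f2, t1, t2, mass, p."""
    import pandas as pd

    rows = []
    for i, cl in enumerate(clusters):
        f1, f2 = cl.f_bounds if cl.f_bounds else (np.nan, np.nan)
        t1, t2 = cl.t_bounds if cl.t_bounds else (np.nan, np.nan)
        rows.append({"cluster_id": i, "polarity": cl.polarity, "f1": f1, "f2": f2,
                     "t1": t1, "t2": t2, "mass": cl.mass, "p_value": cl.p_value,
                     "significant": cl.significant, "size": cl.size})
    return pd.DataFrame(rows)
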
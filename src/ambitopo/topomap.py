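"""Scalp topogram construction: cluster-box averaging and 2-D rendering.

For each trial and each significant cluster, the trial's ERSP is averaged
over the cluster's frequency-band x time-window box at every channel (all
31 channels, not only cluster members), and the resulting per-channel
vector is interpolated onto a head-disc image.  One image per (trial,
cluster): with 3 clusters and 100+100 trials a subject contributes 600
images, the classifier's input.

Rendering uses thin-plate-spline interpolation over the montage's 2-D
electrode positions (exact at the electrodes), pixels outside the unit
head disc set to a background value, and fixed symmetric color limits
across the whole run so that class-informative intensity differences
survive into the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .clusterstats import Cluster
from .montage import Montage
from .spectral import ERSPArray


def cluster_average(trial_ersp: ERSPArray, f_bounds: tuple[float, float],
                    t_bounds: tuple[float, float]) -> np.ndarray:
    """Mean ERSP over a [f1, f2] x [t1, t2] box, for every channel.

    Returns (n_trials, n_channels) for trial-level input.  Axis snapping is
    inclusive: bins whose coordinate falls inside the closed intervals.
    """
    f1, f2 = f_bounds
    t1, t2 = t_bounds
    fsel = (trial_ersp.freqs >= f1 - 1e-12) & (trial_ersp.freqs <= f2 + 1e-12)
    tsel = (trial_ersp.times >= t1 - 1e-12) & (trial_ersp.times <= t2 + 1e-12)
    if not np.any(fsel) or not np.any(tsel):
        raise ValueError(f"degenerate box after axis snapping: f={f_bounds}, t={t_bounds}")
    data = trial_ersp.data
    box = data[..., fsel, :][..., tsel]
    return box.mean(axis=(-2, -1))


def render_topogram(values: np.ndarray, montage: Montage, grid: int = 64,
                    color_limits: tuple[float, float] | None = None,
                    background: float = 0.0) -> np.ndarray:
    """Interpolate a per-channel vector onto a (grid x grid) head-disc image.

    Thin-plate-spline interpolation (exact at electrode positions) over the
    montage's unit-disc coordinates; pixels outside the disc take
    ``background``.  When ``color_limits=(vmin, vmax)`` is given the image
    is affinely mapped so vmin -> -1 and vmax -> +1 and clipped, making
    images comparable across trials; otherwise raw interpolated values are
    returned.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (montage.n_channels,):
        raise ValueError("one value per montage channel required")
    itp = RBFInterpolator(montage.positions, values, kernel="thin_plate_spline")
    ax = np.linspace(-1.0, 1.0, grid)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = (pts**2).sum(axis=1) <= 1.0
    img = np.full(grid * grid, float(background))
    img[inside] = itp(pts[inside])
    img = img.reshape(grid, grid)
    if color_limits is not None:
        vmin, vmax = color_limits
        if not (np.isfinite(vmin) and np.isfinite(vmax)) or vmax <= vmin:
            raise ValueError("color_limits must be finite with vmax > vmin")
        img = np.clip(2.0 * (img - vmin) / (vmax - vmin) - 1.0, -1.0, 1.0)
    return img


def rescale_image(image: np.ndarray, target: int = 224) -> np.ndarray:
    """Bilinear rescale to (target x target); identity when already there."""
    from skimage.transform import resize

    image = np.asarray(image, dtype=float)
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("source image must be at least 8x8")
    if image.shape == (target, target):
        return image.copy()
    return resize(image, (target, target), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


@dataclass
class TopogramStack:
    """Per-subject image stack: (n_trials, n_clusters, H, W) plus labels."""

    subject_id: int
    images: np.ndarray
    labels: np.ndarray                   # (n_trials,) "LA"/"HA"
    render_meta: dict

    def __post_init__(self) -> None:
        if self.images.ndim != 4 or self.images.shape[2] != self.images.shape[3]:
            raise ValueError("images must be (trials, clusters, H, H)")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("labels length mismatch")

    @property
    def n_trials(self) -> int:
        return self.images.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.images.shape[1]

    @property
    def n_images(self) -> int:
        return self.images.shape[0] * self.images.shape[1]

    def flat_images(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(images, labels01, trial_index) flattened over (trial, cluster).

        Labels: LA -> 0, HA -> 1 (HA is the positive class throughout).
        """
        n_t, n_c, h, w = self.images.shape
        imgs = self.images.reshape(n_t * n_c, h, w)
        lab = np.repeat((self.labels == "HA").astype(int), n_c)
        trial = np.repeat(np.arange(n_t), n_c)
        return imgs, lab, trial


def pooled_color_limits(values_per_subject: list[np.ndarray],
                        percentile: float = 98.0) -> tuple[float, float]:
    """Symmetric limits at the given percentile of |cluster-averaged ERSP|
    pooled over subjects; fixed for a whole run."""
    pooled = np.abs(np.concatenate([np.ravel(v) for v in values_per_subject]))
    v = float(np.percentile(pooled, percentile))
    if v <= 0:
        v = 1.0
    return (-v, v)


def build_topogram_stack(
    trial_ersp: ERSPArray,
    clusters: list[Cluster],
    montage: Montage,
    subject_id: int = 0,
    grid: int = 64,
    target: int | None = None,
    color_limits: tuple[float, float] | None = None,
) -> TopogramStack:
    """Render one subject's stack: one image per (trial, significant cluster)."""
    if trial_ersp.labels is None:
        raise ValueError("trial ERSP must carry labels")
    if not clusters:
        raise ValueError("no clusters to render")
    for cl in clusters:
        if cl.f_bounds is None or cl.t_bounds is None:
            raise ValueError("clusters must have extracted bounds")
    vals = [cluster_average(trial_ersp, cl.f_bounds, cl.t_bounds) for cl in clusters]
    if color_limits is None:
        color_limits = pooled_color_limits(vals)
    n_trials = trial_ersp.data.shape[0]
    size = target or grid
    images = np.empty((n_trials, len(clusters), size, size))
    for ci, v in enumerate(vals):
        for ti in range(n_trials):
            img = render_topogram(v[ti], montage, grid=grid, color_limits=color_limits)
            if size != grid:
                img = rescale_image(img, size)
            images[ti, ci] = img
    meta = {"grid": grid, "target": size, "color_limits": tuple(map(float, color_limits)),
            "montage_hash": montage.content_hash()}
    return TopogramStack(subject_id=subject_id, images=images,
                         labels=np.asarray(trial_ersp.labels), render_meta=meta)


def export_png(stack: TopogramStack, out_dir) -> list[str]:
    """Optional grayscale PNG export, one file per (trial, cluster):
    ``s<subject>_t<trial>_c<cluster>_<label>.png``."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for ti in range(stack.n_trials):
        for ci in range(stack.n_clusters):
            img = stack.images[ti, ci]
            u8 = np.uint8(np.clip((img + 1.0) / 2.0, 0, 1) * 255)
            name = f"s{stack.subject_id}_t{ti}_c{ci}_{stack.labels[ti]}.png"
            Image.fromarray(u8, mode="L").save(out / name)
            names.append(name)
    return names
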
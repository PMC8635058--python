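"""End-to-end orchestration: simulate -> ERSP -> cluster contrast ->
topograms -> LOSO CNN -> stability, with a manifest for provenance.

Every stage writes its artifact into the run directory; the manifest
records the config hash and the SHA-256 of each artifact, so a rerun with
the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .classify import CNNConfig, loso_evaluate
from .clusterstats import ClusterSettings, cluster_permutation_test, clusters_to_table
from .montage import build_neighbor_graph, make_standard_montage
from .spectral import WaveletParams, subject_condition_ersp
from .stability import accuracy_regression, loso_cluster_bounds, records_to_frame
from .synthetic import NoiseParams, default_effects, generate_epochs, generate_schedule
from .topomap import build_topogram_stack, pooled_color_limits, cluster_average

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_subjects: int = 20
    n_per_contrast: int = 25
    fs: float = 250.0
    effect_gain: float = 2.5
    neighbor_distance: float = 0.5
    freq_step: float = 1.0
    n_times: int = 50
    alpha: float = 0.01
    cluster_alpha: float = 0.025
    n_perm: int = 2000
    min_channel_neighbors: int = 2
    image_grid: int = 64
    image_size: int = 64
    cnn: dict = field(default_factory=dict)
    run_stability: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order; returns the manifest dict.

    With a null configuration (effect_gain = 1) the contrast typically
    yields no significant cluster; the classification and stability stages
    are then skipped with a notice in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(),
                      "config_hash": config.content_hash(),
                      "stages": {}, "artifacts": {}}

    def record(stage: str, t0: float, **extra) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **extra}

    def add_artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": path.name, "sha256": _sha256(path)}

    try:
        # --- simulate -----------------------------------------------------
        t0 = time.time()
        montage = make_standard_montage()
        montage.to_csv(out / "montage.csv")
        schedule = generate_schedule(config.n_per_contrast, seed=config.seed)
        schedule.to_csv(out / "schedule.csv")
        effects = default_effects(gain=config.effect_gain)
        epochs = generate_epochs(
            n_subjects=config.n_subjects, schedule=schedule, effects=effects,
            noise_params=NoiseParams(), fs=config.fs, montage=montage,
            seed=config.seed)
        aio.save_epochs(out / "epochs.h5", epochs)
        add_artifact("epochs", out / "epochs.h5")
        add_artifact("montage", out / "montage.csv")
        add_artifact("schedule", out / "schedule.csv")
        record("simulate", t0, n_subjects=config.n_subjects)

        # --- ersp ---------------------------------------------------------
        t0 = time.time()
        params = WaveletParams(
            freqs=np.arange(4.0, 40.0 + config.freq_step / 2, config.freq_step),
            n_times=config.n_times)
        trials, ha_means, la_means = [], [], []
        for ep in epochs:
            tr, ha, la = subject_condition_ersp(ep, params)
            trials.append(tr)
            ha_means.append(ha)
            la_means.append(la)
        sids = [ep.subject_id for ep in epochs]
        aio.save_ersp(out / "ersp_trial.h5", trials, sids)
        add_artifact("ersp", out / "ersp_trial.h5")
        record("ersp", t0)

        # --- contrast -----------------------------------------------------
        t0 = time.time()
        graph = build_neighbor_graph(montage, config.neighbor_distance)
        post = trials[0].poststim()
        ha_arr = np.stack([h.poststim().data for h in ha_means])
        la_arr = np.stack([l.poststim().data for l in la_means])
        settings = ClusterSettings(alpha=config.alpha,
                                   cluster_alpha=config.cluster_alpha,
                                   n_perm=config.n_perm,
                                   min_channel_neighbors=config.min_channel_neighbors)
        clusters, _ = cluster_permutation_test(
            ha_arr, la_arr, graph, post.freqs, post.times,
            settings=settings, seed=config.seed)
        clusters_to_table(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
        aio.save_json(out / "clusters.json", [c.to_dict() for c in clusters])
        add_artifact("clusters", out / "clusters.json")
        significant = [c for c in clusters if c.significant]
        record("contrast", t0, n_clusters=len(clusters), n_significant=len(significant))

        if not significant:
            manifest["notice"] = ("no significant cluster; classification and "
                                  "stability stages skipped")
            aio.save_json(out / "manifest.json", manifest)
            return manifest

        # --- topogram -----------------------------------------------------
        t0 = time.time()
        post_trials = [tr.poststim() for tr in trials]
        vals = [np.concatenate([cluster_average(tr, c.f_bounds, c.t_bounds).ravel()
                                for c in significant]) for tr in post_trials]
        limits = pooled_color_limits(vals)
        stacks = [build_topogram_stack(tr, significant, montage, subject_id=sid,
                                       grid=config.image_grid, target=config.image_size,
                                       color_limits=limits)
                  for sid, tr in zip(sids, post_trials)]
        aio.save_stacks(out / "stack.h5", stacks)
        add_artifact("stack", out / "stack.h5")
        record("topogram", t0, n_images=sum(s.n_images for s in stacks))

        # --- train / evaluate ----------------------------------------------
        t0 = time.time()
        cnn_cfg = CNNConfig(**{"seed": config.seed, **config.cnn})
        table = loso_evaluate(stacks, cnn_cfg)
        table.to_csv(out / "eval.csv", index=False)
        add_artifact("eval", out / "eval.csv")
        record("classify", t0,
               mean_accuracy=float(table["accuracy"].mean()),
               sd_accuracy=float(table["accuracy"].std(ddof=1)))

        # --- stability ------------------------------------------------------
        if config.run_stability:
            t0 = time.time()
            records = loso_cluster_bounds(
                ha_arr, la_arr, significant, graph, post.freqs, post.times,
                settings=settings, seed=config.seed, subject_ids=sids)
            rec_df = records_to_frame(records)
            rec_df.to_csv(out / "stability.csv", index=False)
            add_artifact("stability", out / "stability.csv")
            reg_report = {}
            acc = table.set_index("test_subject")["accuracy"]
            for kind in ("delta_t", "delta_f"):
                wide = rec_df.pivot(index="excluded_subject",
                                    columns="cluster_index", values=kind)
                wide.columns = [f"{kind}_{i + 1}" for i in wide.columns]
                try:
                    reg_report[kind] = accuracy_regression(acc, wide).to_dict()
                except ValueError as e:
                    reg_report[kind] = {"error": str(e)}
            aio.save_json(out / "regression.json", reg_report)
            add_artifact("regression", out / "regression.json")
            record("stability", t0)
    except Exception as e:
        stage = len(manifest["stages"])
        raise RuntimeError(f"pipeline aborted after stage {stage}: {e}") from e

    aio.save_json(out / "manifest.json", manifest)
    return manifest
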
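"""End-to-end orchestration: simulate -> fit -> filter -> connectomes ->
metrics -> stats, with a manifest for reproducibility.

All randomness flows from the single config seed through named
substreams; re-running with the same config reproduces every CSV
artifact bit-identically.  With ``resume=True`` stages whose outputs
already exist are skipped, so deleting one artifact recomputes only the
downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import default_effect_spec, simulate_cohort
from .connectome import (Connectome, assign_endpoints, build_commit_connectome,
                         build_raw_connectome, consistency_threshold,
                         proportional_threshold, smn_parcellation_spec)
from .errors import ParameterError
from .fit import fit_weights, filter_tractogram
from .gradients import make_gradient_scheme
from .io import (read_tractogram, read_truth_csv, read_weights_csv,
                 write_connectome_csv, write_dwi, write_tractogram,
                 write_truth_csv, write_weights_csv)
from .metrics import metric_panel
from .model import build_system_matrix
from .phantom import (Tractogram, add_spurious_streamlines, simulate_dwi,
                      two_bundle_phantom)
from .stats import BatteryConfig, analysis_battery

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, typed run configuration; round-trips through YAML.

    Unknown keys in a config file are errors (fail-fast)."""

    seed: int = 0
    # phantom
    grid_x: int = 10
    grid_y: int = 10
    grid_z: int = 3
    voxel_size: float = 1.0
    n_streamlines_per_bundle: int = 6
    n_spurious: int = 30
    lesion: bool = False
    # scheme
    n_b0: int = 1
    shell_bvals: tuple = (1000.0, 2000.0)
    shell_ndirs: tuple = (30, 30)
    snr: float | None = None
    # fit
    fit_tol: float = 1e-8
    fit_max_iter: int = 1000
    weight_threshold: float = 1e-10
    # thresholding: none | proportional | consistency
    threshold_mode: str = "none"
    threshold_value: float = 0.3
    # cohort + stats
    n_hc: int = 24
    n_pms: int = 42
    p_enter: float = 0.05
    p_remove: float = 0.10
    alpha: float = 0.05
    m_global: int = 6
    m_nodal: int = 14

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("none", "proportional", "consistency"):
            raise ParameterError(
                f"unknown threshold_mode {self.threshold_mode!r}")
        if self.snr is not None and self.snr <= 0:
            raise ParameterError("snr must be positive")
        if not (self.grid_x > 0 and self.grid_y > 0 and self.grid_z > 0):
            raise ParameterError("grid dims must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shell_bvals", "shell_ndirs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["shell_bvals"] = list(self.shell_bvals)
        data["shell_ndirs"] = list(self.shell_ndirs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(paths: list[str]) -> bool:
    return all(os.path.exists(p) for p in paths)


def run_pipeline(config: PipelineConfig, out_dir: str,
                 resume: bool = False) -> str:
    """Run every stage into ``out_dir`` and write a manifest; returns the
    run directory path."""
    os.makedirs(out_dir, exist_ok=True)
    art = {name: os.path.join(out_dir, name) for name in (
        "dwi.nii.gz", "bvals", "bvecs", "candidates.tck", "truth.csv",
        "labels.nii.gz", "cohort.csv", "weights.csv", "filtered.tck",
        "connectome_raw.csv", "connectome_commit.csv", "metrics.csv",
        "stats.csv", "config.yaml", "manifest.json")}
    grid = (config.grid_x, config.grid_y, config.grid_z)
    vsize = (config.voxel_size,) * 3
    scheme = make_gradient_scheme(
        config.n_b0,
        list(zip(config.shell_bvals, (int(n) for n in config.shell_ndirs))),
        seed=config.seed)

    # the phantom itself is recreated per run (cheap, deterministic);
    # stages communicate through the on-disk artifacts
    phantom, tractogram = two_bundle_phantom(
        seed=config.seed, grid_dims=grid, voxel_size=vsize,
        n_streamlines=config.n_streamlines_per_bundle, lesion=config.lesion)
    tractogram = add_spurious_streamlines(tractogram, phantom,
                                          config.n_spurious, seed=config.seed)

    stage1 = [art["dwi.nii.gz"], art["bvals"], art["bvecs"],
              art["candidates.tck"], art["truth.csv"], art["cohort.csv"]]
    if not (resume and _stage_done(stage1)):
        vol = simulate_dwi(phantom, scheme, snr=config.snr, seed=config.seed)
        write_dwi(art["dwi.nii.gz"], art["bvals"], art["bvecs"], vol, scheme,
                  affine=phantom.affine)
        write_tractogram(art["candidates.tck"], tractogram)
        write_truth_csv(art["truth.csv"], tractogram)
        import nibabel as nib
        nib.save(nib.Nifti1Image(phantom.label_volume.astype(np.int16),
                                 phantom.affine), art["labels.nii.gz"])
        cohort = simulate_cohort(config.n_hc, config.n_pms,
                                 default_effect_spec(), seed=config.seed)
        cohort.to_csv(art["cohort.csv"], index=False, float_format="%.12g")

    stage2 = [art["weights.csv"], art["filtered.tck"]]
    if not (resume and _stage_done(stage2)):
        import nibabel as nib
        vol = np.asarray(nib.load(art["dwi.nii.gz"]).dataobj, dtype=float)
        streamlines = read_tractogram(art["candidates.tck"])
        truth = read_truth_csv(art["truth.csv"])
        tg = Tractogram(
            streamlines,
            truth["true_weight"].to_numpy(),
            truth["spurious"].to_numpy(dtype=bool),
            [None if a < 0 else (int(a), int(b))
             for a, b in zip(truth["node_a"], truth["node_b"])])
        sm = build_system_matrix(tg, grid, vsize, scheme, phantom.params,
                                 phantom.ec_orientation_source())
        res = fit_weights(sm, vol.reshape(-1), max_iter=config.fit_max_iter,
                          tol=config.fit_tol)
        filtered, kept_w = filter_tractogram(tg, res, config.weight_threshold)
        lengths = tg.lengths()
        kept = res.streamline_weights > config.weight_threshold
        write_weights_csv(art["weights.csv"], res.streamline_weights,
                          lengths, kept)
        write_tractogram(art["filtered.tck"], filtered)

    stage3 = [art["connectome_raw.csv"], art["connectome_commit.csv"]]
    if not (resume and _stage_done(stage3)):
        streamlines = read_tractogram(art["candidates.tck"])
        truth = read_truth_csv(art["truth.csv"])
        wdf = read_weights_csv(art["weights.csv"])
        tg = Tractogram(
            streamlines, truth["true_weight"].to_numpy(),
            truth["spurious"].to_numpy(dtype=bool),
            [None if a < 0 else (int(a), int(b))
             for a, b in zip(truth["node_a"], truth["node_b"])])
        parc = smn_parcellation_spec(phantom.label_volume)
        assignments = assign_endpoints(tg, parc, vsize)
        labels = parc.node_labels
        raw = build_raw_connectome(assignments, parc.n_nodes, labels)
        kept = wdf["kept"].to_numpy(dtype=bool)
        masked_w = np.where(kept, wdf["weight"].to_numpy(), 0.0)
        commit = build_commit_connectome(assignments, masked_w,
                                         wdf["length_mm"].to_numpy(),
                                         parc.n_nodes, labels)
        if config.threshold_mode == "proportional":
            raw = proportional_threshold(raw, config.threshold_value)
        write_connectome_csv(art["connectome_raw.csv"], raw)
        write_connectome_csv(art["connectome_commit.csv"], commit)

    if not (resume and _stage_done([art["metrics.csv"]])):
        from .io import read_connectome_csv
        rows = []
        for name in ("connectome_raw.csv", "connectome_commit.csv"):
            c = read_connectome_csv(art[name])
            panel = metric_panel(c, seed=config.seed)
            row = {"connectome": c.kind, **panel.to_row(c.node_labels)}
            rows.append(row)
        pd.DataFrame(rows).to_csv(art["metrics.csv"], index=False,
                                  float_format="%.12g")

    if not (resume and _stage_done([art["stats.csv"]])):
        cohort = pd.read_csv(art["cohort.csv"])
        cfg = BatteryConfig(outcomes=("edss", "nhpt", "t25fw"),
                            alpha=config.alpha, m_global=config.m_global,
                            m_nodal=config.m_nodal, p_enter=config.p_enter,
                            p_remove=config.p_remove)
        analysis_battery(cohort, cfg).to_csv(art["stats.csv"], index=False,
                                             float_format="%.12g")

    config.to_yaml(art["config.yaml"])
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {name: _sha256(path) for name, path in art.items()
                      if os.path.exists(path)
                      and name not in ("manifest.json",)},
    }
    with open(art["manifest.json"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
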
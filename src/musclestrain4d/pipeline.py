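"""End-to-end pipeline orchestration with config, provenance and file handoffs.

Stages (simulate -> denoise -> track -> strain -> dti -> colormap -> voistats)
communicate through files in the run directory, so each stage can be rerun or
tested in isolation.  A manifest records the config hash, package version and
a checksum per stage output; a rerun with the same config and seed reproduces
the deterministic outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, phantom, preproc, kinematics, strain as strain_mod
from . import fiber_dti, viz, voi_stats

__all__ = ["PipelineConfig", "run_pipeline", "phantom_vois"]

log = logging.getLogger("musclestrain4d")

ALL_STAGES = ("simulate", "denoise", "track", "strain", "dti", "colormap",
              "voistats")


@dataclass
class PipelineConfig:
    """Everything a run needs: paths, stage toggles, and stage parameters."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    phantom: dict = field(default_factory=dict)
    force: dict = field(default_factory=dict)
    shading_correction: dict = field(default_factory=lambda: {"poly_order": 2})
    filter: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=lambda: {"ref_frame": 0,
                                                    "scheme": "euler"})
    strain: dict = field(default_factory=lambda: {"finite": False})
    dti: dict = field(default_factory=lambda: {"b_value": 400.0,
                                               "n_directions": 30,
                                               "s0": 1000.0,
                                               "noise_sigma": 20.0})
    vois: str = "auto_phantom"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "voistats" in self.stages and not self.vois:
            raise ValueError("config field 'vois' is required when the "
                             "voistats stage is enabled")

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "seed": self.seed,
            "stages": list(self.stages), "phantom": self.phantom,
            "force": self.force,
            "shading_correction": self.shading_correction,
            "filter": self.filter, "tracking": self.tracking,
            "strain": self.strain, "dti": self.dti, "vois": self.vois,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def phantom_vois(spec: phantom.PhantomSpec) -> list[voi_stats.Voi]:
    """Agonist/antagonist VOIs at the phantom region centroids."""
    vois = []
    for label, name, group in ((phantom.AGONIST, "agonist", "quadriceps"),
                               (phantom.ANTAGONIST, "antagonist", "hamstrings")):
        center = spec.region_center(label)
        vois.append(voi_stats.build_voi(
            name, tuple(center), spacing=spec.spacing,
            grid_shape=spec.grid_shape, group=group,
        ))
    return vois


def _load_vois(config: PipelineConfig, spec: phantom.PhantomSpec):
    if config.vois == "auto_phantom":
        return phantom_vois(spec)
    with open(config.vois) as fh:
        entries = yaml.safe_load(fh)
    return [
        voi_stats.build_voi(
            e["muscle"], tuple(e["center_mm"]),
            box_mm=tuple(e.get("box_mm", (9.38, 28.13))),
            n_slices=int(e.get("n_slices", 5)),
            spacing=spec.spacing, grid_shape=spec.grid_shape,
            group=e.get("group", ""),
        )
        for e in entries
    ]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure aborts with the stage name in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    spec = phantom.PhantomSpec(**{"seed": config.seed, **config.phantom})
    force = phantom.make_force_trace(
        n_frames=spec.n_frames, period=spec.period, **config.force
    )

    state: dict = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in paths}
        }
        log.info("stage %s complete (%d outputs)", stage, len(paths))

    try:
        if "simulate" in config.stages:
            stage = "simulate"
            series, gt = phantom.synthesize_velocity_series(spec, force)
            state["series"], state["gt"] = series, gt
            io.save_velocity_series(out / "series", series)
            io.save_volume(out / "labels.nii.gz", gt.labels.astype(np.uint8),
                           spec.spacing)
            io.save_force_trace(out / "force.csv", force)
            sidecar = {
                "spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in vars(spec).items()},
                "files": {"series": "series/", "labels": "labels.nii.gz",
                          "force": "force.csv"},
            }
            (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
            record(stage, out / "labels.nii.gz", out / "force.csv",
                   out / "phantom.json")
        else:
            state["series"] = io.load_velocity_series(out / "series")
            labels, _ = io.load_volume(out / "labels.nii.gz")
            state["labels"] = labels.astype(int)

        if "denoise" in config.stages:
            stage = "denoise"
            series = state["series"]
            labels = state["gt"].labels if "gt" in state else state["labels"]
            static = preproc_static_mask(labels)
            series = preproc.correct_series_shading(
                series, static, **config.shading_correction
            )
            params = preproc.DiffusionFilterParams(**config.filter)
            series = preproc.denoise_series(series, params)
            state["series"] = series
            io.save_velocity_series(out / "series_denoised", series)
            record(stage, out / "series_denoised" / "velocity.nii.gz")

        if "track" in config.stages:
            stage = "track"
            disp = kinematics.track_voxels(state["series"], **config.tracking)
            state["disp"] = disp
            io.save_volume(
                out / "displacement.nii.gz",
                np.transpose(disp.displacement, (2, 3, 4, 0, 1)),
                disp.spacing, descrip="displacement [mm]",
            )
            record(stage, out / "displacement.nii.gz")

        if "strain" in config.stages:
            stage = "strain"
            fields = strain_mod.compute_strain_series(
                state["disp"], **config.strain
            )
            state["strain"] = fields
            peak = voi_stats.peak_force_frame(force)
            f = fields[peak]
            for name, vol in (
                ("l_lambda1", f.eigenvalues[..., 0]),
                ("l_lambda2", f.eigenvalues[..., 1]),
                ("l_lambda3", f.eigenvalues[..., 2]),
                ("l_max", f.l_max), ("l_vol", f.l_vol),
                ("ev1", f.eigenvectors[..., :, 0]),
            ):
                io.save_volume(out / f"strain_{name}_peak.nii.gz", vol,
                               state["disp"].spacing)
            record(stage, *(out.glob("strain_*_peak.nii.gz")))

        if "dti" in config.stages:
            stage = "dti"
            dwi = phantom.synthesize_dwi(spec, **config.dti)
            tensors = fiber_dti.fit_dti_wls(dwi)
            state["tensors"] = tensors
            io.save_dwi(out / "dwi", dwi)
            io.save_volume(out / "dti_fa.nii.gz", tensors.fa, spec.spacing)
            io.save_volume(out / "dti_v1.nii.gz", tensors.lead_eigenvector,
                           spec.spacing)
            record(stage, out / "dti_fa.nii.gz", out / "dti_v1.nii.gz")

        if "colormap" in config.stages:
            stage = "colormap"
            labels = state["gt"].labels if "gt" in state else state["labels"]
            mask = labels > 0
            peak = voi_stats.peak_force_frame(force)
            f = state["strain"][peak]
            strain_rgb = viz.eigenvector_colormap(
                f.eigenvectors[..., :, 0], mask & f.valid_mask,
                source="strain compression eigenvector",
            )
            io.save_volume(out / "strain_dec.nii.gz", strain_rgb.rgb,
                           spec.spacing)
            outputs = [out / "strain_dec.nii.gz"]
            if "tensors" in state:
                dti_rgb = viz.eigenvector_colormap(
                    state["tensors"].lead_eigenvector, mask,
                    weight=state["tensors"].fa, source="DTI lead eigenvector",
                )
                io.save_volume(out / "dti_dec.nii.gz", dti_rgb.rgb,
                               spec.spacing)
                outputs.append(out / "dti_dec.nii.gz")
            record(stage, *outputs)

        if "voistats" in config.stages:
            stage = "voistats"
            vois = _load_vois(config, spec)
            peak = voi_stats.peak_force_frame(force)
            rows = []
            for voi in vois:
                row = voi_stats.extract_voi_indices(
                    state["strain"], voi, peak, subject_id="phantom",
                    pct_mvc=force.pct_mvc,
                )
                if row is not None:
                    rows.append(row)
            table = pd.DataFrame(rows)
            table.to_csv(out / "voi_table.csv", index=False)
            outputs = [out / "voi_table.csv"]
            if set(table.group) >= {"quadriceps", "hamstrings"}:
                ratio = voi_stats.coactivation_ratio(table)
                ratio.to_csv(out / "coactivation.csv", index=False)
                outputs.append(out / "coactivation.csv")
            record(stage, *outputs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def preproc_static_mask(labels: np.ndarray, margin: int = 3) -> np.ndarray:
    """Background voxels safely away from moving tissue (for shading fits)."""
    from scipy.ndimage import binary_dilation

    moving = np.asarray(labels) > 0
    return ~binary_dilation(moving, iterations=margin)
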
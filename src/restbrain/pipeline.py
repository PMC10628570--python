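"""End-to-end pipeline orchestration from a single YAML config.

A run generates (or loads) every input, executes the enabled stages in
dependency order — brain extraction, ReHo, DTI, QSM, group statistics —
and writes each output NIfTI with a JSON sidecar recording the stage
parameters, package version, and seed. One global seed fans out to
per-stage seeds by stable hashing, so stochastic stages reproduce
bit-identically when the config and seed are unchanged.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, brain_extraction, cluster_stats, dti, phantoms, qsm, reho
from .volgrid import BoldSeries, MaskVolume, Volume, gaussian_smooth, read_volume, write_volume

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("bet", "reho", "dti", "qsm", "groupstats")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Validated run configuration.

    ``simulate`` maps phantom names to generator kwargs; ``inputs`` maps
    logical names to existing file paths; ``stages`` enables pipeline
    stages; ``params`` carries per-stage parameter blocks.
    """

    outdir: Path
    seed: int = 0
    simulate: dict[str, dict] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate", {}) or {},
            inputs=raw.get("inputs", {}) or {},
            stages=list(raw.get("stages", _STAGES)),
            params=raw.get("params", {}) or {},
        )
        for st in cfg.stages:
            if st not in _STAGES:
                raise ValueError(f"unknown stage '{st}' (allowed: {_STAGES})")
        # validate referenced files before any compute
        for name, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input '{name}' missing: {p}")
        return cfg


def _sidecar(path: Path, stage: str, seed: int, params: dict) -> None:
    meta = {"stage": stage, "seed": seed, "version": __version__,
            "params": {k: v for k, v in params.items()
                       if isinstance(v, (int, float, str, bool, list, tuple, type(None)))}}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def _write(vol, path: Path, stage: str, seed: int, params: dict,
           manifest: dict[str, str]) -> None:
    if path.exists():
        raise FileExistsError(f"output exists (write-once per run): {path}")
    write_volume(vol, path)
    _sidecar(path, stage, seed, params)
    manifest[path.stem.replace(".nii", "")] = str(path)


def run_pipeline(cfg: RunConfig | str | Path) -> dict[str, str]:
    """Execute the configured stages; returns a manifest of written outputs."""
    if not isinstance(cfg, RunConfig):
        cfg = RunConfig.from_yaml(cfg)
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    bundles: dict[str, phantoms.PhantomBundle] = {}
    sim_seed = stage_seed(cfg.seed, "simulate")
    generators = {
        "structural": phantoms.make_structural_phantom,
        "bold": phantoms.make_bold_phantom,
        "dwi": phantoms.make_dwi_phantom,
        "qsm": phantoms.make_susceptibility_phantom,
        "groups": phantoms.make_group_maps,
    }
    for name, kwargs in cfg.simulate.items():
        if name not in generators:
            raise ValueError(f"unknown phantom '{name}'")
        kw = dict(kwargs or {})
        kw.setdefault("seed", stage_seed(sim_seed, name))
        for key in ("shape", "shape_xyz", "spacing"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        bundles[name] = generators[name](**kw)

    loaded: dict[str, Any] = {}
    for name, p in cfg.inputs.items():
        loaded[name] = read_volume(p)

    def _stage_fail(stage: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"stage '{stage}' failed: {exc}")

    mask_vol: MaskVolume | None = None

    if "bet" in cfg.stages:
        stage, seed = "bet", stage_seed(cfg.seed, "bet")
        try:
            vol = loaded.get("structural") or (bundles["structural"].volumes["structural"]
                                               if "structural" in bundles else None)
            if vol is None:
                raise ValueError("no structural input")
            p = brain_extraction.BETParams(**cfg.params.get("bet", {}))
            mask_vol = brain_extraction.extract_brain(vol, p)
            _write(mask_vol, out / "mask.nii.gz", stage, seed, cfg.params.get("bet", {}), manifest)
        except Exception as exc:
            raise _stage_fail(stage, exc) from exc

    if "reho" in cfg.stages:
        stage, seed = "reho", stage_seed(cfg.seed, "reho")
        try:
            series = loaded.get("bold") or bundles["bold"].volumes["bold"]
            rp = dict(cfg.params.get("reho", {}))
            rcfg = reho.RehoConfig(
                neighborhood=rp.get("neighborhood", 27),
                band_hz=tuple(rp.get("band_hz", (0.01, 0.08))),
                smooth_fwhm_mm=rp.get("smooth_fwhm_mm", 6.0))
            rmask = MaskVolume(np.ones(series.data.shape[:3], np.uint8),
                               series.spacing, series.affine.copy())
            filtered = reho.bandpass_filter(series, rcfg.band_hz)
            rmap = reho.reho_map(filtered, rmask, rcfg)
            rmap = reho.standardize_reho(rmap, rmask)
            rmap = gaussian_smooth(rmap, rcfg.smooth_fwhm_mm)
            _write(rmap, out / "reho.nii.gz", stage, seed, rp, manifest)
        except Exception as exc:
            raise _stage_fail(stage, exc) from exc

    if "dti" in cfg.stages:
        stage, seed = "dti", stage_seed(cfg.seed, "dti")
        try:
            bundle = bundles.get("dwi")
            if bundle is not None:
                series = bundle.volumes["dwi"]
                scheme = bundle.params["scheme"]
            else:
                series = loaded["dwi"]
                scheme = dti.read_scheme(cfg.inputs["bvec"], cfg.inputs["bval"])
            tf = dti.fit_tensor(series.data, scheme,
                                spacing=series.spacing, affine=series.affine)
            fa, md = dti.tensor_scalars(tf)
            dp = cfg.params.get("dti", {})
            _write(fa, out / "fa.nii.gz", stage, seed, dp, manifest)
            _write(md, out / "md.nii.gz", stage, seed, dp, manifest)
        except Exception as exc:
            raise _stage_fail(stage, exc) from exc

    if "qsm" in cfg.stages:
        stage, seed = "qsm", stage_seed(cfg.seed, "qsm")
        try:
            qp = dict(cfg.params.get("qsm", {}))
            bundle = bundles.get("qsm")
            if bundle is not None:
                wrapped = bundle.volumes["wrapped_phase"]
                qmask = bundle.truth["mask"]
                qp.setdefault("field_scale", bundle.truth["field_scale"])
            else:
                wrapped = loaded["phase"]
                qmask = MaskVolume(loaded["qsm_mask"].data.astype(np.uint8) if "qsm_mask" in loaded
                                   else np.ones(wrapped.data.shape, np.uint8),
                                   wrapped.spacing, wrapped.affine.copy())
            pv = qsm.PhaseVolume(wrapped.data, wrapped.spacing, wrapped=True)
            unwrapped = qsm.laplacian_unwrap(pv)
            nh = qsm.smv_background_remove(unwrapped, qmask)
            chi = qsm.invert_susceptibility(
                nh, qmask, lam=qp.get("lam", 0.0),
                field_scale=qp.get("field_scale", 1.0))
            _write(Volume(chi.data, wrapped.spacing, wrapped.affine.copy(), "ppm"),
                   out / "chi.nii.gz", stage, seed, qp, manifest)
        except Exception as exc:
            raise _stage_fail(stage, exc) from exc

    if "groupstats" in cfg.stages:
        stage, seed = "groupstats", stage_seed(cfg.seed, "groupstats")
        try:
            gp = dict(cfg.params.get("groupstats", {}))
            bundle = bundles["groups"]
            gmask = bundle.truth["mask"]
            stat = cluster_stats.voxelwise_ttest(bundle.volumes["group_a"],
                                                 bundle.volumes["group_b"], gmask)
            extent = cluster_stats.alphasim_threshold(
                gmask, fwhm_mm=gp.get("fwhm_mm", 6.0),
                voxel_p=gp.get("voxel_p", 0.005), alpha=gp.get("alpha", 0.05),
                n_iter=gp.get("n_iter", 1000), seed=seed)
            table = cluster_stats.report_clusters(stat, gp.get("voxel_p", 0.005), extent)
            path = out / "clusters.tsv"
            if path.exists():
                raise FileExistsError(f"output exists (write-once per run): {path}")
            table.to_tsv(path)
            _sidecar(path, stage, seed, {**gp, "min_extent": extent})
            manifest["clusters"] = str(path)
        except Exception as exc:
            raise _stage_fail(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(
        {"seed": cfg.seed, "version": __version__, "outputs": manifest}, indent=2))
    return manifest
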
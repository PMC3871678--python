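"""Experiment orchestration: configuration, the full Monte Carlo pipeline,
and reproducible result bundles.

A single master seed drives every random draw through a documented
per-stage offset scheme (see :func:`stage_seed`), so any stage can be rerun
in isolation and two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import forward as fwd
from .geometry import HeadModel, build_cortical_surface, icosphere_vertex_count
from .metrics import (
    ScaleCurve,
    SensorStats,
    compute_ctf,
    correlation_distance,
    propagate,
    resolvable_scale,
)
from .montage import build_montage
from .patterns import SCALE_SEED_COUNTS, ScaleSpec, generate_ensemble

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "stage_seed"]

# fixed per-stage offsets; every RNG seed is (master * 100003 + offset + index) mod 2^31
_STAGE_OFFSETS = {"surface": 11, "seed_pick": 23, "ensemble": 41}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-seed for one pipeline stage."""
    return (master_seed * 100003 + _STAGE_OFFSETS[stage] * 9973 + index) % (2**31)


@dataclass
class ExperimentConfig:
    """Complete description of one Monte Carlo experiment."""

    master_seed: int = 0
    mesh_level: int = 5
    target_area: float = 1100.0
    fold_band: tuple[int, int] = (12, 24)
    fold_amplitude: float | None = None  # None -> auto-calibrated to target_area
    cortex_mean_radius: float = 6.2
    center_offset: float = 0.0
    medial_cap_deg: float = 15.0
    symmetric_folds: bool = False
    n_instances: int = 200
    scales: tuple[int, ...] = SCALE_SEED_COUNTS
    r_threshold: float = 0.5
    r_mode: str = "absolute"
    spline_p: float = 0.95
    sd_rule: str = "at_minimum"
    modalities: tuple[str, ...] = ("eeg", "meg_mag", "meg_grad", "dot", "fmri")
    eeg: dict = field(default_factory=lambda: {"n": 286, "cap_deg": 120.0})
    meg: dict = field(
        default_factory=lambda: {
            "n_sites": 102,
            "cap_deg": 110.0,
            "helmet_offset": 2.5,
            "baseline": 1.68,
        }
    )
    dot: dict = field(
        default_factory=lambda: {
            "cap_deg": 120.0,
            "row_spacing": 2.2,
            "in_row_spacing": 2.2,
            "pair_window": (2.0, 3.0),
        }
    )
    fmri: dict = field(
        default_factory=lambda: {
            "voxel_size": 0.3,
            "min_nodes": 4,
            "min_gm_fraction": 0.5,
            "cortical_thickness": 0.3,
            "z_range": None,
        }
    )
    head: dict = field(default_factory=dict)  # HeadModel overrides
    out_dir: str | None = None

    @classmethod
    def fast(cls, **overrides) -> "ExperimentConfig":
        """CI-sized profile: ico5 mesh, K=200, the 7 largest spatial scales.

        The fMRI voxel filter is density-matched to the coarser mesh
        (min_nodes=2: ico5 carries a quarter of the ico6 node density) and
        restricted to a slab around z = 1.9 cm, the single-slice analysis
        mode."""
        cfg = cls(
            mesh_level=5,
            n_instances=200,
            scales=SCALE_SEED_COUNTS[:7],
            fmri={
                "voxel_size": 0.3,
                "min_nodes": 2,
                "min_gm_fraction": 0.5,
                "cortical_thickness": 0.3,
                "z_range": (1.6, 2.2),
            },
        )
        return dataclasses.replace(cfg, **overrides)

    @classmethod
    def paper(cls, **overrides) -> "ExperimentConfig":
        """Full-resolution profile: ico6 mesh, K=1000, all nine scales,
        fMRI in single-slice mode around z = 1.9 cm."""
        cfg = cls(
            mesh_level=6,
            n_instances=1000,
            scales=SCALE_SEED_COUNTS,
            fmri={
                "voxel_size": 0.3,
                "min_nodes": 4,
                "min_gm_fraction": 0.5,
                "cortical_thickness": 0.3,
                "z_range": (1.75, 2.05),
            },
        )
        return dataclasses.replace(cfg, **overrides)

    def validate(self) -> None:
        n_hemi = icosphere_vertex_count(self.mesh_level)
        bad = [s for s in self.scales if s > n_hemi]
        if bad:
            raise ValueError(
                f"scales {bad} exceed the {n_hemi}-node hemisphere at mesh_level {self.mesh_level}"
            )
        unknown = [m for m in self.modalities if m not in ("eeg", "meg_mag", "meg_grad", "dot", "fmri")]
        if unknown:
            raise ValueError(f"unknown modalities {unknown}")
        if self.n_instances < 3:
            raise ValueError("n_instances must be >= 3")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fold_band"] = list(self.fold_band)
        d["scales"] = list(self.scales)
        d["modalities"] = list(self.modalities)
        if d["dot"].get("pair_window") is not None:
            d["dot"]["pair_window"] = list(d["dot"]["pair_window"])
        if d["fmri"].get("z_range") is not None:
            d["fmri"]["z_range"] = list(d["fmri"]["z_range"])
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        d = dict(d)
        for key, caster in (("fold_band", tuple), ("scales", tuple), ("modalities", tuple)):
            if key in d and d[key] is not None:
                d[key] = caster(d[key])
        if "dot" in d and d["dot"].get("pair_window") is not None:
            d["dot"] = {**d["dot"], "pair_window": tuple(d["dot"]["pair_window"])}
        if "fmri" in d and d["fmri"].get("z_range") is not None:
            d["fmri"] = {**d["fmri"], "z_range": tuple(d["fmri"]["z_range"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    scale_specs: list[ScaleSpec]
    stats: dict[str, dict[float, SensorStats]]  # modality -> scale_area -> stats
    curves: dict[str, ScaleCurve]
    surface_info: dict
    montage_info: dict

    def summary_frame(self):
        import pandas as pd

        rows = []
        for mod, per_scale in self.stats.items():
            for area, st in sorted(per_scale.items()):
                rows.append(
                    {
                        "modality": mod,
                        "scale_area_cm2": area,
                        "ctf_mean": st.ctf_mean,
                        "corr_distance_mean_cm": st.corr_distance_mean,
                        "corr_distance_sd_cm": st.corr_distance_sd,
                        "n_instances": st.n_instances,
                    }
                )
        return pd.DataFrame(rows)

    def resolvable_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "modality": mod,
                    "resolvable_scale_cm2": c.resolvable_scale,
                    "defined": c.defined,
                    "threshold_cm": c.threshold,
                }
                for mod, c in self.curves.items()
            ],
            columns=["modality", "resolvable_scale_cm2", "defined", "threshold_cm"],
        )


def _stage_path(stage_dir: Path, cfg: ExperimentConfig, count: int) -> Path:
    return stage_dir / f"scale_{count}_{cfg.config_hash()}.json"


def _save_stage(stage_dir: Path, cfg: ExperimentConfig, count: int, per_mod: dict) -> None:
    payload = {}
    for mod, st in per_mod.items():
        payload[mod] = {
            "scale_area": st.scale_area,
            "ctf_per_sensor": st.ctf_per_sensor.tolist(),
            "ctf_mean": st.ctf_mean,
            "corr_distance_per_sensor": st.corr_distance_per_sensor.tolist(),
            "corr_distance_mean": st.corr_distance_mean,
            "corr_distance_sd": st.corr_distance_sd,
            "rms_x": st.rms_x,
            "n_instances": st.n_instances,
            "degenerate_channels": st.degenerate_channels.tolist(),
        }
    _stage_path(stage_dir, cfg, count).write_text(json.dumps(payload))


def _load_stage(stage_dir: Path, cfg: ExperimentConfig, count: int) -> dict | None:
    p = _stage_path(stage_dir, cfg, count)
    if not p.exists():
        return None
    raw = json.loads(p.read_text())
    if set(raw) != set(cfg.modalities):
        return None
    out = {}
    for mod, d in raw.items():
        out[mod] = SensorStats(
            modality=mod,
            scale_area=d["scale_area"],
            ctf_per_sensor=np.array(d["ctf_per_sensor"]),
            ctf_mean=d["ctf_mean"],
            corr_distance_per_sensor=np.array(d["corr_distance_per_sensor"]),
            corr_distance_mean=d["corr_distance_mean"],
            corr_distance_sd=d["corr_distance_sd"],
            rms_x=d["rms_x"],
            n_instances=d["n_instances"],
            degenerate_channels=np.array(d["degenerate_channels"], dtype=np.int64),
        )
    return out


def _build_forward_models(cfg: ExperimentConfig, surface, head) -> dict[str, fwd.ForwardModel]:
    models: dict[str, fwd.ForwardModel] = {}
    for mod in cfg.modalities:
        if mod == "eeg":
            m = fwd.eeg_leadfield(surface, build_montage("eeg", head, **cfg.eeg), head)
        elif mod == "meg_mag":
            m = fwd.meg_leadfield(surface, build_montage("meg_mag", head, **cfg.meg), head)
        elif mod == "meg_grad":
            m = fwd.meg_leadfield(surface, build_montage("meg_grad", head, **cfg.meg), head)
        elif mod == "dot":
            m = fwd.dot_sensitivity(surface, build_montage("dot", head, **cfg.dot), head)
        elif mod == "fmri":
            m = fwd.fmri_voxel_model(surface, **cfg.fmri)
        models[mod] = fwd.normalize_rows(m)
    return models


def run_experiment(
    cfg: ExperimentConfig,
    progress: bool = False,
    keep_correlation_matrices: bool = False,
) -> ExperimentResult:
    """Run the full pipeline: geometry, montages, forward models, ensembles,
    propagation and all summary statistics."""
    cfg.validate()
    head = HeadModel(cortex_mean_radius=cfg.cortex_mean_radius, fold_band=cfg.fold_band, **cfg.head)
    surface = build_cortical_surface(
        mesh_level=cfg.mesh_level,
        fold_amplitude=cfg.fold_amplitude,
        fold_band=cfg.fold_band,
        target_area=cfg.target_area,
        mean_radius=cfg.cortex_mean_radius,
        seed=stage_seed(cfg.master_seed, "surface"),
        symmetric=cfg.symmetric_folds,
        medial_cap_deg=cfg.medial_cap_deg,
        center_offset=cfg.center_offset,
    )
    head = dataclasses.replace(head, fold_amplitude=surface.fold_amplitude)
    head.validate()
    models = _build_forward_models(cfg, surface, head)

    stage_dir = None
    if cfg.out_dir:
        stage_dir = Path(cfg.out_dir) / "stages"
        stage_dir.mkdir(parents=True, exist_ok=True)

    stats: dict[str, dict[float, SensorStats]] = {m: {} for m in cfg.modalities}
    specs: list[ScaleSpec] = []
    for si, count in enumerate(sorted(cfg.scales)):
        spec = ScaleSpec.from_surface(count, surface)
        specs.append(spec)
        if stage_dir is not None:
            cached = _load_stage(stage_dir, cfg, count)
            if cached is not None:
                for mod in cfg.modalities:
                    stats[mod][spec.estimated_area] = cached[mod]
                if progress:
                    print(f"scale {spec.estimated_area:9.3f} cm^2 ({count} seeds) resumed from cache")
                continue
        ens = generate_ensemble(
            spec, surface, cfg.n_instances, seed=stage_seed(cfg.master_seed, "ensemble", si)
        )
        for mod, model in models.items():
            y = propagate(model, ens)
            ctf, ctf_mean = compute_ctf(y, ens, surface.cortical_mask)
            cd = correlation_distance(
                y, model.montage, r_threshold=cfg.r_threshold, r_mode=cfg.r_mode, return_matrix=keep_correlation_matrices
            )
            stats[mod][spec.estimated_area] = SensorStats(
                modality=mod,
                scale_area=spec.estimated_area,
                ctf_per_sensor=ctf,
                ctf_mean=ctf_mean,
                corr_distance_per_sensor=cd["per_sensor"],
                corr_distance_mean=cd["mean"],
                corr_distance_sd=cd["sd"],
                rms_x=ens.rms(surface.cortical_mask),
                n_instances=cfg.n_instances,
                correlation_matrix=cd["correlation_matrix"],
                degenerate_channels=cd["degenerate_channels"],
            )
        if stage_dir is not None:
            _save_stage(stage_dir, cfg, count, {m: stats[m][spec.estimated_area] for m in cfg.modalities})
        if progress:
            print(f"scale {spec.estimated_area:9.3f} cm^2 ({count} seeds) done", flush=True)

    curves: dict[str, ScaleCurve] = {}
    for mod in cfg.modalities:
        areas = np.array(sorted(stats[mod]))
        if len(areas) >= 5:
            curves[mod] = resolvable_scale(
                areas,
                np.array([stats[mod][a].corr_distance_mean for a in areas]),
                np.array([stats[mod][a].corr_distance_sd for a in areas]),
                modality=mod,
                p=cfg.spline_p,
                sd_rule=cfg.sd_rule,
            )

    result = ExperimentResult(
        config=cfg,
        scale_specs=specs,
        stats=stats,
        curves=curves,
        surface_info={
            "n_nodes": surface.n_nodes,
            "fold_amplitude": surface.fold_amplitude,
            "hemisphere_area_lh": surface.hemisphere_area(0),
            "hemisphere_area_rh": surface.hemisphere_area(1),
            "cortical_area_per_hemisphere": surface.cortical_area_per_hemisphere,
        },
        montage_info={
            m: {"n_channels": models[m].n_channels, "min_separation": models[m].montage.min_separation}
            for m in models
        },
    )
    if cfg.out_dir:
        write_results(result, Path(cfg.out_dir), models=models, surface=surface)
    return result


def write_results(
    result: ExperimentResult,
    out_dir: Path,
    models: dict | None = None,
    surface=None,
    store_gains: bool = False,
) -> None:
    """Write tidy CSV tables, per-sensor CSVs, an HDF5 bundle and provenance."""
    import h5py
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.summary_frame().to_csv(out_dir / "summary.csv", index=False)
    result.resolvable_frame().to_csv(out_dir / "resolvable_scales.csv", index=False)
    for mod, per_scale in result.stats.items():
        rows = []
        for area, st in sorted(per_scale.items()):
            mont = models[mod].montage if models else None
            for i in range(len(st.ctf_per_sensor)):
                rows.append(
                    {
                        "channel": mont.channel_ids[i] if mont else i,
                        "scale_area_cm2": area,
                        "ctf": st.ctf_per_sensor[i],
                        "corr_distance_cm": st.corr_distance_per_sensor[i],
                    }
                )
        df = pd.DataFrame(rows)
        if models is not None:
            foc = models[mod].focality()
            df["focal_sources_pct"] = df["channel"].map(
                dict(zip(models[mod].montage.channel_ids, foc))
                if models
                else {}
            )
        df.to_csv(out_dir / f"per_sensor_{mod}.csv", index=False)

    with h5py.File(out_dir / "bundle.h5", "w") as h5:
        h5.attrs["config"] = result.config.to_yaml()
        h5.attrs["config_hash"] = result.config.config_hash()
        if surface is not None:
            g = h5.create_group("surface")
            g.create_dataset("node_positions", data=surface.node_positions)
            g.create_dataset("node_normals", data=surface.node_normals)
            g.create_dataset("node_areas", data=surface.node_areas)
            g.create_dataset("sphere_map", data=surface.sphere_map)
            g.create_dataset("hemisphere_label", data=surface.hemisphere_label)
            g.create_dataset("cortical_mask", data=surface.cortical_mask)
        for mod, per_scale in result.stats.items():
            g = h5.create_group(f"stats/{mod}")
            areas = sorted(per_scale)
            g.create_dataset("scale_areas", data=np.array(areas))
            g.create_dataset("ctf_mean", data=np.array([per_scale[a].ctf_mean for a in areas]))
            g.create_dataset(
                "corr_distance_mean", data=np.array([per_scale[a].corr_distance_mean for a in areas])
            )
            g.create_dataset(
                "corr_distance_sd", data=np.array([per_scale[a].corr_distance_sd for a in areas])
            )
        if models is not None and store_gains:
            for mod, model in models.items():
                gains = model.gains.toarray() if hasattr(model.gains, "toarray") else model.gains
                h5.create_dataset(f"gains/{mod}", data=gains)

    provenance = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "surface": result.surface_info,
        "montages": result.montage_info,
        "versions": _library_versions(),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))


def _library_versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("numpy", "scipy", "pandas", "h5py", "neuroscale"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
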
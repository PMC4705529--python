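"""End-to-end orchestration: config-driven scene analysis.

A :class:`PipelineConfig` parsed from a single YAML file drives the whole
chain: simulate a treatment panel, preprocess, segment, compute the object
feature table, pixel colocalization, PCA with optional gates, and
(independently) the LFQ differential-expression chain. Every artefact is
written with a JSON provenance block (config hash, seed, versions), and a
rerun with the same config reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import lfq as clfq
from .coloc import coloc_stats
from .features import FeatureTable, compute_feature_table
from .multivar import PcaResult, ScoreGate, gate_scores, run_pca
from .preprocess import deconvolve_rl_tv, make_gaussian_psf, register_translational
from .scene import PsfParams, PunctaClassConfig, SceneConfig, render_treatment_panel
from .segment import label_objects, mesh_from_mask, threshold_channel

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def default_treatment_effects() -> dict:
    """Qualitative treatment signatures the analysis should recover.

    Endotoxin (LPS) drives scaffold aggregation and particle growth; the
    NOD1 ligand (iE-DAP) drives perinuclear relocation and strong
    co-localization with the autophagosome marker. Magnitudes are chosen
    for detectability at the desk-scale default scene size.
    """
    big = (PunctaClassConfig("NALP3", radius_mean_nm=330.0,
                             intensity_mean=60000.0, intensity_sd=6000.0),
           PunctaClassConfig("LC3"))
    return {
        "n.t.": {},
        "LPS": {"aggregation": 0.7, "classes": big},
        "iE-DAP": {"perinuclear_bias": 1.0,
                   "coloc": ((("NALP3", "LC3"), 1.0),)},
    }


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full pipeline run."""

    scene: SceneConfig = SceneConfig()
    treatments: dict = field(default_factory=default_treatment_effects)
    pairing: dict = field(default_factory=lambda: {"NALP3": "LC3",
                                                   "LC3": "NALP3"})
    register: bool = False
    deconvolve: bool = True
    rl_iterations: int = 50
    tv_lambda: float = 0.002
    connectivity: int = 26
    min_voxels: int = 5
    pca_attributes: tuple | None = None
    gates: tuple = ()
    lfq: dict = field(default_factory=lambda: {
        "n_proteins": 2000, "n_per_group": 3, "de_fraction": 0.05,
        "effect_log2": 2.0, "missing_rate": 0.1,
    })
    output_dir: str = "cocompart_out"
    seed: int = 0

    def __post_init__(self) -> None:
        classes = {c.name for c in self.scene.classes}
        for cls, partner in self.pairing.items():
            if cls not in classes or partner not in classes:
                raise ConfigError(
                    f"pairing {cls!r} -> {partner!r} references classes "
                    f"outside {sorted(classes)}"
                )
            if cls == partner:
                raise ConfigError(f"class {cls!r} cannot be its own partner")


_SCENE_FIELDS = {f.name for f in dataclasses.fields(SceneConfig)}
_PIPE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def _scene_from_dict(d: dict) -> SceneConfig:
    unknown = set(d) - _SCENE_FIELDS
    if unknown:
        raise ConfigError(f"unknown scene keys: {sorted(unknown)}")
    d = dict(d)
    if "classes" in d:
        d["classes"] = tuple(PunctaClassConfig(**c) for c in d["classes"])
    if "coloc" in d:
        d["coloc"] = tuple(
            ((p["a"], p["b"]), p["fraction"]) for p in d["coloc"]
        )
    if d.get("psf") is not None and "psf" in d:
        d["psf"] = PsfParams(**d["psf"])
    for key in ("shape", "voxel_size_nm", "cell_axes_nm", "nucleus_axes_nm"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneConfig(**d)


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _PIPE_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "scene" in kwargs:
        kwargs["scene"] = _scene_from_dict(kwargs["scene"])
    if "treatments" in kwargs:
        for t, ov in kwargs["treatments"].items():
            if "coloc" in ov:
                ov["coloc"] = tuple(
                    ((p["a"], p["b"]), p["fraction"]) for p in ov["coloc"]
                )
    if "gates" in kwargs:
        kwargs["gates"] = tuple(ScoreGate(**g) for g in kwargs["gates"])
    if "pca_attributes" in kwargs and kwargs["pca_attributes"] is not None:
        kwargs["pca_attributes"] = tuple(kwargs["pca_attributes"])
    return PipelineConfig(**kwargs)


def analyze_scene(
    channels: dict,
    treatment: str,
    pairing: dict[str, str],
    config: PipelineConfig | None = None,
    scene_id: str = "",
) -> tuple[FeatureTable, dict]:
    """Segment one scene's channels and compute its feature table.

    Returns the table and per-pair pixel colocalization statistics computed
    inside the cell mask.
    """
    cfg = config or PipelineConfig()
    cell_mask = channels["cellmask"].data > 0
    nucleus_stack = channels["nucleus"]
    nucleus_mask = threshold_channel(nucleus_stack, method="fixed", value=0.0)
    vsz = nucleus_stack.voxel_size_nm

    stacks = {}
    for name, stack in channels.items():
        if name in ("nucleus", "cellmask"):
            continue
        if cfg.register:
            stack, _ = register_translational(stack)
        stacks[name] = stack
    if cfg.deconvolve and cfg.scene.psf is not None:
        psf = make_gaussian_psf(cfg.scene.psf.na, cfg.scene.psf.wavelength_nm,
                                cfg.scene.psf.refractive_index, vsz)
        deconvolved = {
            n: deconvolve_rl_tv(s, psf, iterations=cfg.rl_iterations,
                                tv_lambda=cfg.tv_lambda)
            for n, s in stacks.items()
        }
    else:
        deconvolved = stacks

    labels = {}
    for name, stack in deconvolved.items():
        mask = threshold_channel(stack, method="otsu", within_mask=cell_mask)
        labels[name] = label_objects(mask, connectivity=cfg.connectivity,
                                     min_voxels=cfg.min_voxels, channel=name)
    nucleus_mesh = mesh_from_mask(nucleus_mask, vsz, role="nucleus")
    cell_mesh = mesh_from_mask(cell_mask, vsz, role="membrane")
    # intensities measured on the registered, non-deconvolved stacks
    table = compute_feature_table(labels, stacks, nucleus_mesh, cell_mesh,
                                  pairing, treatment=treatment,
                                  scene_id=scene_id)
    coloc = {}
    seen = set()
    for cls, partner in pairing.items():
        key = tuple(sorted((cls, partner)))
        if key in seen:
            continue
        seen.add(key)
        coloc[f"{key[0]}|{key[1]}"] = coloc_stats(
            stacks[key[0]].data, stacks[key[1]].data, mask=cell_mask
        )
    return table, coloc


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    pca: PcaResult
    coloc: dict
    de: clfq.DEResult
    gated: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write all artefacts under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _config_to_dict(config)

    base = dataclasses.replace(config.scene, seed=config.seed)
    panel = render_treatment_panel(base, dict(config.treatments))
    tables, coloc_all = [], {}
    for treatment, channels, gt in panel:
        scene_id = f"scene_{treatment.replace('.', '').replace(' ', '_')}"
        cio.write_scene_tiff(out / f"{scene_id}.ome.tif", channels)
        cio.write_ground_truth(out / f"{scene_id}_truth", gt)
        table, coloc = analyze_scene(channels, treatment, config.pairing,
                                     config, scene_id=scene_id)
        tables.append(table.table)
        coloc_all[treatment] = coloc
    feature_table = pd.concat(tables)
    feature_table.to_csv(out / "feature_table.csv", index_label="object_id")

    pca = run_pca(feature_table, attributes=config.pca_attributes)
    scree = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
        "eigenvalue": pca.eigenvalues,
        "variance_fraction": pca.variance_fractions,
    })
    scree.to_csv(out / "pca_scree.csv", index=False)
    loadings = pd.DataFrame(pca.loadings, index=list(pca.attributes),
                            columns=list(scree["component"]))
    loadings.to_csv(out / "pca_loadings.csv")
    pca.score_frame().join(pca.rows).to_csv(out / "pca_scores.csv")

    gated = {}
    for gate in config.gates:
        sel = gate_scores(pca, gate)
        name = gate.label or f"gate_PC{gate.pc_x}_PC{gate.pc_y}"
        sel.to_csv(out / f"{name}.csv")
        gated[name] = sel

    coloc_rows = []
    for treatment, pairs in coloc_all.items():
        for pair, res in pairs.items():
            coloc_rows.append({
                "treatment": treatment, "pair": pair, "r_total": res.r_total,
                "m1": res.m1, "m2": res.m2, "n_voxels": res.n_voxels,
            })
    pd.DataFrame(coloc_rows).to_csv(out / "coloc_report.csv", index=False)

    lfq_params = dict(config.lfq)
    matrix, truth = clfq.generate_lfq(seed=config.seed + 90001, **lfq_params)
    de = clfq.de_pipeline(matrix, q_threshold=0.05)
    de.table.join(truth).to_csv(out / "de_report.csv", index_label="protein")

    cio.write_provenance(out / "provenance.json", cfg_dict, config.seed,
                         extra={"artefacts": sorted(p.name for p in out.iterdir())})
    return PipelineResult(feature_table=feature_table, pca=pca,
                          coloc=coloc_all, de=de, gated=gated, output_dir=out)


def _config_to_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)
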
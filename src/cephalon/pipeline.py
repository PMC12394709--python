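"""Configuration-driven pipeline runs with JSON provenance sidecars.

Every stage is described by a :class:`RunConfig` (stage name, input and
output paths, a parameter block, a seed).  Unknown keys are rejected.
Each output file gets a ``<name>.prov.json`` sidecar recording the stage,
its full parameter block, the seed, the SHA-256 digest of every input and
the package version, so a run can be audited and re-run bit-identically:
no stage reads parameters from anywhere but its config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

import cephalon
from cephalon import cones, isolation, symmetry, synthetic
from cephalon.cladistics import (
    MkLikelihoodSpec,
    Tree,
    bootstrap,
    heuristic_search,
    mk_loglik,
    read_nexus,
    strict_consensus,
    successive_reweight,
    write_nexus,
)
from cephalon.cladistics.tree import random_binary_tree
from cephalon.plate import DensityMap, LandmarkSet, read_plate, write_plate

__all__ = ["RunConfig", "PipelineConfig", "run_pipeline", "execute_stage", "StageError"]


class StageError(RuntimeError):
    """Raised with the failing stage's name attached."""


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stage: str
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}
    params: dict[str, Any] = {}
    seed: int = 0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stages: list[RunConfig]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar(out_path: str, cfg: RunConfig, extra: dict | None = None) -> None:
    record = {
        "stage": cfg.stage,
        "params": cfg.params,
        "seed": cfg.seed,
        "inputs": {k: _sha256(v) for k, v in cfg.inputs.items()},
        "package": f"cephalon {cephalon.__version__}",
    }
    if extra:
        record.update(extra)
    Path(out_path + ".prov.json").write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str)
    )


def _write_json(path: str, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate_plate(cfg: RunConfig) -> dict:
    p = dict(cfg.params)
    taph = synthetic.TaphonomyParams(
        rotation_asymmetry=p.pop("rotation_asymmetry", 0.0),
        lateral_shift=p.pop("lateral_shift", 0.0),
        speckle_rate=p.pop("speckle_rate", 0.0),
        tone_gradient=p.pop("tone_gradient", 0.0),
        seed=cfg.seed,
    )
    density = p.pop("punctum_density", 0.015)
    layout = p.pop("layout", None)
    if p:
        raise StageError(f"simulate-plate: unknown parameter(s) {sorted(p)}")
    template = synthetic.make_template(layout, seed=cfg.seed)
    plate, truth = synthetic.render_plate(template, density, taph)
    write_plate(plate.pixels, cfg.outputs["plate"])
    template.landmarks().to_json(cfg.outputs["landmarks"])
    if "truth" in cfg.outputs:
        _write_json(
            cfg.outputs["truth"],
            {
                "n_puncta_left": int(len(truth.puncta["left"])),
                "n_puncta_right": int(len(truth.puncta["right"])),
                "n_speckle": int(len(truth.speckle)),
                "template_area_px": int(template.region_mask().sum()),
            },
        )
    return cfg.outputs


def _stage_isolate(cfg: RunConfig) -> dict:
    params = isolation.IsolationParams(**cfg.params)
    plate = read_plate(cfg.inputs["plate"])
    dens = isolation.isolate_traces(plate, params)
    write_plate(dens.pixels, cfg.outputs["density"])
    return cfg.outputs


def _stage_symmetrize(cfg: RunConfig) -> dict:
    lm = LandmarkSet.from_json(cfg.inputs["landmarks"])
    dens = DensityMap(read_plate(cfg.inputs["density"]).pixels)
    recon = symmetry.symmetrize(
        dens,
        lm,
        reference_side=cfg.params.get("reference_side", "left"),
        blend=cfg.params.get("blend", "max"),
    )
    unknown = set(cfg.params) - {"reference_side", "blend"}
    if unknown:
        raise StageError(f"symmetrize: unknown parameter(s) {sorted(unknown)}")
    write_plate(recon.map.pixels, cfg.outputs["symmetric"])
    return cfg.outputs


def _stage_composite(cfg: RunConfig) -> dict:
    unknown = set(cfg.params) - {"alpha", "blend"}
    if unknown:
        raise StageError(f"composite: unknown parameter(s) {sorted(unknown)}")
    params = symmetry.CompositeParams(
        alpha=cfg.params.get("alpha", 1.0 / 3.0),
        blend=cfg.params.get("blend", "additive"),
    )
    layers = []
    i = 0
    while f"density{i}" in cfg.inputs:
        layers.append(
            (
                DensityMap(read_plate(cfg.inputs[f"density{i}"]).pixels),
                LandmarkSet.from_json(cfg.inputs[f"landmarks{i}"]),
            )
        )
        i += 1
    comp = symmetry.composite_specimens(layers, params)
    write_plate(comp.pixels, cfg.outputs["composite"])
    return cfg.outputs


def _stage_count_cones(cfg: RunConfig) -> dict:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(cfg.inputs["image"]), float)
    if img.dtype.kind != "f" or img.max() > 1.0:
        img = img / 255.0
    rois = json.loads(Path(cfg.inputs["rois"]).read_text())["rois"]
    window = cones.ChromaWindow(
        hue_lo=cfg.params.get("hue_lo", 70.0),
        hue_hi=cfg.params.get("hue_hi", 150.0),
        min_saturation=cfg.params.get("min_saturation", 0.3),
        q=cfg.params.get("q", 0.95),
    )
    min_area = cfg.params.get("min_area_px", 3)
    unknown = set(cfg.params) - {"hue_lo", "hue_hi", "min_saturation", "q", "min_area_px"}
    if unknown:
        raise StageError(f"count-cones: unknown parameter(s) {sorted(unknown)}")
    results = {}
    for name, poly in rois.items():
        mask = cones.chroma_peak_mask(img, np.asarray(poly), window)
        cc = cones.count_units(mask, np.asarray(poly), min_area, roi_id=name)
        results[name] = {
            "n_units": cc.n_units,
            "ambiguous": cc.ambiguous,
            "centroids": cc.centroids.tolist(),
            "window": [window.hue_lo, window.hue_hi],
        }
    _write_json(cfg.outputs["counts"], results)
    return cfg.outputs


def _stage_simulate_matrix(cfg: RunConfig) -> dict:
    p = dict(cfg.params)
    n_taxa = p.pop("n_taxa", 12)
    n_chars = p.pop("n_chars", 200)
    branch_length = p.pop("branch_length", 0.1)
    missing_frac = p.pop("missing_frac", 0.0)
    if p:
        raise StageError(f"simulate-matrix: unknown parameter(s) {sorted(p)}")
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"taxon_{i + 1:02d}" for i in range(n_taxa)]
    tree = random_binary_tree(taxa, rng, branch_length=branch_length)
    model = synthetic.SimTreeModel(
        tree=tree, n_chars=n_chars, missing_frac=missing_frac, seed=cfg.seed
    )
    matrix = synthetic.simulate_characters(model)
    write_nexus(matrix, cfg.outputs["nexus"])
    if "tree" in cfg.outputs:
        Path(cfg.outputs["tree"]).write_text(tree.to_newick() + "\n")
    return cfg.outputs


def _stage_pars(cfg: RunConfig) -> dict:
    matrix = read_nexus(cfg.inputs["nexus"])
    res = heuristic_search(
        matrix,
        n_replicates=cfg.params.get("n_replicates", 100),
        seed=cfg.seed,
        max_trees=cfg.params.get("max_trees", 100),
    )
    unknown = set(cfg.params) - {"n_replicates", "max_trees"}
    if unknown:
        raise StageError(f"pars: unknown parameter(s) {sorted(unknown)}")
    cons = strict_consensus(res.trees)
    _write_json(
        cfg.outputs["results"],
        {
            "best_length": res.best_length,
            "n_mpts": res.n_trees,
            "ci": round(res.ci, 4),
            "ri": round(res.ri, 4),
            "ci_informative_only": round(res.ci_informative, 4),
            "ri_informative_only": round(res.ri_informative, 4),
            "search_log": res.search_log,
            "mpts": [t.to_newick(include_lengths=False) for t in res.trees],
            "strict_consensus": cons.to_newick(include_lengths=False),
        },
    )
    return cfg.outputs


def _stage_boot(cfg: RunConfig) -> dict:
    matrix = read_nexus(cfg.inputs["nexus"])
    table = bootstrap(
        matrix,
        B=cfg.params.get("B", 1000),
        seed=cfg.seed,
        n_replicates=cfg.params.get("n_replicates", 2),
    )
    unknown = set(cfg.params) - {"B", "n_replicates"}
    if unknown:
        raise StageError(f"boot: unknown parameter(s) {sorted(unknown)}")
    _write_json(
        cfg.outputs["support"],
        {
            "B": table.n_replicates,
            "splits": [
                {"taxa": list(group), "support_pct": pct} for group, pct in table.named()
            ],
        },
    )
    return cfg.outputs


def _stage_reweight(cfg: RunConfig) -> dict:
    matrix = read_nexus(cfg.inputs["nexus"])
    out = successive_reweight(
        matrix,
        seed=cfg.seed,
        n_replicates=cfg.params.get("n_replicates", 10),
        max_rounds=cfg.params.get("max_rounds", 10),
        convention=cfg.params.get("convention", "max"),
    )
    unknown = set(cfg.params) - {"n_replicates", "max_rounds", "convention"}
    if unknown:
        raise StageError(f"reweight: unknown parameter(s) {sorted(unknown)}")
    res = out["final_result"]
    _write_json(
        cfg.outputs["results"],
        {
            "rounds_to_stable": out["rounds_to_stable"],
            "converged": out["converged"],
            "final_weighted_length": res.best_length,
            "final_n_mpts": res.n_trees,
            "final_trees": [t.to_newick(include_lengths=False) for t in res.trees],
            "final_weights": np.round(out["weights_trajectory"][-1], 6).tolist(),
        },
    )
    return cfg.outputs


def _stage_mklnl(cfg: RunConfig) -> dict:
    matrix = read_nexus(cfg.inputs["nexus"])
    tree = Tree.from_newick(Path(cfg.inputs["tree"]).read_text())
    spec = MkLikelihoodSpec(
        conditioning=cfg.params.get("conditioning", "variable")
    )
    unknown = set(cfg.params) - {"conditioning"}
    if unknown:
        raise StageError(f"mklnl: unknown parameter(s) {sorted(unknown)}")
    ll = mk_loglik(tree, matrix, spec)
    _write_json(
        cfg.outputs["results"],
        {"log_likelihood": ll, "conditioning": spec.conditioning},
    )
    return cfg.outputs


def _stage_consensus(cfg: RunConfig) -> dict:
    trees = [
        Tree.from_newick(line, rooted=False)
        for line in Path(cfg.inputs["trees"]).read_text().splitlines()
        if line.strip()
    ]
    cons = strict_consensus(trees)
    Path(cfg.outputs["tree"]).write_text(cons.to_newick(include_lengths=False) + "\n")
    return cfg.outputs


STAGES: dict[str, Callable[[RunConfig], dict]] = {
    "simulate-plate": _stage_simulate_plate,
    "isolate": _stage_isolate,
    "symmetrize": _stage_symmetrize,
    "composite": _stage_composite,
    "count-cones": _stage_count_cones,
    "simulate-matrix": _stage_simulate_matrix,
    "pars": _stage_pars,
    "boot": _stage_boot,
    "reweight": _stage_reweight,
    "mklnl": _stage_mklnl,
    "consensus": _stage_consensus,
}


def execute_stage(cfg: RunConfig) -> dict:
    """Run one stage; write outputs and provenance sidecars."""
    if cfg.stage not in STAGES:
        raise StageError(f"unknown stage {cfg.stage!r}; known: {sorted(STAGES)}")
    for key, path in cfg.inputs.items():
        if not Path(path).exists():
            raise StageError(f"{cfg.stage}: input {key}={path} does not exist")
    try:
        outputs = STAGES[cfg.stage](cfg)
    except StageError:
        raise
    except (TypeError, ValueError) as exc:
        raise StageError(f"{cfg.stage}: {exc}") from exc
    for path in outputs.values():
        _sidecar(path, cfg)
    return outputs


def run_pipeline(config: PipelineConfig | dict | str | Path) -> list[dict]:
    """Execute the stages of a config in order; abort on the first error."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    if isinstance(config, dict):
        try:
            config = PipelineConfig(**config)
        except ValidationError as exc:
            raise StageError(f"invalid pipeline config: {exc}") from exc
    return [execute_stage(stage) for stage in config.stages]
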
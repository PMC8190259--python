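"""End-to-end orchestration of the synthetic analysis pipeline.

A single YAML config (all keys optional; defaults are the production
parameters) drives five stages: crosslink simulation + filtering,
coarse-grained sampling + ensemble clustering, AP-MS enrichment, condensate
quantification, and FRAP fitting. One master seed deterministically derives
a per-stage seed; the run manifest records inputs, outputs, seeds and
checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import condensate, enrichment, ensemble, ms_filters, sampler, synthetic
from .cg_model import system_from_truth
from .sampler import CompiledScore

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "DEFAULTS"]

# Canonical defaults: the production analysis parameters.
DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "stages": ["crosslinks", "modeling", "enrichment", "condensates", "frap", "array"],
    "sampler": {
        "n_replicas": 32,
        "n_frames": 15000,
        "t_min": 1.0,
        "t_max": 2.5,
        "max_translation": 10.0,
        "max_rotation": 1.0,
        "save_fraction": 0.25,
        "n_runs": 3,
    },
    "clustering": {"n_best": 500, "rmsd_cutoff": 10.0},
    "crosslink_filter": {"min_ld": 30.0, "max_deltaS": 0.95, "max_fdr": 0.05},
    "enrichment": {
        "min_valid": 5,
        "impute_width": 0.3,
        "impute_shift": 1.8,
        "s0": 2.0,
        "fdr": 0.001,
        "z_threshold": 0.3,
    },
    "segmentation": {"radius": 15, "min_size": 4, "min_circularity": 0.85},
    "synthetic": {},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled in."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(DEFAULTS["stages"]))
    sampler: dict = field(default_factory=lambda: dict(DEFAULTS["sampler"]))
    clustering: dict = field(default_factory=lambda: dict(DEFAULTS["clustering"]))
    crosslink_filter: dict = field(default_factory=lambda: dict(DEFAULTS["crosslink_filter"]))
    enrichment: dict = field(default_factory=lambda: dict(DEFAULTS["enrichment"]))
    segmentation: dict = field(default_factory=lambda: dict(DEFAULTS["segmentation"]))
    synthetic: dict = field(default_factory=dict)
    out_dir: str = "h1ub_run"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def validate_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected.

    An empty or missing file yields all documented defaults.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    known = set(DEFAULTS) | {"out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged: dict[str, Any] = {}
    for key, default in DEFAULTS.items():
        if isinstance(default, dict):
            sub = dict(default)
            extra = raw.get(key, {}) or {}
            bad = set(extra) - (set(default) | set(extra))
            if bad:
                raise ValueError(f"unknown keys in {key}: {sorted(bad)}")
            sub.update(extra)
            merged[key] = sub
        else:
            merged[key] = raw.get(key, default)
    merged["out_dir"] = raw.get("out_dir", "h1ub_run")
    cfg = PipelineConfig(**merged)
    sf = cfg.sampler.get("save_fraction", 0.25)
    if not (0 < sf <= 1):
        raise ValueError(f"save_fraction must be in (0, 1], got {sf}")
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, scaled: bool = True) -> dict:
    """Run the enabled stages on synthetic inputs and write a manifest.

    With ``scaled=True`` (the default, suitable for a desk run) the sampling
    stage uses 4 replicas x 2000 frames instead of the production 32 x 15000.
    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "outputs": {}}

    if "crosslinks" in config.stages or "modeling" in config.stages:
        seed = config.stage_seed("crosslinks")
        spec = synthetic.SyntheticSpec(seed=seed, **config.synthetic)
        truth = synthetic.make_toy_complex(seed=seed)
        table = synthetic.simulate_crosslinks(truth, spec)
        path = out / "crosslinks.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["stages"]["crosslinks"] = {"seed": seed, "n_rows": len(table)}
        manifest["outputs"]["crosslinks"] = str(path)

        filtered = ms_filters.filter_crosslinks(table, ms_filters.MODELING_POLICY)
        links = ms_filters.collapse_and_weight(filtered)

        if "modeling" in config.stages:
            mseed = config.stage_seed("modeling")
            rng = np.random.default_rng(mseed)
            system = system_from_truth(truth, fixed=("body0",), randomize=rng)
            score = CompiledScore(system, links)
            scfg = sampler.SamplerConfig(
                n_replicas=4 if scaled else config.sampler["n_replicas"],
                n_frames=2000 if scaled else config.sampler["n_frames"],
                t_min=config.sampler["t_min"],
                t_max=config.sampler["t_max"],
                max_translation=config.sampler["max_translation"],
                max_rotation=config.sampler["max_rotation"],
                save_fraction=config.sampler["save_fraction"],
                seed=mseed,
            )
            runs = [
                sampler.run_replica_exchange(system, score, scfg, run_id=r)
                for r in range(2 if scaled else config.sampler["n_runs"])
            ]
            best = ensemble.pool_and_select(runs, n_best=min(
                config.clustering["n_best"], sum(len(r) for r in runs)
            ))
            mobile = [n for n in truth.body_names if n != "body0"]
            rmsd = ensemble.rmsd_matrix(best, system, mobile)
            clusters = ensemble.threshold_cluster(rmsd, config.clustering["rmsd_cutoff"])
            scores_path = out / "model_scores.tsv"
            best.scores_table().to_csv(scores_path, sep="\t", index=False)
            manifest["stages"]["modeling"] = {
                "seed": mseed,
                "n_models": len(best),
                "n_clusters": clusters.n_clusters,
                "best_score": float(best.scores.min()),
            }
            manifest["outputs"]["model_scores"] = str(scores_path)

    if "enrichment" in config.stages:
        seed = config.stage_seed("enrichment")
        spec = synthetic.SyntheticSpec(seed=seed, **config.synthetic)
        matrix, truth_labels = synthetic.simulate_apms_matrix(spec)
        groups = [c.rsplit("_", 2)[0] for c in matrix.columns]
        ecfg = enrichment.EnrichmentConfig(
            min_valid=config.enrichment["min_valid"],
            impute_width=config.enrichment["impute_width"],
            impute_shift=config.enrichment["impute_shift"],
            s0=config.enrichment["s0"],
            fdr=config.enrichment["fdr"],
            z_threshold=config.enrichment["z_threshold"],
            seed=seed,
        )
        clean = enrichment.preprocess(matrix, ecfg, groups=groups, log_transform=False)
        filled, _ = enrichment.impute(clean, ecfg)
        result = enrichment.s0_anova_fdr(filled, [groups[list(matrix.columns).index(c)] for c in filled.columns], ecfg)
        path = out / "enrichment.tsv"
        pd.DataFrame(
            {"statistic": result.statistic, "q": result.qvalues,
             "significant": result.statistic.index.isin(result.significant)}
        ).to_csv(path, sep="\t")
        manifest["stages"]["enrichment"] = {
            "seed": seed,
            "n_proteins": len(filled),
            "n_significant": len(result.significant),
        }
        manifest["outputs"]["enrichment"] = str(path)

    if "condensates" in config.stages:
        seed = config.stage_seed("condensates")
        spec = synthetic.SyntheticSpec(seed=seed, **config.synthetic)
        image, mask, droplets = synthetic.simulate_condensate_image(spec)
        seg = condensate.segment_droplets(
            image[0],
            condensate.SegmentationConfig(
                radius=config.segmentation["radius"],
                min_size=config.segmentation["min_size"],
                min_circularity=config.segmentation["min_circularity"],
            ),
        )
        part = condensate.partition_coefficient(image[0], seg)
        path = out / "droplets.tsv"
        seg.table.to_csv(path, sep="\t", index=False)
        manifest["stages"]["condensates"] = {
            "seed": seed,
            "n_droplets": part.n_droplets,
            "partition_coefficient": part.coefficient,
            "mean_size_px": part.mean_size_px,
        }
        manifest["outputs"]["droplets"] = str(path)

    if "frap" in config.stages:
        seed = config.stage_seed("frap")
        spec = synthetic.SyntheticSpec(seed=seed, **config.synthetic)
        trace = synthetic.simulate_frap_trace(spec)
        corrected = condensate.frap_correct(trace)
        fit = condensate.frap_fit(corrected)
        path = out / "frap_fit.json"
        path.write_text(json.dumps(asdict(fit), indent=2))
        manifest["stages"]["frap"] = {"seed": seed, "k": fit.k, "y_inf": fit.y_inf}
        manifest["outputs"]["frap_fit"] = str(path)

    if "array" in config.stages:
        seq = synthetic.build_601_array()
        path = out / "array_12mer.fasta"
        path.write_text(">array_12mer\n" + "\n".join(
            seq[i : i + 70] for i in range(0, len(seq), 70)
        ) + "\n")
        manifest["stages"]["array"] = {
            "length_bp": len(seq),
            "paci_sites": seq.count("TTAATTAA"),
        }
        manifest["outputs"]["array"] = str(path)

    manifest["checksums"] = {
        name: _checksum(Path(p)) for name, p in manifest["outputs"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
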
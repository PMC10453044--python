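"""Top-level pipeline: simulate -> call -> map -> annotate -> wsc.

Each invocation writes its outputs plus a machine-readable manifest
(package version, seed, config hash, per-stage outputs) into one run
directory, so a run can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, annotation, calling, io, mapping, sim, wsc
from .types import CallerConfig, MapperConfig, SimConfig, TrueDeletion

log = logging.getLogger("clustershift")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "sim": {
        "n_markers": 300,
        "multi_site_fraction": 0.7,
        "noise_sd": 0.05,
        "biotype_rate": 0.0,
        "n_panel": 96,
        "chrom_length": 100_000_000,
        "deletions": {
            "mut6A": [
                {"subgenome": "6A", "start": 40_000_000, "end": 45_000_000, "zygosity": "hom"}
            ]
        },
    },
    "caller": {},
    "mapper": {"target_loci": {"6A": [42_000_000, 42_003_000]}},
    "annotation": {"ratio_threshold": 0.1, "stage": "reproductive", "hc_only": False},
    "wsc": {
        "parent_line": "Chara",
        "treatment": "water_deficit",
        "t_start": 12,
        "t_end": 22,
        "n_rep": 6,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _dataclass_from(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} options: {sorted(unknown)}")
    return cls(**data)


def build_sim_config(config: dict, seed: Optional[int] = None) -> SimConfig:
    sim_cfg = dict(config.get("sim", {}))
    deletions = {
        sid: [TrueDeletion(**d) for d in dels]
        for sid, dels in sim_cfg.pop("deletions", {}).items()
    }
    sim_cfg["deletions"] = deletions
    sim_cfg["seed"] = seed if seed is not None else config.get("seed", 0)
    return _dataclass_from(SimConfig, sim_cfg)


def build_mapper_config(config: dict) -> MapperConfig:
    mapper_cfg = dict(config.get("mapper", {}))
    mapper_cfg["target_loci"] = {
        chrom: tuple(bounds) for chrom, bounds in mapper_cfg.get("target_loci", {}).items()
    }
    return _dataclass_from(MapperConfig, mapper_cfg)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: Optional[dict] = None,
    outdir: "str | Path" = "run",
    seed: Optional[int] = None,
) -> dict:
    """Run all five stages on a simulated experiment; returns the manifest.

    ``config`` overrides :data:`DEFAULT_CONFIG` key-by-key. Partial
    outputs are retained on stage failure (the exception propagates after
    being logged and recorded in the manifest).
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        config["seed"] = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "clustershift",
        "version": __version__,
        "seed": config["seed"],
        "config_hash": config_hash(config),
        "stages": [],
        "outputs": {},
    }
    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.error("pipeline failed: %s", manifest["error"])
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _run_stages(config: dict, outdir: Path, manifest: dict) -> None:
    # --- simulate -----------------------------------------------------
    log.info("stage simulate")
    sim_config = build_sim_config(config)
    mapper_config = build_mapper_config(config)
    result = sim.simulate_experiment(sim_config)
    genes = sim.simulate_genes(sim_config, target_loci=mapper_config.target_loci)
    expression = sim.simulate_expression(genes, sim_config)
    pheno = sim.simulate_wsc(seed=sim_config.seed, n_rep=config["wsc"].get("n_rep", 6))
    io.write_marker_map(result.markers, outdir / "markers.csv")
    io.write_intensities(result.intensities, outdir / "intensities.csv")
    io.write_truth(result.truth, outdir / "truth.json")
    io.write_gff3_genes(genes, outdir / "genes.gff3")
    io.write_expression(expression, outdir / "expression.tsv")
    io.write_phenotype(pheno, outdir / "pheno.csv")
    manifest["stages"].append("simulate")
    manifest["outputs"]["simulate"] = [
        "markers.csv", "intensities.csv", "truth.json",
        "genes.gff3", "expression.tsv", "pheno.csv",
    ]

    # --- call ---------------------------------------------------------
    log.info("stage call")
    caller_config = _dataclass_from(CallerConfig, config.get("caller", {}))
    truth = result.truth
    mutants = sorted(truth["deletions"])
    calls_by_mutant = {}
    call_outputs = []
    for mutant in mutants:
        calls, biotype_report = calling.call_sample(
            result.intensities,
            result.markers,
            parent_id=truth["parent_id"],
            sample_id=mutant,
            f1_id=f"{mutant}_f1",
            panel_ids=truth["panel_ids"],
            second_parent_id=truth["hib_stock_id"],
            config=caller_config,
        )
        calls_by_mutant[mutant] = calls
        io.write_calls(calling.calls_to_frame(calls), outdir / f"calls_{mutant}.csv")
        pd.DataFrame({"marker_name": biotype_report}).to_csv(
            outdir / f"biotype_report_{mutant}.csv", index=False
        )
        call_outputs += [f"calls_{mutant}.csv", f"biotype_report_{mutant}.csv"]
    manifest["stages"].append("call")
    manifest["outputs"]["call"] = call_outputs

    # --- map ----------------------------------------------------------
    log.info("stage map")
    intervals_by_mutant = {}
    map_outputs = []
    for mutant in mutants:
        intervals = mapping.map_intervals(
            calls_by_mutant[mutant], result.markers, mapper_config
        )
        intervals_by_mutant[mutant] = intervals
        io.write_intervals(intervals, outdir / f"intervals_{mutant}.csv")
        io.write_bed(intervals, outdir / f"intervals_{mutant}.bed")
        map_outputs += [f"intervals_{mutant}.csv", f"intervals_{mutant}.bed"]
    manifest["stages"].append("map")
    manifest["outputs"]["map"] = map_outputs

    # --- annotate -----------------------------------------------------
    log.info("stage annotate")
    ann_cfg = config.get("annotation", {})
    reference_genes = {chrom: f"FEH_{chrom}" for chrom in mapper_config.target_loci}
    ann_outputs = []
    for mutant in mutants:
        table = annotation.annotate_intervals(
            intervals_by_mutant[mutant],
            genes,
            expression=expression,
            reference_genes=reference_genes,
            stage=ann_cfg.get("stage", "reproductive"),
            ratio_threshold=ann_cfg.get("ratio_threshold", 0.1),
            hc_only=ann_cfg.get("hc_only", False),
        )
        table.to_csv(outdir / f"genes_{mutant}.tsv", sep="\t", index=False)
        ann_outputs.append(f"genes_{mutant}.tsv")
    manifest["stages"].append("annotate")
    manifest["outputs"]["annotate"] = ann_outputs

    # --- wsc ----------------------------------------------------------
    log.info("stage wsc")
    wsc_cfg = config["wsc"]
    report = wsc.wsc_report(
        pheno,
        parent_line=wsc_cfg["parent_line"],
        treatment=wsc_cfg.get("treatment", "water_deficit"),
        t_start=wsc_cfg.get("t_start", 12),
        t_end=wsc_cfg.get("t_end", 22),
    )
    report.to_csv(outdir / "wsc_report.tsv", sep="\t", index=False)
    r, p, n = wsc.grain_remobilisation_correlation(
        pheno,
        treatment=wsc_cfg.get("treatment", "water_deficit"),
        t_start=wsc_cfg.get("t_start", 12),
        t_end=wsc_cfg.get("t_end", 22),
    )
    (outdir / "wsc_correlation.json").write_text(
        json.dumps({"pearson_r": r, "p_value": p, "n": n}, indent=2) + "\n"
    )
    manifest["stages"].append("wsc")
    manifest["outputs"]["wsc"] = ["wsc_report.tsv", "wsc_correlation.json"]
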
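"""End-to-end orchestration: gene trees in, reports out.

Stage order: load & validate gene trees -> infer (or accept) a species tree
-> estimate coalescent-unit branch lengths -> concordance mapping + ICA +
quartet sampling -> ILS simulation test -> network scan.  Every stage
writes its artifact into the output directory and logs a ``key=value``
line to stderr; a single master seed determines each stage's sub-seed via
a fixed hash, so results are byte-identical across runs and invariant to
adding or removing other stages.
"""

from __future__ import annotations

import json
import math
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .treecore import Tree, TreeError, read_newick_file, reroot, write_newick, write_newick_file
from .conflict import (
    annotated_species_tree,
    conflict_table,
    map_concordance,
    qs_table,
    quartet_sampling,
)
from .speciestree import estimate_coalescent_branch_lengths, infer_species_tree
from .ils_test import ils_discordance_test, normalized_rf_values
from .network import ranked_table, scan_and_rank_networks

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "write_report",
    "stage_seed",
    "REPORT_SCHEMA",
    "validate_report",
]

# minimal structural schema for report.json: key -> (type, required)
REPORT_SCHEMA = {
    "status": (str, True),
    "version": (str, True),
    "config": (dict, True),
    "seeds": (dict, True),
    "files": (dict, True),
    "headline": (dict, True),
}

_HEADLINE_SCHEMA = {
    "ica_min": (float, int),
    "ica_max": (float, int),
    "qc_min": (float, int, type(None)),
    "qc_max": (float, int, type(None)),
    "ils_overlap": (float, int),
    "ils_verdict": (str,),
    "n_reticulations": (int,),
    "tree_log_pl": (float, int),
}


def validate_report(manifest: dict) -> None:
    """Check a report manifest against the shipped structural schema;
    raises ``ValueError`` naming the offending key."""
    for key, (typ, required) in REPORT_SCHEMA.items():
        if key not in manifest:
            if required:
                raise ValueError(f"report missing required key {key!r}")
            continue
        if not isinstance(manifest[key], typ):
            raise ValueError(f"report key {key!r} has type {type(manifest[key]).__name__}, expected {typ.__name__}")
    headline = manifest["headline"]
    for key, types in _HEADLINE_SCHEMA.items():
        if key not in headline:
            raise ValueError(f"headline missing key {key!r}")
        if not isinstance(headline[key], types):
            raise ValueError(f"headline key {key!r} has unexpected type {type(headline[key]).__name__}")
    for stage, sub in manifest["seeds"].items():
        if not isinstance(sub, int) or not 0 <= sub < 2**31:
            raise ValueError(f"stage seed for {stage!r} out of range")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline knobs; flags mirror these field names."""

    gene_trees: str
    out_dir: str
    outgroup: str
    species_tree: Optional[str] = None
    min_support: float = 50.0
    qs_replicates: int = 1000
    cu_draws: int = 2000
    n_sim: int = 20000
    overlap_threshold: float = 0.75
    max_reticulations: int = 5
    improvement_threshold: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.min_support <= 100:
            raise ValueError("min_support must lie in [0, 100]")
        if not 0 <= self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must lie in [0, 1]")
        for name in ("qs_replicates", "cu_draws", "n_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_reticulations < 0:
            raise ValueError("max_reticulations must be >= 0")

    @staticmethod
    def from_yaml(path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: independent of the other stages."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def _log(stage: str, **kv) -> None:
    items = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"stage={stage} {items}", file=sys.stderr)


def _round6(x):
    """Recursively round floats to 6 significant digits for stable reports."""
    if isinstance(x, float):
        if math.isnan(x) or math.isinf(x):
            return None
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def _write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    headline: dict = {}
    manifest_path = out / "report.json"

    def finish_stage(stage: str, t0: float, **kv):
        _log(stage, seed=stage_seed(config.seed, stage), wall_s=f"{time.time() - t0:.2f}", **kv)

    try:
        stage, t0 = "load", time.time()
        gene_trees = read_newick_file(config.gene_trees)
        if not gene_trees:
            raise TreeError("no gene trees in input")
        for g in gene_trees:
            g.validate()
        finish_stage(stage, t0, n_genes=len(gene_trees))

        stage, t0 = "speciestree", time.time()
        sub = stage_seed(config.seed, stage)
        if config.species_tree:
            species = read_newick_file(config.species_tree)[0]
        else:
            species = infer_species_tree(gene_trees, seed=sub)
        if config.outgroup not in species.taxa:
            raise TreeError(f"outgroup {config.outgroup!r} not in the species tree")
        species = reroot(species, config.outgroup)
        write_newick_file(out / "species_tree.nwk", [species])
        inventory["species_tree"] = "species_tree.nwk"
        finish_stage(stage, t0, taxa=len(species.taxa))

        stage, t0 = "branch_lengths", time.time()
        sub = stage_seed(config.seed, stage)
        guide, bl_table = estimate_coalescent_branch_lengths(
            species,
            gene_trees,
            draws_per_branch=config.cu_draws,
            seed=sub,
            return_table=True,
        )
        write_newick_file(out / "guide_tree.nwk", [guide.tree])
        _write_tsv(bl_table, out / "branch_lengths.tsv")
        inventory["guide_tree"] = "guide_tree.nwk"
        inventory["branch_lengths"] = "branch_lengths.tsv"
        finish_stage(stage, t0, draws=config.cu_draws)

        stage, t0 = "conflict", time.time()
        summaries = map_concordance(species, gene_trees, min_support=config.min_support)
        _write_tsv(conflict_table(summaries), out / "conflict.tsv")
        (out / "annotated_species_tree.nwk").write_text(
            annotated_species_tree(species, summaries) + "\n", encoding="utf-8"
        )
        inventory["conflict"] = "conflict.tsv"
        inventory["annotated_species_tree"] = "annotated_species_tree.nwk"
        icas = [s.ica for s in summaries]
        headline["ica_min"] = min(icas)
        headline["ica_max"] = max(icas)
        finish_stage(stage, t0, nodes=len(summaries))

        stage, t0 = "qs", time.time()
        sub = stage_seed(config.seed, stage)
        scores = quartet_sampling(
            species, gene_trees, replicates_per_branch=config.qs_replicates, seed=sub
        )
        _write_tsv(qs_table(scores), out / "quartet_sampling.tsv")
        inventory["quartet_sampling"] = "quartet_sampling.tsv"
        qcs = [s.qc for s in scores if s.qc is not None]
        headline["qc_min"] = min(qcs) if qcs else None
        headline["qc_max"] = max(qcs) if qcs else None
        finish_stage(stage, t0, replicates=config.qs_replicates)

        stage, t0 = "ilstest", time.time()
        sub = stage_seed(config.seed, stage)
        result = ils_discordance_test(
            gene_trees,
            guide,
            n_sim=config.n_sim,
            seed=sub,
            overlap_threshold=config.overlap_threshold,
        )
        with open(out / "ils_test.json", "w", encoding="utf-8") as fh:
            json.dump(_round6(result.to_dict()), fh, indent=2, sort_keys=True)
            fh.write("\n")
        obs_vals, _ = normalized_rf_values(guide.tree, gene_trees)
        with open(out / "rf_distances.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_index\tnormalized_rf\n")
            for i, v in enumerate(obs_vals):
                fh.write(f"{i}\t{v:.6g}\n")
        inventory["ils_test"] = "ils_test.json"
        inventory["rf_distances"] = "rf_distances.tsv"
        headline["ils_overlap"] = result.overlap
        headline["ils_verdict"] = result.verdict
        finish_stage(stage, t0, overlap=f"{result.overlap:.4f}", verdict=result.verdict)

        stage, t0 = "network", time.time()
        scan = scan_and_rank_networks(
            gene_trees,
            guide,
            config.outgroup,
            max_reticulations=config.max_reticulations,
            improvement_threshold=config.improvement_threshold,
        )
        _write_tsv(ranked_table(scan), out / "network_ranking.tsv")
        lines = [write_newick(guide.tree)]
        for f in scan.retained:
            r = f.model.reticulations[-1]
            lines.append(
                "recipient={}, donor={}, gamma={:.6g}, tau={:.6g}".format(
                    "|".join(sorted(r.recipient)), "|".join(sorted(r.donor)), r.gamma, r.tau
                )
            )
        (out / "selected_network.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        inventory["network_ranking"] = "network_ranking.tsv"
        inventory["selected_network"] = "selected_network.txt"
        headline["n_reticulations"] = scan.n_reticulations
        if scan.retained:
            best = scan.retained[0]
            headline["selected_recipient"] = "|".join(sorted(best.recipient))
            headline["selected_donor"] = "|".join(sorted(best.donor))
            headline["gamma_minor"] = best.gamma_hat
            headline["gamma_major"] = 1.0 - best.gamma_hat
        headline["tree_log_pl"] = scan.tree_log_pl
        finish_stage(stage, t0, retained=scan.n_reticulations)
    except Exception as exc:
        partial = {
            "status": "failed",
            "failed_stage": stage,
            "error": str(exc),
            "config": asdict(config),
            "files": inventory,
        }
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(_round6(partial), fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise StageError(stage, str(exc)) from exc

    return write_report(config, inventory, headline, manifest_path)


def write_report(config: PipelineConfig, inventory: dict, headline: dict, path) -> dict:
    """Single top-level JSON manifest; all numbers at 6 significant digits."""
    from . import __version__

    manifest = {
        "status": "ok",
        "version": __version__,
        "config": asdict(config),
        "seeds": {
            stage: stage_seed(config.seed, stage)
            for stage in ("speciestree", "branch_lengths", "qs", "ilstest")
        },
        "files": inventory,
        "headline": headline,
    }
    manifest = _round6(manifest)
    validate_report(manifest)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
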
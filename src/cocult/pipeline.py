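"""One-command orchestration: generate -> screen -> bin -> circularity ->
marker QC -> marker selection -> tree, with a reproducible run manifest.

A single run seed fans out to fixed per-stage child seeds (via
``numpy.random.SeedSequence(seed).spawn``), so any stage can be re-run
independently yet reproducibly. Every scientific output is written under
one directory and listed in ``manifest.json`` with a content hash; two runs
with the same config and seed produce byte-identical scientific outputs.
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

from . import binning, circularity, marker_qc, marker_selection, phylogeny
from . import genome_stats, rrna_screen
from .seq_io import write_fasta, write_newick, write_tsv
from .synthetic import (
    CocultureParams,
    MarkerScenarioParams,
    generate_coculture,
    generate_marker_scenario,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("generate", "screen", "bin", "circles", "qc", "select", "tree")


@dataclass
class RunConfig:
    """Everything a run needs; serialisable and echoed into the manifest."""

    seed: int = 42
    outdir: str = "cocult_run"
    coculture: CocultureParams = field(default_factory=CocultureParams)
    markers: MarkerScenarioParams = field(default_factory=MarkerScenarioParams)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    # thresholds (defaults follow the published analysis)
    coverage_cutoff: float = 180.0
    gc_min: float = 0.42
    gc_max: float = 0.54
    screen_k: int = 21
    screen_min_hits: int = 5
    circle_k: int = 51
    circle_support_cutoff: int = 15
    prevalence_threshold: float = 0.90
    redundancy_threshold: float = 0.90
    max_divergent_fraction: float = 0.01
    bootstrap_reps: int = 100
    contamination_convention: str = "detected-copies"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coculture"]["plasmid_lens"] = list(d["coculture"]["plasmid_lens"])
        d["coculture"]["rrna_read_counts"] = {
            f"{t}|{g}": c
            for (t, g), c in d["coculture"]["rrna_read_counts"].items()
        }
        return d

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cc = dict(d.pop("coculture", {}))
        if "plasmid_lens" in cc:
            cc["plasmid_lens"] = tuple(cc["plasmid_lens"])
        if "rrna_read_counts" in cc:
            cc["rrna_read_counts"] = {
                tuple(k.split("|", 1)): v
                for k, v in cc["rrna_read_counts"].items()
            }
        ms = dict(d.pop("markers", {}))
        return cls(
            coculture=CocultureParams(**cc),
            markers=MarkerScenarioParams(**ms),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest dictionary."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = dict(zip(_STAGES, _child_seeds(cfg.seed, len(_STAGES))))
    manifest: dict = {
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def emit(name: str, path: Path):
        artifacts[name] = path

    def stage_enabled(name: str) -> bool:
        on = cfg.stages.get(name, True)
        if not on:
            manifest["stages"][name] = {"skipped": True}
            logger.info("stage %s skipped by config", name)
        return on

    coculture = None
    scenario = None
    try:
        # ---- generate ----------------------------------------------------
        if stage_enabled("generate"):
            t = time.time()
            cc_params = dataclasses.replace(cfg.coculture, seed=seeds["generate"])
            mk_params = dataclasses.replace(
                cfg.markers, seed=(seeds["generate"] + 1) % (2**31)
            )
            coculture = generate_coculture(cc_params)
            scenario = generate_marker_scenario(mk_params)
            for name, path in coculture.write(outdir / "coculture").items():
                emit(f"coculture/{name}", path)
            for name, path in scenario.write(outdir / "markers").items():
                emit(f"markers/{name}", path)
            manifest["stages"]["generate"] = {
                "n_contigs": len(coculture.contigs),
                "n_read_pairs": len(coculture.reads),
                "n_families": len(scenario.presence.families),
                "seconds": round(time.time() - t, 2),
            }

        if coculture is None:
            raise RuntimeError("downstream stages need the generate stage")

        # ---- rRNA screen -------------------------------------------------
        if stage_enabled("screen"):
            t = time.time()
            index = rrna_screen.build_kmer_index(coculture.rrna_refs, cfg.screen_k)
            result = rrna_screen.screen_reads(
                coculture.all_reads_flat(), index, cfg.screen_min_hits
            )
            path = outdir / "screen.tsv"
            write_tsv(result.to_frame(), path)
            emit("screen", path)
            manifest["stages"]["screen"] = {
                "counts": {f"{t_}|{g}": c for (t_, g), c in result.counts.items()},
                "unassigned": result.unassigned,
                "seconds": round(time.time() - t, 2),
            }

        # ---- binning -----------------------------------------------------
        assignment = None
        if stage_enabled("bin"):
            t = time.time()
            metrics = binning.contig_metrics(coculture.contigs, coculture.coverage)
            assignment = binning.assign_bins(
                metrics,
                binning.BinningParams(cfg.coverage_cutoff, cfg.gc_min, cfg.gc_max),
            )
            fractions = binning.bin_fractions(assignment)
            path = outdir / "bins.tsv"
            write_tsv(assignment.to_frame(), path)
            emit("bins", path)
            path = outdir / "bin_summary.tsv"
            summary = assignment.per_bin()
            summary["data_fraction"] = [
                fractions[b] for b in summary["bin"]
            ]
            write_tsv(summary, path)
            emit("bin_summary", path)
            manifest["stages"]["bin"] = {
                "predator_data_fraction": fractions[binning.PREDATOR],
                "seconds": round(time.time() - t, 2),
            }

        # ---- circularity ---------------------------------------------------
        if stage_enabled("circles"):
            t = time.time()
            graph = circularity.build_end_graph(
                coculture.contigs,
                k=cfg.circle_k,
                reads=coculture.all_reads_flat(),
                support_cutoff=cfg.circle_support_cutoff,
            )
            calls = circularity.detect_circular(graph, cfg.circle_support_cutoff)
            import pandas as pd

            path = outdir / "circularity.tsv"
            write_tsv(
                pd.DataFrame(
                    [
                        {
                            "contig_id": c.contig_id,
                            "is_circular": c.is_circular,
                            "reason": c.reason,
                            "support": "" if c.support is None else c.support,
                        }
                        for c in calls
                    ]
                ),
                path,
            )
            emit("circularity", path)
            path = outdir / "end_graph.tsv"
            write_tsv(graph.to_frame(), path)
            emit("end_graph", path)
            manifest["stages"]["circles"] = {
                "n_circular": sum(c.is_circular for c in calls),
                "circular_ids": sorted(
                    c.contig_id for c in calls if c.is_circular
                ),
                "seconds": round(time.time() - t, 2),
            }

        # ---- marker QC of the predator bin -----------------------------------
        if stage_enabled("qc"):
            t = time.time()
            if assignment is not None:
                bin_ids = {
                    cid
                    for cid, b in assignment.bins.items()
                    if b == binning.PREDATOR
                }
                bin_contigs = [c for c in coculture.contigs if c.id in bin_ids]
            else:
                bin_contigs = coculture.predator_contigs()
            table = marker_qc.count_marker_hits(bin_contigs, coculture.marker_tags)
            report = marker_qc.qc_report(table, cfg.contamination_convention)
            path = outdir / "marker_hits.tsv"
            write_tsv(table.to_frame(), path)
            emit("marker_hits", path)
            path = outdir / "qc.tsv"
            write_tsv(report.to_frame(), path)
            emit("qc", path)
            stats = genome_stats.assembly_report(bin_contigs)
            path = outdir / "assembly_report.tsv"
            write_tsv(stats.to_frame(), path)
            emit("assembly_report", path)
            manifest["stages"]["qc"] = {
                "completeness": report.completeness,
                "contamination": report.contamination,
                "n50": stats.n50_bp,
                "seconds": round(time.time() - t, 2),
            }

        # ---- marker selection -------------------------------------------------
        selected = None
        if stage_enabled("select"):
            t = time.time()
            if scenario is None:
                raise RuntimeError("select stage needs the generate stage")
            selected = marker_selection.select_markers(
                scenario.presence,
                scenario.gene_tree_objects(),
                marker_selection.SelectionConfig(
                    cfg.prevalence_threshold,
                    cfg.redundancy_threshold,
                    cfg.max_divergent_fraction,
                ),
            )
            import pandas as pd

            path = outdir / "selected_markers.tsv"
            write_tsv(
                pd.DataFrame({"family_id": selected.retained}), path
            )
            emit("selected_markers", path)
            path = outdir / "selection_audit.json"
            path.write_text(
                json.dumps(
                    {
                        "initial": selected.initial,
                        "redundancy_removed": [
                            list(p) for p in selected.redundancy_removed
                        ],
                        "candidates": selected.candidates,
                        "divergence_removed": selected.divergence_removed,
                        "retained": selected.retained,
                    },
                    indent=1,
                )
            )
            emit("selection_audit", path)
            manifest["stages"]["select"] = {
                "n_initial": len(selected.initial),
                "n_candidates": len(selected.candidates),
                "n_divergence_removed": len(selected.divergence_removed),
                "n_retained": len(selected.retained),
                "seconds": round(time.time() - t, 2),
            }

        # ---- concatenated tree --------------------------------------------------
        if stage_enabled("tree"):
            t = time.time()
            if scenario is None:
                raise RuntimeError("tree stage needs the generate stage")
            families = (
                selected.retained
                if selected is not None
                else sorted(scenario.blocks)
            )
            blocks = {f: scenario.blocks[f] for f in families}
            genomes = list(scenario.presence.genomes)
            matrix = phylogeny.concatenate(blocks, genomes, families)
            path = outdir / "supermatrix.fasta"
            write_fasta(matrix.to_records(), path)
            emit("supermatrix", path)
            import pandas as pd

            path = outdir / "partitions.tsv"
            write_tsv(
                pd.DataFrame(
                    matrix.boundaries, columns=["family", "start", "end"]
                ),
                path,
            )
            emit("partitions", path)
            tree = phylogeny.bootstrap_support(
                matrix, n_reps=cfg.bootstrap_reps, seed=seeds["tree"]
            )
            path = outdir / "tree.nwk"
            write_newick(tree, path)
            emit("tree", path)
            manifest["stages"]["tree"] = {
                "n_taxa": len(genomes),
                "n_columns": matrix.n_columns,
                "bootstrap_reps": cfg.bootstrap_reps,
                "seconds": round(time.time() - t, 2),
            }
    except Exception as exc:
        failing = _current_stage(manifest)
        manifest["failed_stage"] = failing
        manifest["error"] = str(exc)
        _write_manifest(manifest, artifacts, outdir, t0)
        raise RuntimeError(f"pipeline stage {failing!r} failed: {exc}") from exc

    cfg.to_yaml(outdir / "config.yaml")
    emit("config", outdir / "config.yaml")
    return _write_manifest(manifest, artifacts, outdir, t0)


def _current_stage(manifest: dict) -> str:
    done = set(manifest["stages"])
    for s in _STAGES:
        if s not in done:
            return s
    return "finalise"


def _write_manifest(manifest, artifacts, outdir: Path, t0: float) -> dict:
    manifest["artifacts"] = {
        name: {"path": str(p), "sha256": _sha256(p)}
        for name, p in sorted(artifacts.items())
    }
    manifest["wall_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
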
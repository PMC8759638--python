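"""End-to-end orchestration: simulate/load -> downsample -> partition ->
coverage -> peaks -> domains -> architecture -> quantification, with a run
manifest for reproducibility.

The config is a YAML/JSON document::

    seed: 1
    outdir: scratch/run1
    control_condition: control
    analysis: {short_threshold_bp: 120, all_bin_bp: 25, ...}   # optional
    simulate: {fixture: dhd, replicates: 3}                    # either this
    inputs:                                                    # ... or this
      genome: chrom.sizes
      fragments:
        control: {rep1: control_rep1.bed, rep2: control_rep2.bed}
        kd:      {rep1: kd_rep1.bed,      rep2: kd_rep2.bed}

A single global seed fans out deterministically to per-stage child seeds, so
re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .fragio import (
    AnalysisConfig,
    Fragment,
    GenomeTable,
    coverage,
    downsample,
    partition_by_size,
    read_fragments,
    read_genome_table,
    write_fragments,
)
from .synthetic import dhd_fixture, generate, write_manifest
from .peaks import call_short_fragment_peaks, reproducible_peaks, write_peaks
from .domains import Domain, segment_domains, domain_scatter, write_domains
from .architecture import BORDER_SLACK_BP, classify_peaks, profile_matrix, vplot
from .quantify import Region, quantify_regions, quant_table

__all__ = ["RunManifest", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, dict] = field(default_factory=dict)  # stage -> {path, rows}
    version: str = ""

    def declare(self, stage: str, path: Path | None, rows: int) -> None:
        self.outputs[stage] = {
            "path": str(path) if path is not None else None,
            "rows": rows,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analysis_config(doc: dict) -> AnalysisConfig:
    kwargs = dict(doc.get("analysis", {}))
    kwargs.setdefault("seed", int(doc.get("seed", 0)))
    try:
        return AnalysisConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineError("config", exc) from exc


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute every stage and return (and write) the run manifest."""
    doc = load_config(config_path)
    cfg = _analysis_config(doc)
    seed = int(doc.get("seed", 0))
    outdir = Path(doc.get("outdir", "minidomain_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=doc, seed=seed, version=__version__)
    manifest.input_digests["config"] = _sha256(Path(config_path))

    # --- inputs: simulate or load -----------------------------------------
    stage = "simulate"
    try:
        if "simulate" in doc:
            sim = doc["simulate"] or {}
            if sim.get("fixture", "dhd") != "dhd":
                raise ValueError(f"unknown fixture {sim.get('fixture')!r}")
            spec = dhd_fixture(seed=seed, replicates=int(sim.get("replicates", 3)))
            genome = spec.genome
            libraries = generate(spec, conditions=sim.get("conditions"))
            write_manifest(spec, outdir / "ground_truth.json")
            for (cond, rep), frags in libraries.items():
                write_fragments(frags, outdir / f"fragments_{cond}_{rep}.bed")
            manifest.declare(stage, outdir / "ground_truth.json", len(libraries))
        elif "inputs" in doc:
            inputs = doc["inputs"]
            genome = read_genome_table(inputs["genome"])
            manifest.input_digests["genome"] = _sha256(Path(inputs["genome"]))
            libraries = {}
            for cond, reps in inputs["fragments"].items():
                for rep, path in reps.items():
                    libraries[(cond, rep)] = read_fragments(
                        path, "BED", genome=genome, sample=cond, replicate=rep
                    )
                    manifest.input_digests[f"{cond}/{rep}"] = _sha256(Path(path))
            manifest.declare(stage, None, len(libraries))
        else:
            raise ValueError("config needs a 'simulate' or an 'inputs' section")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    control = doc.get("control_condition", "control")
    conditions = sorted({c for c, _ in libraries})
    reps = sorted({r for _, r in libraries})
    if control not in conditions:
        raise PipelineError(
            "config", ValueError(f"control condition {control!r} not in libraries")
        )

    try:
        stage = "downsample"
        flat = {f"{c}/{r}": libraries[(c, r)] for c, r in libraries}
        flat = downsample(flat, target="min", seed=seed)
        libraries = {tuple(k.split("/")): v for k, v in flat.items()}

        stage = "partition"
        short = {
            key: partition_by_size(frags, cfg.short_threshold_bp)[0]
            for key, frags in libraries.items()
        }

        stage = "coverage"
        all_tracks = {
            key: coverage(frags, genome, cfg.all_bin_bp)
            for key, frags in libraries.items()
        }
        domain_tracks = {
            key: coverage(frags, genome, cfg.domain_bin_bp)
            for key, frags in libraries.items()
        }

        stage = "peaks"
        per_rep_peaks = [
            call_short_fragment_peaks(short[(control, r)], genome, cfg) for r in reps
        ]
        stage = "reproducible_peaks"
        peaks = (
            reproducible_peaks(per_rep_peaks) if len(reps) > 1 else per_rep_peaks[0]
        )
        write_peaks(peaks, outdir / "peaks.bed")
        manifest.declare("peaks", outdir / "peaks.bed", len(peaks))

        stage = "domains"
        per_rep_domains = [
            segment_domains(domain_tracks[(control, r)], cfg) for r in reps
        ]
        domains = _reproducible_domains(per_rep_domains)
        write_domains(domains, outdir / "domains.bed")
        manifest.declare("domains", outdir / "domains.bed", len(domains))
        scatter = domain_scatter(domains)
        scatter.to_csv(outdir / "domain_scatter.tsv", sep="\t", index=False)
        manifest.declare("domain_scatter", outdir / "domain_scatter.tsv", len(scatter))

        stage = "architecture"
        track1 = all_tracks[(control, reps[0])]
        # segmentation reports borders only to bin resolution, so the border
        # tolerance grows by one segmentation bin on top of the base slack
        classes = classify_peaks(
            peaks,
            domains,
            border_slack_bp=BORDER_SLACK_BP + cfg.domain_bin_bp,
            track=track1,
        )
        with open(outdir / "peak_classes.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tsummit\tlabel\tflank_log2_ratio\n")
            for c in classes:
                p = c.peak
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t{c.label}\t"
                    f"{c.flank_log2_ratio:.4f}\n"
                )
        manifest.declare("peak_classes", outdir / "peak_classes.tsv", len(classes))
        if peaks:
            pm = profile_matrix(peaks, track1, cfg)
            _write_matrix(
                outdir / "profile_matrix.tsv", pm.matrix, pm.positions,
                "position_bp_from_summit",
            )
            manifest.declare(
                "profile_matrix", outdir / "profile_matrix.tsv", pm.matrix.shape[0]
            )
            vm = vplot(
                libraries[(control, reps[0])], [p.summit for p in peaks], cfg
            )
            _write_matrix(
                outdir / "vplot.tsv", vm.counts,
                (vm.x_edges[:-1] + vm.x_edges[1:]) / 2, "midpoint_offset_bp",
            )
            manifest.declare("vplot", outdir / "vplot.tsv", vm.total)

        stage = "quantify"
        regions = [
            Region(f"domain_{k}", d.chrom, d.start, d.end)
            for k, d in enumerate(domains, start=1)
        ] + [Region(f"peak_{k}", p.chrom, p.start, p.end)
             for k, p in enumerate(peaks, start=1)]
        pooled = {
            cond: [f for r in reps for f in libraries[(cond, r)]]
            for cond in conditions
        }
        quants = quantify_regions(pooled, regions, control=control)
        table = quant_table(quants)
        table.to_csv(outdir / "region_quant.tsv", sep="\t", index=False)
        manifest.declare("region_quant", outdir / "region_quant.tsv", len(table))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def _reproducible_domains(per_replicate: list[list[Domain]]) -> list[Domain]:
    """Replicate-1 domains overlapping a domain in every other replicate."""
    if len(per_replicate) == 1:
        return per_replicate[0]
    kept = []
    for d in per_replicate[0]:
        ok = True
        for rep in per_replicate[1:]:
            if not any(
                e.chrom == d.chrom and e.start < d.end and d.start < e.end
                for e in rep
            ):
                ok = False
                break
        if ok:
            kept.append(d)
    return kept


def _write_matrix(path: Path, matrix, col_labels, col_name: str) -> None:
    with open(path, "w") as fh:
        fh.write("# " + col_name + "\t" + "\t".join(f"{c:g}" for c in col_labels) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:g}" for v in row) + "\n")
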
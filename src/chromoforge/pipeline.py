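"""End-to-end orchestration: simulate -> screen -> qc -> linkage -> anchor ->
build -> liftover, from a single config, with a manifest of every artifact.

Every stage writes plain-text artifacts into the run directory and appends
survivor counts to the run report; re-running with the same config and seed
produces byte-identical payloads (no timestamps are embedded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tomllib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import anchoring, linkage, liftover, pseudomolecule, qc, screen, synth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScreenParams:
    n_chimeras: int = 5
    insert_mean: float = 5000.0
    insert_sd: float = 500.0
    coverage: float = 20.0
    read_length: int = 100
    min_span: int = 1
    edge_exclusion: int | None = None  # default: insert_mean + 3 sd
    min_contig: int = 1000

    def effective_edge_exclusion(self) -> int:
        if self.edge_exclusion is not None:
            return self.edge_exclusion
        return int(self.insert_mean + 3 * self.insert_sd)


@dataclass
class LinkageParams:
    rf_max: float = 0.35
    lod_min: float = 5.0


@dataclass
class AnchorParams:
    k_terminal: int = 3
    rounds: int = 1


@dataclass
class BuildParams:
    gap_size: int = 100
    density_window: int = 400_000


@dataclass
class LiftoverParams:
    flank: int = 20
    n_genes: int = 50
    max_intron_inflation: float = 10.0


@dataclass
class StageToggles:
    screen: bool = True
    qc: bool = True
    linkage: bool = True
    anchor: bool = True
    build: bool = True
    liftover: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "chromoforge_run"
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    screen: ScreenParams = field(default_factory=ScreenParams)
    qc: qc.QCParams = field(default_factory=qc.QCParams)
    linkage: LinkageParams = field(default_factory=LinkageParams)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    build: BuildParams = field(default_factory=BuildParams)
    liftover: LiftoverParams = field(default_factory=LiftoverParams)

    def __post_init__(self) -> None:
        # the master seed propagates to the simulator unless set explicitly
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)


_SECTION_TYPES = {
    "sim": synth.SimConfig,
    "stages": StageToggles,
    "screen": ScreenParams,
    "qc": qc.QCParams,
    "linkage": LinkageParams,
    "anchor": AnchorParams,
    "build": BuildParams,
    "liftover": LiftoverParams,
}


def load_config(path: str) -> RunConfig:
    """Parse a TOML run config; unknown sections or keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top = {k: v for k, v in raw.items() if not isinstance(v, dict)}
    unknown_top = set(top) - {"seed", "outdir"}
    if unknown_top:
        raise ValueError(f"unknown config keys: {sorted(unknown_top)}")
    sections = {k: v for k, v in raw.items() if isinstance(v, dict)}
    unknown_sec = set(sections) - set(_SECTION_TYPES)
    if unknown_sec:
        raise ValueError(f"unknown config sections: {sorted(unknown_sec)}")
    kwargs: dict[str, Any] = dict(top)
    for name, cls in _SECTION_TYPES.items():
        if name not in sections:
            continue
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sections[name]) - fields
        if unknown:
            raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
        payload = dict(sections[name])
        for key in ("seg_type_proportions",):
            if key in payload:
                payload[key] = tuple(payload[key])
        kwargs[name] = cls(**payload)
    return RunConfig(**kwargs)


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(report: RunReport, outdir: str, *names: str) -> None:
    for name in names:
        report.manifest[name] = _sha256(os.path.join(outdir, name))


def _scaffold_object_map(agp: pseudomolecule.AgpAssembly) -> dict[str, tuple]:
    """scaffold id -> (object, offset, orientation, length) from W records."""
    out = {}
    for rec in agp.records:
        if rec.component_type == "W":
            out[rec.component_id] = (
                rec.object, rec.object_beg - 1, rec.orientation,
                rec.component_end - rec.component_beg + 1,
            )
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in fixed order and write all artifacts.

    Against synthetic data the truth is known, so the report also carries
    recovery metrics (breakpoint detection, layout accuracy, transfer rate).
    """
    os.makedirs(config.outdir, exist_ok=True)
    report = RunReport()
    report.parameters = {
        name: dataclasses.asdict(getattr(config, name))
        for name in _SECTION_TYPES
    }
    report.parameters["seed"] = config.seed
    out = config.outdir

    def stage(name: str, enabled: bool = True):
        def wrap(fn):
            if not enabled:
                report.stages.append({"name": name, "status": "skipped"})
                return None
            try:
                details = fn() or {}
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                report.stages.append(
                    {"name": name, "status": "failed", "error": str(exc)}
                )
                report.to_json(os.path.join(out, "run_report.json"))
                raise PipelineError(name, str(exc)) from exc
            report.stages.append(
                {"name": name, "status": "ok", "details": details}
            )
            logger.info("stage %s: %s", name, details)
            return details

        return wrap

    state: dict[str, Any] = {}

    @stage("simulate")
    def _simulate():
        genome = synth.simulate_genome(config.sim)
        contigs, true_bps = synth.inject_misassemblies(
            genome, config.screen.n_chimeras, seed=config.seed
        )
        pairs = synth.simulate_mate_pairs(
            contigs,
            insert_mean=config.screen.insert_mean,
            insert_sd=config.screen.insert_sd,
            coverage=config.screen.coverage,
            read_length=config.screen.read_length,
            seed=config.seed,
        )
        gm = synth.degrade_genotypes(
            synth.simulate_cross(genome, config.sim), config.sim
        )
        genes = synth.simulate_gene_models(
            genome, config.liftover.n_genes, seed=config.seed
        )
        scaffolds = genome.scaffold_sequences()
        synth.write_fasta(scaffolds, os.path.join(out, "scaffolds.fasta"))
        synth.write_fasta(contigs.sequences, os.path.join(out, "contigs.fasta"))
        screen.write_pair_table(pairs, os.path.join(out, "pairs.tsv"))
        qc.write_vcf(gm, os.path.join(out, "genotypes.vcf"))
        liftover.write_gff3(genes, os.path.join(out, "genes.gff3"))
        synth.write_truth_json(
            genome, os.path.join(out, "truth.json"), breakpoints=true_bps
        )
        _register(report, out, "scaffolds.fasta", "contigs.fasta", "pairs.tsv",
                  "genotypes.vcf", "genes.gff3", "truth.json")
        state.update(
            genome=genome, contigs=contigs, true_bps=true_bps, pairs=pairs,
            gm=gm, genes=genes, scaffolds=scaffolds,
        )
        return {
            "n_scaffolds": len(scaffolds),
            "n_contigs": len(contigs.sequences),
            "n_pairs": len(pairs),
            "n_markers": gm.n_markers,
            "n_genes": len(genes),
        }

    @stage("screen", config.stages.screen)
    def _screen():
        contigs = state["contigs"]
        lengths = {cid: len(s) for cid, s in contigs.sequences.items()}
        calls = screen.detect_misassemblies(
            state["pairs"], lengths,
            min_span=config.screen.min_span,
            edge_exclusion=config.screen.effective_edge_exclusion(),
        )
        flat = [bp for bps in calls.values() for bp in bps]
        cleaned = screen.split_at_breakpoints(
            contigs.sequences, flat, min_length=config.screen.min_contig
        )
        screen.write_breakpoints_bed(flat, os.path.join(out, "breakpoints.bed"))
        synth.write_fasta(cleaned, os.path.join(out, "contigs_cleaned.fasta"))
        _register(report, out, "breakpoints.bed", "contigs_cleaned.fasta")
        truth = {bp.contig_id: bp.position for bp in state["true_bps"]}
        detected = sum(
            any(bp.window[0] <= pos <= bp.window[1]
                for bp in calls.get(cid, []))
            for cid, pos in truth.items()
        )
        false_calls = sum(
            len(bps) for cid, bps in calls.items() if cid not in truth
        ) + sum(
            sum(not (bp.window[0] <= truth[cid] <= bp.window[1]) for bp in bps)
            for cid, bps in calls.items() if cid in truth
        )
        report.metrics["chimera_detection_rate"] = (
            detected / len(truth) if truth else 1.0
        )
        report.metrics["false_breakpoint_calls"] = false_calls
        return {
            "n_breakpoints": len(flat),
            "n_true_chimeras": len(truth),
            "n_detected": detected,
            "false_calls": false_calls,
            "n_contigs_out": len(cleaned),
        }

    @stage("qc", config.stages.qc)
    def _qc():
        gm = qc.load_vcf(os.path.join(out, "genotypes.vcf"))
        filtered, qc_report = qc.run_qc_cascade(gm, config.qc)
        qc.write_vcf(filtered, os.path.join(out, "genotypes_qc.vcf"))
        pd.DataFrame(qc_report.to_rows()).to_csv(
            os.path.join(out, "qc_report.tsv"), sep="\t", index=False
        )
        _register(report, out, "genotypes_qc.vcf", "qc_report.tsv")
        state["gm_qc"] = filtered
        report.metrics["qc_survivors"] = filtered.n_markers
        return {s: n for s, n in qc_report.stages}

    @stage("linkage", config.stages.linkage)
    def _linkage():
        if "gm_qc" in state:
            gm = state["gm_qc"]
        else:
            report.warnings.append(
                "linkage running on raw genotypes: qc stage is disabled"
            )
            gm = qc.load_vcf(os.path.join(out, "genotypes.vcf"))
        rm = linkage.build_rf_matrix(gm)
        lga = linkage.assign_linkage_groups(
            rm, config.linkage.rf_max, config.linkage.lod_min
        )
        marker_scaffold = {m.marker_id: m.scaffold_id for m in gm.markers}
        conflicts = linkage.check_scaffold_consistency(lga, marker_scaffold)
        rm.write_tsv(os.path.join(out, "rf.tsv"), os.path.join(out, "lod.tsv"))
        lga.to_frame().to_csv(
            os.path.join(out, "linkage_groups.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"scaffold": c.scaffold_id,
                 "groups": ";".join(f"{g}:{n}" for g, n in c.groups)}
                for c in conflicts
            ],
            columns=["scaffold", "groups"],
        ).to_csv(os.path.join(out, "scaffold_conflicts.tsv"), sep="\t",
                 index=False)
        _register(report, out, "rf.tsv", "lod.tsv", "linkage_groups.tsv",
                  "scaffold_conflicts.tsv")
        state.update(rm=rm, lga=lga, marker_scaffold=marker_scaffold, gm_map=gm)
        report.metrics["n_linkage_groups"] = sum(
            1 for n in lga.sizes.values() if n >= 2
        )
        report.metrics["n_scaffold_conflicts"] = len(conflicts)
        return {
            "n_groups": report.metrics["n_linkage_groups"],
            "n_conflicts": len(conflicts),
        }

    @stage("anchor", config.stages.anchor)
    def _anchor():
        if "rm" not in state:
            raise PipelineError("anchor", "anchor requires the linkage stage")
        gm = state["gm_map"]
        positions = {m.marker_id: m.position for m in gm.markers}
        layout = anchoring.anchor(
            state["rm"], state["lga"], state["marker_scaffold"], positions,
            k_terminal=config.anchor.k_terminal, rounds=config.anchor.rounds,
        )
        layout.to_frame().to_csv(
            os.path.join(out, "layout.tsv"), sep="\t", index=False
        )
        marker_map = anchoring.build_marker_map(
            state["rm"], state["marker_scaffold"], positions
        )
        for g, order in layout.groups.items():
            ids, mat, bounds = anchoring.export_linkage_heatmap(
                state["rm"], order, marker_map
            )
            pd.DataFrame(mat, index=ids, columns=ids).to_csv(
                os.path.join(out, f"heatmap_group{g}.tsv"), sep="\t",
                float_format="%.6g",
            )
        _register(report, out, "layout.tsv")
        state["layout"] = layout
        metrics = anchoring.layout_accuracy(
            layout.groups,
            state["genome"].true_layout(),
            orientable={s for s, known in layout.orientation_known.items()
                        if known},
        )
        report.metrics.update(
            layout_adjacency_recall=metrics["adjacency_recall"],
            layout_orientation_accuracy=metrics["orientation_accuracy"],
        )
        return {
            "n_groups": len(layout.groups),
            "n_anchored": len(layout.all_scaffolds()),
            **{k: round(v, 4) for k, v in metrics.items()},
        }

    @stage("build", config.stages.build)
    def _build():
        if "layout" not in state:
            raise PipelineError("build", "build requires the anchor stage")
        scaffolds = state["scaffolds"]
        lengths = {sid: len(s) for sid, s in scaffolds.items()}
        agp = pseudomolecule.build_agp(
            state["layout"], lengths, gap_size=config.build.gap_size
        )
        agp.write(os.path.join(out, "assembly.agp"))
        objects = pseudomolecule.build_fasta(agp, scaffolds)
        synth.write_fasta(objects, os.path.join(out, "pseudomolecules.fasta"))
        stats = pseudomolecule.assembly_stats(scaffolds, state["layout"])
        with open(os.path.join(out, "assembly_stats.json"), "w") as fh:
            json.dump(stats.to_dict(), fh, indent=1, sort_keys=True)
        obj_map = _scaffold_object_map(agp)
        chrom_lengths = {
            name: len(s) for name, s in objects.items()
            if name.startswith("chr")
        }
        features = []
        gm = state.get("gm_map") or state["gm"]
        for m in gm.markers:
            if m.scaffold_id in obj_map:
                obj, off, orient, ln = obj_map[m.scaffold_id]
                if obj in chrom_lengths:
                    pos = off + (m.position if orient == "+" else ln - 1 - m.position)
                    features.append((obj, pos))
        pseudomolecule.density_tracks(
            features, chrom_lengths, window=config.build.density_window
        ).to_csv(os.path.join(out, "marker_density.tsv"), sep="\t", index=False)
        _register(report, out, "assembly.agp", "pseudomolecules.fasta",
                  "assembly_stats.json", "marker_density.tsv")
        state.update(agp=agp, objects=objects)
        report.metrics["assembly_n50"] = stats.n50
        report.metrics["anchored_pct"] = stats.anchored_pct
        return {"n50": stats.n50, "anchored_pct": round(stats.anchored_pct, 2)}

    @stage("liftover", config.stages.liftover)
    def _liftover():
        if "objects" not in state:
            raise PipelineError("liftover", "liftover requires the build stage")
        results = liftover.transfer_genes(
            state["genes"], state["scaffolds"], state["objects"],
            flank=config.liftover.flank,
            max_intron_inflation=config.liftover.max_intron_inflation,
        )
        transferred = [
            liftover.GeneModel(r.gene_id, r.seq_id, r.strand, r.exons)
            for r in results if r.status == "transferred"
        ]
        liftover.write_gff3(
            transferred, os.path.join(out, "genes_transferred.gff3")
        )
        summary = liftover.transfer_report(results)
        pd.DataFrame(
            [
                {"gene_id": r.gene_id, "status": r.status,
                 "reason": r.reason or "", "target": r.seq_id or ""}
                for r in results
            ]
        ).to_csv(os.path.join(out, "liftover_report.tsv"), sep="\t", index=False)
        _register(report, out, "genes_transferred.gff3", "liftover_report.tsv")
        report.metrics["transfer_rate_pct"] = summary["transfer_rate_pct"]
        return summary

    report.to_json(os.path.join(out, "run_report.json"))
    return report
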
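"""End-to-end orchestration of the turnover-detection stages on one config.

``run_pipeline`` executes simulate -> coverage -> subtract -> dating -> dosage
with a single root seed (per-stage streams are derived from it), writes a
machine-readable JSON report, and — since the simulator's truth is available —
scores every stage against it: window-label accuracy, Y-transcript
precision/recall, the XY-age estimate with its bootstrap CI, and the
per-tissue dosage calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__, coverage, dosage, io, simulate, subtract
from .align import ExactReadMapper, depth_tracks
from .dating import (
    GametologueRecord,
    classify_stratum,
    date_xy_system,
    gametologue_topology,
    pairwise_ds,
)
from .errors import ConfigurationError

logger = logging.getLogger("neoxy")

DEFAULT_CALIBRATION_AGE_MA = 85.7
DEFAULT_CALIBRATION_NODE = ("Basiliscus_vittatus", "Anolis_carolinensis")


@dataclass
class PipelineConfig:
    outdir: str = "neoxy_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "coverage": True, "subtract": True,
        "dating": True, "dosage": True,
    })
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    coverage: coverage.CoverageConfig = field(default_factory=coverage.CoverageConfig)
    subtract_k: int = 35
    subtract_min_count: int = 10
    subtract_min_overlap: int = 30
    species_tree: str = simulate.DEFAULT_SPECIES_TREE
    calibration_node: tuple[str, str] = DEFAULT_CALIBRATION_NODE
    calibration_age_ma: float = DEFAULT_CALIBRATION_AGE_MA
    n_bootstrap: int = 100
    dosage_alpha: float = 0.05
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "strata" in sim_raw:
            sim_raw["strata"] = tuple(
                simulate.Stratum(tuple(s["interval"]), float(s["arrest_ma"]))
                for s in sim_raw["strata"]
            )
        if "par_segments" in sim_raw:
            sim_raw["par_segments"] = tuple(tuple(p) for p in sim_raw["par_segments"])
        cov_raw = raw.pop("coverage", {})
        preset = cov_raw.pop("preset", None)
        cov = (coverage.CoverageConfig.preset(preset, **cov_raw) if preset
               else coverage.CoverageConfig(**cov_raw))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "calibration_node" in raw:
            raw["calibration_node"] = tuple(raw["calibration_node"])
        return cls(sim=simulate.SimConfig(**sim_raw), coverage=cov, **raw)

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.coverage.validate()
        return self


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    # independent per-stage streams derived from the root seed, kept < 2^31
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def subtract_scores(candidates, truth: simulate.SimTruth) -> dict:
    """Transcript-level precision/recall of accepted contigs against the
    planted male-specific Y transcripts (matched by male-genome placement)."""
    planted = truth.y_transcript_ids
    y_genes = truth.genes[truth.genes["y_copy"] == "retained"]
    recovered: set[str] = set()
    false_contigs = 0
    accepted = [c for c in candidates if c.status == subtract.ACCEPTED]
    for c in accepted:
        hit = c.male_hit
        match = None
        if hit is not None and hit.chrom == truth.y_chrom:
            for _, g in y_genes.iterrows():
                if hit.ref_start < g["y_end"] and hit.ref_start + hit.aligned_length > g["y_start"]:
                    match = f"{g['gene_id']}_Y"
                    break
        if match is None:
            false_contigs += 1
        else:
            recovered.add(match)
    tp = len(recovered & planted)
    fp = false_contigs + len(recovered - planted)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_accepted_contigs": len(accepted),
        "planted": sorted(planted),
        "recovered": sorted(recovered),
        "precision": precision,
        "recall": recall,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return (and write) the run report.

    Identical config and seed give an identical report; a stage failure halts
    the run with the failing stage named, keeping partial outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    seeds = _stage_seeds(config.seed)
    report: dict = {"neoxy_version": __version__, "seed": config.seed,
                    "stage_seeds": seeds, "stages_run": []}
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    order = ["simulate", "coverage", "subtract", "dating", "dosage"]
    runners = {
        "simulate": _stage_simulate, "coverage": _stage_coverage,
        "subtract": _stage_subtract, "dating": _stage_dating,
        "dosage": _stage_dosage,
    }
    for name in order:
        if not config.stages.get(name, False):
            continue
        logger.info("stage %s starting", name)
        try:
            report[name] = runners[name](config, seeds, state)
        except Exception as exc:
            report["failed_stage"] = name
            report["error"] = str(exc)
            if config.write_outputs:
                io.write_json(report, outdir / "report.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages_run"].append(name)
    if config.write_outputs:
        io.write_json(report, outdir / "report.json")
    return report


def _stage_simulate(config: PipelineConfig, seeds, state) -> dict:
    cfg = replace(config.sim, seed=seeds[0])
    male, female, truth = simulate.simulate_genome_pair(cfg)
    state.update(male=male, female=female, truth=truth, sim_cfg=cfg)
    state["male_reads"] = simulate.simulate_sample_reads(male, cfg, "male", seeds[1])
    state["female_reads"] = simulate.simulate_sample_reads(female, cfg, "female", seeds[1] + 1)
    out = {
        "autosomes": list(cfg.autosome_lengths),
        "x_length": cfg.x_length,
        "y_length": len(male.sequences["Y"]),
        "n_genes_total": int(len(truth.genes)),
        "n_y_retained": int((truth.genes["y_copy"] == "retained").sum()),
        "n_y_specific": len(truth.y_transcript_ids),
        "n_reads_male": len(state["male_reads"]),
        "n_reads_female": len(state["female_reads"]),
    }
    if config.write_outputs:
        outdir = Path(config.outdir)
        io.write_fasta(male.sequences, outdir / "male_genome.fa")
        io.write_fasta(female.sequences, outdir / "female_genome.fa")
        io.write_fastq(state["male_reads"], outdir / "male_dna.fastq")
        io.write_fastq(state["female_reads"], outdir / "female_dna.fastq")
        io.write_json(truth.to_dict(), outdir / "truth.json")
        (outdir / "species_tree.nwk").write_text(config.species_tree + "\n")
    return out


def _stage_coverage(config: PipelineConfig, seeds, state) -> dict:
    truth = state["truth"]
    mapper = ExactReadMapper(state["female"].sequences)
    male_tracks, male_unmapped = depth_tracks(state["male_reads"], mapper)
    female_tracks, female_unmapped = depth_tracks(state["female_reads"], mapper)
    windows = []
    for chrom in state["female"].sequences:
        windows.extend(coverage.classify_windows(
            male_tracks[chrom], female_tracks[chrom], config.coverage,
            chrom, on_x=(chrom == truth.x_chrom)))
    score = coverage.score_against_truth(windows, truth)
    x_hemi = [w for w in windows
              if w.chrom == truth.x_chrom
              and truth.label_window(w.chrom, w.start, w.end) == simulate.X_HEMI]
    out = {
        "male_unmapped": male_unmapped,
        "female_unmapped": female_unmapped,
        "n_windows": score["n_windows"],
        "label_accuracy": score["label_accuracy"],
        "par_runs": [list(r) for r in score["par_runs"]],
        "mean_male_depth_x_hemi": float(np.mean([w.male_depth for w in x_hemi]))
        if x_hemi else float("nan"),
        "mean_female_depth_x_hemi": float(np.mean([w.female_depth for w in x_hemi]))
        if x_hemi else float("nan"),
    }
    if config.write_outputs:
        coverage.windows_table(windows).to_csv(
            Path(config.outdir) / "windows.bed", sep="\t", index=False)
    state["windows"] = windows
    return out


def _stage_subtract(config: PipelineConfig, seeds, state) -> dict:
    cfg, truth = state["sim_cfg"], state["truth"]
    male_rna = simulate.simulate_rna_reads(truth, state["male"], cfg, "male", seeds[2])
    female_rna = simulate.simulate_rna_reads(truth, state["female"], cfg, "female", seeds[2] + 1)
    candidates, stats = subtract.run_subtraction(
        male_rna, female_rna, state["male"].sequences, state["female"].sequences,
        k=config.subtract_k, min_count=config.subtract_min_count,
        min_overlap=config.subtract_min_overlap)
    scores = subtract_scores(candidates, truth)
    if config.write_outputs:
        outdir = Path(config.outdir)
        subtract.candidates_table(candidates).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False)
        accepted = {c.id: c.sequence for c in candidates if c.status == subtract.ACCEPTED}
        io.write_fasta(accepted, outdir / "male_specific_transcripts.fa")
    return {"stats": stats, **scores}


def _stage_dating(config: PipelineConfig, seeds, state) -> dict:
    cfg = state["sim_cfg"]
    alignments = simulate.simulate_gametologues(
        cfg, species_tree=config.species_tree, seed=seeds[3])
    records = []
    for aln in alignments:
        rec = GametologueRecord(
            gene_id=aln.gene_id,
            x_seq=aln.sequences["X"], y_seq=aln.sequences["Y"],
            ds=pairwise_ds(aln.sequences["X"], aln.sequences["Y"]),
            outgroup_presence=aln.stratum == 1,
        )
        records.append(classify_stratum(rec))
    stratum1 = [a.sequences for a, r in zip(alignments, records) if r.stratum == 1]
    topology = gametologue_topology(config.species_tree)
    # in the gametologue tree the focal species is represented by its X tip
    calib = tuple(
        "X" if label == simulate.DEFAULT_FOCAL else label
        for label in config.calibration_node
    )
    dated = date_xy_system(
        stratum1, topology, calib,
        config.calibration_age_ma, n_bootstrap=config.n_bootstrap, seed=seeds[4])
    truth_arrest = max(st.arrest_ma for st in cfg.strata) if cfg.strata else float("nan")
    out = {
        "n_gametologues": len(records),
        "mean_ds_by_stratum": {
            str(s): float(np.mean([r.ds for r in records if r.stratum == s]))
            for s in sorted({r.stratum for r in records})
        },
        "xy_age_ma": dated.xy_age_ma,
        "ci95_ma": list(dated.ci95_ma) if dated.ci95_ma else None,
        "truth_arrest_ma": truth_arrest,
    }
    if config.write_outputs:
        outdir = Path(config.outdir)
        io.write_json(dated.to_dict(), outdir / "dating.json")
        rows = "\n".join(f"{r.gene_id}\t{r.ds:.4f}\t{r.stratum}" for r in records)
        (outdir / "gametologue_ds.tsv").write_text("gene\tds\tstratum\n" + rows + "\n")
    return out


def _stage_dosage(config: PipelineConfig, seeds, state) -> dict:
    cfg, truth = state["sim_cfg"], state["truth"]
    matrix = simulate.simulate_expression(truth, cfg, seeds[5])
    shared = matrix.genes_of_class("AUTOSOME")
    normalized = dosage.median_scale_normalize(matrix, shared)
    results = dosage.DosageCompensationAnalysis(normalized).fit(alpha=config.dosage_alpha)
    if config.write_outputs:
        outdir = Path(config.outdir)
        matrix.to_tsv(outdir / "tpm.tsv", outdir / "samples.tsv", outdir / "genes.tsv")
        results.summary().to_csv(outdir / "dosage_results.tsv", sep="\t", index=False)
    return {
        "calls": results.calls(),
        "median_log2_ratio": {
            r.tissue: r.median_log2_ratio for r in results.results
        },
    }


def generate_fixtures(seed: int, outdir, cfg: simulate.SimConfig | None = None,
                      n_per_stratum: tuple[int, ...] = (10, 10)) -> Path:
    """Write the demo/fixture dataset (default config) to ``outdir``:
    genomes, DNA reads, truth, gametologue alignments, species tree and the
    TPM matrix.  Deterministic in ``seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    cfg = replace(cfg or simulate.SimConfig(), seed=seeds[0])
    male, female, truth = simulate.simulate_genome_pair(cfg)
    io.write_fasta(male.sequences, outdir / "male_genome.fa")
    io.write_fasta(female.sequences, outdir / "female_genome.fa")
    io.write_fastq(simulate.simulate_sample_reads(male, cfg, "male", seeds[1]),
                   outdir / "male_dna.fastq")
    io.write_fastq(simulate.simulate_sample_reads(female, cfg, "female", seeds[1] + 1),
                   outdir / "female_dna.fastq")
    alignments = simulate.simulate_gametologues(
        cfg, seed=seeds[3], n_per_stratum=n_per_stratum)
    for aln in alignments:
        io.write_fasta(aln.sequences, outdir / f"gametologue_{aln.gene_id}.fa")
    matrix = simulate.simulate_expression(truth, cfg, seeds[5])
    matrix.to_tsv(outdir / "tpm.tsv", outdir / "samples.tsv", outdir / "genes.tsv")
    io.write_json(truth.to_dict(), outdir / "truth.json")
    (outdir / "species_tree.nwk").write_text(simulate.DEFAULT_SPECIES_TREE + "\n")
    return outdir
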
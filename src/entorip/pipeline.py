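"""End-to-end pipeline wiring the analysis stages together.

Stages communicate only through files in the package's declared formats —
no hidden in-memory coupling — so any stage can be replayed in isolation.
A run manifest records every output file with a SHA-256 checksum; with a
fixed config and seed the manifest checksums are identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import __version__
from . import domainarch, domainsets, enrichment, io_core, orthoccupancy
from . import ripscan as ripscan_mod
from . import synthetic_data as sim

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "ripscan", "enrich", "arch", "og")

_CONFIG_KEYS = {"seed", "out_dir", "stages", "inputs", "params", "log_level"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    out_dir: Path
    stages: tuple
    inputs: Mapping[str, str] = field(default_factory=dict)
    params: Mapping[str, Mapping] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        stages = tuple(raw.get("stages", KNOWN_STAGES))
        bad = [s for s in stages if s not in KNOWN_STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "entorip_out")),
            stages=stages,
            inputs=dict(raw.get("inputs", {})),
            params=dict(raw.get("params", {})),
            log_level=raw.get("log_level", "INFO"),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    p = config.params.get("simulate", {})
    genome_params = sim.SimGenomeParams(
        n_sequences=p.get("n_sequences", 1),
        length_bp=p.get("length_bp", 200_000),
        gc_fraction=p.get("gc_fraction", 0.5),
        repeat_families=tuple(
            sim.RepeatFamily(*f) for f in p.get(
                "repeat_families", [["rep1", 2000, 30]])),
        rip_rate=p.get("rip_rate", 0.2),
        rip_target_fraction=p.get("rip_target_fraction", 1.0),
        seed=config.seed)
    sequences, truth = sim.simulate_genome(genome_params)
    fasta = out / "genome.fasta"
    io_core.write_fasta(sequences, fasta)
    regions = out / "repeat_regions.tsv"
    with open(regions, "w") as handle:
        handle.write("seq_id\tstart\tend\tfamily_id\tripped\n")
        for r in truth.regions:
            handle.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.family_id}\t"
                         f"{str(r.ripped).lower()}\n")

    ann_params = sim.SimAnnotationParams(
        n_genomes=p.get("n_genomes", 4),
        n_domains=p.get("n_domains", 100),
        baseline_lambda=p.get("baseline_lambda", 10.0),
        totals=p.get("totals", 1000),
        planted_enrichments=tuple(
            sim.PlantedEnrichment(*e)
            for e in p.get("planted_enrichments",
                           [["SYN00000", "G1", 8.0]])),
        planted_architectures=tuple(
            sim.PlantedArchitecture(*a)
            for a in p.get("planted_architectures",
                           [["G1", "WC1", 1], ["G1", "AGO", 2],
                            ["G2", "RID_CANDIDATE", 1]])),
        seed=config.seed)
    records, totals, _ = sim.simulate_domain_annotations(ann_params)
    annotations = out / "annotations.tsv"
    io_core.write_domain_annotations(records, annotations)
    totals_path = out / "protein_totals.tsv"
    with open(totals_path, "w") as handle:
        handle.write("genome_id\tn_proteins\n")
        for genome, total in sorted(totals.items()):
            handle.write(f"{genome}\t{total}\n")

    og_params = sim.SimOgParams(
        species=tuple(p.get("species", ["EMU", "EMA", "ZRA", "NTH"])),
        n_core=p.get("n_core", 80),
        shared_counts={tuple(k.split(",")): v for k, v in p.get(
            "shared_counts", {"EMU,EMA": 20}).items()},
        specific_counts=p.get("specific_counts", {"EMU": 40, "ZRA": 10}),
        unassigned_counts=p.get("unassigned_counts", {"EMU": 30}),
        seed=config.seed)
    ogs, universe, expression, _ = sim.simulate_orthogroups(og_params)
    og_path = out / "orthogroups.tsv"
    io_core.write_orthogroups(ogs, og_path)
    universe_path = out / "gene_universe.tsv"
    with open(universe_path, "w") as handle:
        handle.write("species\tgene_id\n")
        for sp, genes in universe.items():
            for gene in genes:
                handle.write(f"{sp}\t{gene}\n")
    expr_path = out / "expression.tsv"
    io_core.write_expression(expression, expr_path)
    return [fasta, regions, annotations, totals_path, og_path,
            universe_path, expr_path]


def _stage_ripscan(config: PipelineConfig, out: Path) -> list[Path]:
    p = config.params.get("ripscan", {})
    fasta = Path(config.inputs.get("genome", out / "genome.fasta"))
    params = ripscan_mod.RipScanParams(
        window_bp=p.get("window_bp", 1000),
        step_bp=p.get("step_bp", 500),
        min_window_fraction=p.get("min_window_fraction", 0.5),
        rip_threshold=p.get("rip_threshold", 0.0))
    genome = io_core.read_fasta(fasta)
    windows = ripscan_mod.scan_windows(genome, params)
    summary = ripscan_mod.summarize_rip(windows, params)
    bed = out / "rip_composite.bedgraph"
    table = out / "rip_windows.tsv"
    summ = out / "rip_summary.json"
    ripscan_mod.write_bedgraph(windows, bed)
    ripscan_mod.write_window_table(windows, table)
    ripscan_mod.write_summary_json(summary, params, summ)
    return [bed, table, summ]


def _read_totals(path: Path) -> dict:
    totals = {}
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            genome, n = line.rstrip("\n").split("\t")
            totals[genome] = int(n)
    return totals


def _stage_enrich(config: PipelineConfig, out: Path) -> list[Path]:
    p = config.params.get("enrich", {})
    annotations = Path(config.inputs.get("annotations",
                                         out / "annotations.tsv"))
    totals_path = Path(config.inputs.get("totals",
                                         out / "protein_totals.tsv"))
    records = io_core.read_domain_annotations(annotations)
    totals = _read_totals(totals_path)
    matrix = domainsets.build_domain_count_matrix(
        records, totals, db_filter=p.get("db_filter"))
    params = enrichment.EnrichmentParams(
        alpha=p.get("alpha", 0.01),
        min_genomes_present=p.get("min_genomes_present", 2))
    results = enrichment.pairwise_domain_enrichment(matrix, params)
    path = out / "enrichment.tsv"
    with open(path, "w") as handle:
        handle.write("domain_accession\tdomain_db\tgenome\tcount\tmedian\t"
                     "fold\tdirection\tn_significant_pairs\tmin_adjusted_p\t"
                     "skipped\n")
        for r in results:
            min_p = min(r.pairwise_adjusted_p.values(), default=float("nan"))
            fold = "NA" if r.fold is None else f"{r.fold:.6g}"
            handle.write(
                f"{r.domain[0]}\t{r.domain[1]}\t{r.genome}\t{r.count}\t"
                f"{r.median_count:.6g}\t{fold}\t{r.direction}\t"
                f"{r.n_significant_pairs}\t{min_p:.6g}\t"
                f"{str(r.skipped).lower()}\n")
    sets = domainsets.domain_presence_sets(matrix)
    report = domainsets.exclusive_intersections(sets)
    inter_path = out / "intersections.tsv"
    domainsets.write_intersections(report, inter_path)
    return [path, inter_path]


def _stage_arch(config: PipelineConfig, out: Path) -> list[Path]:
    p = config.params.get("arch", {})
    annotations = Path(config.inputs.get("annotations",
                                         out / "annotations.tsv"))
    records = io_core.read_domain_annotations(annotations)
    ruleset = domainarch.RULESETS[p.get("rules", "all")]
    table = domainarch.classify_genome_candidates(records, ruleset)
    path = out / "architectures.tsv"
    with open(path, "w") as handle:
        handle.write("genome_id\tlabel\tn\tprotein_ids\n")
        for genome in sorted(table):
            for label, ids in table[genome].items():
                handle.write(f"{genome}\t{label}\t{len(ids)}\t"
                             + ",".join(ids) + "\n")
    survey = domainarch.survey_domains(
        records, list(domainarch.LIGHT_DOMAIN_SURVEY.values()))
    survey_path = out / "light_domain_survey.tsv"
    accs = list(domainarch.LIGHT_DOMAIN_SURVEY.values())
    with open(survey_path, "w") as handle:
        handle.write("genome_id\t" + "\t".join(accs) + "\n")
        for genome in sorted(survey):
            handle.write(genome + "\t" + "\t".join(
                str(survey[genome][a]) for a in accs) + "\n")
    return [path, survey_path]


def _stage_og(config: PipelineConfig, out: Path) -> list[Path]:
    p = config.params.get("og", {})
    og_path = Path(config.inputs.get("orthogroups", out / "orthogroups.tsv"))
    universe_path = Path(config.inputs.get("gene_universe",
                                           out / "gene_universe.tsv"))
    expr_path = Path(config.inputs.get("expression", out / "expression.tsv"))
    ogs = io_core.read_orthogroups(og_path)
    universe: dict[str, list] = {}
    with open(universe_path) as handle:
        handle.readline()
        for line in handle:
            sp, gene = line.rstrip("\n").split("\t")
            universe.setdefault(sp, []).append(gene)
    expression = io_core.read_expression(expr_path)

    classes = orthoccupancy.classify_orthogroups(ogs, list(universe))
    class_path = out / "og_classes.tsv"
    with open(class_path, "w") as handle:
        handle.write("og_id\tclass\tspecies\n")
        for og_id, occ in classes.items():
            handle.write(f"{og_id}\t{occ.kind}\t"
                         + ",".join(sorted(occ.species)) + "\n")
    summary = orthoccupancy.occupancy_summary(classes)
    statuses = orthoccupancy.classify_genes(ogs, universe)
    filt = orthoccupancy.apply_expression_filter(
        statuses, expression,
        orthoccupancy.OccupancyParams(
            min_total_counts=p.get("min_total_counts", 5.0)))
    summary_path = out / "og_summary.json"
    with open(summary_path, "w") as handle:
        json.dump({
            "n_ogs": summary.n_ogs,
            "n_core": summary.n_core,
            "pct_core": summary.pct_core,
            "pct_with_species": summary.pct_with_species,
            "pct_specific_by_species": summary.pct_specific_by_species,
            "gene_status_pct": orthoccupancy.gene_status_percentages(
                statuses),
            "potentially_specific_pct_before": filt["pct_before"],
            "potentially_specific_pct_after": filt["pct_after"],
        }, handle, indent=2)
        handle.write("\n")
    return [class_path, summary_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ripscan": _stage_ripscan,
    "enrich": _stage_enrich,
    "arch": _stage_arch,
    "og": _stage_og,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and write a manifest.

    Raises on stage failure after recording a FAILED marker for the stage
    in the manifest (partial outputs are retained).
    """
    for name, path in config.inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"input {name!r} does not exist: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    failure: Optional[BaseException] = None
    for stage in config.stages:
        entry: dict = {"stage": stage, "parameters":
                       dict(config.params.get(stage, {}))}
        t0 = time.monotonic()
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # record, then re-raise after writing
            entry["status"] = "FAILED"
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            failure = exc
            break
        entry["status"] = "ok"
        entry["wall_seconds"] = round(time.monotonic() - t0, 3)
        entry["outputs"] = [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for p in outputs]
        manifest["stages"].append(entry)
        logger.info("stage %s: %d output(s) in %.2fs", stage,
                    len(outputs), entry["wall_seconds"])
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
    if failure is not None:
        raise failure
    return manifest
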
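"""Simulators producing inputs with the statistical structure the analysis
stages assume.

Three generators:

* genomes — i.i.d. background nucleotides at a chosen GC fraction, with
  non-overlapping copies of repeat-family master units placed at random
  positions.  RIP mutations are applied to a chosen fraction of the repeat
  copies using the CpA context only: within a mutated region every CpA has
  its C switched to T with the given per-site rate, and every TpG (the
  reverse-strand CpA) has its G switched to A.  This is exactly the
  dinucleotide shift the composite RIP index measures, so index
  parameter-recovery tests stay interpretable.

* domain-annotation tables — per (genome, domain) protein counts drawn
  Poisson(baseline_lambda), replaced by Poisson(fold * baseline_lambda)
  for planted enrichments; planted architecture proteins carry exactly the
  rule-satisfying Pfam combination for their label, accompanied by
  near-miss decoy proteins that match no rule.  Random background domains
  use synthetic accessions disjoint from the rule Pfams.

* orthogroup tables — orthogroups built to a requested occupancy
  structure (core / shared subsets / species-specific) plus unassigned
  genes, with sparse pooled expression: per-gene totals follow a
  zero-inflated log-normal and are split evenly over the pooled samples
  (zero-total genes are omitted from the table, as transcript quantifiers
  do).

All randomness flows from a single seed through a named stream per
sub-simulator, so adding one simulator never perturbs another's draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_core import (DomainAnnotationRecord, ExpressionRecord,
                      GenomeSequence, OrthogroupRecord, ValidationError)
from . import domainarch

logger = logging.getLogger(__name__)

_STREAMS = {"genome": 1, "rip": 2, "domains": 3, "og": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


class CapacityError(ValueError):
    """Requested structure does not fit (repeats, protein totals...)."""


# ---------------------------------------------------------------------------
# Genome simulation


@dataclass(frozen=True)
class RepeatFamily:
    family_id: str
    unit_length: int
    n_copies: int


@dataclass(frozen=True)
class SimGenomeParams:
    n_sequences: int = 1
    length_bp: int = 100_000
    gc_fraction: float = 0.5
    repeat_families: tuple = ()
    rip_rate: float = 0.0
    rip_target_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if not (0 <= self.rip_rate <= 1):
            raise ValueError("rip_rate must be in [0, 1]")
        if not (0 <= self.rip_target_fraction <= 1):
            raise ValueError("rip_target_fraction must be in [0, 1]")
        total_repeat = sum(f.unit_length * f.n_copies
                           for f in self.repeat_families)
        if total_repeat > self.n_sequences * self.length_bp:
            raise ValueError("total repeat length exceeds sequence length")


@dataclass(frozen=True)
class RepeatRegion:
    seq_id: str
    start: int
    end: int
    family_id: str
    ripped: bool


@dataclass(frozen=True)
class GenomeTruth:
    regions: tuple  # of RepeatRegion
    mutated_sites: Mapping[str, tuple]  # seq_id -> site coordinates


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int,
                  gc_fraction: float) -> np.ndarray:
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    return rng.choice(_BASES, size=n, p=[at, gc, gc, at])


_PLACEMENT_ATTEMPT_CAP = 1000


def simulate_genome(params: SimGenomeParams):
    """Simulate sequences with planted repeat copies and optional RIP.

    Returns ``(sequences, truth)`` where truth records every repeat region
    (with whether it was subjected to RIP) and every mutated coordinate.
    """
    rng = _rng(params.seed, "genome")
    seqs = {
        f"chr{i + 1}": _random_bases(rng, params.length_bp,
                                     params.gc_fraction)
        for i in range(params.n_sequences)
    }
    seq_ids = list(seqs)

    # master unit per family, then non-overlapping copy placement by
    # rejection sampling with an attempt cap to guarantee termination
    occupied: dict[str, list] = {sid: [] for sid in seq_ids}
    regions: list[RepeatRegion] = []
    for fam in params.repeat_families:
        master = _random_bases(rng, fam.unit_length, params.gc_fraction)
        for _ in range(fam.n_copies):
            placed = False
            for _attempt in range(_PLACEMENT_ATTEMPT_CAP):
                sid = seq_ids[rng.integers(len(seq_ids))]
                if params.length_bp < fam.unit_length:
                    break
                start = int(rng.integers(
                    0, params.length_bp - fam.unit_length + 1))
                end = start + fam.unit_length
                if any(s < end and start < e for s, e in occupied[sid]):
                    continue
                occupied[sid].append((start, end))
                seqs[sid][start:end] = master
                regions.append(RepeatRegion(
                    seq_id=sid, start=start, end=end,
                    family_id=fam.family_id, ripped=False))
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place copy of {fam.family_id} after "
                    f"{_PLACEMENT_ATTEMPT_CAP} attempts")

    # choose which repeat copies undergo RIP
    rip_rng = _rng(params.seed, "rip")
    n_targets = round(params.rip_target_fraction * len(regions))
    target_idx = set(
        rip_rng.choice(len(regions), size=n_targets, replace=False)
        ) if regions else set()
    final_regions = []
    mutated_sites: dict[str, list] = {sid: [] for sid in seq_ids}
    for sid in seq_ids:
        target_regions = [
            (regions[i].start, regions[i].end)
            for i in sorted(target_idx) if regions[i].seq_id == sid]
        seq_str = seqs[sid].tobytes().decode("ascii")
        mutated, sites = apply_rip_mutations(
            seq_str, target_regions, params.rip_rate,
            rng=rip_rng)
        seqs[sid] = np.frombuffer(mutated.encode("ascii"), dtype=np.uint8)
        mutated_sites[sid] = sites
    for i, region in enumerate(regions):
        final_regions.append(RepeatRegion(
            seq_id=region.seq_id, start=region.start, end=region.end,
            family_id=region.family_id, ripped=i in target_idx))

    sequences = [
        GenomeSequence(seq_id=sid, residues=seqs[sid].tobytes().decode("ascii"))
        for sid in seq_ids]
    truth = GenomeTruth(
        regions=tuple(final_regions),
        mutated_sites={sid: tuple(v) for sid, v in mutated_sites.items()})
    logger.info("simulated %d sequence(s), %d repeat region(s), "
                "%d RIP-mutated site(s)", len(sequences), len(final_regions),
                sum(len(v) for v in mutated_sites.values()))
    return sequences, truth


def apply_rip_mutations(sequence: str, regions: Sequence[tuple],
                        rate: float, seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None):
    """Mutate CpA -> TpA (C to T) and TpG -> TpA (G to A, the
    reverse-strand CpA context) within the given regions.

    Eligible sites are read off the *input* sequence, each mutated
    independently with probability ``rate``.  Returns the mutated sequence
    and the sorted list of mutated coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    spans = sorted(regions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValidationError(f"overlapping regions {(s1, e1)} and "
                                  f"{(s2, e2)}")
    arr = bytearray(sequence.encode("ascii"))
    sites: list[int] = []
    for start, end in spans:
        if start < 0 or end > len(arr):
            raise ValidationError(f"region {(start, end)} outside sequence")
        window = sequence[start:end]
        for i in range(len(window) - 1):
            pair = window[i:i + 2]
            if pair == "CA" and rng.random() < rate:
                arr[start + i] = ord("T")
                sites.append(start + i)
            elif pair == "TG" and rng.random() < rate:
                arr[start + i + 1] = ord("A")
                sites.append(start + i + 1)
    return arr.decode("ascii"), sorted(sites)


# ---------------------------------------------------------------------------
# Domain annotation simulation


@dataclass(frozen=True)
class PlantedEnrichment:
    domain_accession: str
    genome_id: str
    fold: float


@dataclass(frozen=True)
class PlantedArchitecture:
    genome_id: str
    label: str
    n_proteins: int


@dataclass(frozen=True)
class SimAnnotationParams:
    n_genomes: int = 7
    n_domains: int = 500
    baseline_lambda: float = 20.0
    totals: int = 5000  # annotated proteins per genome
    planted_enrichments: tuple = ()
    planted_architectures: tuple = ()
    domain_db: str = "Pfam"
    with_decoys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for pe in self.planted_enrichments:
            if pe.fold <= 0:
                raise ValueError("planted fold must be > 0")


@dataclass(frozen=True)
class AnnotationTruth:
    planted_enrichments: tuple
    planted_proteins: Mapping[tuple, tuple]  # (genome, label) -> protein ids
    decoy_proteins: Mapping[str, tuple]      # genome -> protein ids


#: minimal Pfam combination satisfying each built-in rule label (and no
#: other label), used for planting
PLANT_COMBOS = {
    "FRQ": {domainarch.PF_FRQ: 1},
    "WC1": {domainarch.PF_GATA: 1, domainarch.PF_PAS_3: 1,
            domainarch.PF_PAS_9: 1},
    "WC2": {domainarch.PF_GATA: 1, domainarch.PF_PAS_3: 1},
    "RHODOPSIN": {domainarch.PF_7TM_1: 1},
    "RDRP": {domainarch.PF_RDRP: 1},
    "DICER": {domainarch.PF_DICER_DIMER: 1},
    "AGO": {domainarch.PF_PAZ: 1, domainarch.PF_PIWI: 1},
    "DICER_ALT": {domainarch.PF_RNASE_3: 1, domainarch.PF_DEAD: 1},
    "RID_CANDIDATE": {domainarch.PF_DNA_METHYLASE: 2},
}

#: near-miss domain profiles matching no rule label
DECOY_COMBOS = (
    {domainarch.PF_GATA: 1},                  # GATA without PAS_3
    {domainarch.PF_PAZ: 1},                   # PAZ without Piwi/RNase III
    {domainarch.PF_DNA_METHYLASE: 1},         # single methylase domain
    {domainarch.PF_PAS_3: 1, domainarch.PF_PAS_9: 1},  # PAS without GATA
)


def genome_ids(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def domain_accessions(n: int) -> list[str]:
    # synthetic accessions, deliberately disjoint from real rule Pfams
    return [f"SYN{i:05d}" for i in range(n)]


def simulate_domain_annotations(params: SimAnnotationParams):
    """Simulate a multi-genome annotation table with planted effects.

    Returns ``(records, totals, truth)``; ``totals`` maps genome id to its
    annotated-protein count and always covers the planted proteins.
    """
    rng = _rng(params.seed, "domains")
    genomes = genome_ids(params.n_genomes)
    domains = domain_accessions(params.n_domains)
    fold_of = {(pe.genome_id, pe.domain_accession): pe.fold
               for pe in params.planted_enrichments}

    records: list[DomainAnnotationRecord] = []
    totals: dict[str, int] = {}
    planted_map: dict[tuple, list] = {}
    decoy_map: dict[str, list] = {g: [] for g in genomes}

    for genome in genomes:
        protein_pool = [f"{genome}_p{k + 1}" for k in range(params.totals)]
        for domain in domains:
            lam = params.baseline_lambda * fold_of.get((genome, domain), 1.0)
            count = int(rng.poisson(lam))
            if count > params.totals:
                raise CapacityError(
                    f"{genome}/{domain}: drawn count {count} exceeds "
                    f"protein total {params.totals}")
            if count == 0:
                continue
            carriers = rng.choice(params.totals, size=count, replace=False)
            for k in carriers:
                records.append(DomainAnnotationRecord(
                    genome_id=genome, protein_id=protein_pool[int(k)],
                    domain_accession=domain, domain_db=params.domain_db,
                    n_instances=1))
        next_id = params.totals
        for pa in params.planted_architectures:
            if pa.genome_id != genome:
                continue
            combo = PLANT_COMBOS[pa.label]
            ids = []
            for _ in range(pa.n_proteins):
                next_id += 1
                pid = f"{genome}_arch{next_id}"
                ids.append(pid)
                for acc, n_inst in combo.items():
                    records.append(DomainAnnotationRecord(
                        genome_id=genome, protein_id=pid,
                        domain_accession=acc, domain_db="Pfam",
                        n_instances=n_inst))
            planted_map.setdefault((genome, pa.label), []).extend(ids)
        if params.with_decoys and any(
                pa.genome_id == genome
                for pa in params.planted_architectures):
            for combo in DECOY_COMBOS:
                next_id += 1
                pid = f"{genome}_decoy{next_id}"
                decoy_map[genome].append(pid)
                for acc, n_inst in combo.items():
                    records.append(DomainAnnotationRecord(
                        genome_id=genome, protein_id=pid,
                        domain_accession=acc, domain_db="Pfam",
                        n_instances=n_inst))
        totals[genome] = next_id

    truth = AnnotationTruth(
        planted_enrichments=tuple(params.planted_enrichments),
        planted_proteins={k: tuple(v) for k, v in planted_map.items()},
        decoy_proteins={g: tuple(v) for g, v in decoy_map.items()})
    return records, totals, truth


def simulate_domain_count_matrix(params: SimAnnotationParams):
    """Draw a genome x domain count matrix directly (no protein records).

    Same count law as :func:`simulate_domain_annotations` — Poisson
    baseline with planted fold-enrichments — materialised as a
    DomainCountMatrix.  This is the replicate-friendly path for
    enrichment calibration studies, where only the counts matter.
    """
    from .domainsets import DomainCountMatrix

    rng = _rng(params.seed, "domains")
    genomes = tuple(genome_ids(params.n_genomes))
    domains = tuple((acc, params.domain_db)
                    for acc in domain_accessions(params.n_domains))
    lam = np.full((params.n_genomes, params.n_domains),
                  params.baseline_lambda)
    g_index = {g: i for i, g in enumerate(genomes)}
    d_index = {acc: i for i, (acc, _) in enumerate(domains)}
    for pe in params.planted_enrichments:
        lam[g_index[pe.genome_id], d_index[pe.domain_accession]] *= pe.fold
    counts = rng.poisson(lam)
    if counts.max(initial=0) > params.totals:
        raise CapacityError("drawn count exceeds protein total")
    keep = counts.any(axis=0)
    matrix = DomainCountMatrix(
        genomes=genomes,
        domains=tuple(d for d, k in zip(domains, keep) if k),
        counts=counts[:, keep],
        totals={g: params.totals for g in genomes})
    truth = AnnotationTruth(
        planted_enrichments=tuple(params.planted_enrichments),
        planted_proteins={}, decoy_proteins={})
    return matrix, truth


# ---------------------------------------------------------------------------
# Orthogroup simulation


@dataclass(frozen=True)
class SimOgParams:
    species: tuple = ("EMU", "EMA", "ZRA", "NTH")
    n_core: int = 200
    shared_counts: Mapping[tuple, int] = field(default_factory=dict)
    specific_counts: Mapping[str, int] = field(default_factory=dict)
    unassigned_counts: Mapping[str, int] = field(default_factory=dict)
    max_genes_per_og: int = 3
    p_zero_expression: float = 0.3
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.5
    n_samples: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_zero_expression <= 1):
            raise ValueError("p_zero_expression must be in [0, 1]")
        for subset in self.shared_counts:
            unknown = set(subset) - set(self.species)
            if unknown:
                raise ValueError(f"unknown species in subset: {unknown}")
            if not (1 < len(subset) < len(self.species)):
                raise ValueError(
                    "shared subsets must be strictly between one species "
                    "and all species")


@dataclass(frozen=True)
class OgTruth:
    og_class: Mapping[str, str]        # og_id -> core/shared/specific kind
    gene_class: Mapping[tuple, str]    # (species, gene) -> status
    gene_totals: Mapping[str, float]   # gene -> pooled expression total


def simulate_orthogroups(params: SimOgParams):
    """Simulate OG membership, the gene universe and pooled expression.

    Returns ``(og_records, gene_universe, expression_records, truth)``.
    """
    rng = _rng(params.seed, "og")
    species = list(params.species)
    counters = dict.fromkeys(species, 0)
    gene_universe: dict[str, list] = {sp: [] for sp in species}

    def new_gene(sp: str) -> str:
        counters[sp] += 1
        gene = f"{sp}_g{counters[sp]:06d}"
        gene_universe[sp].append(gene)
        return gene

    og_records: list[OrthogroupRecord] = []
    og_class: dict[str, str] = {}
    gene_class: dict[tuple, str] = {}
    og_n = 0

    def add_og(present: Sequence[str], kind: str) -> None:
        nonlocal og_n
        og_n += 1
        og_id = f"OG{og_n:07d}"
        members = {}
        for sp in species:
            if sp in present:
                n_genes = int(rng.integers(1, params.max_genes_per_og + 1))
                members[sp] = tuple(new_gene(sp) for _ in range(n_genes))
            else:
                members[sp] = ()
        og_records.append(OrthogroupRecord(og_id=og_id, members=members))
        og_class[og_id] = kind
        status = ("assigned_species_specific" if kind == "species-specific"
                  else "assigned_shared")
        for sp in present:
            for gene in members[sp]:
                gene_class[(sp, gene)] = status

    for _ in range(params.n_core):
        add_og(species, "core")
    for subset, count in params.shared_counts.items():
        for _ in range(count):
            add_og(list(subset), "shared-subset")
    for sp in species:
        for _ in range(params.specific_counts.get(sp, 0)):
            add_og([sp], "species-specific")
        for _ in range(params.unassigned_counts.get(sp, 0)):
            gene = new_gene(sp)
            gene_class[(sp, gene)] = "unassigned"

    # pooled expression: zero-inflated log-normal totals, split evenly
    expression: list[ExpressionRecord] = []
    gene_totals: dict[str, float] = {}
    sample_ids = [f"s{j + 1:02d}" for j in range(params.n_samples)]
    for sp in species:
        for gene in gene_universe[sp]:
            if rng.random() < params.p_zero_expression:
                total = 0.0
            else:
                total = float(rng.lognormal(params.lognormal_mu,
                                            params.lognormal_sigma))
            gene_totals[gene] = total
            if total > 0:
                share = total / params.n_samples
                for sid in sample_ids:
                    expression.append(ExpressionRecord(
                        gene_id=gene, sample_id=sid, est_counts=share))

    truth = OgTruth(og_class=og_class, gene_class=gene_class,
                    gene_totals=gene_totals)
    gene_universe_t = {sp: tuple(v) for sp, v in gene_universe.items()}
    logger.info("simulated %d OG(s), %d gene(s)", len(og_records),
                sum(len(v) for v in gene_universe_t.values()))
    return og_records, gene_universe_t, expression, truth
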
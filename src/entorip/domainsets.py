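"""Genome x domain count matrices and set-membership structure.

The count matrix records, for every genome and every domain accession, the
number of distinct proteins carrying at least one instance of the domain
("accessions containing a domain" — proteins, not domain instances), plus
the total number of annotated proteins per genome, which later serves as
the background margin for enrichment tests.

The set layer reduces counts to presence/absence and computes exclusive
intersections (UpSet-style): each domain is assigned to exactly one subset
of genomes — the exact set of genomes that contain it — so subset counts
partition the domain universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import DomainAnnotationRecord, PathLike, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainCountMatrix:
    """Protein counts per (genome, domain) with per-genome totals.

    ``domains`` are (accession, db) pairs; all-zero domain columns are
    excluded by construction.
    """

    genomes: tuple
    domains: tuple  # of (accession, domain_db)
    counts: np.ndarray  # shape (n_genomes, n_domains), int
    totals: Mapping[str, int]

    def __post_init__(self) -> None:
        for gi, genome in enumerate(self.genomes):
            total = self.totals[genome]
            if self.counts.size and self.counts[gi].max(initial=0) > total:
                raise ValidationError(
                    f"genome {genome}: domain count exceeds protein total "
                    f"{total}")

    def count(self, genome: str, accession: str) -> int:
        gi = self.genomes.index(genome)
        di = next(i for i, (acc, _) in enumerate(self.domains)
                  if acc == accession)
        return int(self.counts[gi, di])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.T,
            index=pd.MultiIndex.from_tuples(
                self.domains, names=["domain_accession", "domain_db"]),
            columns=list(self.genomes))


@dataclass(frozen=True)
class IntersectionReport:
    """Exclusive-intersection counts over genome subsets.

    ``exclusive`` maps a frozenset of genomes to the sorted tuple of
    domains present in exactly those genomes; ``unique`` is the per-genome
    single-genome slice of the same partition.
    """

    genomes: tuple
    exclusive: Mapping[frozenset, tuple]
    unique: Mapping[str, tuple]

    def counts_sorted(self) -> list[tuple[frozenset, int]]:
        """(subset, size) pairs ordered by size descending, then subset."""
        items = [(s, len(d)) for s, d in self.exclusive.items()]
        items.sort(key=lambda kv: (-kv[1], sorted(kv[0])))
        return items


def build_domain_count_matrix(
        records: Iterable[DomainAnnotationRecord],
        totals: Mapping[str, int],
        db_filter: Optional[str] = None) -> DomainCountMatrix:
    """Count distinct proteins per (genome, domain).

    ``totals`` must cover every genome present in the records; a protein
    with several instances of a domain counts once.  ``db_filter``
    restricts the matrix to one domain database.
    """
    seen_proteins: dict[tuple, set] = {}
    for rec in records:
        if db_filter is not None and rec.domain_db != db_filter:
            continue
        if rec.genome_id not in totals:
            raise ValidationError(
                f"genome {rec.genome_id!r} missing from totals")
        key = (rec.genome_id, (rec.domain_accession, rec.domain_db))
        seen_proteins.setdefault(key, set()).add(rec.protein_id)

    genomes = tuple(sorted(totals))
    domains = tuple(sorted({key[1] for key in seen_proteins}))
    counts = np.zeros((len(genomes), len(domains)), dtype=np.int64)
    g_index = {g: i for i, g in enumerate(genomes)}
    d_index = {d: i for i, d in enumerate(domains)}
    for (genome, domain), proteins in seen_proteins.items():
        counts[g_index[genome], d_index[domain]] = len(proteins)
    return DomainCountMatrix(genomes=genomes, domains=domains,
                             counts=counts, totals=dict(totals))


def domain_presence_sets(matrix: DomainCountMatrix) -> dict:
    """Genome -> set of domains with count >= 1."""
    return {
        genome: {matrix.domains[di]
                 for di in np.nonzero(matrix.counts[gi])[0]}
        for gi, genome in enumerate(matrix.genomes)
    }


def exclusive_intersections(sets: Mapping[str, set]) -> IntersectionReport:
    """Partition the domain universe by the exact genome subset holding
    each domain (the quantity an UpSet plot displays)."""
    if not sets:
        raise ValidationError("need at least one genome")
    genomes = tuple(sorted(sets))
    assignment: dict[object, frozenset] = {}
    for domain in set().union(*sets.values()):
        assignment[domain] = frozenset(
            g for g in genomes if domain in sets[g])
    exclusive: dict[frozenset, list] = {}
    for domain, subset in assignment.items():
        exclusive.setdefault(subset, []).append(domain)
    exclusive_sorted = {s: tuple(sorted(d)) for s, d in exclusive.items()}
    unique = {
        g: exclusive_sorted.get(frozenset({g}), ())
        for g in genomes
    }
    return IntersectionReport(genomes=genomes, exclusive=exclusive_sorted,
                              unique=unique)


def unique_and_missing_domains(matrix: DomainCountMatrix, focal: str):
    """Domains found only in the focal genome, and domains the focal
    genome lacks but at least one other genome has."""
    if focal not in matrix.genomes:
        raise KeyError(f"unknown focal genome {focal!r}")
    presence = domain_presence_sets(matrix)
    focal_set = presence[focal]
    others = set().union(*(presence[g] for g in matrix.genomes
                           if g != focal)) if len(matrix.genomes) > 1 else set()
    unique = tuple(sorted(focal_set - others))
    missing = tuple(sorted(others - focal_set))
    return unique, missing


def write_count_matrix(matrix: DomainCountMatrix, path: PathLike) -> None:
    df = matrix.to_frame().reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: PathLike, totals: Mapping[str, int]
                      ) -> DomainCountMatrix:
    df = pd.read_csv(path, sep="\t")
    domains = tuple(
        (row.domain_accession, row.domain_db)
        for row in df.itertuples(index=False))
    genomes = tuple(c for c in df.columns
                    if c not in ("domain_accession", "domain_db"))
    counts = df[list(genomes)].to_numpy(dtype=np.int64).T
    return DomainCountMatrix(genomes=genomes, domains=domains,
                             counts=counts, totals=dict(totals))


def write_intersections(report: IntersectionReport, path: PathLike) -> None:
    with open(path, "w") as out:
        out.write("genomes\tn_domains\tdomains\n")
        for subset, n in report.counts_sorted():
            out.write(",".join(sorted(subset)) + f"\t{n}\t"
                      + ";".join(str(d[0]) for d in report.exclusive[subset])
                      + "\n")
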
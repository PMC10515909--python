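"""Readers and writers for the toolkit's external formats.

All tabular formats are UTF-8, tab-separated text with a mandatory header
row.  The domain-annotation dialect is defined by this package (one row per
genome/protein/domain triple); the orthogroup dialect follows the de facto
``Orthogroups.tsv`` layout written by common orthology tools (first column
the orthogroup id, one column per species, cells holding comma-separated
gene ids), so real clustering outputs load unchanged.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

DOMAIN_DBS = ("Pfam", "CAZy", "MEROPS")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class ValidationError(ValueError):
    """Record-level constraint violated (negative counts, missing keys...)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A nucleotide sequence with an identifier.

    ``residues`` is uppercase over the alphabet {A, C, G, T, N}; lowercase
    input is folded to uppercase at read time and anything else rejected.
    """

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.residues) - NUCLEOTIDE_ALPHABET
        if bad:
            offset = next(
                i for i, ch in enumerate(self.residues) if ch in bad
            )
            raise AlphabetError(
                f"sequence {self.seq_id!r}: illegal character "
                f"{self.residues[offset]!r} at position {offset + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotationRecord:
    """One protein-domain call: a protein in a genome carries a domain.

    ``n_instances`` counts how many copies of the domain the protein holds
    (>= 1).  ``secreted`` is the upstream secretion prediction if present.
    """

    genome_id: str
    protein_id: str
    domain_accession: str
    domain_db: str
    n_instances: int
    secreted: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.domain_db not in DOMAIN_DBS:
            raise FormatError(
                f"unknown domain_db {self.domain_db!r}; "
                f"expected one of {DOMAIN_DBS}"
            )
        if self.n_instances < 1:
            raise ValidationError(
                f"n_instances must be >= 1, got {self.n_instances} for "
                f"{self.genome_id}/{self.protein_id}/{self.domain_accession}"
            )


@dataclass(frozen=True)
class OrthogroupRecord:
    """An orthogroup: species mapped to their (possibly empty) gene lists."""

    og_id: str
    members: Mapping[str, tuple]

    def species_present(self) -> frozenset:
        return frozenset(s for s, genes in self.members.items() if genes)


@dataclass(frozen=True)
class ExpressionRecord:
    """Estimated counts for one gene in one sample."""

    gene_id: str
    sample_id: str
    est_counts: float

    def __post_init__(self) -> None:
        if self.est_counts < 0:
            raise ValidationError(
                f"negative est_counts {self.est_counts} for "
                f"{self.gene_id}/{self.sample_id}"
            )


@dataclass(frozen=True)
class GenomeCatalogEntry:
    """One genome in a multi-species catalog (sizes in base pairs)."""

    species: str
    assembly_size: int
    gene_count: int
    phylum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assembly_size <= 0:
            raise ValidationError(f"assembly_size must be > 0 for {self.species}")
        if self.gene_count <= 0:
            raise ValidationError(f"gene_count must be > 0 for {self.species}")


@dataclass(frozen=True)
class CatalogSummary:
    median_assembly_size: float
    median_gene_count: float
    n_included: int
    n_excluded: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence objects.

    The header token before the first whitespace becomes ``seq_id``;
    lowercase residues are folded to uppercase.  Raises FormatError for an
    empty or malformed file and AlphabetError for illegal characters.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise FormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: expected '>' header on line 1")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append(GenomeSequence(seq_id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    logger.info("read %d sequence(s) from %s", len(records), path)
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: PathLike,
                width: int = 80) -> None:
    with open(path, "w") as out:
        for seq in sequences:
            out.write(f">{seq.seq_id}\n")
            for i in range(0, len(seq.residues), width):
                out.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain annotations

_ANNOT_COLUMNS = ["genome_id", "protein_id", "domain_accession",
                  "domain_db", "n_instances"]

_BOOL_MAP = {"true": True, "1": True, "yes": True,
             "false": False, "0": False, "no": False}


def read_domain_annotations(path: PathLike) -> list[DomainAnnotationRecord]:
    """Read the domain-annotation TSV dialect.

    Duplicate rows for the same (genome, protein, accession) key have their
    instance counts summed; a ``secreted`` column is optional.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    has_secreted = "secreted" in df.columns
    try:
        df["n_instances"] = df["n_instances"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer n_instances: {exc}") from exc
    if (df["n_instances"] < 0).any():
        raise ValidationError(f"{path}: negative n_instances")

    aggregated: dict[tuple, dict] = {}
    for row in df.itertuples(index=False):
        key = (row.genome_id, row.protein_id, row.domain_accession)
        secreted = None
        if has_secreted and isinstance(row.secreted, str):
            token = row.secreted.strip().lower()
            if token:
                if token not in _BOOL_MAP:
                    raise FormatError(
                        f"{path}: unparseable secreted value {row.secreted!r}")
                secreted = _BOOL_MAP[token]
        if key in aggregated:
            aggregated[key]["n_instances"] += row.n_instances
            if secreted is not None:
                aggregated[key]["secreted"] = secreted
        else:
            aggregated[key] = {
                "domain_db": row.domain_db,
                "n_instances": row.n_instances,
                "secreted": secreted,
            }
    records = [
        DomainAnnotationRecord(
            genome_id=g, protein_id=p, domain_accession=d,
            domain_db=v["domain_db"], n_instances=v["n_instances"],
            secreted=v["secreted"],
        )
        for (g, p, d), v in aggregated.items()
    ]
    logger.info("read %d annotation record(s) from %s", len(records), path)
    return records


def write_domain_annotations(records: Iterable[DomainAnnotationRecord],
                             path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append({
            "genome_id": r.genome_id,
            "protein_id": r.protein_id,
            "domain_accession": r.domain_accession,
            "domain_db": r.domain_db,
            "n_instances": r.n_instances,
            "secreted": "" if r.secreted is None else str(r.secreted).lower(),
        })
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS + ["secreted"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Orthogroups


def read_orthogroups(path: PathLike) -> list[OrthogroupRecord]:
    """Read an Orthogroups.tsv-style table.

    First column holds the orthogroup id, remaining columns one species
    each; cells are comma-separated gene ids (empty cell = no members).
    """
    path = Path(path)
    records: list[OrthogroupRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.split("\t")
        if len(columns) < 2:
            raise FormatError(f"{path}: need an OG column plus >=1 species")
        species = columns[1:]
        n_cols = len(columns)
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != n_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(cells)}")
            og_id = cells[0]
            if og_id in seen:
                raise FormatError(f"{path}: duplicate og_id {og_id!r} "
                                  f"(line {lineno})")
            seen.add(og_id)
            members = {}
            all_genes: list[str] = []
            for sp, cell in zip(species, cells[1:]):
                genes = tuple(g.strip() for g in cell.split(",") if g.strip())
                members[sp] = genes
                all_genes.extend(genes)
            if len(set(all_genes)) != len(all_genes):
                raise FormatError(
                    f"{path}: duplicate gene id within {og_id}")
            records.append(OrthogroupRecord(og_id=og_id, members=members))
    logger.info("read %d orthogroup(s) from %s", len(records), path)
    return records


def write_orthogroups(records: Sequence[OrthogroupRecord],
                      path: PathLike) -> None:
    if not records:
        raise ValidationError("no orthogroups to write")
    species = list(records[0].members.keys())
    with open(path, "w") as out:
        out.write("Orthogroup\t" + "\t".join(species) + "\n")
        for rec in records:
            cells = [", ".join(rec.members.get(sp, ())) for sp in species]
            out.write(rec.og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Expression


def read_expression(path: PathLike) -> list[ExpressionRecord]:
    """Read an expression table, long or wide form (auto-detected).

    Long form has columns (gene_id, sample_id, est_counts); any other
    header is treated as wide form: first column gene ids, remaining
    columns one sample each.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = list(df.columns)
    records: list[ExpressionRecord] = []
    if cols[:3] == ["gene_id", "sample_id", "est_counts"]:
        for row in df.itertuples(index=False):
            records.append(ExpressionRecord(str(row.gene_id),
                                            str(row.sample_id),
                                            float(row.est_counts)))
    else:
        gene_col = cols[0]
        samples = cols[1:]
        if not samples:
            raise FormatError(f"{path}: wide table needs >=1 sample column")
        for _, row in df.iterrows():
            for sample in samples:
                records.append(ExpressionRecord(str(row[gene_col]),
                                                str(sample),
                                                float(row[sample])))
    seen = set()
    for r in records:
        key = (r.gene_id, r.sample_id)
        if key in seen:
            raise FormatError(f"{path}: duplicate (gene, sample) pair {key}")
        seen.add(key)
    logger.info("read %d expression record(s) from %s", len(records), path)
    return records


def write_expression(records: Iterable[ExpressionRecord],
                     path: PathLike) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.sample_id, r.est_counts) for r in records],
        columns=["gene_id", "sample_id", "est_counts"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome catalog


def read_genome_catalog(path: PathLike) -> list[GenomeCatalogEntry]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("species", "assembly_size", "gene_count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    entries = []
    for row in df.itertuples(index=False):
        phylum = getattr(row, "phylum", None)
        if phylum is not None and pd.isna(phylum):
            phylum = None
        entries.append(GenomeCatalogEntry(
            species=str(row.species),
            assembly_size=int(row.assembly_size),
            gene_count=int(row.gene_count),
            phylum=phylum))
    return entries


def write_genome_catalog(entries: Iterable[GenomeCatalogEntry],
                         path: PathLike) -> None:
    df = pd.DataFrame(
        [(e.species, e.assembly_size, e.gene_count, e.phylum or "")
         for e in entries],
        columns=["species", "assembly_size", "gene_count", "phylum"])
    df.to_csv(path, sep="\t", index=False)


def summarize_genome_catalog(catalog: Sequence[GenomeCatalogEntry],
                             size_cutoff: float) -> CatalogSummary:
    """Median assembly size and gene count after excluding outsized genomes.

    Entries with assembly_size > size_cutoff (base pairs) are excluded
    before the medians are taken; for an even number of remaining entries
    the median is the midpoint of the central pair.
    """
    if not catalog:
        raise ValidationError("empty genome catalog")
    included = [e for e in catalog if e.assembly_size <= size_cutoff]
    n_excluded = len(catalog) - len(included)
    if not included:
        raise ValidationError(
            f"all {len(catalog)} catalog entries exceed the "
            f"{size_cutoff:g} bp cutoff")
    return CatalogSummary(
        median_assembly_size=statistics.median(
            e.assembly_size for e in included),
        median_gene_count=statistics.median(
            e.gene_count for e in included),
        n_included=len(included),
        n_excluded=n_excluded,
    )
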
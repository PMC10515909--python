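"""Orthogroup occupancy classes and gene-level orthogroup status.

An orthogroup (OG) is classed by the exact set of species contributing at
least one gene: *core* (every species in the analysis universe present),
*species-specific* (exactly one species) or *shared-subset* (any other
non-empty subset, identified by that subset).  Genes are then classed as
assigned to a shared OG, assigned to a species-specific OG, or unassigned;
the latter two together form the *potentially species-specific* gene set,
which can be filtered by pooled expression evidence (genes whose total
estimated counts across the pooled samples fall below a threshold are
dropped, absent genes counting as zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_core import (ExpressionRecord, OrthogroupRecord, ValidationError)

logger = logging.getLogger(__name__)

CORE = "core"
SHARED_SUBSET = "shared-subset"
SPECIES_SPECIFIC = "species-specific"

ASSIGNED_SHARED = "assigned_shared"
ASSIGNED_SPECIES_SPECIFIC = "assigned_species_specific"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class OccupancyClass:
    """Occupancy class of one OG plus the exact species subset."""

    kind: str  # CORE | SHARED_SUBSET | SPECIES_SPECIFIC
    species: frozenset


@dataclass(frozen=True)
class GeneStatus:
    gene_id: str
    species: str
    status: str  # ASSIGNED_SHARED | ASSIGNED_SPECIES_SPECIFIC | UNASSIGNED
    expressed: Optional[bool] = None

    @property
    def potentially_species_specific(self) -> bool:
        return self.status != ASSIGNED_SHARED


@dataclass(frozen=True)
class OccupancyParams:
    """Expression-filter settings for the potentially-specific gene set."""

    min_total_counts: float = 5.0
    species_universe: tuple = ()

    def __post_init__(self) -> None:
        if self.min_total_counts < 0:
            raise ValueError("min_total_counts must be >= 0")


def classify_orthogroups(ogs: Sequence[OrthogroupRecord],
                         species_universe: Sequence[str]) -> dict:
    """og_id -> OccupancyClass, from the exact species subset with >= 1
    gene.  Every member species must belong to the universe."""
    universe = frozenset(species_universe)
    if not universe:
        raise ValidationError("empty species universe")
    out: dict[str, OccupancyClass] = {}
    for og in ogs:
        present = og.species_present()
        unknown = present - universe
        if unknown:
            raise ValidationError(
                f"{og.og_id}: species {sorted(unknown)} not in universe")
        if not present:
            raise ValidationError(f"{og.og_id}: no member genes")
        if present == universe:
            kind = CORE
        elif len(present) == 1:
            kind = SPECIES_SPECIFIC
        else:
            kind = SHARED_SUBSET
        out[og.og_id] = OccupancyClass(kind=kind, species=present)
    return out


@dataclass(frozen=True)
class OccupancySummary:
    n_ogs: int
    n_core: int
    pct_core: float
    subset_counts: Mapping[frozenset, int]
    subset_percentages: Mapping[frozenset, float]
    pct_with_species: Mapping[str, float]       # OGs containing >= 1 gene
    pct_specific_by_species: Mapping[str, float]


def occupancy_summary(classified: Mapping[str, OccupancyClass]
                      ) -> OccupancySummary:
    """Per-class counts/percentages over all OGs, plus per-species
    participation and species-specific percentages."""
    if not classified:
        raise ValidationError("no orthogroups to summarize")
    n = len(classified)
    subset_counts: dict[frozenset, int] = {}
    species: set = set()
    for occ in classified.values():
        subset_counts[occ.species] = subset_counts.get(occ.species, 0) + 1
        species |= occ.species
    universe = frozenset(species)
    n_core = sum(cnt for sub, cnt in subset_counts.items()
                 if sub == universe)
    pct_with = {
        sp: 100.0 * sum(cnt for sub, cnt in subset_counts.items()
                        if sp in sub) / n
        for sp in sorted(species)}
    pct_specific = {
        sp: 100.0 * subset_counts.get(frozenset({sp}), 0) / n
        for sp in sorted(species)}
    return OccupancySummary(
        n_ogs=n, n_core=n_core, pct_core=100.0 * n_core / n,
        subset_counts=subset_counts,
        subset_percentages={s: 100.0 * c / n
                            for s, c in subset_counts.items()},
        pct_with_species=pct_with,
        pct_specific_by_species=pct_specific)


def classify_genes(ogs: Sequence[OrthogroupRecord],
                   gene_universe: Mapping[str, Sequence[str]]
                   ) -> list[GeneStatus]:
    """Per-gene OG status for every gene in the universe.

    ``gene_universe`` maps species -> all annotated gene ids.  Genes in no
    OG are unassigned; genes in a single-species OG are assigned
    species-specific; the rest are assigned shared.
    """
    universe_sets = {sp: set(genes) for sp, genes in gene_universe.items()}
    classes = classify_orthogroups(ogs, list(gene_universe))
    status_of: dict[tuple, str] = {}
    for og in ogs:
        occ = classes[og.og_id]
        status = (ASSIGNED_SPECIES_SPECIFIC
                  if occ.kind == SPECIES_SPECIFIC else ASSIGNED_SHARED)
        for sp, genes in og.members.items():
            for gene in genes:
                if gene not in universe_sets.get(sp, ()):
                    raise ValidationError(
                        f"{og.og_id}: gene {gene!r} not in {sp} universe")
                status_of[(sp, gene)] = status
    out = []
    for sp in sorted(gene_universe):
        for gene in gene_universe[sp]:
            out.append(GeneStatus(
                gene_id=gene, species=sp,
                status=status_of.get((sp, gene), UNASSIGNED)))
    return out


def gene_status_percentages(statuses: Sequence[GeneStatus]) -> dict:
    """Per-species percentage of each status plus the potentially-
    species-specific share (sums to 100 per species across statuses)."""
    by_species: dict[str, list] = {}
    for st in statuses:
        by_species.setdefault(st.species, []).append(st)
    out = {}
    for sp, items in sorted(by_species.items()):
        n = len(items)
        counts = {ASSIGNED_SHARED: 0, ASSIGNED_SPECIES_SPECIFIC: 0,
                  UNASSIGNED: 0}
        for st in items:
            counts[st.status] += 1
        out[sp] = {
            "n_genes": n,
            **{k: 100.0 * v / n for k, v in counts.items()},
            "potentially_species_specific": 100.0 * (
                counts[ASSIGNED_SPECIES_SPECIFIC] + counts[UNASSIGNED]) / n,
        }
    return out


def apply_expression_filter(
        statuses: Sequence[GeneStatus],
        expression: Sequence[ExpressionRecord],
        params: OccupancyParams = OccupancyParams()) -> dict:
    """Filter the potentially-species-specific set by pooled expression.

    A gene is retained iff the sum of its estimated counts across all
    samples reaches ``min_total_counts``; genes absent from the expression
    table total zero and are removed.  Returns the retained statuses plus
    per-species percentages before/after filtering.
    """
    totals: dict[str, float] = {}
    for rec in expression:
        totals[rec.gene_id] = totals.get(rec.gene_id, 0.0) + rec.est_counts

    candidates = [st for st in statuses if st.potentially_species_specific]
    retained = [st for st in candidates
                if totals.get(st.gene_id, 0.0) >= params.min_total_counts]

    def pct_by_species(subset):
        genes_per_species: dict[str, int] = {}
        for st in statuses:
            genes_per_species[st.species] = (
                genes_per_species.get(st.species, 0) + 1)
        kept: dict[str, int] = {}
        for st in subset:
            kept[st.species] = kept.get(st.species, 0) + 1
        return {sp: 100.0 * kept.get(sp, 0) / n
                for sp, n in sorted(genes_per_species.items())}

    return {
        "retained": retained,
        "n_before": len(candidates),
        "n_after": len(retained),
        "pct_before": pct_by_species(candidates),
        "pct_after": pct_by_species(retained),
    }
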
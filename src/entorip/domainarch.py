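"""Rule-based protein domain-architecture classification.

Candidate genes for the fungal circadian clock, the RNAi pathway and the
RIP-associated methyltransferase RID are identified purely from the Pfam
domain content of each protein: a rule is a set of per-domain instance
constraints (min/max copies) and a protein matches a label when every
constraint holds.  "At least one" is the default reading of a required
domain (tandem repeats of a domain are common in Pfam annotations and
should not disqualify a candidate); exclusions such as "no PAS_9" are
exact-zero constraints.

Built-in rule sets:

* circadian — FRQ (FRQ domain), WC1 (GATA + PAS_3 + PAS_9), WC2 (GATA +
  PAS_3, no PAS_9), RHODOPSIN (7tm_1);
* rnai — RDRP (RdRP), DICER (Dicer_dimer), AGO (PAZ + Piwi), DICER_ALT
  (Ribonuclease_3 plus DEAD or PAZ);
* rid — RID_CANDIDATE: at least two DNA_methylase (PF00145) instances on
  one protein.  (Adjacency of the two domains is not checked: the
  annotation table carries no coordinates.)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io_core import DomainAnnotationRecord, PathLike, ValidationError

logger = logging.getLogger(__name__)

UNBOUNDED = None


@dataclass(frozen=True)
class ArchitectureRule:
    """A labelled conjunction of per-domain instance-count constraints.

    ``constraints`` holds (accession, min_instances, max_instances)
    triples; ``max_instances`` of None means unbounded.  Disjunctions are
    expressed as alternative constraint lists: a protein matches if any
    alternative is fully satisfied.
    """

    label: str
    alternatives: tuple  # of tuples of (accession, min, max-or-None)

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValidationError(f"rule {self.label}: no constraints")
        for alt in self.alternatives:
            if not any(lo >= 1 for _, lo, _ in alt):
                raise ValidationError(
                    f"rule {self.label}: needs >=1 required domain")
            for acc, lo, hi in alt:
                if hi is not None and lo > hi:
                    raise ValidationError(
                        f"rule {self.label}: min > max for {acc}")

    def matches(self, domain_counts: Mapping[str, int]) -> bool:
        for alt in self.alternatives:
            ok = True
            for acc, lo, hi in alt:
                n = domain_counts.get(acc, 0)
                if n < lo or (hi is not None and n > hi):
                    ok = False
                    break
            if ok:
                return True
        return False


def rule(label: str, *constraints) -> ArchitectureRule:
    return ArchitectureRule(label=label, alternatives=(tuple(constraints),))


# Pfam accessions used by the built-in rules
PF_FRQ = "PF09421"
PF_GATA = "PF00320"
PF_PAS_3 = "PF08447"
PF_PAS_9 = "PF13426"
PF_7TM_1 = "PF00001"
PF_RDRP = "PF05183"
PF_DICER_DIMER = "PF03368"
PF_PAZ = "PF02170"
PF_PIWI = "PF02171"
PF_RNASE_3 = "PF00636"
PF_DEAD = "PF00270"
PF_DNA_METHYLASE = "PF00145"

CIRCADIAN_RULES = (
    rule("FRQ", (PF_FRQ, 1, None)),
    rule("WC1", (PF_GATA, 1, None), (PF_PAS_3, 1, None), (PF_PAS_9, 1, None)),
    rule("WC2", (PF_GATA, 1, None), (PF_PAS_3, 1, None), (PF_PAS_9, 0, 0)),
    rule("RHODOPSIN", (PF_7TM_1, 1, None)),
)

RNAI_RULES = (
    rule("RDRP", (PF_RDRP, 1, None)),
    rule("DICER", (PF_DICER_DIMER, 1, None)),
    rule("AGO", (PF_PAZ, 1, None), (PF_PIWI, 1, None)),
    ArchitectureRule(
        label="DICER_ALT",
        alternatives=(
            ((PF_RNASE_3, 1, None), (PF_DEAD, 1, None)),
            ((PF_RNASE_3, 1, None), (PF_PAZ, 1, None)),
        ),
    ),
)

RID_RULES = (
    rule("RID_CANDIDATE", (PF_DNA_METHYLASE, 2, None)),
)

RULESETS = {
    "circadian": CIRCADIAN_RULES,
    "rnai": RNAI_RULES,
    "rid": RID_RULES,
    "all": CIRCADIAN_RULES + RNAI_RULES + RID_RULES,
}

#: single-domain survey list for light-sensing and clock-associated Pfams
LIGHT_DOMAIN_SURVEY = {
    "7tm_1": "PF00001",
    "Bac_rhodopsin": "PF01036",
    "DNA_photolyase": "PF00875",
    "FAD_binding_7": "PF03441",
    "PHY": "PF00360",
    "GpcrRhopsn4": "PF10192",
    "GAF": "PF01590",
    "PAS": "PF00989",
    "PAS_3": "PF08447",
    "PAS_9": "PF13426",
    "GATA": "PF00320",
    "FRQ": "PF09421",
}


def classify_protein_architecture(
        protein_domains: Mapping[str, int],
        ruleset: Sequence[ArchitectureRule]) -> list[str]:
    """All rule labels a protein's domain-count profile satisfies, in
    ruleset order (a protein may match several labels)."""
    for acc, n in protein_domains.items():
        if n < 0:
            raise ValidationError(f"negative instance count for {acc}")
    return [r.label for r in ruleset if r.matches(protein_domains)]


def _proteins_by_genome(records: Iterable[DomainAnnotationRecord]) -> dict:
    out: dict[str, dict[str, dict[str, int]]] = {}
    for rec in records:
        domains = out.setdefault(rec.genome_id, {}).setdefault(
            rec.protein_id, {})
        domains[rec.domain_accession] = (
            domains.get(rec.domain_accession, 0) + rec.n_instances)
    return out


def survey_domains(records: Iterable[DomainAnnotationRecord],
                   domain_list: Sequence[str]) -> dict:
    """Per-genome count of distinct proteins carrying each listed domain.

    Absent domains are reported with count 0 (surveys report absences).
    """
    if not domain_list:
        raise ValidationError("empty domain list")
    genomes = _proteins_by_genome(records)
    table: dict[str, dict[str, int]] = {}
    for genome, proteins in genomes.items():
        row = dict.fromkeys(domain_list, 0)
        for domains in proteins.values():
            for acc in domain_list:
                if domains.get(acc, 0) >= 1:
                    row[acc] += 1
        table[genome] = row
    return table


def classify_genome_candidates(
        records: Iterable[DomainAnnotationRecord],
        ruleset: Sequence[ArchitectureRule]) -> dict:
    """Apply the ruleset to every protein of every genome.

    Returns genome -> label -> sorted tuple of matching protein ids; every
    label appears for every genome, possibly with an empty tuple.
    """
    genomes = _proteins_by_genome(records)
    labels = [r.label for r in ruleset]
    out: dict[str, dict[str, tuple]] = {}
    for genome, proteins in genomes.items():
        hits: dict[str, list] = {label: [] for label in labels}
        for protein_id, domains in proteins.items():
            for label in classify_protein_architecture(domains, ruleset):
                hits[label].append(protein_id)
        out[genome] = {label: tuple(sorted(ids))
                       for label, ids in hits.items()}
    return out


def load_ruleset(path: PathLike) -> tuple:
    """Load a custom rule set from JSON.

    Layout: {"LABEL": [[accession, min, max-or-null], ...] or
    {"any_of": [[...], [...]]}} — the latter expresses disjunctions.
    """
    with open(path) as handle:
        raw = json.load(handle)
    rules = []
    for label, spec in raw.items():
        if isinstance(spec, dict) and "any_of" in spec:
            alternatives = tuple(
                tuple((acc, int(lo), None if hi is None else int(hi))
                      for acc, lo, hi in alt)
                for alt in spec["any_of"])
        else:
            alternatives = (tuple(
                (acc, int(lo), None if hi is None else int(hi))
                for acc, lo, hi in spec),)
        rules.append(ArchitectureRule(label=label, alternatives=alternatives))
    return tuple(rules)
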
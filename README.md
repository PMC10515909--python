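# entorip

Comparative-genomics toolkit for entomophthoralean fungi (and other
repeat-rich genomes): windowed RIP-index genome scanning, cross-genome
protein-domain enrichment, rule-based domain-architecture classification,
orthogroup occupancy analysis, and matched synthetic-data generators so
every stage is testable without genome downloads.

## Who this is for

Fungal comparative genomicists who have a set of assemblies and their
domain annotations (Pfam / CAZy / MEROPS), orthology-clustering output
(`Orthogroups.tsv` layout) and optionally pooled expression counts, and
want reproducible answers to questions like: *how much of this genome has
been altered by repeat-induced point mutation? which domain families are
expanded or depleted relative to the other genomes? which proteins look
like White Collar 1, Dicer, Argonaute or RID? which orthogroups and genes
are species-specific?*

## The statistics at the core

**Composite RIP index.** Repeat-induced point mutation (RIP) converts C→T
in repetitive DNA, preferentially in the CpA context (TpG on the reverse
strand). In a sliding window (default 1 kb every 500 bp) the index is

    composite = TpA/ApT − (CpA + TpG)/(ApC + GpT)

Windows with composite > 0 are RIP-positive; the genome-level "%RIPped"
is the share of evaluable windows (both denominators > 0) that are
RIP-positive.

**Pairwise domain enrichment.** For every domain present in ≥ 2 genomes
and every unordered genome pair (i, j), a two-sided Fisher exact test on

    [[ c_i, T_i − c_i ],
     [ c_j, T_j − c_j ]]

where c is the number of proteins carrying the domain and T the total
annotated proteins. P-values are Bonferroni-corrected within each
domain's family of C(G, 2) pairwise tests and called significant at
corrected p < 0.01; each (domain, genome) additionally gets a fold and
direction versus the cross-genome median count. Gene-set enrichment
(subset vs universe) reports the odds ratio ad/bc per Pfam with a
two-sided exact p (threshold p ≤ 0.001), including a NO_PFAM
pseudo-domain for genes without any Pfam assignment.

**Architecture rules.** Candidates are called purely from per-protein
Pfam instance counts, e.g. WC1 = GATA ∧ PAS_3 ∧ PAS_9; WC2 = GATA ∧
PAS_3 ∧ no PAS_9; AGO = PAZ ∧ Piwi; RID candidate = ≥ 2 DNA_methylase
(PF00145) instances on one protein.

**Orthogroup occupancy.** Orthogroups are classed core / shared-subset /
species-specific by the exact species set with ≥ 1 gene; genes are
assigned-shared / assigned-species-specific / unassigned, and the
potentially-species-specific set (the latter two) can be filtered by
pooled expression (drop genes with summed estimated counts < 5).

## Worked example

```python
from entorip.synthetic_data import (SimGenomeParams, RepeatFamily,
                                    simulate_genome)
from entorip.ripscan import scan_windows, summarize_rip

params = SimGenomeParams(
    length_bp=500_000, gc_fraction=0.5,
    repeat_families=(RepeatFamily("rep1", 3000, 50),),  # 30% repeats
    rip_rate=0.2, seed=77)
seqs, truth = simulate_genome(params)
summary = summarize_rip(scan_windows(seqs))
print(f"{summary.n_rip_positive}/{summary.n_evaluable} windows RIP-positive "
      f"({summary.pct_ripped:.1f}% RIPped)")
```

prints

```
668/999 windows RIP-positive (66.9% RIPped)
```

i.e. on a genome whose repeat copies (30% of 500 kb) were C→T mutated at
a per-site rate of 0.2, about two thirds of all 1 kb windows score
RIP-positive; the unmutated twin of the same genome (rate 0) scores
45.6%, so the index separates the two conditions clearly. The same
machinery is available from the shell:

```sh
entorip ripscan genome.fasta --window 1000 --step 500
entorip domains enrich annotations.tsv totals.tsv --alpha 0.01
entorip arch classify annotations.tsv --rules all
entorip og classify orthogroups.tsv --species EMU,EMA,ZRA,NTH
entorip run --config demo.json        # simulate → scan → enrich → classify
```

On published count tables the statistics reproduce the printed numbers:
the 2×2 chi-squared on [[17, 3], [45, 60]] (secretion status of under-
vs overrepresented Pfam families) gives p = 0.00055; the BD-FAE
(PF20434) counts {1, 2, 3, 23, 25, 20, 23} give a 20-fold depletion of
the focal genome versus the median.

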
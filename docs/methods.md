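# Methods

This note documents the models and procedures implemented in `entorip`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## RIP-index scanning (`entorip.ripscan`)

Repeat-induced point mutation (RIP) is a fungal genome-defence process
that converts cytosine to thymine in repetitive DNA, dominantly in the
CpA dinucleotide context (whose reverse-strand image is TpG). Its
footprint is a dinucleotide skew: TpA rises while the CpA/TpG substrate
pool falls. The composite index per window is

    product   = TpA / ApT
    substrate = (CpA + TpG) / (ApC + GpT)
    composite = product − substrate

computed from overlapping dinucleotides counted left-to-right on the
stored strand. Computing the same quantities on the reverse complement
maps CpA↔TpG and ApC↔GpT and leaves TpA and ApT fixed, so the composite
index is strand-invariant; this is asserted by property tests, and
justifies scanning the forward strand only.

Parameters (`RipScanParams`): `window_bp` (default 1000), `step_bp`
(default 500), `min_window_fraction` (default 0.5) and `rip_threshold`
(default 0). Defaults give 1 kb windows every 500 bp with windows called
RIP-positive when composite is strictly greater than zero.

Numerical and edge-case choices:

* A window is *evaluable* only when both denominators (ApT and ApC+GpT)
  are positive; non-evaluable windows carry no signal and all three
  indices are undefined for them.
* **%RIPped denominator.** The genome-level percentage is taken over
  evaluable windows, not all windows, because a non-evaluable window is
  evidence of nothing. The JSON summary records the denominator
  convention and all raw counts so the all-windows figure is recoverable
  from the same output.
* **Terminal short windows** are kept iff they reach at least half a full
  window (`min_window_fraction`), balancing discarded sequence against
  unstable ratios on tiny windows. Windows never cross sequence
  boundaries.
* **N handling.** Windows containing N are kept; only N-containing pairs
  are dropped from the counts. Masked assemblies are the expected input.
* The index is a deterministic statistic, not a hypothesis test, so no
  multiple-testing machinery applies per window.

Note that on i.i.d. random sequence the composite index is centred near
zero, so roughly half of random windows score "positive"; the statistic
is informative as a *contrast* (mutated vs unmutated sequence, or genome
vs genome), which is how it is used here and how the percentages should
be read.

## Domain count matrices and set structure (`entorip.domainsets`)

Counts are *proteins carrying at least one instance* of a domain, not
domain instances; instance counts remain available in the annotation
records. Callers must supply one record set per gene's representative
protein (e.g. the longest peptide per gene) — the matrix builder does not
attempt isoform deduplication, because isoform→gene mapping is
input-specific.

Exclusive intersections assign each domain to the exact subset of
genomes containing it, so subset counts partition the domain universe
(property-tested); the per-genome "unique domain" list is the
single-genome cell of this partition, and the unique/missing analysis is
consistent with it by construction.

## Enrichment statistics (`entorip.enrichment`)

**Fisher's exact test** is implemented directly: conditioning on the
margins, the first cell is hypergeometric, and the two-sided p sums the
probabilities of all tables no more probable than the observed one. A
relative tolerance of 1e−7 on that comparison absorbs floating error in
the tie decision. The scalar path uses exact integer arithmetic
(`math.comb` with integer cross-multiplication for the tie comparison);
the vectorised batch path works in log space from a shared log-factorial
table. Tests verify both paths against an exact-rational enumeration
oracle and against an independent library implementation.

**Pairwise enrichment** design choices:

* The 2×2 background margin is total annotated proteins per genome — the
  only genome-level denominator available in the count tables; this is
  recorded in the output.
* The Bonferroni family is the set of pairwise comparisons for a single
  domain (C(G, 2) tests), matching per-domain pairwise-test semantics and
  making "number of significant pairwise comparisons" a per-domain
  quantity. Significance is corrected p strictly below `alpha` (default
  0.01). Benjamini–Hochberg is available behind `correction="bh"` but is
  not the default procedure.
* Domains present in fewer than `min_genomes_present` (default 2) genomes
  are reported with a `skipped` flag and no tests.
* A reporting-level "overrepresented in g" call is direction = up with at
  least one significant pair (symmetrically for "underrepresented"); this
  minimal rule is exposed as `DomainEnrichmentResult.representation` and
  is configurable by consumers.
* Pairs in which neither genome carries the domain have a degenerate
  (single-table) conditional distribution; their p is 1 by definition
  rather than an error, since the domain passed the presence filter
  globally.

**Fold versus median** uses the median over all genomes including the
focal one (even n: midpoint of the central pair); fold is max/min ≥ 1
with an infinite sentinel when one side is zero and the counts differ.

**Gene-set enrichment** builds a 2×2 of set-membership × domain-presence
over the gene universe per Pfam, plus a NO_PFAM pseudo-domain for genes
without any Pfam record. The odds ratio is ad/bc (+∞ when bc = 0) and
significance is p ≤ `gene_set_alpha` (default 0.001). Degenerate designs
(set = universe, empty set, domain in every gene) are flagged and never
significant. The universe should be passed explicitly; otherwise it
defaults to annotated genes plus the set.

**Chi-squared 2×2** is the Pearson statistic with 1 df, *without*
continuity correction by default (correction available via flag).

## Architecture rules (`entorip.domainarch`)

A rule is a conjunction of per-domain instance-count constraints, with
disjunctions expressed as alternative constraint lists. "One GATA and one
PAS_3..." is read as *at least one* — Pfam routinely reports tandem
repeats of a domain, and a strict exactly-one reading would silently drop
biologically identical candidates — while explicit exclusions ("no
PAS_9") are exact-zero constraints. Constraint bounds are data (JSON
rule files), so a strict reading is one config edit away. Proteins may
match several labels; the built-in WC1/WC2 pair is mutually exclusive by
construction (PAS_9 ≥ 1 vs = 0).

The RID candidate rule is ≥ 2 DNA_methylase (PF00145) instances on one
protein. Known divergence: adjacency of the two domains is *not* checked,
because the annotation table carries no coordinates; a coordinate-aware
check would require the raw domain-scanner output, which is out of scope.

## Orthogroup occupancy (`entorip.orthoccupancy`)

Classes are determined by the exact species subset with ≥ 1 gene; the
species universe must be given explicitly so orthogroups from a larger
clustering can be sliced deterministically. Gene statuses partition each
species' universe (percentages sum to 100, asserted to 1e−9).

The expression filter applies "fewer than 5 estimated counts" to the
*sum* over the pooled samples, strict inequality (total ≥ 5 retained);
both the aggregation and the threshold are parameters. Genes absent from
the expression table count as zero rather than erroring, because
transcript quantifiers routinely omit zero-count genes.

## Synthetic data (`entorip.synthetic_data`)

The generators produce inputs with exactly the structure the analyses
assume, so recovery tests are interpretable:

* **Genomes**: i.i.d. background at a set GC fraction; one master unit
  per repeat family; copies placed non-overlapping by rejection sampling
  (attempt cap 1000 per copy guarantees termination). RIP mutation uses
  only the CpA↔TpG context — the dominant RIP context and precisely the
  shift the composite index measures — applied per eligible site
  independently at the given rate, with eligible sites read off the
  pre-mutation sequence.
* **Annotation tables**: per (genome, domain) protein counts are
  Poisson(λ), replaced by Poisson(fold·λ) for planted enrichments;
  background accessions are synthetic (SYNxxxxx) and disjoint from the
  rule Pfams, so planted architectures (minimal rule-satisfying
  combinations plus near-miss decoys) are recovered exactly iff the
  classifier is correct. A count-matrix-only fast path
  (`simulate_domain_count_matrix`) draws the same count law without
  materialising protein records, for replicate studies.
* **Orthogroups**: occupancy structure is planted directly (core /
  per-subset shared / species-specific counts plus unassigned genes);
  per-gene pooled expression totals follow a zero-inflated log-normal
  split evenly over 27 samples, with zero-total genes omitted from the
  table as quantifiers do.

All randomness flows from one seed through a named stream per
sub-simulator, so adding a simulator never perturbs another's draws;
identical seeds give byte-identical outputs.

What the simulations do *not* emulate — and hence what passing tests do
not show about real data: realistic LTR retrotransposon sequence
structure and divergence landscapes, GC-content heterogeneity and
isochore structure, correlated domain co-occurrence within proteins,
isoform redundancy, unbalanced orthogroup gene counts, and read-level
expression noise. Calibration figures (false-positive and recovery
rates) therefore validate the statistical machinery under its own model
assumptions, not field performance on any particular genome.

## Study problem sizes

The replicate studies use 200 replicates of 7 genomes × 500 null domains
(Poisson λ = 20, 5,000 proteins per genome) with five planted 8-fold
effects; RIP recovery uses a 500 kb single-sequence genome with 30%
repeat content (fifty 3 kb copies) at mutation rates 0 and 0.2; Fisher
validation enumerates all 44,515 non-degenerate 2×2 tables with N ≤ 30.
These sizes keep the full suite comfortably within a coffee break on one
CPU while leaving the statistical conclusions stable across seeds.

## Known limitations

* The %RIPped percentage is sensitive to the evaluable-window convention
  on heavily masked assemblies (many non-evaluable windows); both
  conventions are derivable from the per-window TSV.
* The pairwise-enrichment background margin (total proteins) treats every
  genome's annotation depth as comparable; systematically shallower
  annotations bias folds and tests together.
* Architecture calls are only as good as the upstream domain scanner;
  the rules cannot distinguish degenerate or partial domains, and manual
  curation (e.g. tandem gene pairs) is out of scope.
* The UpSet-style set analysis is emitted as tables; plotting is left to
  downstream tools.
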
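"""Domain-count enrichment statistics across genomes.

Three layers:

* Exact and chi-squared tests on 2x2 tables.  Fisher's exact test is
  implemented here by summation of hypergeometric probabilities (the
  two-sided rule: sum the probabilities of all tables with the observed
  margins that are no more probable than the observed table, with a small
  relative tolerance on the comparison to absorb floating error).  A
  vectorised batch path shares a log-factorial table so that the pairwise
  scan over hundreds of domains stays fast.

* Pairwise enrichment: for every domain present in at least
  ``min_genomes_present`` genomes, every unordered genome pair is tested on
  the 2x2 table [[c_i, T_i - c_i], [c_j, T_j - c_j]] (c = proteins carrying
  the domain, T = total annotated proteins).  P-values are Bonferroni
  corrected within the domain's own family of pairwise tests; each
  (domain, genome) result carries the number of significant pairs plus the
  fold and direction versus the cross-genome median count.

* Gene-set enrichment: frequency of each Pfam inside a gene set versus the
  whole annotated universe (including a NO_PFAM pseudo-domain for genes
  without any Pfam assignment), as an odds ratio with a two-sided exact p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .io_core import DomainAnnotationRecord, ValidationError
from .domainsets import DomainCountMatrix

logger = logging.getLogger(__name__)

#: relative tolerance used when comparing hypergeometric probabilities to
#: the observed table's probability in the two-sided summation
P_COMPARE_RTOL = 1e-7


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin (or zero expected cell)."""


@dataclass(frozen=True)
class EnrichmentParams:
    """Thresholds for the enrichment stage.

    ``alpha`` applies to Bonferroni-corrected pairwise p-values (strict <);
    ``gene_set_alpha`` applies to raw gene-set p-values (<=, matching the
    reporting convention for subset-vs-universe tests).
    """

    alpha: float = 0.01
    correction: str = "bonferroni"
    min_genomes_present: int = 2
    gene_set_alpha: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError("correction must be 'bonferroni' or 'bh'")


@dataclass(frozen=True)
class DomainEnrichmentResult:
    domain: tuple  # (accession, domain_db)
    genome: str
    count: int
    median_count: float
    fold: Optional[float]  # >= 1, math.inf sentinel, or None when skipped
    direction: str  # 'up' | 'down' | 'at_median'
    n_significant_pairs: int
    pairwise_adjusted_p: Mapping[str, float]
    skipped: bool = False

    @property
    def representation(self) -> Optional[str]:
        """Minimal over/under call: direction plus >=1 significant pair."""
        if self.skipped or self.n_significant_pairs < 1:
            return None
        if self.direction == "up":
            return "over"
        if self.direction == "down":
            return "under"
        return None


NO_PFAM = "NO_PFAM"


@dataclass(frozen=True)
class GeneSetEnrichmentResult:
    pfam: str  # accession or NO_PFAM
    in_set_with: int
    in_set_without: int
    out_set_with: int
    out_set_without: int
    odds_ratio: float
    p: float
    significant: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Exact test


def _validate_table(a: int, b: int, c: int, d: int) -> None:
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"table [[{a},{b}],[{c},{d}]] has a zero margin")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Exact integer arithmetic: conditioning on the margins, the first cell
    follows a hypergeometric law; the p-value sums P(table) over all tables
    whose probability does not exceed the observed one (relative tolerance
    1e-7 on the comparison).
    """
    _validate_table(a, b, c, d)
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    # integer numerators share the denominator comb(N, m); the <= is
    # checked by exact cross-multiplication: term <= obs * (1 + rtol)
    obs = math.comb(r1, a) * math.comb(r2, c)
    scale = 10_000_000  # 1 / P_COMPARE_RTOL
    total = 0
    for k in range(lo, hi + 1):
        term = math.comb(r1, k) * math.comb(r2, m - k)
        if term * scale <= obs * (scale + 1):
            total += term
    p = total / math.comb(r1 + r2, m)
    return min(p, 1.0)


def fisher_exact_batch(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher exact test on parallel arrays.

    Same statistic as :func:`fisher_exact_two_sided` computed in log space
    with a shared log-factorial table; tables with a zero column margin
    (no carrier in either genome) get p = 1, tables with a zero row margin
    are rejected.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    r1, r2 = a + b, c + d
    m = a + c
    n = b + d
    if (r1 == 0).any() or (r2 == 0).any():
        raise DegenerateTableError("zero row margin in batch")
    N = r1 + r2
    lg = gammaln(np.arange(int(N.max()) + 2))

    def lcomb(n_arr, k_arr):
        return lg[n_arr + 1] - lg[k_arr + 1] - lg[n_arr - k_arr + 1]

    lo = np.maximum(0, m - r2)
    hi = np.minimum(r1, m)
    width = int((hi - lo).max()) + 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    k_clip = np.minimum(k, hi[:, None])
    logp = (lcomb(r1[:, None], k_clip) + lcomb(r2[:, None], m[:, None] - k_clip)
            - lcomb(N[:, None], m[:, None]))
    log_obs = lcomb(r1, a) + lcomb(r2, c) - lcomb(N, m)
    keep = valid & (logp <= (log_obs[:, None] + math.log1p(P_COMPARE_RTOL)))
    p = np.exp(logp, where=keep, out=np.zeros_like(logp)).sum(axis=1)
    p = np.minimum(p, 1.0)
    # zero column margin: single possible table, p = 1
    p[(m == 0) | (n == 0)] = 1.0
    return p


def chi_squared_2x2(a: int, b: int, c: int, d: int,
                    continuity_correction: bool = False):
    """Pearson chi-squared test (1 df) on a 2x2 table.

    Returns ``(statistic, p)``.  Without continuity correction by default;
    raises DegenerateTableError when any expected cell is zero.
    """
    _validate_table(a, b, c, d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) == 0:
        raise DegenerateTableError("zero expected cell")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Fold versus median


def fold_vs_median(counts: Mapping[str, float], focal: str):
    """Fold change of the focal genome's count against the cross-genome
    median (median taken over *all* genomes, focal included).

    Returns ``(fold, direction, median)`` with fold = max(c, m)/min(c, m)
    >= 1; an infinite sentinel when one side is zero and they differ.
    """
    if focal not in counts:
        raise KeyError(f"focal genome {focal!r} not in counts")
    if len(counts) < 2:
        raise ValidationError("fold_vs_median needs >= 2 genomes")
    values = sorted(counts.values())
    n = len(values)
    mid = n // 2
    median = float(values[mid]) if n % 2 else (values[mid - 1] + values[mid]) / 2
    c = counts[focal]
    if c > median:
        direction = "up"
    elif c < median:
        direction = "down"
    else:
        direction = "at_median"
    lo, hi = min(c, median), max(c, median)
    if c == median:
        fold = 1.0
    elif lo == 0:
        fold = math.inf
    else:
        fold = hi / lo
    return fold, direction, median


# ---------------------------------------------------------------------------
# Pairwise enrichment


def pairwise_domain_enrichment(
        matrix: DomainCountMatrix,
        params: EnrichmentParams = EnrichmentParams()
) -> list[DomainEnrichmentResult]:
    """Pairwise Fisher enrichment for every domain across all genome pairs.

    Domains present in fewer than ``min_genomes_present`` genomes are
    emitted with ``skipped=True`` and no tests.  The multiple-testing
    family is the set of pairwise comparisons of one domain (C(G, 2)
    tests); a pair is significant when its corrected p is strictly below
    ``alpha``.
    """
    genomes = matrix.genomes
    for g in genomes:
        if g not in matrix.totals:
            raise ValidationError(f"missing protein total for {g}")
    totals = np.array([matrix.totals[g] for g in genomes], dtype=np.int64)
    pairs = list(combinations(range(len(genomes)), 2))
    n_pairs = len(pairs)

    tested_idx: list[int] = []
    tables = {"a": [], "b": [], "c": [], "d": []}
    for di in range(len(matrix.domains)):
        col = matrix.counts[:, di]
        if int((col >= 1).sum()) < params.min_genomes_present:
            continue
        tested_idx.append(di)
        for i, j in pairs:
            tables["a"].append(col[i])
            tables["b"].append(totals[i] - col[i])
            tables["c"].append(col[j])
            tables["d"].append(totals[j] - col[j])

    if tested_idx:
        pvals = fisher_exact_batch(tables["a"], tables["b"],
                                   tables["c"], tables["d"])
        pvals = pvals.reshape(len(tested_idx), n_pairs)
    else:
        pvals = np.empty((0, n_pairs))

    adjusted = _adjust(pvals, params.correction)

    results: list[DomainEnrichmentResult] = []
    tested_set = set(tested_idx)
    row_of = {di: r for r, di in enumerate(tested_idx)}
    for di, domain in enumerate(matrix.domains):
        col = matrix.counts[:, di]
        count_map = {g: int(col[gi]) for gi, g in enumerate(genomes)}
        for gi, genome in enumerate(genomes):
            fold, direction, median = fold_vs_median(count_map, genome)
            if di not in tested_set:
                results.append(DomainEnrichmentResult(
                    domain=domain, genome=genome, count=int(col[gi]),
                    median_count=median, fold=None, direction=direction,
                    n_significant_pairs=0, pairwise_adjusted_p={},
                    skipped=True))
                continue
            row = adjusted[row_of[di]]
            adj_map = {}
            n_sig = 0
            for pi, (i, j) in enumerate(pairs):
                if gi not in (i, j):
                    continue
                other = genomes[j if gi == i else i]
                adj_map[other] = float(row[pi])
                if row[pi] < params.alpha:
                    n_sig += 1
            results.append(DomainEnrichmentResult(
                domain=domain, genome=genome, count=int(col[gi]),
                median_count=median, fold=fold, direction=direction,
                n_significant_pairs=n_sig, pairwise_adjusted_p=adj_map))
    logger.info("pairwise enrichment: %d domain(s) tested, %d skipped",
                len(tested_idx), len(matrix.domains) - len(tested_idx))
    return results


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    """Per-row (per-domain family) multiple-testing adjustment."""
    if pvals.size == 0:
        return pvals
    if method == "bonferroni":
        return np.minimum(pvals * pvals.shape[1], 1.0)
    # Benjamini-Hochberg, available behind the flag only
    order = np.argsort(pvals, axis=1)
    ranked = np.take_along_axis(pvals, order, axis=1)
    n = pvals.shape[1]
    scaled = ranked * n / np.arange(1, n + 1)
    monotone = np.minimum.accumulate(scaled[:, ::-1], axis=1)[:, ::-1]
    out = np.empty_like(pvals)
    np.put_along_axis(out, order, np.minimum(monotone, 1.0), axis=1)
    return out


# ---------------------------------------------------------------------------
# Gene-set enrichment


def gene_set_domain_enrichment(
        set_genes: Iterable[str],
        universe_annotations: Iterable[DomainAnnotationRecord],
        params: EnrichmentParams = EnrichmentParams(),
        universe_genes: Optional[Iterable[str]] = None,
) -> list[GeneSetEnrichmentResult]:
    """Pfam occurrence in a gene set versus the whole annotated universe.

    ``universe_genes`` should list every annotated gene; genes without any
    Pfam record are tallied under the NO_PFAM pseudo-domain.  When omitted,
    the universe defaults to the genes present in the annotation records
    plus the set itself.
    """
    set_genes = set(set_genes)
    pfam_to_genes: dict[str, set] = {}
    annotated: set = set()
    for rec in universe_annotations:
        if rec.domain_db != "Pfam":
            continue
        annotated.add(rec.protein_id)
        pfam_to_genes.setdefault(rec.domain_accession, set()).add(
            rec.protein_id)
    if universe_genes is None:
        universe = annotated | set_genes
    else:
        universe = set(universe_genes)
    stray = set_genes - universe
    if stray:
        raise ValidationError(
            f"{len(stray)} set gene(s) missing from the universe, "
            f"e.g. {sorted(stray)[:3]}")
    pfam_to_genes[NO_PFAM] = universe - annotated

    n_set = len(set_genes)
    n_out = len(universe) - n_set
    results = []
    for pfam in sorted(pfam_to_genes):
        with_dom = pfam_to_genes[pfam] & universe
        a = len(with_dom & set_genes)
        b = n_set - a
        c = len(with_dom) - a
        d = n_out - c
        degenerate = n_out == 0 or n_set == 0 or len(with_dom) in (
            0, len(universe))
        if degenerate:
            odds, p, significant = 1.0, 1.0, False
        else:
            odds = math.inf if b * c == 0 else (a * d) / (b * c)
            p = fisher_exact_two_sided(a, b, c, d)
            significant = p <= params.gene_set_alpha
        results.append(GeneSetEnrichmentResult(
            pfam=pfam, in_set_with=a, in_set_without=b,
            out_set_with=c, out_set_without=d,
            odds_ratio=odds, p=p, significant=significant,
            degenerate=degenerate))
    return results
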
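"""Windowed RIP-index scanning of genome sequences.

Repeat-induced point mutation (RIP) converts cytosine to thymine in
repetitive DNA, preferentially at CpA sites (TpG on the other strand).
The footprint it leaves is a dinucleotide skew: TpA accumulates while the
CpA/TpG substrate pool is depleted.  The composite RIP index measures this
as

    composite = TpA/ApT  -  (CpA + TpG)/(ApC + GpT)

("product" minus "substrate" index); values above zero flag RIP-altered
sequence.  The scanner evaluates the index in sliding windows (default
1 kb windows every 500 bp) and summarises the fraction of windows with a
positive composite index as the percentage of the genome RIPped.

Both index denominators must be positive for a window to be *evaluable*;
the genome-level percentage is taken over evaluable windows only (logged
alongside the raw counts so the all-windows convention is recoverable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_core import NUCLEOTIDE_ALPHABET, AlphabetError, GenomeSequence, PathLike

logger = logging.getLogger(__name__)

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class RipScanParams:
    """Sliding-window parameters for the RIP scan.

    window_bp / step_bp default to the 1 kb / 500 bp scheme; a terminal
    short window is kept only if it covers at least ``min_window_fraction``
    of a full window.  ``rip_threshold`` is the strict lower bound a
    composite index must exceed for a window to count as RIP-positive.
    """

    window_bp: int = 1000
    step_bp: int = 500
    min_window_fraction: float = 0.5
    rip_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if not (0 < self.min_window_fraction <= 1):
            raise ValueError("min_window_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DinucleotideCounts:
    """Counts of the 16 overlapping dinucleotides over {A,C,G,T}.

    Pairs containing N contribute nothing, so the total may be less than
    sequence length minus one.
    """

    counts: dict

    def __getitem__(self, dinuc: str) -> int:
        return self.counts.get(dinuc, 0)


@dataclass(frozen=True)
class RipWindow:
    seq_id: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    product_index: Optional[float]
    substrate_index: Optional[float]
    composite_index: Optional[float]
    evaluable: bool


@dataclass(frozen=True)
class RipSummary:
    n_windows: int
    n_evaluable: int
    n_rip_positive: int
    pct_ripped: Optional[float]


def count_dinucleotides(sequence: str) -> DinucleotideCounts:
    """Count overlapping dinucleotides left-to-right on the given strand."""
    bad = set(sequence) - NUCLEOTIDE_ALPHABET
    if bad:
        raise AlphabetError(f"illegal character(s) {sorted(bad)} in sequence")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(sequence) - 1):
        pair = sequence[i:i + 2]
        if "N" not in pair:
            counts[pair] += 1
    return DinucleotideCounts(counts=counts)


def _count_dinucleotides_array(arr: np.ndarray) -> dict:
    """Vectorised dinucleotide counting on a uint8 code array.

    Codes: A=0, C=1, G=2, T=3, N=4.  Pairs involving N are masked out.
    """
    if arr.size < 2:
        return dict.fromkeys(DINUCLEOTIDES, 0)
    left, right = arr[:-1], arr[1:]
    valid = (left < 4) & (right < 4)
    codes = left[valid] * 4 + right[valid]
    binned = np.bincount(codes, minlength=16)
    return {DINUCLEOTIDES[i]: int(binned[i]) for i in range(16)}


_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _base in enumerate("ACGT"):
    _CODE_TABLE[ord(_base)] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4 for vectorised window counting."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    bad = codes == 4
    if bad.any():
        n_positions = raw == ord("N")
        if (bad & ~n_positions).any():
            offset = int(np.nonzero(bad & ~n_positions)[0][0])
            raise AlphabetError(
                f"illegal character {sequence[offset]!r} at position "
                f"{offset + 1}")
    return codes


def compute_rip_indices(counts: DinucleotideCounts):
    """Product, substrate and composite RIP indices from window counts.

    Returns ``(product, substrate, composite, evaluable)``.  When either
    denominator (ApT, or ApC+GpT) is zero the window carries no usable
    signal: it is flagged non-evaluable and all indices are None.
    """
    tpa, apt = counts["TA"], counts["AT"]
    cpa, tpg = counts["CA"], counts["TG"]
    apc, gpt = counts["AC"], counts["GT"]
    if apt == 0 or (apc + gpt) == 0:
        return None, None, None, False
    product = tpa / apt
    substrate = (cpa + tpg) / (apc + gpt)
    return product, substrate, product - substrate, True


def iter_window_spans(length: int, params: RipScanParams):
    """Yield (start, end) spans for one sequence of the given length.

    Windows start at multiples of step_bp; a terminal short window is
    emitted only if its length reaches min_window_fraction * window_bp.
    Windows never cross sequence boundaries.
    """
    min_len = params.min_window_fraction * params.window_bp
    start = 0
    while start < length:
        end = min(start + params.window_bp, length)
        if end - start >= min_len:
            yield start, end
        if end == length:
            break
        start += params.step_bp


def scan_windows(genome: Iterable[GenomeSequence],
                 params: RipScanParams = RipScanParams()) -> list[RipWindow]:
    """Compute RIP indices for every window of every sequence."""
    windows: list[RipWindow] = []
    for seq in genome:
        codes = encode_sequence(seq.residues)
        for start, end in iter_window_spans(len(seq.residues), params):
            counts = DinucleotideCounts(
                _count_dinucleotides_array(codes[start:end]))
            product, substrate, composite, evaluable = compute_rip_indices(
                counts)
            windows.append(RipWindow(
                seq_id=seq.seq_id, start=start, end=end,
                product_index=product, substrate_index=substrate,
                composite_index=composite, evaluable=evaluable))
    logger.info("scanned %d window(s)", len(windows))
    return windows


def summarize_rip(windows: Sequence[RipWindow],
                  params: RipScanParams = RipScanParams()) -> RipSummary:
    """Genome-level %RIPped: share of evaluable windows with composite
    index strictly above the threshold."""
    n_windows = len(windows)
    evaluable = [w for w in windows if w.evaluable]
    n_positive = sum(
        1 for w in evaluable if w.composite_index > params.rip_threshold)
    if evaluable:
        pct = 100.0 * n_positive / len(evaluable)
    else:
        logger.warning("no evaluable windows; %%RIPped undefined")
        pct = None
    return RipSummary(n_windows=n_windows, n_evaluable=len(evaluable),
                      n_rip_positive=n_positive, pct_ripped=pct)


# ---------------------------------------------------------------------------
# Output writers


def write_bedgraph(windows: Iterable[RipWindow], path: PathLike) -> None:
    """Composite index per window as bedGraph (0-based half-open);
    non-evaluable windows are omitted."""
    with open(path, "w") as out:
        for w in windows:
            if w.evaluable:
                out.write(f"{w.seq_id}\t{w.start}\t{w.end}\t"
                          f"{w.composite_index:.6g}\n")


def write_window_table(windows: Iterable[RipWindow], path: PathLike) -> None:
    with open(path, "w") as out:
        out.write("seq_id\tstart\tend\tproduct_index\tsubstrate_index\t"
                  "composite_index\tevaluable\n")
        for w in windows:
            fmt = lambda v: "NA" if v is None else f"{v:.6g}"
            out.write(f"{w.seq_id}\t{w.start}\t{w.end}\t"
                      f"{fmt(w.product_index)}\t{fmt(w.substrate_index)}\t"
                      f"{fmt(w.composite_index)}\t{str(w.evaluable).lower()}\n")


def write_summary_json(summary: RipSummary, params: RipScanParams,
                       path: PathLike) -> None:
    payload = {
        "n_windows": summary.n_windows,
        "n_evaluable": summary.n_evaluable,
        "n_rip_positive": summary.n_rip_positive,
        "pct_ripped": summary.pct_ripped,
        "pct_ripped_denominator": "evaluable_windows",
        "parameters": {
            "window_bp": params.window_bp,
            "step_bp": params.step_bp,
            "min_window_fraction": params.min_window_fraction,
            "rip_threshold": params.rip_threshold,
        },
    }
    with open(path, "w") as out:
        json.dump(payload, out, indent=2)
        out.write("\n")
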
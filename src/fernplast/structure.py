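"""Quadripartite structure: inverted-repeat detection and region partition.

The large inverted repeat (IR) of a plastome is present in two
reverse-complementary copies (IRa/IRb) that divide the circle into a large and
a small single-copy region (LSC/SSC).  The detector seeds exact k-mer matches
between the sequence and its reverse complement, groups them by the anti-
diagonal they share (substitutions between the copies do not move a pair off
its anti-diagonal), and refines the boundaries by outward extension followed
by trimming of trailing mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import Interval, Plastome, RegionPartition, find_igs, revcomp
from .stemloops import encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IRPair:
    """The two copies of a detected inverted repeat (copy_b precedes copy_a)."""

    copy_b: Interval
    copy_a: Interval
    length: int
    mismatches: int


@dataclass(frozen=True)
class PlastomeSummary:
    genome_id: str
    total_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int
    gc_percent: float


def count_ir_mismatches(seq: str, pair: IRPair) -> int:
    a = seq[pair.copy_a.start : pair.copy_a.end]
    b = seq[pair.copy_b.start : pair.copy_b.end]
    ea, eb = encode(revcomp(a)), encode(b)
    return int(np.sum(ea != eb))


def detect_inverted_repeat(
    p: Plastome,
    min_ir_len: int = 1000,
    max_mismatch_frac: float = 0.01,
    seed_k: int = 21,
    mismatch_penalty: int = 5,
    xdrop: int = 30,
) -> Optional[IRPair]:
    """Find the maximal pair of non-overlapping inverted repeats.

    Boundary refinement extends the seeded exact-match core one base at a time,
    scoring +1 per complementary pair and ``-mismatch_penalty`` per mismatch,
    stopping when the running score falls ``xdrop`` below its maximum; the
    boundary is placed at the score maximum, which trims trailing mismatches.
    The returned pair must satisfy the overall mismatch budget
    ``mismatches <= max_mismatch_frac * length``; ``None`` if nothing
    qualifies.
    """
    if min_ir_len < seed_k:
        raise ValueError(f"min_ir_len ({min_ir_len}) must be >= seed_k ({seed_k})")
    seq = p.sequence
    L = len(seq)
    if L < 2 * min_ir_len:
        return None
    enc = encode(seq)

    index: dict[str, list[int]] = {}
    for i in range(L - seed_k + 1):
        index.setdefault(seq[i : i + seed_k], []).append(i)
    # seed (i, j): seq[i:i+k] == revcomp(seq[j:j+k]); base x pairs base c - x
    # with c = i + j + k - 1 constant along one inverted repeat
    diag: dict[int, list[int]] = {}
    for j in range(L - seed_k + 1):
        rc = revcomp(seq[j : j + seed_k])
        for i in index.get(rc, ()):
            if i < j:
                diag.setdefault(i + j + seed_k - 1, []).append(i)

    best: Optional[IRPair] = None
    for c, iis in diag.items():
        lo, hi = min(iis), max(iis)
        # seeded arm core: left copy [lo, hi + k), right copy [c - hi, c - lo + k)
        x0, x1 = _extend(enc, c, lo, hi + seed_k - 1, mismatch_penalty, xdrop)
        length = x1 - x0 + 1
        if length < min_ir_len:
            continue
        b_iv = Interval(x0, x1 + 1)
        a_iv = Interval(c - x1, c - x0 + 1)
        if a_iv.start < b_iv.end:  # overlapping copies
            continue
        cand = IRPair(copy_b=b_iv, copy_a=a_iv, length=length,
                      mismatches=_pair_mismatches(enc, c, x0, x1))
        if cand.mismatches > max_mismatch_frac * cand.length:
            continue
        if best is None or (cand.length, -cand.mismatches, -cand.copy_b.start) > (
            best.length, -best.mismatches, -best.copy_b.start
        ):
            best = cand
    return best


def _pair_mismatches(enc: np.ndarray, c: int, x0: int, x1: int) -> int:
    left = enc[x0 : x1 + 1]
    right = enc[c - x1 : c - x0 + 1][::-1]
    return int(np.sum((left + right) != 3))


def _extend(enc: np.ndarray, c: int, x0: int, x1: int,
            mismatch_penalty: int, xdrop: int) -> tuple[int, int]:
    """X-drop extension of the arm [x0, x1] (left-copy coords, pairs (x, c-x))."""
    L = len(enc)

    def ok(x: int) -> bool:
        return 0 <= x < L and 0 <= c - x < L and enc[x] + enc[c - x] == 3

    # outward (x0 decreasing)
    score, best, best_x = 0, 0, x0
    x = x0 - 1
    while x >= 0 and c - x < L:
        score += 1 if ok(x) else -mismatch_penalty
        if score > best:
            best, best_x = score, x
        if score < best - xdrop:
            break
        x -= 1
    x0 = best_x
    # inward (x1 increasing, arms must not meet: x < c - x)
    score, best, best_x = 0, 0, x1
    x = x1 + 1
    while 2 * x < c:
        score += 1 if ok(x) else -mismatch_penalty
        if score > best:
            best, best_x = score, x
        if score < best - xdrop:
            break
        x += 1
    return x0, best_x


def partition_quadripartite(p: Plastome, ir: IRPair) -> RegionPartition:
    """Assign LSC/SSC to the two single-copy arcs between the IR copies.

    The longer arc is the LSC; on a tie the arc containing position 0 is the
    LSC.  Region order around the circle is LSC, IRb, SSC, IRa starting from
    the LSC.
    """
    L = len(p.sequence)
    span_b = ir.copy_a.start - ir.copy_b.end
    span_w = (L - ir.copy_a.end) + ir.copy_b.start
    if span_b <= 0 or span_w <= 0:
        raise ValueError("degenerate partition: IR copies are adjacent")
    between = Interval(ir.copy_b.end, ir.copy_a.start)
    if ir.copy_a.end == L:
        wrap = Interval(0, ir.copy_b.start)
    elif ir.copy_b.start == 0:
        wrap = Interval(ir.copy_a.end, L)
    else:
        wrap = Interval(ir.copy_a.end, ir.copy_b.start, wraps_origin=True)
    if span_b > span_w:
        lsc, ssc = between, wrap
        # walking from LSC: next copy is copy_a
        return RegionPartition(lsc=lsc, irb=ir.copy_a, ssc=ssc, ira=ir.copy_b)
    # wrap arc contains position 0; it wins ties by the documented rule
    return RegionPartition(lsc=wrap, irb=ir.copy_b, ssc=between, ira=ir.copy_a)


def summarize_plastome(p: Plastome) -> PlastomeSummary:
    """Per-region lengths and overall GC% (requires a partition)."""
    if p.partition is None:
        raise ValueError("plastome has no quadripartite partition")
    L = len(p.sequence)
    part = p.partition
    return PlastomeSummary(
        genome_id=p.id,
        total_bp=L,
        lsc_bp=part.lsc.span(L),
        ssc_bp=part.ssc.span(L),
        ir_bp=part.ira.span(L),
        gc_percent=round(p.gc_percent, 2),
    )


def summary_table(summaries: list[PlastomeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Species": [s.genome_id for s in summaries],
            "Total length (bp)": [s.total_bp for s in summaries],
            "LSC (bp)": [s.lsc_bp for s in summaries],
            "SSC (bp)": [s.ssc_bp for s in summaries],
            "IR (bp)": [s.ir_bp for s in summaries],
            "GC content (%)": [s.gc_percent for s in summaries],
        }
    )


@dataclass
class IgsLengthTable:
    locus: str
    lengths: pd.Series  # genome id -> length (NaN when locus missing)

    @property
    def min(self) -> float:
        return float(self.lengths.min())

    @property
    def max(self) -> float:
        return float(self.lengths.max())

    @property
    def range(self) -> float:
        return float(self.lengths.max() - self.lengths.min())

    def expansion_matrix(self) -> pd.DataFrame:
        """Pairwise length differences (row minus column)."""
        v = self.lengths
        return pd.DataFrame(
            v.to_numpy()[:, None] - v.to_numpy()[None, :],
            index=v.index, columns=v.index,
        )


def igs_length_table(genomes: list[Plastome], locus: str) -> IgsLengthTable:
    """Per-genome length of one IGS locus; genomes lacking the locus get NaN."""
    lengths = {}
    for g in genomes:
        rec = find_igs(g, locus)
        if rec is None:
            logger.warning("locus %s missing in genome %s", locus, g.id)
            lengths[g.id] = float("nan")
        else:
            lengths[g.id] = rec.length
    series = pd.Series(lengths, name=locus, dtype=float)
    if series.isna().all():
        logger.warning("locus %s absent from every genome", locus)
    return IgsLengthTable(locus=locus, lengths=series)
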
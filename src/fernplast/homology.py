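"""Seed-and-extend homology search for mobile-ORF (MORFFO) cassettes, plus
genomic-context classification of the detected loci.

The search finds exact k-mer seeds of each query on both strands of the
target, extends seed clusters ungapped under an X-drop rule to size a window,
and resolves each window with an optimal affine-gap local alignment (Gotoh DP,
numba-compiled).  Hits shorter than ``min_hit_len`` alignment columns or below
``min_identity`` are discarded; the identity floor is deliberately more
conservative than a bare length rule.

A full Smith-Waterman (:func:`smith_waterman`) over two complete sequences is
exposed separately; the test-suite uses it as the optimality oracle for the
windowed search and cross-checks its scores against Biopython's aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .model import Feature, Interval, Plastome, intergenic_regions, revcomp
from .stemloops import StemLoop, encode

logger = logging.getLogger(__name__)

NEG = -(10**9)


@dataclass(frozen=True)
class Scoring:
    """Affine scheme: a gap of length g costs gap_open + g * gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


@dataclass(frozen=True)
class HomologySearchParams:
    seed_k: int = 12
    min_hit_len: int = 100  # alignment columns
    min_identity: float = 0.70
    xdrop: int = 20
    scoring: Scoring = field(default_factory=Scoring)

    def validate(self) -> None:
        if self.min_hit_len < self.seed_k:
            raise ValueError("min_hit_len must be >= seed_k")


@dataclass
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def aln_len(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        if not self.aligned_a:
            return 0.0
        m = sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-")
        return m / len(self.aligned_a)


@njit(cache=False)
def _gotoh_local(a, b, match, mismatch, gap_open, gap_extend):
    """Fill H/E/F matrices for local affine alignment; returns matrices and best cell."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in b (consumes a)
    best = 0
    bi = 0
    bj = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + first
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + first
            if fo > f:
                f = fo
            F[i, j] = f
            s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def smith_waterman(a: str, b: str, scoring: Scoring | None = None,
                   max_cells: int = 100_000_000) -> LocalAlignment:
    """Optimal local alignment of two DNA strings under the affine scheme."""
    sc = scoring or Scoring()
    if len(a) * len(b) > max_cells:
        raise ValueError(f"problem size {len(a)}x{len(b)} exceeds {max_cells} cells")
    ea, eb = encode(a), encode(b)
    if len(a) == 0 or len(b) == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    H, E, F, best, bi, bj = _gotoh_local(
        ea, eb, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    )
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    # traceback by score recomputation
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = bi, bj
    state = "H"
    first = sc.gap_open + sc.gap_extend
    while i > 0 or j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = sc.match if ea[i - 1] == eb[j - 1] and ea[i - 1] < 4 else sc.mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            out_a.append("-")
            out_b.append(b[j - 1])
            if E[i, j] == H[i, j - 1] + first:
                state = "H"
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i, j] == H[i - 1, j] + first:
                state = "H"
            i -= 1
    return LocalAlignment(
        score=int(best), a_start=i, a_end=bi, b_start=j, b_end=bj,
        aligned_a="".join(reversed(out_a)), aligned_b="".join(reversed(out_b)),
    )


@dataclass
class HomologyHit:
    query_id: str
    target_id: str
    query_interval: Interval
    target_interval: Interval
    strand: str
    aln_len: int
    identity: float
    score: int
    aligned_query: str = ""
    aligned_target: str = ""

    def recompute_identity(self) -> float:
        if not self.aligned_query:
            return self.identity
        m = sum(1 for x, y in zip(self.aligned_query, self.aligned_target)
                if x == y and x != "-")
        return m / len(self.aligned_query)


def _ungapped_extend(qs: str, ts: str, qi: int, ti: int, length: int,
                     sc: Scoring, xdrop: int) -> tuple[int, int]:
    """Extend an exact seed ungapped both ways; returns (q_lo, q_hi) extents."""
    score = best = 0
    q, t = qi - 1, ti - 1
    lo = qi
    while q >= 0 and t >= 0:
        score += sc.match if qs[q] == ts[t] else sc.mismatch
        if score > best:
            best, lo = score, q
        if score < best - xdrop:
            break
        q -= 1
        t -= 1
    score = best = 0
    q, t = qi + length, ti + length
    hi = qi + length
    while q < len(qs) and t < len(ts):
        score += sc.match if qs[q] == ts[t] else sc.mismatch
        if score > best:
            best, hi = score, q + 1
        if score < best - xdrop:
            break
        q += 1
        t += 1
    return lo, hi


def _cluster_seeds(seeds: list[tuple[int, int]], band: int = 48,
                   max_gap: int = 400) -> list[list[tuple[int, int]]]:
    """Group (qpos, tpos) seeds into clusters of nearby diagonals/positions."""
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters: list[list[tuple[int, int]]] = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        pd, pt = cur[-1][1] - cur[-1][0], cur[-1][1]
        d, t = s[1] - s[0], s[1]
        if abs(d - pd) <= band and (d != pd or 0 <= t - pt <= max_gap):
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    # merge clusters overlapping in target space on nearby diagonals
    merged: list[list[tuple[int, int]]] = []
    for cl in sorted(clusters, key=lambda c: min(t for _, t in c)):
        if merged:
            prev = merged[-1]
            pdiags = {t - q for q, t in prev}
            cdiags = {t - q for q, t in cl}
            if (min(abs(x - y) for x in pdiags for y in cdiags) <= band
                    and min(t for _, t in cl) - max(t for _, t in prev) <= max_gap):
                prev.extend(cl)
                continue
        merged.append(cl)
    return merged


def seed_extend_search(
    queries: Sequence[tuple[str, str]],
    target: Plastome,
    params: HomologySearchParams | None = None,
) -> list[HomologyHit]:
    """Find homology hits of each query on both strands of the target genome.

    ``queries`` is a sequence of ``(id, sequence)`` pairs (e.g. from FASTA).
    Returns the highest-scoring non-redundant hits passing the length and
    identity thresholds, with target coordinates on the forward strand.
    """
    params = params or HomologySearchParams()
    params.validate()
    sc = params.scoring
    k = params.seed_k
    tseq = target.sequence
    index: dict[str, list[int]] = {}
    for i in range(len(tseq) - k + 1):
        index.setdefault(tseq[i : i + k], []).append(i)

    hits: list[HomologyHit] = []
    for qid, qseq in queries:
        if len(qseq) < k:
            logger.warning("query %s shorter than seed_k; skipped", qid)
            continue
        qlen = len(qseq)
        for strand in ("+", "-"):
            qs = qseq if strand == "+" else revcomp(qseq)
            seeds = []
            for qi in range(qlen - k + 1):
                for ti in index.get(qs[qi : qi + k], ()):
                    seeds.append((qi, ti))
            cand: list[HomologyHit] = []
            for cluster in _cluster_seeds(seeds):
                qlo = qhi = tlo = thi = None
                for qi, ti in (cluster[0], cluster[-1]):
                    lo, hi = _ungapped_extend(qs, tseq, qi, ti, k, sc, params.xdrop)
                    d = ti - qi
                    qlo = lo if qlo is None else min(qlo, lo)
                    qhi = hi if qhi is None else max(qhi, hi)
                    tlo = lo + d if tlo is None else min(tlo, lo + d)
                    thi = hi + d if thi is None else max(thi, hi + d)
                margin = 32
                qlo = max(0, qlo - margin)
                qhi = min(qlen, qhi + margin)
                tlo = max(0, tlo - margin)
                thi = min(len(tseq), thi + margin)
                aln = smith_waterman(qs[qlo:qhi], tseq[tlo:thi], sc)
                if aln.aln_len < params.min_hit_len or aln.identity < params.min_identity:
                    continue
                q0, q1 = qlo + aln.a_start, qlo + aln.a_end
                if strand == "-":
                    q0, q1 = qlen - q1, qlen - q0
                cand.append(HomologyHit(
                    query_id=qid, target_id=target.id,
                    query_interval=Interval(q0, q1),
                    target_interval=Interval(tlo + aln.b_start, tlo + aln.b_end),
                    strand=strand, aln_len=aln.aln_len,
                    identity=aln.identity, score=aln.score,
                    aligned_query=aln.aligned_a, aligned_target=aln.aligned_b,
                ))
            # non-redundant: greedy by score, drop heavy target overlaps
            cand.sort(key=lambda h: -h.score)
            kept: list[HomologyHit] = []
            for h in cand:
                redundant = False
                for kh in kept:
                    ov = (min(h.target_interval.end, kh.target_interval.end)
                          - max(h.target_interval.start, kh.target_interval.start))
                    if ov > 0.5 * min(h.aln_len, kh.aln_len):
                        redundant = True
                        break
                if not redundant:
                    kept.append(h)
            hits.extend(kept)
    hits.sort(key=lambda h: (h.target_interval.start, h.query_id, h.strand))
    return hits


# ------------------------------------------------------- context analysis

@dataclass
class MorffoLocus:
    locus_label: str
    hits: list[HomologyHit]
    trna_flanked: bool
    stemloop_flanked: bool
    flanking_stemloops: list[StemLoop]
    merged_region: Optional[Interval] = None


@dataclass
class ContextSummary:
    n_loci: int
    n_trna_flanked: int
    n_stemloop_flanked: int
    frac_trna_flanked: Optional[float]
    frac_stemloop_flanked: Optional[float]


def _neighbour_genes(p: Plastome, start: int, end: int) -> tuple[Optional[Feature], Optional[Feature]]:
    """Nearest annotated feature ending at/before start and starting at/after end
    (wrapping around the circle when needed)."""
    feats = p.sorted_features()
    if not feats:
        return None, None
    left = None
    right = None
    for f in feats:
        if f.end <= start and (left is None or f.end > left.end):
            left = f
        if f.start >= end and (right is None or f.start < right.start):
            right = f
    if p.circular:
        if left is None:
            left = feats[-1]
        if right is None:
            right = feats[0]
    return left, right


def classify_locus_context(
    hits: list[HomologyHit],
    p: Plastome,
    stemloops: list[StemLoop],
    flank_window: int = 50,
    trna_both_ends: bool = False,
) -> list[MorffoLocus]:
    """Group hits into loci and flag tRNA-flanking and stem-loop-flanking.

    A locus label is the IGS name (``geneA-geneB``) or gene name containing the
    hit midpoint, else ``unplaced``.  ``trna_flanked`` is true when at least one
    (or, with ``trna_both_ends``, each) of the two genes immediately flanking
    the merged hit region is a tRNA.  ``stemloop_flanked`` requires a stem-loop
    intersecting the ``flank_window`` around EACH end of the merged region.
    """
    igs = intergenic_regions(p)
    L = len(p.sequence)
    groups: dict[str, list[HomologyHit]] = {}
    for h in hits:
        mid = (h.target_interval.start + h.target_interval.end) // 2
        label = None
        for f in p.sorted_features():
            if any(iv.contains(mid, L) for iv in f.location):
                label = f.name
                break
        if label is None:
            for rec in igs:
                if rec.interval.contains(mid, L):
                    label = rec.name
                    break
        groups.setdefault(label or "unplaced", []).append(h)

    out: list[MorffoLocus] = []
    for label, lh in sorted(groups.items()):
        if label == "unplaced":
            out.append(MorffoLocus(label, lh, False, False, []))
            continue
        mstart = min(h.target_interval.start for h in lh)
        mend = max(h.target_interval.end for h in lh)
        left, right = _neighbour_genes(p, mstart, mend)
        trnas = [g is not None and g.is_trna for g in (left, right)]
        trna_flanked = all(trnas) if trna_both_ends else any(trnas)
        w = flank_window
        left_sls = [s for s in stemloops
                    if s.end > mstart - w and s.start < mstart + w]
        right_sls = [s for s in stemloops
                     if s.end > mend - w and s.start < mend + w]
        stemloop_flanked = bool(left_sls) and bool(right_sls)
        flanking = sorted({*left_sls, *right_sls}, key=lambda s: s.start)
        out.append(MorffoLocus(label, lh, trna_flanked, stemloop_flanked,
                               flanking, Interval(mstart, mend)))
    return out


def summarize_contexts(loci: list[MorffoLocus]) -> ContextSummary:
    n = len(loci)
    nt = sum(1 for l in loci if l.trna_flanked)
    ns = sum(1 for l in loci if l.stemloop_flanked)
    return ContextSummary(
        n_loci=n, n_trna_flanked=nt, n_stemloop_flanked=ns,
        frac_trna_flanked=(nt / n) if n else None,
        frac_stemloop_flanked=(ns / n) if n else None,
    )


def loci_table(loci: list[MorffoLocus]):
    import pandas as pd

    rows = []
    for l in loci:
        rows.append({
            "locus": l.locus_label,
            "n_hits": len(l.hits),
            "start": l.merged_region.start if l.merged_region else -1,
            "end": l.merged_region.end if l.merged_region else -1,
            "trna_flanked": l.trna_flanked,
            "stemloop_flanked": l.stemloop_flanked,
            "n_flanking_stemloops": len(l.flanking_stemloops),
        })
    return pd.DataFrame(rows)
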
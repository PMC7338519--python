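"""Pairwise genome alignment and region-masked percent identity.

Identity is defined over global-alignment columns: a column is a match,
a mismatch, or a gap; gap columns count as differences.  Masking removes a
column when either of its genome positions falls inside a masked region (for
instance a hypervariable intergenic spacer), which allows the whole-sequence
vs hotspot-ignored identity contrast to be computed explicitly.

Two alignment modes are provided.  ``exact-dp`` is an optimal global affine
alignment (match +1, mismatch -1, a gap of length g costs 5 + g) and is
limited by a cell cap.  ``anchor-chain`` chains collinear k-mers that are
unique in both genomes and resolves inter-anchor segments with the exact DP,
so it reproduces exact-dp whenever the anchors are correct; very large
low-identity segments fall back to an edit-distance path.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .model import Interval, Plastome, find_igs

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_IN_A, GAP_IN_B = 0, 1, 2, 3


def _make_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    # gap of length g costs 5 + g
    al.open_gap_score = -6
    al.extend_gap_score = -1
    return al


@dataclass
class AlignmentResult:
    a_id: str
    b_id: str
    cls: np.ndarray    # per-column class
    pos_a: np.ndarray  # original-coordinate position in a, -1 on gap columns
    pos_b: np.ndarray
    a_plastome: Optional[Plastome] = None
    b_plastome: Optional[Plastome] = None

    @property
    def n_columns(self) -> int:
        return len(self.cls)

    def counts(self) -> dict[str, int]:
        return {
            "match": int(np.sum(self.cls == MATCH)),
            "mismatch": int(np.sum(self.cls == MISMATCH)),
            "gap_in_a": int(np.sum(self.cls == GAP_IN_A)),
            "gap_in_b": int(np.sum(self.cls == GAP_IN_B)),
        }


@dataclass(frozen=True)
class IdentityResult:
    pct_identity: float
    matches: int
    counted_columns: int
    masked_columns: int


@dataclass(frozen=True)
class PairClass:
    pair_label: str
    relationship: str  # "intraspecific" | "interspecific"
    pct_identity: float


class _ColumnBuilder:
    def __init__(self) -> None:
        self.cls: list[np.ndarray] = []
        self.pa: list[np.ndarray] = []
        self.pb: list[np.ndarray] = []

    def add_gap_a(self, b0: int, n: int) -> None:
        if n <= 0:
            return
        self.cls.append(np.full(n, GAP_IN_A, dtype=np.int8))
        self.pa.append(np.full(n, -1, dtype=np.int64))
        self.pb.append(np.arange(b0, b0 + n, dtype=np.int64))

    def add_gap_b(self, a0: int, n: int) -> None:
        if n <= 0:
            return
        self.cls.append(np.full(n, GAP_IN_B, dtype=np.int8))
        self.pa.append(np.arange(a0, a0 + n, dtype=np.int64))
        self.pb.append(np.full(n, -1, dtype=np.int64))

    def add_block(self, sa: str, sb: str, a0: int, b0: int) -> None:
        n = len(sa)
        if n == 0:
            return
        ea = np.frombuffer(sa.encode(), dtype=np.uint8)
        eb = np.frombuffer(sb.encode(), dtype=np.uint8)
        self.cls.append(np.where(ea == eb, MATCH, MISMATCH).astype(np.int8))
        self.pa.append(np.arange(a0, a0 + n, dtype=np.int64))
        self.pb.append(np.arange(b0, b0 + n, dtype=np.int64))

    def result(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.cls:
            return (np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64))
        return (np.concatenate(self.cls), np.concatenate(self.pa),
                np.concatenate(self.pb))


def _emit_exact(sa: str, sb: str, a_off: int, b_off: int, cb: _ColumnBuilder) -> None:
    """Optimal global affine alignment of two segments into the builder."""
    if not sa:
        cb.add_gap_a(b_off, len(sb))
        return
    if not sb:
        cb.add_gap_b(a_off, len(sa))
        return
    aln = _make_aligner().align(sa, sb)[0]
    blocks_a, blocks_b = aln.aligned
    ca, cbp = 0, 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        cb.add_gap_b(a_off + ca, a0 - ca)
        cb.add_gap_a(b_off + cbp, b0 - cbp)
        cb.add_block(sa[a0:a1], sb[b0:b1], a_off + a0, b_off + b0)
        ca, cbp = a1, b1
    cb.add_gap_b(a_off + ca, len(sa) - ca)
    cb.add_gap_a(b_off + cbp, len(sb) - cbp)


def _emit_edlib(sa: str, sb: str, a_off: int, b_off: int, cb: _ColumnBuilder) -> None:
    res = edlib.align(sa, sb, mode="NW", task="path")
    ca, cbp = 0, 0
    for n_str, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n_str)
        if op in "=XM":
            cb.add_block(sa[ca:ca + n], sb[cbp:cbp + n], a_off + ca, b_off + cbp)
            ca += n
            cbp += n
        elif op == "D":  # consumes target (b)
            cb.add_gap_a(b_off + cbp, n)
            cbp += n
        else:  # I consumes query (a)
            cb.add_gap_b(a_off + ca, n)
            ca += n


def _emit_segment(sa: str, sb: str, a_off: int, b_off: int, cb: _ColumnBuilder,
                  exact_cells: int) -> None:
    if len(sa) * len(sb) <= exact_cells or not sa or not sb:
        _emit_exact(sa, sb, a_off, b_off, cb)
    else:
        logger.info("segment %dx%d above exact cap; using edit-distance path",
                    len(sa), len(sb))
        _emit_edlib(sa, sb, a_off, b_off, cb)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """Position of each k-mer occurring exactly once in seq."""
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        pos[km] = -1 if km in pos else i
    return {km: p for km, p in pos.items() if p >= 0}


def _chain_anchors(sa: str, sb: str, k: int) -> list[tuple[int, int, int]]:
    """Collinear chain of (a_pos, b_pos, length) exact anchor runs."""
    ua = _unique_kmers(sa, k)
    ub = _unique_kmers(sb, k)
    pairs = sorted((pa, ub[km]) for km, pa in ua.items() if km in ub)
    if not pairs:
        return []
    # longest strictly-increasing subsequence in b
    import bisect

    tails: list[int] = []
    tidx: list[int] = []
    back = [-1] * len(pairs)
    for i, (_, pb) in enumerate(pairs):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tidx.append(i)
        else:
            tails[j] = pb
            tidx[j] = i
        back[i] = tidx[j - 1] if j > 0 else -1
    chain = []
    i = tidx[len(tails) - 1]
    while i >= 0:
        chain.append(pairs[i])
        i = back[i]
    chain.reverse()
    # merge same-diagonal consecutive k-mers into runs, then de-overlap
    runs: list[list[int]] = []
    for pa, pb in chain:
        if runs and pa - runs[-1][0] == pb - runs[-1][1] and pa <= runs[-1][0] + runs[-1][2]:
            runs[-1][2] = pa + k - runs[-1][0]
        else:
            runs.append([pa, pb, k])
    out: list[tuple[int, int, int]] = []
    prev_a = prev_b = 0
    for pa, pb, ln in runs:
        trim = max(prev_a - pa, prev_b - pb, 0)
        pa, pb, ln = pa + trim, pb + trim, ln - trim
        if ln <= 0:
            continue
        out.append((pa, pb, ln))
        prev_a, prev_b = pa + ln, pb + ln
    return out


def rotate_to_anchor(p: Plastome, anchor_gene: str = "rrn16") -> tuple[str, int]:
    """Rotate a circular genome's sequence to start at an anchor gene.

    Returns the rotated sequence and the rotation offset (original position of
    the new origin).  Linear genomes and genomes lacking the anchor are
    returned unrotated.
    """
    if not p.circular:
        return p.sequence, 0
    try:
        off = p.feature_by_name(anchor_gene).start
    except KeyError:
        return p.sequence, 0
    return p.sequence[off:] + p.sequence[:off], off


def align_pair(
    a: Plastome,
    b: Plastome,
    mode: str = "auto",
    exact_cap: int = 100_000_000,
    anchor_k: int = 19,
    segment_cap: int = 25_000_000,
    rotation_anchor: str = "rrn16",
) -> AlignmentResult:
    """Global alignment of two plastomes; columns mapped to original coordinates.

    Circular genomes are rotated to a shared anchor gene before alignment so
    that homologous regions are collinear.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    sa, rot_a = rotate_to_anchor(a, rotation_anchor)
    sb, rot_b = rotate_to_anchor(b, rotation_anchor)
    if rot_a or rot_b:
        logger.info("rotated %s by %d and %s by %d to anchor %s",
                    a.id, rot_a, b.id, rot_b, rotation_anchor)
    cells = len(sa) * len(sb)
    if mode == "auto":
        mode = "exact-dp" if cells <= exact_cap else "anchor-chain"
    cb = _ColumnBuilder()
    if mode == "exact-dp":
        if cells > exact_cap:
            raise ValueError(f"exact-dp problem size {cells} exceeds cap {exact_cap}")
        _emit_exact(sa, sb, 0, 0, cb)
    elif mode == "anchor-chain":
        chain = _chain_anchors(sa, sb, anchor_k)
        pa = pb = 0
        for qa, qb, ln in chain:
            _emit_segment(sa[pa:qa], sb[pb:qb], pa, pb, cb, segment_cap)
            cb.add_block(sa[qa:qa + ln], sb[qb:qb + ln], qa, qb)
            pa, pb = qa + ln, qb + ln
        _emit_segment(sa[pa:], sb[pb:], pa, pb, cb, segment_cap)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cls, pa_arr, pb_arr = cb.result()
    # map rotated coordinates back to the original frame
    if rot_a:
        pa_arr = np.where(pa_arr >= 0, (pa_arr + rot_a) % len(sa), -1)
    if rot_b:
        pb_arr = np.where(pb_arr >= 0, (pb_arr + rot_b) % len(sb), -1)
    return AlignmentResult(a_id=a.id, b_id=b.id, cls=cls, pos_a=pa_arr,
                           pos_b=pb_arr, a_plastome=a, b_plastome=b)


# ------------------------------------------------------------- identity

MaskItem = tuple[str, Union[str, Interval]]


def _resolve_mask(p: Plastome, spec: Union[str, Interval]) -> list[Interval]:
    if isinstance(spec, Interval):
        return [spec]
    m = re.fullmatch(r"(\d+)-(\d+)", spec)
    if m:
        return [Interval(int(m.group(1)), int(m.group(2)))]
    rec = find_igs(p, spec)
    if rec is not None:
        return [rec.interval]
    try:
        return list(p.feature_by_name(spec).location)
    except KeyError:
        raise KeyError(f"mask locus {spec!r} not found in genome {p.id}") from None


def _mask_array(p: Plastome, items: list[Union[str, Interval]]) -> np.ndarray:
    arr = np.zeros(len(p.sequence), dtype=bool)
    for spec in items:
        for iv in _resolve_mask(p, spec):
            for s, e in iv.slices(len(p.sequence)):
                arr[s:e] = True
    return arr


def percent_identity(
    aln: AlignmentResult,
    masks: Optional[Sequence[MaskItem]] = None,
    count_gap_columns: bool = True,
) -> IdentityResult:
    """Percent identity over counted columns, with optional region masking.

    A column is masked when either of its genome positions lies inside a mask
    interval; gap columns count as differences unless ``count_gap_columns`` is
    False, in which case they are excluded from the denominator.
    """
    masked = np.zeros(aln.n_columns, dtype=bool)
    if masks:
        by_genome: dict[str, list[Union[str, Interval]]] = {}
        for gid, spec in masks:
            by_genome.setdefault(gid, []).append(spec)
        for gid, items in by_genome.items():
            if gid == aln.a_id:
                arr = _mask_array(aln.a_plastome, items)
                sel = aln.pos_a >= 0
                masked[sel] |= arr[aln.pos_a[sel]]
            elif gid == aln.b_id:
                arr = _mask_array(aln.b_plastome, items)
                sel = aln.pos_b >= 0
                masked[sel] |= arr[aln.pos_b[sel]]
            else:
                raise KeyError(f"mask genome id {gid!r} matches neither {aln.a_id!r} "
                               f"nor {aln.b_id!r}")
    counted = ~masked
    if not count_gap_columns:
        counted &= (aln.cls == MATCH) | (aln.cls == MISMATCH)
    n_counted = int(np.sum(counted))
    n_match = int(np.sum(counted & (aln.cls == MATCH)))
    if n_counted == 0:
        raise ValueError("no counted columns after masking")
    return IdentityResult(
        pct_identity=round(100.0 * n_match / n_counted, 2),
        matches=n_match,
        counted_columns=n_counted,
        masked_columns=int(np.sum(masked)),
    )


def identity_comparison(
    pairs: Sequence[tuple[Plastome, Plastome, str]],
    mode: str = "auto",
) -> tuple[list[PairClass], pd.DataFrame]:
    """Per-pair identity plus min/max summary per relationship class."""
    if not pairs:
        raise ValueError("need at least one pair")
    classes = []
    for a, b, rel in pairs:
        aln = align_pair(a, b, mode=mode)
        ident = percent_identity(aln)
        classes.append(PairClass(f"{a.id}|{b.id}", rel, ident.pct_identity))
    df = pd.DataFrame(
        {"pair": [c.pair_label for c in classes],
         "relationship": [c.relationship for c in classes],
         "pct_identity": [c.pct_identity for c in classes]}
    )
    summary = df.groupby("relationship")["pct_identity"].agg(["count", "min", "max"])
    return classes, summary


def plot_identity_classes(classes: Sequence[PairClass], path) -> None:
    """Strip plot of pairwise identities by relationship class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    xmap = {"intraspecific": 0, "interspecific": 1}
    for c in classes:
        ax.plot(xmap.get(c.relationship, 2), c.pct_identity, "o", color="C0")
    ax.set_xticks(sorted(set(xmap.get(c.relationship, 2) for c in classes)))
    ax.set_xticklabels(sorted({c.relationship for c in classes}))
    ax.set_ylabel("sequence identity (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
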
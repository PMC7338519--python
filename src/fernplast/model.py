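"""Core plastome data model.

A plastome is represented as a (possibly circular) DNA sequence plus a list of
annotated features and an optional quadripartite partition (LSC / IRb / SSC /
IRa).  All coordinates inside the package are 0-based half-open; the I/O layer
(:mod:`fernplast.io`) converts to and from the 1-based inclusive conventions of
GenBank and GFF3 at the boundary.

Circularity is handled natively: an :class:`Interval` may wrap the sequence
origin (``wraps_origin=True``), in which case ``end < start`` is permitted and
the span is ``(L - start) + end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureKind(str, Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    ORF = "ORF"
    MISC = "misc"


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval, optionally wrapping the origin.

    For a wrapping interval on a circular sequence of length ``L`` the covered
    positions are ``[start, L) + [0, end)`` and the span is ``L - start + end``.
    """

    start: int
    end: int
    wraps_origin: bool = False

    def span(self, seq_len: Optional[int] = None) -> int:
        if self.wraps_origin:
            if seq_len is None:
                raise ValueError("seq_len required for a wrapping interval")
            return (seq_len - self.start) + self.end
        return self.end - self.start

    def validate(self, seq_len: int) -> None:
        if not (0 <= self.start < seq_len):
            raise ValueError(f"interval start {self.start} outside [0, {seq_len})")
        if self.wraps_origin:
            if not (0 <= self.end <= seq_len):
                raise ValueError(f"wrapping interval end {self.end} outside [0, {seq_len}]")
        else:
            if not (self.start < self.end <= seq_len):
                raise ValueError(
                    f"interval ({self.start}, {self.end}) not within [0, {seq_len}]"
                )
        if self.span(seq_len) < 1:
            raise ValueError("interval span must be >= 1")

    def contains(self, pos: int, seq_len: Optional[int] = None) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def slices(self, seq_len: int) -> list[tuple[int, int]]:
        """Non-wrapping (start, end) pieces covering the interval, in order."""
        if self.wraps_origin:
            pieces = []
            if self.start < seq_len:
                pieces.append((self.start, seq_len))
            if self.end > 0:
                pieces.append((0, self.end))
            return pieces
        return [(self.start, self.end)]


@dataclass
class Feature:
    """An annotated gene-like feature (possibly multi-part, e.g. with introns)."""

    name: str
    kind: FeatureKind
    strand: str  # "+" or "-"
    location: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.location:
            raise ValueError("feature needs at least one interval")

    @property
    def start(self) -> int:
        return self.location[0].start

    @property
    def end(self) -> int:
        return self.location[-1].end

    def span(self, seq_len: Optional[int] = None) -> int:
        return sum(iv.span(seq_len) for iv in self.location)

    @property
    def is_trna(self) -> bool:
        return self.kind is FeatureKind.TRNA


@dataclass
class RegionPartition:
    """Quadripartite partition of a circular plastome.

    The four intervals tile the circle; the two IR copies have equal span and
    LSC is by definition the longer single-copy region.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval

    def validate(self, seq_len: int) -> None:
        total = sum(iv.span(seq_len) for iv in (self.lsc, self.irb, self.ssc, self.ira))
        if total != seq_len:
            raise ValueError(f"partition spans sum to {total}, expected {seq_len}")
        if self.irb.span(seq_len) != self.ira.span(seq_len):
            raise ValueError("IR copies differ in span")
        if self.lsc.span(seq_len) < self.ssc.span(seq_len):
            raise ValueError("LSC shorter than SSC")


@dataclass
class Plastome:
    """An annotated (usually circular) plastid genome record."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    partition: Optional[RegionPartition] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        """GC percentage over non-N positions."""
        s = self.sequence
        denom = len(s) - s.count("N")
        if denom == 0:
            raise ValueError("no non-N positions")
        return 100.0 * (s.count("G") + s.count("C")) / denom

    def validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for iv in f.location:
                iv.validate(n)
                if iv.wraps_origin and not self.circular:
                    raise ValueError(
                        f"feature {f.name!r} wraps origin on a linear genome"
                    )
        if self.partition is not None:
            self.partition.validate(n)

    def sorted_features(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def extract_subsequence(p: Plastome, iv: Interval, strand: str = "+") -> str:
    """Sequence covered by ``iv``; minus strand returns the reverse complement."""
    if iv.wraps_origin and not p.circular:
        raise ValueError("wrapping interval on a linear genome")
    iv.validate(len(p.sequence))
    seq = "".join(p.sequence[a:b] for a, b in iv.slices(len(p.sequence)))
    if strand == "-":
        return revcomp(seq)
    if strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    return seq


def translate(dna: str, code: int = 11) -> str:
    """Translate an in-frame DNA string under the given genetic code.

    The bacterial/plastid code (NCBI table 11) is the default.  A terminal stop
    is rendered as ``*`` and is excluded from reported amino-acid lengths by
    callers.  Length must be divisible by 3.
    """
    if len(dna) % 3:
        raise ValueError("length not divisible by 3")
    if not dna:
        return ""
    return str(Seq(dna).translate(table=code))


@dataclass
class IgsRecord:
    """An intergenic spacer, named for its flanking genes in genomic order."""

    name: str
    interval: Interval
    length: int
    left_gene: str
    right_gene: str


def intergenic_regions(p: Plastome) -> list[IgsRecord]:
    """All positive-length gaps between adjacent annotated features.

    Overlapping adjacent features yield no IGS (logged); abutting features
    yield none.  On a circular genome the gap between the last and the first
    feature is included and may wrap the origin.
    """
    L = len(p.sequence)
    feats = [f for f in p.sorted_features() if not any(iv.wraps_origin for iv in f.location)]
    out: list[IgsRecord] = []
    if not feats:
        return out
    n = len(feats)
    last = n if p.circular else n - 1
    for i in range(last):
        a = feats[i]
        b = feats[(i + 1) % n]
        gap_start = a.end
        gap_end = b.start
        if i == n - 1:  # circular wrap pair
            if gap_start == L and gap_end > 0:
                iv = Interval(0, gap_end)
            elif gap_start < L:
                if gap_end == 0:
                    iv = Interval(gap_start, L)
                else:
                    iv = Interval(gap_start, gap_end, wraps_origin=True)
            else:
                continue  # abutting across origin
            length = iv.span(L)
        else:
            if gap_end < gap_start:
                logger.warning("overlapping features %s/%s: no IGS", a.name, b.name)
                continue
            if gap_end == gap_start:
                continue
            iv = Interval(gap_start, gap_end)
            length = gap_end - gap_start
        out.append(
            IgsRecord(
                name=f"{a.name}-{b.name}",
                interval=iv,
                length=length,
                left_gene=a.name,
                right_gene=b.name,
            )
        )
    return out


def find_igs(p: Plastome, locus: str) -> Optional[IgsRecord]:
    """Resolve an IGS locus label like ``rrn16-trnV-GAC`` in either orientation."""
    for rec in intergenic_regions(p):
        if rec.name == locus or f"{rec.right_gene}-{rec.left_gene}" == locus:
            return rec
    return None
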
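"""Detection of palindromic stem-loop (DNA hairpin) elements.

A stem-loop is a pair of reverse-complementary arms separated by a loop.  The
default thresholds follow the convention used for fern mobile-element termini:
minimum stem 5 bp, minimum loop 5 bp, minimum total length 20 bp.

A reported hairpin is *maximal*: its stem can be extended neither outward nor
inward by one more complementary pair (within the arm mismatch budget),
irrespective of whether the extension would still satisfy the loop minimum.
All maximal hairpins passing the thresholds are reported; overlapping hits are
not culled.

Bases are Watson-Crick paired exactly (no G.U); ``N`` pairs with nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Interval

# A=0, C=1, G=2, T=3: two bases pair iff their codes sum to 3.  N=10 never pairs.
_ENC = np.full(256, 10, dtype=np.int16)
for _b, _v in zip(b"ACGT", range(4)):
    _ENC[_b] = _v
    _ENC[_b + 32] = _v


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class StemLoopParams:
    min_stem: int = 5
    min_loop: int = 5
    min_total: int = 20
    max_loop: int = 100
    max_arm_mismatch: int = 0

    def validate(self) -> None:
        if self.min_loop > self.max_loop:
            raise ValueError("min_loop > max_loop")
        if self.min_stem < 1 or self.min_loop < 0 or self.min_total < 1:
            raise ValueError("stem-loop thresholds must be positive")


@dataclass(frozen=True)
class StemLoop:
    left_arm: Interval
    right_arm: Interval
    stem_len: int
    loop_len: int
    total_len: int

    @property
    def start(self) -> int:
        return self.left_arm.start

    @property
    def end(self) -> int:
        return self.right_arm.end

    def revalidate(self, seq: str, max_mismatch: int = 0) -> bool:
        """Check the structural invariants directly on the raw sequence."""
        la = seq[self.left_arm.start : self.left_arm.end]
        ra = seq[self.right_arm.start : self.right_arm.end]
        if len(la) != self.stem_len or len(ra) != self.stem_len:
            return False
        enc_l, enc_r = encode(la), encode(ra)[::-1]
        mm = int(np.sum((enc_l + enc_r) != 3))
        return (
            mm <= max_mismatch
            and self.total_len == 2 * self.stem_len + self.loop_len
            and self.loop_len == self.right_arm.start - self.left_arm.end
        )


def _sort_hits(hits: list[StemLoop]) -> list[StemLoop]:
    return sorted(hits, key=lambda h: (h.left_arm.start, -h.stem_len, h.loop_len))


def find_stem_loops(seq: str, params: StemLoopParams | None = None) -> list[StemLoop]:
    """All maximal stem-loops in ``seq`` passing the thresholds.

    With a zero arm-mismatch budget (the default) a vectorized scan over inner
    pair distances is used, which is fast enough for whole plastomes.  A
    positive mismatch budget falls back to direct enumeration and is intended
    for short sequences.
    """
    params = params or StemLoopParams()
    params.validate()
    if params.max_arm_mismatch > 0:
        return _find_with_mismatches(seq, params)
    enc = encode(seq)
    L = len(enc)
    hits: list[StemLoop] = []
    ms = params.min_stem
    # inner stem pair (i, i+d) has loop length d-1
    for d in range(params.min_loop + 1, params.max_loop + 2):
        if 2 * ms + d - 1 > L:  # smallest footprint no longer fits
            break
        cand = np.zeros(L, dtype=bool)
        m = L - d
        cand[:m] = (enc[:m] + enc[d:]) == 3
        # require min_stem outward pairs (i-k, i+d+k)
        for k in range(1, ms):
            dd = d + 2 * k
            q = np.zeros(L, dtype=bool)
            mm = L - dd
            if mm > 0:
                q[k : k + mm] = (enc[:mm] + enc[dd:]) == 3
            cand &= q
        # inward maximality: pair (i+1, i+d-1) must not match
        if d >= 3:
            dd = d - 2
            r = np.zeros(L, dtype=bool)
            mm = L - dd
            if mm > 1:
                r[: mm - 1] = (enc[1:mm] + enc[dd + 1 :]) == 3
            cand &= ~r
        loop_len = d - 1
        for i in np.nonzero(cand)[0]:
            i = int(i)
            s = ms
            while i - s >= 0 and i + d + s < L and enc[i - s] + enc[i + d + s] == 3:
                s += 1
            total = 2 * s + loop_len
            if total >= params.min_total:
                hits.append(
                    StemLoop(
                        left_arm=Interval(i - s + 1, i + 1),
                        right_arm=Interval(i + d, i + d + s),
                        stem_len=s,
                        loop_len=loop_len,
                        total_len=total,
                    )
                )
    return _sort_hits(hits)


def _arm_mismatches(enc: np.ndarray, i: int, s: int, l: int) -> int:
    left = enc[i : i + s]
    right = enc[i + s + l : i + 2 * s + l][::-1]
    return int(np.sum((left + right) != 3))


def _find_with_mismatches(seq: str, params: StemLoopParams) -> list[StemLoop]:
    enc = encode(seq)
    L = len(enc)
    if L > 5000:
        raise ValueError(
            "mismatch-tolerant stem-loop search enumerates candidates directly "
            "and is limited to sequences <= 5 kb"
        )
    budget = params.max_arm_mismatch
    hits = []
    for l in range(params.min_loop, params.max_loop + 1):
        for i in range(L):
            smax = (L - i - l) // 2
            for s in range(params.min_stem, smax + 1):
                mm = _arm_mismatches(enc, i, s, l)
                if mm > budget:
                    continue
                if 2 * s + l < params.min_total:
                    continue
                # outward extension possible?
                if i >= 1 and i + 2 * s + l < L:
                    grown = mm + (0 if enc[i - 1] + enc[i + 2 * s + l] == 3 else 1)
                    if grown <= budget:
                        continue
                # inward extension possible?
                if l >= 2:
                    grown = mm + (0 if enc[i + s] + enc[i + s + l - 1] == 3 else 1)
                    if grown <= budget:
                        continue
                hits.append(
                    StemLoop(
                        left_arm=Interval(i, i + s),
                        right_arm=Interval(i + s + l, i + 2 * s + l),
                        stem_len=s,
                        loop_len=l,
                        total_len=2 * s + l,
                    )
                )
    return _sort_hits(hits)


def stem_loops_to_bed(hits: list[StemLoop], chrom: str) -> str:
    """BED6 text for a list of stem-loops (0-based half-open)."""
    lines = []
    for h in hits:
        name = f"stemloop:stem={h.stem_len};loop={h.loop_len}"
        lines.append(f"{chrom}\t{h.start}\t{h.end}\t{name}\t{h.total_len}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
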
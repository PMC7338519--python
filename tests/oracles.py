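"""Independent brute-force oracles used to validate the scanners.

These deliberately use different algorithms (and mostly different code style)
from the package implementations: the stem-loop oracle builds the full
pair matrix and a run-length DP over it, and the ORF oracle walks codons one
by one from every start.  They are only meant for short sequences.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_STOPS = {"TAA", "TAG", "TGA"}


def stemloop_oracle(seq: str, min_stem: int = 5, min_loop: int = 5,
                    min_total: int = 20, max_loop: int = 100) -> set[tuple[int, int, int]]:
    """All maximal stem-loops as (left_arm_start, stem_len, loop_len) triples."""
    L = len(seq)
    M = np.zeros((L, L), dtype=bool)
    for i in range(L):
        ci = _COMP.get(seq[i])
        if ci is None:
            continue
        for j in range(i + 1, L):
            M[i, j] = seq[j] == ci
    # R[p, q] = length of the pair run (p,q), (p-1,q+1), ... ending outward
    R = np.zeros((L, L), dtype=np.int32)
    R[0] = M[0]
    for i in range(1, L):
        R[i, :-1] = M[i, :-1] * (R[i - 1, 1:] + 1)
        R[i, -1] = M[i, -1]
    out = set()
    for p in range(L):
        for q in range(p + 1 + min_loop, min(L, p + 2 + max_loop)):
            if not M[p, q]:
                continue
            if q - p > 2 and M[p + 1, q - 1]:
                continue  # inward-extendable: not maximal
            s = int(R[p, q])
            loop = q - p - 1
            if s >= min_stem and 2 * s + loop >= min_total:
                out.add((p - s + 1, s, loop))
    return out


def _codon(s: str, i: int, circular: bool) -> str | None:
    L = len(s)
    if i + 3 <= L:
        return s[i : i + 3]
    if not circular:
        return None
    return (s + s)[i : i + 3]


def orf_oracle(seq: str, circular: bool = False, min_nt: int = 304,
               min_aa: int = 101, starts: frozenset = frozenset({"ATG"}),
               ) -> set[tuple[str, int, int]]:
    """All qualifying ORFs as (strand, forward_start, nt_len) triples.

    From every start codon, codons are walked one at a time (around the circle
    when circular) until a stop; per physical stop only the longest ORF (the
    5'-most start) is kept.
    """
    L = len(seq)
    rc = "".join(_COMP[b] for b in reversed(seq))
    found: dict[tuple[str, int], tuple[int, int]] = {}
    for strand, s in (("+", seq), ("-", rc)):
        span = range(L) if circular else range(max(L - 2, 0))
        for a in span:
            if _codon(s, a, circular) not in starts:
                continue
            k = 1  # codons consumed, including the start
            i = a
            while True:
                i = (i + 3) % L if circular else i + 3
                c = _codon(s, i, circular)
                if c is None:
                    break
                k += 1
                nt = 3 * k
                if nt > L:
                    break
                if c in _STOPS:
                    aa = k - 1
                    if nt >= min_nt and aa >= min_aa:
                        stop_end = (i + 3) % L if circular else i + 3
                        key = (strand, stop_end)
                        if key not in found or nt > found[key][1]:
                            found[key] = (a, nt)
                    break
    out = set()
    for (strand, _), (a, nt) in found.items():
        if strand == "+":
            fwd = a
        else:
            fwd = (L - (a + nt)) % L if circular else L - (a + nt)
        out.add((strand, fwd, nt))
    return out
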
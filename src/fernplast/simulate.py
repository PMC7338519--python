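"""Synthetic plastome, cassette, divergence and flow-cytometry simulators.

Every generator is fully deterministic given its seed and returns a truth
record alongside the data, so each pipeline stage can be tested against known
ground truth without any external sequence downloads.

The default configuration emulates filmy-fern plastomes: circular
quadripartite genomes of ~150 kb at GC ~38%, an inverted repeat of 10-25 kb,
a canonical gene complement including the rrn16 / trnV-GAC neighbourhood, and
mobile-ORF cassettes (long ORF flanked by terminal stem-loops) inserted into
intergenic spacers.  Background sequence is i.i.d. per base at the target GC;
see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import (Feature, FeatureKind, Interval, Plastome, RegionPartition,
                    find_igs, revcomp)
from .stemloops import StemLoop

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# sense codons of the bacterial/plastid code (no TAA/TAG/TGA)
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_ALL_FRAME_STOPS = "TTAATTAATTAA"  # contains an in-frame stop in all 3 frames


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.38) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


_DEFAULT_GENES_LSC = [
    ("trnH", FeatureKind.TRNA, 74),
    ("psbA", FeatureKind.CDS, 1062),
    ("atpA", FeatureKind.CDS, 1524),
    ("rbcL", FeatureKind.CDS, 1428),
    ("trnE", FeatureKind.TRNA, 72),
    ("trnG", FeatureKind.TRNA, 71),
    ("rrn16", FeatureKind.RRNA, 1491),
    ("trnV-GAC", FeatureKind.TRNA, 72),
    ("rps12", FeatureKind.CDS, 372),
    ("psbB", FeatureKind.CDS, 1527),
]
_DEFAULT_GENES_SSC = [
    ("ndhF", FeatureKind.CDS, 2220),
    ("rpl32", FeatureKind.CDS, 180),
    ("trnP", FeatureKind.TRNA, 74),
    ("ndhA", FeatureKind.CDS, 1080),
]


@dataclass
class CassetteSpec:
    """A mobile-ORF cassette: terminal stem-loops around a long ORF."""

    target_locus: str = "rrn16-trnV-GAC"
    orf_aa: int = 400  # plausible mid-range of the 101-1274 aa envelope
    flank_stemloops: bool = True
    planted_identity: float = 1.0
    arm_len: int = 8
    loop_len: int = 9
    spacer_len: int = 30


@dataclass
class DivergenceSpec:
    background_sub_rate: float = 0.002
    background_indel_rate: float = 0.0
    indel_max_len: int = 3
    hotspot_locus: Optional[str] = None
    hotspot_sub_rate: float = 0.0
    hotspot_insert_bp: int = 0


@dataclass
class FlowSpec:
    ratios: tuple = (1.0, 3.12)  # peak positions relative to the reference peak
    cvs: tuple = (0.03, 0.03)
    events_per_peak: int = 10_000
    debris_fraction: float = 0.05
    ref_scale: float = 100.0


@dataclass
class SimConfig:
    seed: int = 0
    genome_bp: int = 150_000
    gc_target: float = 0.38
    ir_bp: Optional[int] = None  # drawn uniformly from [10000, 25000] when None
    ssc_bp: int = 21_000
    base_igs_trnv: int = 2_200  # unexpanded rrn16..trnV-GAC spacer
    cassette_specs: list = field(default_factory=list)
    divergence: Optional[DivergenceSpec] = None
    flow: Optional[FlowSpec] = None


@dataclass
class CassetteTruth:
    locus: str
    cassette: Interval
    orf: Interval
    orf_strand: str
    orf_aa: int
    stemloops: list  # StemLoop, genome coordinates
    query_id: str
    query_seq: str
    planted_identity: float


@dataclass
class TruthTable:
    ir_copy_b: Optional[Interval] = None
    ir_copy_a: Optional[Interval] = None
    partition: Optional[RegionPartition] = None
    genes: dict = field(default_factory=dict)  # name -> (Interval, strand, kind)
    cassettes: list = field(default_factory=list)
    n_substitutions: int = 0
    n_indels: int = 0
    hotspot: Optional[Interval] = None
    flow: Optional[dict] = None

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (Interval, RegionPartition, StemLoop)):
                return asdict(o)
            if isinstance(o, FeatureKind):
                return o.value
            if isinstance(o, np.integer):
                return int(o)
            raise TypeError(type(o).__name__)

        d = asdict(self)
        return json.dumps(d, default=enc, indent=1, sort_keys=True)


def _place_genes(specs, region_start: int, region_len: int,
                 fixed_gaps: dict[tuple[str, str], int]) -> list[tuple]:
    """Evenly spaced gene layout inside one region; returns (name, kind, iv)."""
    total_gene = sum(ln for _, _, ln in specs)
    n_gaps = len(specs) + 1
    fixed = sum(fixed_gaps.values())
    free = region_len - total_gene - fixed
    if free < n_gaps - len(fixed_gaps):
        raise ValueError("region too small for gene set")
    per_gap = free // (n_gaps - len(fixed_gaps))
    out = []
    pos = region_start
    prev_name = None
    for name, kind, ln in specs:
        gap = fixed_gaps.get((prev_name, name), per_gap)
        pos += gap
        out.append((name, kind, Interval(pos, pos + ln)))
        pos += ln
        prev_name = name
    return out


def simulate_plastome(cfg: SimConfig) -> tuple[Plastome, TruthTable]:
    """A circular quadripartite plastome with exact reverse-complement IR copies.

    Layout around the circle is LSC, IRb, SSC, IRa (IRa ends at the origin).
    Two bases at each inner IR boundary are set so that the planted repeat is
    also the maximal one, which keeps boundary truth unambiguous.
    """
    rng = np.random.default_rng(cfg.seed)
    ir = cfg.ir_bp if cfg.ir_bp is not None else int(rng.integers(10_000, 25_001))
    ssc = cfg.ssc_bp
    lsc = cfg.genome_bp - 2 * ir - ssc
    if lsc <= ssc:
        raise ValueError("genome_bp too small for the requested IR/SSC sizes")
    gc = cfg.gc_target
    lsc_seq = random_seq(rng, lsc, gc)
    irb_seq = random_seq(rng, ir, gc)
    ssc_seq = list(random_seq(rng, ssc, gc))
    # guard the IR-SSC inner boundary: SSC[t] must not pair SSC[ssc-1-t], t=0,1
    ssc_seq[-1] = ssc_seq[0]
    ssc_seq[-2] = ssc_seq[1]
    ssc_seq = "".join(ssc_seq)
    seq = lsc_seq + irb_seq + ssc_seq + revcomp(irb_seq)

    placed = _place_genes(_DEFAULT_GENES_LSC, 0, lsc,
                          {("rrn16", "trnV-GAC"): cfg.base_igs_trnv})
    placed += _place_genes(_DEFAULT_GENES_SSC, lsc + ir, ssc, {})
    features = []
    truth_genes = {}
    for i, (name, kind, iv) in enumerate(placed):
        strand = "-" if (kind is FeatureKind.CDS and i % 2) else "+"
        features.append(Feature(name=name, kind=kind, strand=strand, location=[iv]))
        truth_genes[name] = {"interval": iv, "strand": strand, "kind": kind}

    copy_b = Interval(lsc, lsc + ir)
    copy_a = Interval(lsc + ir + ssc, cfg.genome_bp)
    partition = RegionPartition(
        lsc=Interval(0, lsc), irb=copy_b, ssc=Interval(lsc + ir, lsc + ir + ssc),
        ira=copy_a,
    )
    p = Plastome(id=f"sim{cfg.seed}", sequence=seq, circular=True,
                 features=features, partition=partition)
    p.validate()
    truth = TruthTable(ir_copy_b=copy_b, ir_copy_a=copy_a, partition=partition,
                       genes=truth_genes)
    return p, truth


def _make_stemloop(rng: np.random.Generator, arm_len: int, loop_len: int,
                   gc: float) -> tuple[str, int]:
    """Stem-loop sequence with an inward-extension guard; returns (seq, arm_len)."""
    arm = random_seq(rng, arm_len, gc)
    loop = list(random_seq(rng, loop_len, gc))
    loop[-1] = loop[0]  # x cannot pair with x: inward extension blocked
    return arm + "".join(loop) + revcomp(arm), arm_len


def build_cassette(rng: np.random.Generator, spec: CassetteSpec,
                   gc: float) -> tuple[str, dict]:
    """Cassette sequence plus relative coordinates of its planted elements."""
    parts: list[str] = []
    rel: dict = {}

    def extend(s: str) -> tuple[int, int]:
        start = sum(len(x) for x in parts)
        parts.append(s)
        return start, start + len(s)

    g0 = random_seq(rng, 1, gc)
    extend(g0)
    if spec.flank_stemloops:
        sl_seq, arm = _make_stemloop(rng, spec.arm_len, spec.loop_len, gc)
        s0, e0 = extend(sl_seq)
        rel["sl_left"] = StemLoop(
            left_arm=Interval(s0, s0 + arm),
            right_arm=Interval(e0 - arm, e0),
            stem_len=arm, loop_len=spec.loop_len,
            total_len=2 * arm + spec.loop_len,
        )
        extend(g0)  # outward guard: same base on both sides never pairs
    extend(random_seq(rng, spec.spacer_len, gc))
    extend(_ALL_FRAME_STOPS)  # upstream in-frame stop pins the ORF 5' end
    codons = rng.choice(len(_SENSE_CODONS), size=spec.orf_aa - 1)
    orf_seq = "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"
    s0, e0 = extend(orf_seq)
    rel["orf"] = (s0, e0)
    extend(random_seq(rng, spec.spacer_len, gc))
    if spec.flank_stemloops:
        g2 = random_seq(rng, 1, gc)
        extend(g2)
        sl_seq, arm = _make_stemloop(rng, spec.arm_len, spec.loop_len, gc)
        s0, e0 = extend(sl_seq)
        rel["sl_right"] = StemLoop(
            left_arm=Interval(s0, s0 + arm),
            right_arm=Interval(e0 - arm, e0),
            stem_len=arm, loop_len=spec.loop_len,
            total_len=2 * arm + spec.loop_len,
        )
        extend(g2)
    cassette = "".join(parts)
    # protected region: terminal stem-loops (and guards) stay unmutated
    core_start = rel["sl_left"].end + 1 if "sl_left" in rel else 0
    core_end = rel["sl_right"].start - 1 if "sl_right" in rel else len(cassette)
    rel["mutable"] = (core_start, core_end)
    return cassette, rel


def _shift_iv(iv: Interval, pos: int, delta: int) -> Interval:
    if iv.wraps_origin:
        raise ValueError("generator does not shift wrapping intervals")
    if iv.start >= pos:
        return Interval(iv.start + delta, iv.end + delta)
    if iv.end > pos:
        return Interval(iv.start, iv.end + delta)
    return iv


def plant_morffo_cassette(
    p: Plastome, spec: CassetteSpec, seed: int,
) -> tuple[Plastome, CassetteTruth]:
    """Insert a mobile-ORF cassette mid-IGS; the clean cassette is the query.

    With ``planted_identity < 1`` substitutions are applied to the genomic copy
    of the cassette interior; the terminal stem-loops are left intact (they are
    the conserved recognition structures of the element).
    """
    rng = np.random.default_rng(seed)
    rec = find_igs(p, spec.target_locus)
    if rec is None:
        raise KeyError(f"locus {spec.target_locus!r} not found in {p.id}")
    if rec.interval.wraps_origin:
        raise ValueError("cassette insertion into a wrapping IGS is unsupported")
    gc = p.gc_percent / 100.0
    cassette, rel = build_cassette(rng, spec, gc)
    genomic = cassette
    if spec.planted_identity < 1.0:
        m0, m1 = rel["mutable"]
        core = np.frombuffer(genomic[m0:m1].encode(), dtype=np.uint8).copy()
        hit = rng.random(len(core)) < (1.0 - spec.planted_identity)
        for i in np.nonzero(hit)[0]:
            choices = _BASES[_BASES != core[i]]
            core[i] = rng.choice(choices)
        genomic = genomic[:m0] + core.tobytes().decode("ascii") + genomic[m1:]
    pos = rec.interval.start + rec.interval.span(len(p.sequence)) // 2
    delta = len(genomic)
    new_seq = p.sequence[:pos] + genomic + p.sequence[pos:]
    new_feats = [
        Feature(name=f.name, kind=f.kind, strand=f.strand,
                location=[_shift_iv(iv, pos, delta) for iv in f.location])
        for f in p.features
    ]
    new_part = None
    if p.partition is not None:
        new_part = RegionPartition(
            lsc=_shift_iv(p.partition.lsc, pos, delta),
            irb=_shift_iv(p.partition.irb, pos, delta),
            ssc=_shift_iv(p.partition.ssc, pos, delta),
            ira=_shift_iv(p.partition.ira, pos, delta),
        )
    newp = Plastome(id=p.id, sequence=new_seq, circular=p.circular,
                    features=new_feats, partition=new_part)
    newp.validate()

    def lift_sl(sl: StemLoop) -> StemLoop:
        return StemLoop(
            left_arm=Interval(sl.left_arm.start + pos, sl.left_arm.end + pos),
            right_arm=Interval(sl.right_arm.start + pos, sl.right_arm.end + pos),
            stem_len=sl.stem_len, loop_len=sl.loop_len, total_len=sl.total_len,
        )

    sls = [lift_sl(rel[k]) for k in ("sl_left", "sl_right") if k in rel]
    o0, o1 = rel["orf"]
    truth = CassetteTruth(
        locus=rec.name,
        cassette=Interval(pos, pos + delta),
        orf=Interval(pos + o0, pos + o1),
        orf_strand="+",
        orf_aa=spec.orf_aa,
        stemloops=sls,
        query_id=f"morffo_{rec.name}",
        query_seq=cassette,
        planted_identity=spec.planted_identity,
    )
    return newp, truth


def mutate_genome(
    p: Plastome, d: DivergenceSpec, seed: int, new_id: Optional[str] = None,
) -> tuple[Plastome, TruthTable]:
    """Apply background substitutions/indels and an optional IGS hotspot.

    Substitutions are applied before indels; the hotspot spacer additionally
    receives ``hotspot_sub_rate`` substitutions and an insertion of
    ``hotspot_insert_bp`` random bases at its midpoint.  Truth coordinates
    refer to the mutated genome.
    """
    rng = np.random.default_rng(seed)
    L = len(p.sequence)
    arr = np.frombuffer(p.sequence.encode(), dtype=np.uint8).copy()
    hotspot_iv = None
    if d.hotspot_locus:
        rec = find_igs(p, d.hotspot_locus)
        if rec is None:
            raise KeyError(f"hotspot locus {d.hotspot_locus!r} not found")
        if rec.interval.wraps_origin:
            raise ValueError("wrapping hotspot unsupported")
        hotspot_iv = rec.interval

    rate = np.full(L, d.background_sub_rate)
    if hotspot_iv is not None and d.hotspot_sub_rate > 0:
        rate[hotspot_iv.start : hotspot_iv.end] += d.hotspot_sub_rate
    hit = np.nonzero(rng.random(L) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    n_subs = len(hit)

    # indel and insertion events in old coordinates
    events: list[tuple[int, int, str]] = []  # (old_pos, del_len, insert_seq)
    n_indels = 0
    if d.background_indel_rate > 0:
        sites = np.nonzero(rng.random(L) < d.background_indel_rate)[0]
        for s in sites:
            ln = int(rng.integers(1, d.indel_max_len + 1))
            if rng.random() < 0.5:
                events.append((int(s), min(ln, L - int(s)), ""))
            else:
                events.append((int(s), 0, random_seq(rng, ln, p.gc_percent / 100)))
        n_indels = len(sites)
    if hotspot_iv is not None and d.hotspot_insert_bp > 0:
        mid = (hotspot_iv.start + hotspot_iv.end) // 2
        events.append((mid, 0, random_seq(rng, d.hotspot_insert_bp, p.gc_percent / 100)))

    events.sort()
    pieces = []
    breaks_old = [0]
    breaks_new = [0]
    cur_old = 0
    cur_new = 0
    for pos, del_len, ins in events:
        if pos < cur_old:
            continue  # overlapping events: keep the first
        seg = arr[cur_old:pos].tobytes().decode("ascii")
        pieces.append(seg)
        cur_new += len(seg)
        if ins:
            pieces.append(ins)
            cur_new += len(ins)
        cur_old = pos + del_len
        breaks_old.append(cur_old)
        breaks_new.append(cur_new)
    pieces.append(arr[cur_old:].tobytes().decode("ascii"))
    new_seq = "".join(pieces)

    b_old = np.asarray(breaks_old)
    b_new = np.asarray(breaks_new)

    def remap(x: int) -> int:
        i = int(np.searchsorted(b_old, x, side="right")) - 1
        upper = int(b_new[i + 1]) if i + 1 < len(b_new) else len(new_seq)
        return min(int(b_new[i]) + max(0, x - int(b_old[i])), upper)

    new_feats = []
    for f in p.features:
        loc = []
        for iv in f.location:
            a, b = remap(iv.start), remap(iv.end)
            if b > a:
                loc.append(Interval(a, b))
        if loc:
            new_feats.append(Feature(name=f.name, kind=f.kind, strand=f.strand,
                                     location=loc))
    newp = Plastome(id=new_id or f"{p.id}_mut", sequence=new_seq,
                    circular=p.circular, features=new_feats, partition=None)
    newp.validate()
    truth = TruthTable(n_substitutions=int(n_subs), n_indels=int(n_indels))
    if hotspot_iv is not None:
        truth.hotspot = Interval(remap(hotspot_iv.start), remap(hotspot_iv.end))
    return newp, truth


def simulate_flow_events(spec: FlowSpec, seed: int,
                         sample_id: str = "mixed") -> tuple["FlowEventTable", dict]:
    """Gaussian mixture of fluorescence peaks plus a uniform debris floor."""
    from .flow import FlowEventTable

    rng = np.random.default_rng(seed)
    if len(spec.ratios) != len(spec.cvs):
        raise ValueError("ratios and cvs must have equal length")
    if any(r <= 0 for r in spec.ratios):
        raise ValueError("ratios must be > 0")
    chunks = []
    means = []
    for r, cv in zip(spec.ratios, spec.cvs):
        mean = spec.ref_scale * r
        means.append(mean)
        chunks.append(rng.normal(mean, cv * mean, size=spec.events_per_peak))
    n_debris = int(spec.debris_fraction * spec.events_per_peak * len(spec.ratios))
    if n_debris:
        chunks.append(rng.uniform(1.0, 1.2 * max(means), size=n_debris))
    ev = np.clip(np.concatenate(chunks), 1e-3, None)
    rng.shuffle(ev)
    truth = {"modes": means, "cvs": list(spec.cvs),
             "events_per_peak": spec.events_per_peak, "n_debris": n_debris}
    return FlowEventTable(sample_id=sample_id, events=ev), truth
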
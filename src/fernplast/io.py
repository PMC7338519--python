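"""Readers and writers for the standard formats the pipeline touches.

GenBank flat files and FASTA+GFF3 pairs are the two supported annotation
formats.  Both use 1-based inclusive coordinates externally and are converted
to the internal 0-based half-open convention here.  Biopython handles GenBank
and FASTA; GFF3 lines are parsed with gffutils' feature iterator.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import Feature, FeatureKind, Interval, Plastome

PathLike = Union[str, os.PathLike]

_GB_KIND = {
    FeatureKind.CDS: "CDS",
    FeatureKind.TRNA: "tRNA",
    FeatureKind.RRNA: "rRNA",
    FeatureKind.ORF: "CDS",
    FeatureKind.MISC: "misc_feature",
}
_KIND_FROM_GB = {
    "CDS": FeatureKind.CDS,
    "tRNA": FeatureKind.TRNA,
    "rRNA": FeatureKind.RRNA,
    "misc_feature": FeatureKind.MISC,
    "gene": FeatureKind.MISC,
}


# ---------------------------------------------------------------- GenBank

def _feature_to_seqfeature(f: Feature, seq_len: int) -> SeqFeature:
    strand = 1 if f.strand == "+" else -1
    parts = []
    for iv in f.location:
        for a, b in iv.slices(seq_len):
            parts.append(SimpleLocation(a, b, strand=strand))
    loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
    ftype = _GB_KIND[f.kind]
    quals = {"gene": [f.name]}
    if f.kind is FeatureKind.ORF:
        quals["note"] = ["ORF"]
    return SeqFeature(location=loc, type=ftype, qualifiers=quals)


def _seqfeature_to_feature(sf: SeqFeature, seq_len: int, circular: bool) -> Feature:
    kind = _KIND_FROM_GB.get(sf.type, FeatureKind.MISC)
    if "ORF" in sf.qualifiers.get("note", []):
        kind = FeatureKind.ORF
    name = sf.qualifiers.get("gene", sf.qualifiers.get("locus_tag", ["unnamed"]))[0]
    strand = "-" if sf.location.strand == -1 else "+"
    raw = [(int(p.start), int(p.end)) for p in sf.location.parts]
    # biopython orders parts along the strand; normalise to genomic order
    if strand == "-":
        raw = raw[::-1]
    intervals: list[Interval] = []
    i = 0
    while i < len(raw):
        a, b = raw[i]
        if b > seq_len:
            raise ValueError(f"feature {name!r} extends beyond sequence length {seq_len}")
        # merge a (x, L) + (0, y) pair into one wrapping interval
        if circular and b == seq_len and i + 1 < len(raw) and raw[i + 1][0] == 0:
            intervals.append(Interval(a, raw[i + 1][1], wraps_origin=True))
            i += 2
        else:
            intervals.append(Interval(a, b))
            i += 1
    return Feature(name=name, kind=kind, strand=strand, location=intervals)


def read_genbank(path: PathLike) -> list[Plastome]:
    """Read one or more plastome records from a GenBank flat file."""
    out = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    for rec in records:
        circular = rec.annotations.get("topology", "linear") == "circular"
        seq = str(rec.seq).upper()
        feats = [
            _seqfeature_to_feature(sf, len(seq), circular)
            for sf in rec.features
            if sf.type != "source"
        ]
        p = Plastome(id=rec.id, sequence=seq, circular=circular, features=feats)
        p.validate()
        out.append(p)
    return out


def write_genbank(plastomes: list[Plastome], path: PathLike) -> None:
    records = []
    for p in plastomes:
        rec = SeqRecord(Seq(p.sequence), id=p.id, name=p.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if p.circular else "linear"
        rec.features = [_feature_to_seqfeature(f, len(p.sequence)) for f in p.features]
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------- FASTA + GFF3

def write_fasta_gff3(plastomes: list[Plastome], fasta: PathLike, gff3: PathLike) -> None:
    recs = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in plastomes]
    SeqIO.write(recs, str(fasta), "fasta")
    with open(gff3, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for p in plastomes:
            L = len(p.sequence)
            fh.write(f"##sequence-region {p.id} 1 {L}\n")
            circ = "true" if p.circular else "false"
            fh.write(
                f"{p.id}\tfernplast\tregion\t1\t{L}\t.\t+\t.\t"
                f"ID=region-{p.id};Is_circular={circ}\n"
            )
            for i, f in enumerate(p.features):
                fid = f"f{i}-{p.id}"
                name = f.name.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")
                for iv in f.location:
                    for a, b in iv.slices(L):
                        fh.write(
                            f"{p.id}\tfernplast\t{f.kind.value}\t{a + 1}\t{b}\t.\t"
                            f"{f.strand}\t.\tID={fid};gene={name}\n"
                        )


_KIND_FROM_GFF = {
    "CDS": FeatureKind.CDS,
    "tRNA": FeatureKind.TRNA,
    "rRNA": FeatureKind.RRNA,
    "ORF": FeatureKind.ORF,
    "misc": FeatureKind.MISC,
    "gene": FeatureKind.MISC,
}


def read_fasta_gff3(fasta: PathLike, gff3: PathLike) -> list[Plastome]:
    """Read plastomes from a FASTA + GFF3 pair (GFF3 1-based inclusive)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta}")
    circular: dict[str, bool] = {sid: False for sid in seqs}
    # grouped by (seqid, ID attribute) so multi-line features reassemble
    grouped: dict[str, dict[str, dict]] = {sid: {} for sid in seqs}
    order: dict[str, list[str]] = {sid: [] for sid in seqs}
    for gf in gffutils.iterators.DataIterator(str(gff3)):
        sid = gf.seqid
        if sid not in seqs:
            raise ValueError(f"GFF3 seqid {sid!r} not present in FASTA")
        if gf.featuretype == "region":
            circular[sid] = gf.attributes.get("Is_circular", ["false"])[0] == "true"
            continue
        fid = gf.attributes.get("ID", [f"{sid}:{gf.start}-{gf.end}"])[0]
        name = gf.attributes.get("gene", gf.attributes.get("Name", [fid]))[0]
        entry = grouped[sid].setdefault(
            fid,
            {"name": name, "kind": _KIND_FROM_GFF.get(gf.featuretype, FeatureKind.MISC),
             "strand": gf.strand if gf.strand in "+-" else "+", "parts": []},
        )
        entry["parts"].append((gf.start - 1, gf.end))
        if fid not in order[sid]:
            order[sid].append(fid)
    out = []
    for sid, seq in seqs.items():
        L = len(seq)
        feats = []
        for fid in order[sid]:
            entry = grouped[sid][fid]
            parts = sorted(entry["parts"])
            intervals: list[Interval] = []
            i = 0
            while i < len(parts):
                a, b = parts[i]
                if circular[sid] and a == 0 and parts[-1][1] == L and len(parts) > 1 and i == 0:
                    # (1..y) + (x..L) pair represents a wrap
                    intervals.append(Interval(parts[-1][0], b, wraps_origin=True))
                    parts = parts[1:-1]
                    continue
                intervals.append(Interval(a, b))
                i += 1
            feats.append(
                Feature(name=entry["name"], kind=entry["kind"], strand=entry["strand"],
                        location=intervals)
            )
        p = Plastome(id=sid, sequence=seq, circular=circular[sid], features=feats)
        p.validate()
        out.append(p)
    return out


# ----------------------------------------------------------- misc tables

def read_flow_table(path: PathLike, column: str = "FL"):
    """One-column fluorescence event table (CSV/TSV with header)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return df[column].to_numpy(dtype=float)


def write_flow_table(events, path: PathLike, column: str = "FL") -> None:
    pd.DataFrame({column: events}).to_csv(path, index=False)


def read_mask_spec(path: PathLike) -> list[tuple[str, str]]:
    """Mask spec TSV: genome_id <tab> locus-name or start-end coordinates."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, spec = line.split("\t")[:2]
            out.append((gid, spec))
    return out
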
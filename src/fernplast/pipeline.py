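"""End-to-end analysis pipeline over synthetic or user-supplied plastomes.

Each stage is a plain function writing TSV/JSON reports into an output
directory; the CLI (:mod:`fernplast.cli`) is a thin wrapper.  Every report is
accompanied by a manifest embedding the exact parameter block, seed and
package version that produced it, and all outputs are byte-deterministic for
a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .divergence import align_pair, identity_comparison, percent_identity
from .flow import (CalibrationStandard, FlowEventTable, aggregate_replicates,
                   detect_peaks, estimate_1c)
from .homology import (HomologySearchParams, classify_locus_context, loci_table,
                       seed_extend_search, summarize_contexts)
from .io import (read_fasta_gff3, read_flow_table, write_fasta_gff3,
                 write_flow_table, write_genbank)
from .model import Plastome, find_igs, intergenic_regions
from .orfs import OrfParams, find_orfs, orfs_to_bed, scan_region_orfs
from .simulate import (CassetteSpec, DivergenceSpec, FlowSpec, SimConfig,
                       mutate_genome, plant_morffo_cassette,
                       simulate_flow_events, simulate_plastome)
from .stemloops import StemLoopParams, find_stem_loops, stem_loops_to_bed
from .structure import (detect_inverted_repeat, igs_length_table,
                        partition_quadripartite, summarize_plastome,
                        summary_table)

logger = logging.getLogger(__name__)


def _block(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Effective parameters for every stage; thresholds default to the
    published analysis conventions (>303 bp ORFs, 5/5/20 stem-loops, 100 bp
    homology floor, 1C standard 5.18)."""

    simulate: SimConfig = field(default_factory=SimConfig)
    cassette: CassetteSpec = field(default_factory=CassetteSpec)
    divergence: DivergenceSpec = field(default_factory=lambda: DivergenceSpec(
        background_sub_rate=0.018, hotspot_locus="rrn16-trnV-GAC",
        hotspot_sub_rate=0.2, hotspot_insert_bp=3000))
    orfs: OrfParams = field(default_factory=OrfParams)
    stemloops: StemLoopParams = field(default_factory=StemLoopParams)
    morffo: HomologySearchParams = field(default_factory=HomologySearchParams)
    flow: FlowSpec = field(default_factory=lambda: FlowSpec(ratios=(1.0, 3.12)))
    flank_window: int = 50
    standard: CalibrationStandard = field(default_factory=CalibrationStandard)
    n_flow_replicates: int = 3
    igs_locus: str = "rrn16-trnV-GAC"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {
            "simulate": SimConfig, "cassette": CassetteSpec,
            "divergence": DivergenceSpec, "orfs": OrfParams,
            "stemloops": StemLoopParams, "morffo": HomologySearchParams,
            "flow": FlowSpec, "standard": CalibrationStandard,
        }
        kwargs = {}
        for key, val in data.items():
            if key in blocks:
                if not isinstance(val, dict):
                    raise ValueError(f"config block {key!r} must be a mapping")
                if key == "flow" and "ratios" in val:
                    val = {**val, "ratios": tuple(val["ratios"])}
                if key == "flow" and "cvs" in val:
                    val = {**val, "cvs": tuple(val["cvs"])}
                kwargs[key] = _block(blocks[key], val, key)
            elif key in ("flank_window", "n_flow_replicates", "igs_locus"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(outdir: Path, subcommand: str, seed: int, params,
                   inputs: list[str], outputs: list[str]) -> None:
    def rel(p: str) -> str:
        try:
            return str(Path(p).relative_to(outdir))
        except ValueError:
            return str(p)

    inputs = [rel(p) for p in inputs]
    outputs = [rel(p) for p in outputs]
    manifest = {
        "tool": "fernplast",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "parameters": dataclasses.asdict(params) if dataclasses.is_dataclass(params) else params,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
    }
    path = outdir / f"manifest_{subcommand}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")


def load_genomes(paths: list[str]) -> list[Plastome]:
    """Load plastomes from GenBank files or FASTA+GFF3 pairs (``fasta,gff3``)."""
    from .io import read_genbank

    out: list[Plastome] = []
    for spec in paths:
        if "," in spec:
            fa, gff = spec.split(",", 1)
            out.extend(read_fasta_gff3(fa, gff))
        else:
            out.extend(read_genbank(spec))
    return out


# --------------------------------------------------------------- stages

def run_simulate(outdir: Path, seed: int, cfg: PipelineConfig,
                 genbank: bool = False) -> dict:
    """Generate the synthetic study: two diverged genomes, queries, flow data."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulate, seed=seed)
    base, truth = simulate_plastome(sim)
    base.id = "speciesA"
    a, cass_truth = plant_morffo_cassette(base, cfg.cassette, seed=seed + 1)
    div = cfg.divergence
    b, mut_truth = mutate_genome(a, div, seed=seed + 2, new_id="speciesB")

    outputs = []
    for g in (a, b):
        fa, gff = outdir / f"{g.id}.fasta", outdir / f"{g.id}.gff3"
        write_fasta_gff3([g], fa, gff)
        outputs += [str(fa), str(gff)]
        if genbank:
            gb = outdir / f"{g.id}.gb"
            write_genbank([g], gb)
            outputs.append(str(gb))
    qpath = outdir / "morffo_queries.fasta"
    qpath.write_text(f">{cass_truth.query_id}\n{cass_truth.query_seq}\n",
                     encoding="utf-8")
    outputs.append(str(qpath))

    flow_files = {}
    ratios_by_sample = {"reference": 1.0}
    for i, r in enumerate(cfg.flow.ratios):
        if r != 1.0:
            ratios_by_sample[f"sample{i}"] = r
    for rep in range(cfg.n_flow_replicates):
        tbl, _ = simulate_flow_events(cfg.flow, seed=seed + 10 + rep)
        fp = outdir / f"flow_rep{rep}.csv"
        write_flow_table(tbl.events, fp)
        flow_files[f"rep{rep}"] = str(fp)
        outputs.append(str(fp))

    truth_path = outdir / "truth.json"
    truth.cassettes = [dataclasses.asdict(cass_truth)]
    truth.n_substitutions = mut_truth.n_substitutions
    truth.hotspot = mut_truth.hotspot
    truth_path.write_text(truth.to_json() + "\n", encoding="utf-8")
    outputs.append(str(truth_path))
    write_manifest(outdir, "simulate", seed, cfg, [], outputs)
    return {"genomes": [a, b], "queries": [(cass_truth.query_id, cass_truth.query_seq)],
            "flow_files": flow_files, "truth": truth}


def run_structure(outdir: Path, genomes: list[Plastome], cfg: PipelineConfig,
                  seed: int = 0) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for g in genomes:
        ir = detect_inverted_repeat(g)
        if ir is None:
            logger.warning("no inverted repeat found in %s", g.id)
            continue
        g.partition = partition_quadripartite(g, ir)
        summaries.append(summarize_plastome(g))
    df = summary_table(summaries)
    df.to_csv(outdir / "structure_summary.tsv", sep="\t", index=False)
    tbl = igs_length_table(genomes, cfg.igs_locus)
    tbl.lengths.to_frame("length_bp").to_csv(outdir / "igs_lengths.tsv", sep="\t")
    write_manifest(outdir, "structure", seed, cfg,
                   [g.id for g in genomes],
                   [str(outdir / "structure_summary.tsv"), str(outdir / "igs_lengths.tsv")])
    return df


def run_orfscan(outdir: Path, genomes: list[Plastome], cfg: PipelineConfig,
                seed: int = 0) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for g in genomes:
        params = dataclasses.replace(cfg.orfs, circular=g.circular)
        hits = find_orfs(g.sequence, params)
        path = outdir / f"orfs_{g.id}.bed"
        path.write_text(orfs_to_bed(hits, g.id), encoding="utf-8")
        outputs.append(str(path))
    write_manifest(outdir, "orfscan", seed, cfg, [g.id for g in genomes], outputs)


def run_stemloops(outdir: Path, genomes: list[Plastome], cfg: PipelineConfig,
                  seed: int = 0) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for g in genomes:
        hits = find_stem_loops(g.sequence, cfg.stemloops)
        path = outdir / f"stemloops_{g.id}.bed"
        path.write_text(stem_loops_to_bed(hits, g.id), encoding="utf-8")
        outputs.append(str(path))
    write_manifest(outdir, "stemloops", seed, cfg, [g.id for g in genomes], outputs)


def run_morffo(outdir: Path, genomes: list[Plastome],
               queries: list[tuple[str, str]], cfg: PipelineConfig,
               seed: int = 0) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    all_loci = []
    for g in genomes:
        hits = seed_extend_search(queries, g, cfg.morffo)
        sls = find_stem_loops(g.sequence, cfg.stemloops)
        loci = classify_locus_context(hits, g, sls, flank_window=cfg.flank_window)
        all_loci.extend(loci)
        for h in hits:
            rows.append({
                "query": h.query_id, "target": h.target_id,
                "t_start": h.target_interval.start, "t_end": h.target_interval.end,
                "q_start": h.query_interval.start, "q_end": h.query_interval.end,
                "strand": h.strand, "aln_len": h.aln_len,
                "identity": round(h.identity, 4), "score": h.score,
            })
    pd.DataFrame(rows).to_csv(outdir / "morffo_hits.tsv", sep="\t", index=False)
    ltab = loci_table(all_loci)
    ltab.to_csv(outdir / "morffo_loci.tsv", sep="\t", index=False)
    summ = summarize_contexts(all_loci)
    (outdir / "morffo_context.json").write_text(
        json.dumps(dataclasses.asdict(summ), indent=1, sort_keys=True) + "\n",
        encoding="utf-8")
    write_manifest(outdir, "morffo", seed, cfg, [g.id for g in genomes],
                   [str(outdir / n) for n in
                    ("morffo_hits.tsv", "morffo_loci.tsv", "morffo_context.json")])
    return {"loci": all_loci, "summary": summ}


def run_identity(outdir: Path, a: Plastome, b: Plastome, cfg: PipelineConfig,
                 seed: int = 0) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    aln = align_pair(a, b, mode="auto")
    unmasked = percent_identity(aln)
    result = {
        "pair": f"{a.id}|{b.id}",
        "unmasked_pct_identity": unmasked.pct_identity,
        "columns": aln.n_columns,
        "masked_pct_identity": None,
        "mask_locus": cfg.igs_locus,
    }
    masks = []
    for g in (a, b):
        if find_igs(g, cfg.igs_locus) is not None:
            masks.append((g.id, cfg.igs_locus))
    if masks:
        masked = percent_identity(aln, masks=masks)
        result["masked_pct_identity"] = masked.pct_identity
        result["masked_columns"] = masked.masked_columns
    (outdir / "identity.json").write_text(
        json.dumps(result, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    write_manifest(outdir, "identity", seed, cfg, [a.id, b.id],
                   [str(outdir / "identity.json")])
    return result


def run_genomesize(outdir: Path, flow_files: dict[str, str], cfg: PipelineConfig,
                   seed: int = 0) -> dict:
    """Estimate 1C from mixed reference+sample event tables (one per replicate)."""
    outdir.mkdir(parents=True, exist_ok=True)
    per_rep = []
    for rep, path in sorted(flow_files.items()):
        events = read_flow_table(path)
        tbl = FlowEventTable(sample_id=rep, events=events)
        peaks = detect_peaks(tbl, n_peaks=len(cfg.flow.ratios))
        ref = peaks[0]  # lowest-intensity mode is the reference peak
        for peak in peaks[1:]:
            per_rep.append(estimate_1c(peak, ref, cfg.standard))
    est = aggregate_replicates(per_rep)
    result = {
        "standard": cfg.standard.name,
        "standard_1c": cfg.standard.c_value,
        "replicates": per_rep,
        "mean_1c": round(est.mean_1c, 2),
        "sd_1c": round(est.sd_1c, 4),
        "display": est.display(),
    }
    (outdir / "genomesize.json").write_text(
        json.dumps(result, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    write_manifest(outdir, "genomesize", seed, cfg, sorted(flow_files.values()),
                   [str(outdir / "genomesize.json")])
    return result


def run_all(outdir: Path, seed: int, cfg: Optional[PipelineConfig] = None) -> dict:
    """simulate -> structure -> morffo -> identity -> genomesize on synthetic data."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    sim = run_simulate(outdir, seed, cfg)
    a, b = sim["genomes"]
    run_structure(outdir, [a, b], cfg, seed)
    run_orfscan(outdir, [a, b], cfg, seed)
    run_stemloops(outdir, [a, b], cfg, seed)
    morffo = run_morffo(outdir, [a, b], sim["queries"], cfg, seed)
    ident = run_identity(outdir, a, b, cfg, seed)
    gsize = run_genomesize(outdir, sim["flow_files"], cfg, seed)
    return {"simulate": sim, "morffo": morffo, "identity": ident,
            "genomesize": gsize}
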
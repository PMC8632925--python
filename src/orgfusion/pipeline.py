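"""Configuration-driven orchestration of the full analysis.

``run_full_pipeline`` sequences ORF calling, cross-line clustering and Type
classification, the four-criterion candidate screen, structural analysis of
the candidates and (when read evidence is supplied) RNA-editing analysis,
writing plain TSV/JSON reports plus a manifest with per-output checksums so
deterministic stages can be verified to reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as ofio
from .editing import (
    CdsCoordinateMap,
    EditingThresholds,
    compare_groups,
    detect_editing_sites,
    site_table,
)
from .homology import classify_types, greedy_cluster, type_positional_map
from .orfs import find_orfs
from .records import GenomeRecord
from .screen import ScreenConfig, copy_number_table, screen_candidates
from .structure import detect_chimera
from .study import synthetic_study

__version__ = "0.1.0"

ALL_STAGES = ("orfs", "classify", "screen", "structure", "editing")


@dataclass
class GenomeInput:
    line_id: str
    role: str
    fasta: str
    gff: Optional[str] = None
    organelle: str = "mitochondrion"
    circular: bool = False


@dataclass
class RunConfig:
    genomes: list[GenomeInput] = field(default_factory=list)
    synthetic: bool = False
    min_nt: int = 75
    min_aa: int = 70
    identity_threshold: float = 0.9
    evalue_max: float = 1e-50
    expression_min_reads: int = 10
    expression_min_coverage_fraction: float = 0.5
    editing_min_rate: float = 0.05
    editing_min_coverage: int = 100
    editing_control_max: float = 0.01
    reads_tsv: Optional[str] = None
    pileup_tsv: Optional[str] = None
    gdna_sample: str = "gDNA"
    editing_gene: Optional[str] = None   # gene id carrying the editing map
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genomes = [GenomeInput(**g) for g in raw.pop("genomes", [])]
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(genomes=genomes, stages=stages, **raw)

    def validate(self) -> None:
        if not self.synthetic and not self.genomes:
            raise ValueError("config lists no genomes and synthetic=False")
        for g in self.genomes:
            if not Path(g.fasta).exists():
                raise ValueError(f"genome FASTA not found: {g.fasta}")
            if g.gff and not Path(g.gff).exists():
                raise ValueError(f"GFF not found: {g.gff}")
        for p in (self.reads_tsv, self.pileup_tsv):
            if p and not Path(p).exists():
                raise ValueError(f"input not found: {p}")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold out of (0, 1]")
        if self.min_aa < 25 or self.min_nt < 75:
            raise ValueError("thresholds below the ORF-calling minimum")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunManifest:
    version: str
    config: dict
    stage_seconds: dict[str, float]
    checksums: dict[str, str]
    stage_log: dict[str, dict]

    def write(self, path) -> None:
        ofio.write_json(path, self.__dict__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_genomes(config: RunConfig) -> dict[str, GenomeRecord]:
    if config.synthetic:
        bundle = synthetic_study(seed=config.seed)
        genomes = bundle.mito_genomes()
        genomes["__bundle__"] = bundle  # type: ignore[assignment]
        return genomes
    out: dict[str, GenomeRecord] = {}
    for g in config.genomes:
        contigs = ofio.read_fasta(g.fasta, circular=g.circular)
        genes = ofio.read_gff3(g.gff) if g.gff else []
        out[g.line_id] = GenomeRecord(g.line_id, g.role, contigs, genes, g.organelle)
    return out


def run_full_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_all: dict[str, float] = {}
    log: dict[str, dict] = {}
    outputs: list[Path] = []

    genomes = _load_genomes(config)
    bundle = genomes.pop("__bundle__", None)

    current = None
    try:
        current = "orfs"
        t0 = time.perf_counter()
        orf_sets: dict[str, list] = {}
        for line, genome in genomes.items():
            orfs = []
            for contig in genome.contigs:
                found = find_orfs(contig, min_nt=config.min_nt)
                for o in found:
                    o.line_id = line
                orfs.extend(found)
            orf_sets[line] = orfs
            path = outdir / f"{line}.orfs.gff3"
            ofio.write_orf_gff3(path, orfs)
            outputs.append(path)
        log["orfs"] = {line: len(v) for line, v in orf_sets.items()}
        t_all["orfs"] = time.perf_counter() - t0

        labels = None
        if "classify" in config.stages:
            current = "classify"
            t0 = time.perf_counter()
            roles = {line: g.role for line, g in genomes.items()}
            all_orfs = [o for v in orf_sets.values() for o in v]
            clusters = greedy_cluster(all_orfs, config.identity_threshold)
            labels, fractions = classify_types(clusters, roles)
            posmap = type_positional_map(labels, all_orfs)
            fpath = outdir / "type_fractions.tsv"
            fractions.to_csv(fpath, sep="\t", index=False)
            ppath = outdir / "type_positional_map.tsv"
            posmap.to_csv(ppath, sep="\t", index=False)
            cpath = outdir / "clusters.tsv"
            pd.DataFrame(
                [
                    {
                        "cluster_id": c.cluster_id,
                        "representative": c.representative_id,
                        "n_members": len(c.member_ids),
                        "members": ",".join(c.member_ids),
                        "lines": ",".join(sorted(set(c.member_lines))),
                    }
                    for c in clusters
                ]
            ).to_csv(cpath, sep="\t", index=False)
            outputs += [fpath, ppath, cpath]
            log["classify"] = {
                "n_clusters": len(clusters),
                "clusters_without_cms": fractions.attrs["clusters_without_cms"],
            }
            t_all["classify"] = time.perf_counter() - t0

        report = None
        if "screen" in config.stages:
            current = "screen"
            t0 = time.perf_counter()
            cms = {l: g for l, g in genomes.items() if g.role == "cms"
                   and g.organelle == "mitochondrion"}
            fertile = {
                l: g for l, g in genomes.items()
                if g.role in ("nuclear_donor", "fertile_relative")
                and g.organelle == "mitochondrion"
            }
            if cms and fertile:
                sc = ScreenConfig(
                    min_aa=config.min_aa,
                    evalue_max=config.evalue_max,
                    expression_min_reads=config.expression_min_reads,
                    expression_min_coverage_fraction=config.expression_min_coverage_fraction,
                )
                if bundle is not None:
                    reads = bundle.expression_reads
                    focal = bundle.focal_line
                elif config.reads_tsv:
                    reads = ofio.read_reads_tsv(config.reads_tsv)
                    focal = None
                else:
                    reads = None
                    focal = None
                cms_orfs = {l: orf_sets[l] for l in cms}
                report = screen_candidates(
                    cms_orfs, cms, fertile, reads, sc, focal_line=focal
                )
                jpath = outdir / "candidates.json"
                ofio.write_json(
                    jpath,
                    {
                        "focal_line": report.focal_line,
                        "stage_counts": report.stage_counts,
                        "candidates": report.candidates,
                        "untested": report.untested,
                    },
                )
                tpath = outdir / "candidates.tsv"
                report.to_frame().to_csv(tpath, sep="\t", index=False)
                outputs += [jpath, tpath]
                cand_seqs = {}
                focal_orfs = {o.orf_id: o for o in orf_sets[report.focal_line]}
                for c in report.candidates:
                    cand_seqs[c["orf_id"]] = focal_orfs[c["orf_id"]].nt_sequence
                if cand_seqs:
                    mito = {
                        l: g for l, g in genomes.items()
                        if g.organelle == "mitochondrion"
                    }
                    copies = copy_number_table(cand_seqs, mito, config.evalue_max)
                    cnpath = outdir / "copy_numbers.tsv"
                    copies.to_csv(cnpath, sep="\t")
                    outputs.append(cnpath)
                log["screen"] = report.stage_counts
            else:
                log["screen"] = {"skipped": "need >=1 CMS and >=1 fertile genome"}
            t_all["screen"] = time.perf_counter() - t0

        if "structure" in config.stages and report is not None:
            current = "structure"
            t0 = time.perf_counter()
            known = []
            for line, g in genomes.items():
                if g.role in ("nuclear_donor", "cytoplasmic_donor"):
                    for ann in g.genes:
                        known.append((ann.gene_id, ann.extract(g.contig(ann.contig_id))))
            calls = []
            focal_orfs = {o.orf_id: o for o in orf_sets[report.focal_line]}
            focal_genome = genomes[report.focal_line]
            for c in report.candidates:
                orf = focal_orfs[c["orf_id"]]
                contig = focal_genome.contig(orf.contig_id)
                lo, hi = orf.span()
                if orf.strand == "+":
                    ctx = contig.sequence[max(0, lo - 101) : lo - 1]
                else:
                    from .records import revcomp

                    ctx = revcomp(contig.sequence[hi : hi + 100])
                call = detect_chimera(orf, known, upstream_context=ctx) if known else None
                calls.append(
                    {
                        "orf_id": orf.orf_id,
                        "kind": call.kind if call else "novel",
                        "source_gene": call.source_gene_id if call else None,
                        "matched_bp": call.matched_bp if call else 0,
                        "novel_bp": call.novel_bp if call else orf.nt_length,
                    }
                )
            spath = outdir / "structure.json"
            ofio.write_json(spath, calls)
            outputs.append(spath)
            log["structure"] = {
                "n_candidates": len(calls),
                "chimeras": sum(1 for c in calls if c["kind"] == "chimera"),
            }
            t_all["structure"] = time.perf_counter() - t0

        if "editing" in config.stages:
            current = "editing"
            t0 = time.perf_counter()
            pileup = None
            cmap = None
            cds = None
            groups = None
            if bundle is not None:
                sim = bundle.amplicon
                pileup = sim.pileup
                cmap = sim.cmap
                focal_genome = genomes[bundle.focal_line]
                cds = focal_genome.gene_sequence("orf265like")[:-3]
                groups = sim.sample_groups
            elif config.pileup_tsv and config.editing_gene:
                pileup = ofio.read_pileup_tsv(config.pileup_tsv)
                # anchor/strand must come from the annotated gene
                for line, g in genomes.items():
                    for ann in g.genes:
                        if ann.gene_id == config.editing_gene:
                            lo, hi = ann.span()
                            cmap = CdsCoordinateMap(
                                ann.contig_id, ann.strand, ann.start,
                                hi - lo + 1,
                            )
                            cds = ann.extract(g.contig(ann.contig_id))[:-3]
                groups = None
            if pileup is not None and cmap is not None:
                gdna = pileup[pileup["sample_id"] == config.gdna_sample]
                cdna = pileup[pileup["sample_id"] != config.gdna_sample]
                thresholds = EditingThresholds(
                    min_rate=config.editing_min_rate,
                    min_coverage=config.editing_min_coverage,
                    control_max=config.editing_control_max,
                )
                sites = detect_editing_sites(
                    cdna, gdna if len(gdna) else None, cmap, cds,
                    sample_groups=groups, thresholds=thresholds,
                )
                comparisons = {}
                for s in sites:
                    gnames = sorted(g for g in s.rates if g != "gdna")
                    if len(gnames) == 2:
                        a = list(s.rates[gnames[0]].values())
                        b = list(s.rates[gnames[1]].values())
                        if len(a) >= 2 and len(b) >= 2:
                            comparisons[s.cds_pos] = compare_groups(
                                a, b, gnames[0], gnames[1]
                            )
                st = site_table(sites, comparisons)
                epath = outdir / "editing_sites.tsv"
                st.to_csv(epath, sep="\t", index=False)
                outputs.append(epath)
                log["editing"] = {
                    "n_sites": len(sites),
                    "n_significant": sum(
                        1 for c in comparisons.values() if c.significant
                    ),
                }
            else:
                log["editing"] = {"skipped": "no pileup/gene provided"}
            t_all["editing"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"pipeline stage {current!r} failed: {e}") from e

    checksums = {p.name: _sha256(p) for p in outputs}
    cfg = {k: v for k, v in config.__dict__.items() if k != "genomes"}
    cfg["genomes"] = [g.__dict__ for g in config.genomes]
    cfg["stages"] = list(config.stages)
    manifest = RunManifest(
        version=__version__,
        config=cfg,
        stage_seconds={k: round(v, 3) for k, v in t_all.items()},
        checksums=checksums,
        stage_log=log,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
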
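"""The four-criterion CMS-associated candidate screen.

A mitochondrial ORF of a focal CMS line is a candidate when it
(1) encodes >= 70 amino acids, (2) is absent from every male-fertile genome
(no similarity hit at E <= 1e-50), (3) is present in all CMS lines, and
(4) is expressed in anthers (enough reads covering enough of the ORF).

The criteria are conjunctive filters, so the final set is order-independent;
survivor counts are reported per stage for auditability and every failing
ORF records *all* the criteria it failed, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .homology import count_non_overlapping_hits, is_present
from .records import GenomeRecord, OrfRecord

READ_COLUMNS = ["sample_id", "contig", "start", "end"]


@dataclass
class ScreenConfig:
    min_aa: int = 70
    evalue_max: float = 1e-50
    expression_min_reads: int = 10
    expression_min_coverage_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_aa < 25:
            raise ValueError("min_aa must be >= 25")
        if not 0 < self.expression_min_coverage_fraction <= 1:
            raise ValueError("expression_min_coverage_fraction must be in (0, 1]")


@dataclass
class CandidateReport:
    focal_line: str
    stage_counts: dict[str, int]
    candidates: list[dict]
    eliminations: dict[str, list[str]]
    untested: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates)


def expression_filter(
    orfs: Iterable[OrfRecord],
    reads: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
    known_contigs: Optional[set[str]] = None,
) -> dict[str, tuple[int, float, bool]]:
    """Per-ORF (n_reads, covered_fraction, expressed) from aligned reads.

    An ORF counts as expressed when >= expression_min_reads overlap it and
    their union covers >= expression_min_coverage_fraction of its length.
    Reads referencing contigs outside ``known_contigs`` raise.
    """
    orfs = list(orfs)
    for col in READ_COLUMNS:
        if col not in reads.columns:
            raise ValueError(f"read table missing required column {col!r}")
    if known_contigs is None:
        known_contigs = {o.contig_id for o in orfs}
    unknown = set(reads["contig"].unique()) - set(known_contigs)
    if unknown:
        raise ValueError(f"reads reference unknown contigs: {sorted(unknown)}")
    out = {}
    for orf in orfs:
        lo, hi = orf.span()
        sel = reads[
            (reads["contig"] == orf.contig_id)
            & (reads["end"] >= lo)
            & (reads["start"] <= hi)
        ]
        n = len(sel)
        if n == 0:
            out[orf.orf_id] = (0, 0.0, False)
            continue
        covered = 0
        intervals = sorted(
            (max(lo, int(s)), min(hi, int(e)))
            for s, e in zip(sel["start"], sel["end"])
        )
        cur_lo, cur_hi = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_hi + 1:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = s, e
            else:
                cur_hi = max(cur_hi, e)
        covered += cur_hi - cur_lo + 1
        frac = covered / (hi - lo + 1)
        expressed = (
            n >= config.expression_min_reads
            and frac >= config.expression_min_coverage_fraction
        )
        out[orf.orf_id] = (n, frac, expressed)
    return out


def screen_candidates(
    cms_orf_sets: dict[str, list[OrfRecord]],
    cms_genomes: dict[str, GenomeRecord],
    fertile_genomes: dict[str, GenomeRecord],
    expression_evidence: Optional[pd.DataFrame],
    config: ScreenConfig = ScreenConfig(),
    focal_line: Optional[str] = None,
) -> CandidateReport:
    """Run the four-criterion screen on the focal CMS line's ORF catalog.

    ``expression_evidence`` is a read table (sample_id, contig, start, end)
    for the focal line's anther transcriptome, or None, in which case stage-3
    survivors are reported as candidates flagged "untested" rather than
    silently dropped.
    """
    if not fertile_genomes:
        raise ValueError("criterion 2 undefined: fertile genome set is empty")
    if not cms_orf_sets:
        raise ValueError("no CMS ORF sets supplied")
    if focal_line is None:
        focal_line = sorted(cms_orf_sets)[0]
    orfs = [o for o in cms_orf_sets[focal_line] if not o.truncated]
    other_cms = {l: g for l, g in cms_genomes.items()}

    stage_counts = {"input": len(orfs)}
    eliminations: dict[str, list[str]] = {}

    stage1 = [o for o in orfs if o.aa_length >= config.min_aa]
    for o in orfs:
        if o.aa_length < config.min_aa:
            eliminations.setdefault(o.orf_id, []).append(
                f"criterion1: {o.aa_length} aa < {config.min_aa}"
            )
    stage_counts["criterion1_length"] = len(stage1)

    # evaluate criteria 2-4 for every stage-1 survivor so multi-criterion
    # failures are all recorded
    in_fertile: dict[str, bool] = {}
    in_all_cms: dict[str, bool] = {}
    for o in stage1:
        hit_fertile = any(
            is_present(o.nt_sequence, g, config.evalue_max)
            for g in fertile_genomes.values()
        )
        in_fertile[o.orf_id] = hit_fertile
        if hit_fertile:
            eliminations.setdefault(o.orf_id, []).append(
                "criterion2: present in a fertile genome"
            )
        present_all = all(
            is_present(o.nt_sequence, g, config.evalue_max)
            for g in other_cms.values()
        )
        in_all_cms[o.orf_id] = present_all
        if not present_all:
            eliminations.setdefault(o.orf_id, []).append(
                "criterion3: absent from at least one CMS line"
            )
    stage2 = [o for o in stage1 if not in_fertile[o.orf_id]]
    stage_counts["criterion2_absent_fertile"] = len(stage2)
    stage3 = [o for o in stage2 if in_all_cms[o.orf_id]]
    stage_counts["criterion3_all_cms"] = len(stage3)

    untested: list[str] = []
    candidates: list[dict] = []
    if expression_evidence is None:
        for o in stage3:
            untested.append(o.orf_id)
            candidates.append(
                {
                    "orf_id": o.orf_id,
                    "aa_length": o.aa_length,
                    "contig": o.contig_id,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "n_reads": None,
                    "coverage_fraction": None,
                    "status": "untested",
                }
            )
        stage_counts["criterion4_expressed"] = 0
    else:
        expr = expression_filter(
            stage1, expression_evidence, config,
            known_contigs={c.id for c in cms_genomes[focal_line].contigs},
        )
        for o in stage1:
            n, frac, expressed = expr[o.orf_id]
            if not expressed:
                eliminations.setdefault(o.orf_id, []).append(
                    f"criterion4: not expressed ({n} reads, {frac:.0%} covered)"
                )
        final = [o for o in stage3 if expr[o.orf_id][2]]
        stage_counts["criterion4_expressed"] = len(final)
        for o in final:
            n, frac, _ = expr[o.orf_id]
            candidates.append(
                {
                    "orf_id": o.orf_id,
                    "aa_length": o.aa_length,
                    "contig": o.contig_id,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "n_reads": n,
                    "coverage_fraction": round(frac, 4),
                    "status": "candidate",
                }
            )
    return CandidateReport(
        focal_line=focal_line,
        stage_counts=stage_counts,
        candidates=candidates,
        eliminations=eliminations,
        untested=untested,
    )


def copy_number_table(
    candidates: dict[str, str],
    genomes: dict[str, GenomeRecord],
    evalue_max: float = 1e-50,
) -> pd.DataFrame:
    """Candidate x genome matrix of non-overlapping hit counts.

    Rows are candidate ids (mapping to their nucleotide sequences), columns
    genome/line ids — the per-genome copy number of each candidate gene.
    """
    rows = {}
    for cand_id, nt in candidates.items():
        rows[cand_id] = {
            gid: count_non_overlapping_hits(nt, g, evalue_max)
            for gid, g in genomes.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(genomes)]
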
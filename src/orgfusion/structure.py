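"""Structural explanation of candidate genes.

Three detectors mirror the classic architectures of CMS-associated loci:

* :func:`decompose_homology_blocks` — split a mitogenome region into ordered,
  non-overlapping collinear homology blocks against a reference (typically
  plastid) region, with boundary flanks for conservation inspection;
* :func:`detect_frameshift` — find a single isolated 1-bp indel that breaks
  a known gene's reading frame into two sub-ORFs;
* :func:`detect_chimera` — recognise an ORF whose 5' end (plus upstream
  context) matches a known gene while the remainder is novel.

Alignment scoring constants are implementation policy (match +1, mismatch -2
ungapped for block search; edit-distance alignment for frameshift calls) and
are recorded in the returned records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import edlib

from .homology import local_similarity_search
from .orfs import find_orfs
from .records import GeneAnnotation, OrfRecord, SequenceRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
FLANK_K = 15


@dataclass
class HomologyBlock:
    q_start: int  # 1-based inclusive on the query region
    q_end: int
    s_start: int  # 1-based inclusive on the subject region (plus strand)
    s_end: int
    identity: float
    orientation: str  # "+" collinear, "-" inverted
    q_left_flank: str = ""
    q_right_flank: str = ""


def decompose_homology_blocks(
    query_region: str,
    subject_region: str,
    min_block_bp: int = 100,
) -> list[HomologyBlock]:
    """Maximal collinear local-alignment blocks >= min_block_bp.

    Blocks are chosen greedily by score, kept non-overlapping on the query,
    and returned ordered by query start; gaps between consecutive blocks are
    implied by the coordinates. Each block carries its query boundary flanks
    (FLANK_K bases outside either end) for border-conservation inspection.
    """
    if not query_region or not subject_region:
        raise ValueError("both regions must be non-empty")
    subject = SequenceRecord("subject", subject_region)
    hits = local_similarity_search(
        query_region, subject, evalue_max=float("inf"),
        min_length=min_block_bp,
    )
    hits.sort(key=lambda h: (-h.score, h.q_start))
    chosen = []
    occupied: list[tuple[int, int]] = []
    for h in hits:
        lo, hi = h.q_start, h.q_end
        if any(not (hi < a or lo > b) for a, b in occupied):
            continue
        occupied.append((lo, hi))
        chosen.append(h)
    blocks = []
    for h in sorted(chosen, key=lambda h: h.q_start):
        blocks.append(
            HomologyBlock(
                q_start=h.q_start,
                q_end=h.q_end,
                s_start=h.s_start,
                s_end=h.s_end,
                identity=h.identity,
                orientation=h.strand,
                q_left_flank=query_region[max(0, h.q_start - 1 - FLANK_K) : h.q_start - 1],
                q_right_flank=query_region[h.q_end : h.q_end + FLANK_K],
            )
        )
    return blocks


@dataclass
class FrameshiftCall:
    gene_id: str
    indel_type: str            # "insertion" | "deletion" | "complex"
    position_nt: Optional[int]  # 1-based reference-gene coordinate
    sub_orfs: list[OrfRecord] = field(default_factory=list)
    n_indel_events: int = 1


def _parse_indels(cigar: str) -> list[tuple[str, int, int]]:
    """(event, ref_bases_consumed_before_event, length) for each indel run.

    The cigar comes from edlib.align(reference, query_region): 'I' consumes
    the reference only (a reference base missing from the query = deletion in
    the genome copy), 'D' consumes the query only (an extra base in the
    genome copy = insertion).
    """
    events = []
    ref_pos = 0  # bases of reference consumed so far
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in ("=", "X", "M"):
            ref_pos += n
        elif op == "I":
            events.append(("deletion", ref_pos, n))
            ref_pos += n
        elif op == "D":
            events.append(("insertion", ref_pos, n))
    return events


def _merge_nearby(events, gap: int = 3):
    """Merge same-type indel runs separated by <= gap reference bases.

    Edit-distance alignment may split one multi-base indel into runs
    interleaved with short matches when the flanking bases allow; merged they
    represent a single mutational event.
    """
    merged = []
    for op, pos, length in events:
        if (
            merged
            and merged[-1][0] == op
            and pos - (merged[-1][1] + (merged[-1][2] if op == "deletion" else 0))
            <= gap
        ):
            prev_op, prev_pos, prev_len = merged[-1]
            merged[-1] = (prev_op, prev_pos, prev_len + length)
        else:
            merged.append((op, pos, length))
    return merged


def detect_frameshift(
    query_region: str,
    reference_gene: Union[tuple[str, str], OrfRecord],
    min_nt: int = 75,
) -> Optional[FrameshiftCall]:
    """Detect a single isolated 1-bp indel disrupting a known gene.

    The reference CDS is aligned glocally inside the query region; one indel
    run of length 1 triggers a frameshift call at its 1-based reference-gene
    coordinate, with the sub-ORFs the caller recomputes on the query region.
    Identical sequences (or substitutions only, or an in-frame indel whose
    length is a multiple of 3) return None; anything else is reported as a
    complex call with position None.
    """
    if isinstance(reference_gene, OrfRecord):
        gene_id = reference_gene.orf_id
        ref = reference_gene.nt_sequence
    else:
        gene_id, ref = reference_gene
    res = edlib.align(ref, query_region, mode="HW", task="path")
    events = _merge_nearby(_parse_indels(res["cigar"]))
    if not events:
        return None
    if len(events) == 1:
        op, ref_pos, length = events[0]
        if length % 3 == 0:
            return None  # in-frame indel preserves the reading frame
        if length == 1:
            sub = [
                o for o in find_orfs(SequenceRecord("q", query_region), min_nt=min_nt)
                if o.strand == "+"
            ]
            return FrameshiftCall(
                gene_id=gene_id,
                indel_type=op,
                position_nt=ref_pos + 1,
                sub_orfs=sub,
                n_indel_events=1,
            )
    return FrameshiftCall(
        gene_id=gene_id,
        indel_type="complex",
        position_nt=None,
        sub_orfs=[],
        n_indel_events=len(events),
    )


@dataclass
class ChimeraCall:
    orf_id: str
    kind: str                  # "chimera" | "homolog"
    source_gene_id: Optional[str]
    matched_bp: int            # terminal match length, upstream context included
    match_q_start: int         # 1-based on (context + ORF)
    match_q_end: int
    novel_bp: int              # unmatched remainder of the ORF


def detect_chimera(
    orf: OrfRecord,
    known_genes: Sequence[tuple[str, str]],
    upstream_context: str = "",
    min_match_bp: int = 60,
    max_orf_cover: float = 0.8,
) -> Optional[ChimeraCall]:
    """Recognise an ORF whose 5' terminus matches a known gene.

    The ORF, prefixed with up to ``upstream_context`` bases of its genomic
    context, is searched against each known gene. A chimera call requires the
    best terminal match to start within the context or at the ORF 5' end,
    span >= min_match_bp, and cover < max_orf_cover of the ORF; a match
    covering the ORF almost fully is reported as a plain homolog instead.
    Returns None when nothing matches.
    """
    if not known_genes:
        raise ValueError("known gene set must be non-empty")
    query = upstream_context + orf.nt_sequence
    ctx = len(upstream_context)
    best = None
    for gene_id, gene_nt in known_genes:
        hits = local_similarity_search(
            query, SequenceRecord(gene_id, gene_nt),
            evalue_max=float("inf"), min_length=min_match_bp,
        )
        for h in hits:
            if h.strand != "+":
                continue
            if best is None or h.score > best[1].score:
                best = (gene_id, h)
    if best is None:
        return None
    gene_id, h = best
    # terminal anchoring: the match must begin in the upstream context or at
    # the very start of the ORF
    if h.q_start > ctx + 1:
        return None
    orf_cover = (h.q_end - ctx) / orf.nt_length
    if orf_cover >= max_orf_cover:
        return ChimeraCall(
            orf_id=orf.orf_id,
            kind="homolog",
            source_gene_id=gene_id,
            matched_bp=h.q_end - h.q_start + 1,
            match_q_start=h.q_start,
            match_q_end=h.q_end,
            novel_bp=max(0, orf.nt_length - (h.q_end - ctx)),
        )
    return ChimeraCall(
        orf_id=orf.orf_id,
        kind="chimera",
        source_gene_id=gene_id,
        matched_bp=h.q_end - h.q_start + 1,
        match_q_start=h.q_start,
        match_q_end=h.q_end,
        novel_bp=orf.nt_length - (h.q_end - ctx),
    )


@dataclass
class NeighborFeature:
    gene_id: str
    relation: str  # "upstream" | "downstream" | "overlapping"
    distance: int  # bp between feature edge and ORF edge (0 if adjacent)
    strand: str


def neighborhood_context(
    orf: Union[OrfRecord, GeneAnnotation],
    annotations: Iterable[GeneAnnotation],
    window_bp: int = 2000,
) -> list[NeighborFeature]:
    """Annotated features within window_bp of an ORF, ordered by distance.

    "Upstream"/"downstream" are relative to the ORF's transcription direction,
    supporting co-transcription (operon) hypotheses.
    """
    o_lo, o_hi = orf.span()
    contig = orf.contig_id
    out = []
    for g in annotations:
        if g.contig_id != contig:
            continue
        gid = getattr(orf, "orf_id", None) or getattr(orf, "gene_id", None)
        if g.gene_id == gid:
            continue
        g_lo, g_hi = g.span()
        if g_hi < o_lo:
            dist = o_lo - g_hi - 1
            side_plus = "left"
        elif g_lo > o_hi:
            dist = g_lo - o_hi - 1
            side_plus = "right"
        else:
            dist = 0
            side_plus = "overlapping"
        if dist > window_bp:
            continue
        if side_plus == "overlapping":
            relation = "overlapping"
        elif orf.strand == "+":
            relation = "upstream" if side_plus == "left" else "downstream"
        else:
            relation = "upstream" if side_plus == "right" else "downstream"
        out.append(NeighborFeature(g.gene_id, relation, dist, g.strand))
    out.sort(key=lambda f: (f.distance, f.gene_id))
    return out
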
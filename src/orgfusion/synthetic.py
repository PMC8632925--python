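"""Synthetic organelle genomes with known ground truth.

This module emulates, at desk scale (tens of kb rather than 0.5-1 Mb), the
genomic situation created by asymmetric cell fusion between a cultivated
nuclear donor and a wild cytoplasmic donor:

* two donor mitogenomes sharing a core of orthologous genes (diverged by
  point substitutions) plus donor-unique genes;
* a CMS mitogenome assembled as a duplicated patchwork of segments cut from
  both donors, interleaved with novel junction ORFs, so its length exceeds
  either donor;
* injected gene events mirroring the classic CMS-associated architectures —
  a chimeric ORF with a known-gene prefix and novel remainder, and a
  plastid-derived insertion carrying a single-base frameshift that splits a
  gene into two sub-ORFs;
* a CMS chloroplast that is a low-divergence copy of the nuclear donor's;
* amplicon reads (or per-site pileup count tables) over a gene with per-site
  C->U editing at given rates in two replicate groups, with an unedited gDNA
  control.

Every construction is recorded in a :class:`FusionTruth` ledger, the target
of all downstream recovery tests. Divergence is substitution-only (no indels)
except the explicitly injected frameshift, so each detector has an isolated
test surface. All generators are deterministic under their seed.

Design notes on identifiability: injected ORFs are preceded by an in-frame
stop-codon guard so the ORF caller recovers exactly the annotated interval;
a chimera's first eight novel bases are forced to mismatch the source-gene
continuation, and a frameshift's inserted base differs from both neighbours,
so breakpoint/insertion coordinates are unambiguous and detectors can be held
to exact (+/- 0) recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    GeneAnnotation,
    GenomeRecord,
    OrfRecord,
    SequenceRecord,
    revcomp,
)
from .orfs import STOP_CODONS, find_orfs, translate

BASES = "ACGT"
GUARD = "TAATAATAA"  # in-frame stop guard placed immediately 5' of injected ORFs
#: 12-bp six-frame terminator: stop codons in all three frames on both
#: strands (it is its own reverse complement). Flanking injected cassettes
#: with it prevents reading frames from crossing an injection boundary, so
#: injected loci contribute exactly the ORFs the truth ledger declares.
TERMINATOR = "TTAATTAATTAA"
MIN_SPACER = 12


# ---------------------------------------------------------------------------
# low-level sequence samplers


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=p))


def random_sense_codon(rng: np.random.Generator, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while True:
        codon = "".join(rng.choice(list(BASES), size=3, p=p))
        if codon not in STOP_CODONS:
            return codon


def random_gene(rng: np.random.Generator, nt_length: int, gc: float = 0.45) -> str:
    """A clean ORF: ATG + sense codons + one stop codon, nt_length total."""
    if nt_length % 3 != 0 or nt_length < 9:
        raise ValueError("gene length must be a multiple of 3 and >= 9")
    n_sense = nt_length // 3 - 2
    body = "".join(random_sense_codon(rng, gc) for _ in range(n_sense))
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "ATG" + body + stop


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence: Binomial(L, rate) sites, no indels."""
    if not 0 <= rate < 1:
        raise ValueError("divergence must be in [0, 1)")
    if rate == 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in positions:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def mutate_gene(seq: str, rate: float, rng: np.random.Generator) -> str:
    """ORF-preserving divergence: start and stop codons are untouched and no
    substitution may create an in-frame stop codon."""
    if rate == 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    eligible = np.arange(3, len(seq) - 3)
    k = min(k, len(eligible))
    positions = rng.choice(eligible, size=k, replace=False)
    out = list(seq)
    for p in sorted(positions):
        cstart = 3 * (p // 3)
        codon = out[cstart : cstart + 3]
        off = p - cstart
        ok = []
        for b in BASES:
            if b == out[p]:
                continue
            trial = codon.copy()
            trial[off] = b
            if "".join(trial) not in STOP_CODONS:
                ok.append(b)
        out[p] = ok[rng.integers(0, len(ok))]
    return "".join(out)


# ---------------------------------------------------------------------------
# donor genomes


@dataclass
class DonorGenomeSpec:
    """Parameters of the two donor organelle genomes.

    ``divergence_between_donors`` is applied as point substitutions both to
    orthologous gene pairs (ORF-preserving) and to the intergenic backbone.
    ``shared_gene_fraction`` controls how many genes are orthologous pairs;
    the remainder are donor-unique, which is what makes Type 2/3 classes
    possible downstream.
    """

    genome_length: int = 30_000
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (300, 1500)
    gc_fraction: float = 0.45
    divergence_between_donors: float = 0.10
    shared_gene_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_between_donors < 1:
            raise ValueError("divergence must be in [0, 1)")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        lo, hi = self.gene_length_range
        if lo < 75 or hi < lo:
            raise ValueError("invalid gene_length_range")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


def _sample_gene_lengths(rng, spec: DonorGenomeSpec) -> list[int]:
    """Gene lengths (codon multiples) fitting the genome's length budget.

    Structurally impossible requests (even minimum-length genes do not fit)
    raise; otherwise the largest draws are shrunk until the cassettes fit.
    """
    lo, hi = spec.gene_length_range
    lo3 = 3 * math.ceil(lo / 3)
    budget = (
        spec.genome_length
        - (spec.n_genes + 1) * MIN_SPACER
        - spec.n_genes * len(GUARD)
    )
    if spec.n_genes * lo3 > budget:
        raise ValueError(
            f"n_genes={spec.n_genes} incompatible with genome_length="
            f"{spec.genome_length}"
        )
    lengths = [int(rng.integers(lo // 3, hi // 3 + 1)) * 3
               for _ in range(spec.n_genes)]
    while sum(lengths) > budget:
        i = int(np.argmax(lengths))
        excess = sum(lengths) - budget
        lengths[i] = max(lo3, lengths[i] - 3 * math.ceil(excess / 3))
    return lengths


def _assemble(
    rng,
    spec: DonorGenomeSpec,
    cassettes: list[tuple[str, str, str]],  # (gene_id, gene_seq, strand)
    contig_id: str,
) -> tuple[str, list[GeneAnnotation]]:
    """Lay cassettes (guard + gene) along a contig with random spacers."""
    built = []
    for gid, gseq, strand in cassettes:
        cass = GUARD + gseq
        built.append(cass if strand == "+" else revcomp(cass))
    total = sum(len(c) for c in built)
    rest = spec.genome_length - total
    n_gaps = len(built) + 1
    if rest < n_gaps * MIN_SPACER:
        raise ValueError(
            f"n_genes={spec.n_genes} incompatible with genome_length="
            f"{spec.genome_length}: gene cassettes need {total} bp"
        )
    w = rng.random(n_gaps)
    extra = np.floor(w / w.sum() * (rest - n_gaps * MIN_SPACER)).astype(int)
    extra[-1] += (rest - n_gaps * MIN_SPACER) - extra.sum()
    spacer_lens = [MIN_SPACER + int(e) for e in extra]

    parts = []
    annotations = []
    pos = 0
    for (gid, gseq, strand), cass, sp in zip(cassettes, built, spacer_lens):
        spacer = random_sequence(rng, sp, spec.gc_fraction)
        parts.append(spacer)
        pos += sp
        glen = len(gseq)
        if strand == "+":
            # cassette layout on plus axis: GUARD then gene
            gstart0 = pos + len(GUARD)
            start, end = gstart0 + 1, gstart0 + glen
        else:
            # revcomp cassette: gene first on plus axis, guard after
            gstart0 = pos
            start, end = gstart0 + glen, gstart0 + 1
        annotations.append(
            GeneAnnotation(gid, contig_id, start, end, strand,
                           ortholog_id=gid if gid.startswith("og") else None)
        )
        parts.append(cass)
        pos += len(cass)
    parts.append(random_sequence(rng, spacer_lens[-1], spec.gc_fraction))
    return "".join(parts), annotations


def generate_donor_genomes(
    spec: DonorGenomeSpec,
    line_a: str = "nuclearA",
    line_b: str = "acauleB",
    organelle: str = "mitochondrion",
) -> tuple[GenomeRecord, GenomeRecord]:
    """Two donor genomes with orthologous gene pairs diverged at the stated
    rate plus donor-unique genes; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.shared_gene_fraction * spec.n_genes))
    n_unique = spec.n_genes - n_shared
    lengths = _sample_gene_lengths(rng, spec)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(spec.n_genes)]
    unique_slots = set(
        rng.choice(spec.n_genes, size=n_unique, replace=False).tolist()
    )

    cass_a, cass_b = [], []
    shared_i = unique_i = 0
    for slot in range(spec.n_genes):
        if slot in unique_slots:
            unique_i += 1
            ga = random_gene(rng, lengths[slot], spec.gc_fraction)
            # the unique gene in the other donor reuses the slot's length so
            # both genomes respect the same length budget
            gb = random_gene(rng, lengths[slot], spec.gc_fraction)
            cass_a.append((f"uA{unique_i:03d}", ga, strands[slot]))
            cass_b.append((f"uB{unique_i:03d}", gb,
                           "+" if rng.random() < 0.5 else "-"))
        else:
            shared_i += 1
            ga = random_gene(rng, lengths[slot], spec.gc_fraction)
            gb = mutate_gene(ga, spec.divergence_between_donors, rng)
            cass_a.append((f"og{shared_i:03d}", ga, strands[slot]))
            cass_b.append((f"og{shared_i:03d}", gb, strands[slot]))

    contig_a = f"{line_a}_c01"
    contig_b = f"{line_b}_c01"
    seq_a, ann_a = _assemble(rng, spec, cass_a, contig_a)
    seq_b, ann_b = _assemble(rng, spec, cass_b, contig_b)
    donor_a = GenomeRecord(
        line_a, "nuclear_donor",
        [SequenceRecord(contig_a, seq_a, circular=False)], ann_a, organelle,
    )
    donor_b = GenomeRecord(
        line_b, "cytoplasmic_donor",
        [SequenceRecord(contig_b, seq_b, circular=False)], ann_b, organelle,
    )
    return donor_a, donor_b


def set_gene_codons(
    genome: GenomeRecord, gene_id: str, codons: dict[int, str]
) -> None:
    """Overwrite specific codons (1-based codon index) of an annotated gene
    in place; used to engineer genes with prescribed editable sites."""
    ann = next(g for g in genome.genes if g.gene_id == gene_id)
    contig = genome.contig(ann.contig_id)
    gene = ann.extract(contig)
    for idx, codon in codons.items():
        if codon.upper() in STOP_CODONS:
            raise ValueError("refusing to write an internal stop codon")
        gene = gene[: 3 * (idx - 1)] + codon.upper() + gene[3 * idx :]
    lo, hi = ann.span()
    insert = gene if ann.strand == "+" else revcomp(gene)
    contig.sequence = contig.sequence[: lo - 1] + insert + contig.sequence[hi:]


# ---------------------------------------------------------------------------
# fusion mitogenome


@dataclass
class FusionParams:
    """How the post-fusion CMS mitogenome is assembled from donor segments.

    ``type_proportions`` are the nominal shares of the four presence classes
    (unique / nuclear-only / cytoplasmic-only / shared). The Type-1 count is
    ``n_novel_junction_orfs``; the total CMS gene draw is derived from it as
    round(n_novel / p1) unless ``n_genes`` is given explicitly.
    """

    segment_length_range: tuple[int, int] = (700, 2600)
    duplication_rate: float = 0.15
    type_proportions: tuple[float, float, float, float] = (0.11, 0.155, 0.11, 0.625)
    n_novel_junction_orfs: int = 3
    n_genes: Optional[int] = None
    novel_orf_length_range: tuple[int, int] = (225, 900)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if any(p < 0 for p in self.type_proportions):
            raise ValueError("type_proportions must be non-negative")
        if not 0 <= self.duplication_rate <= 1:
            raise ValueError("duplication_rate must be in [0, 1]")

    def class_counts(self) -> tuple[int, int, int, int]:
        p1, p2, p3, p4 = self.type_proportions
        if self.n_genes is not None:
            total = self.n_genes
            n1 = int(round(p1 * total))
        else:
            if self.n_novel_junction_orfs > 0 and p1 == 0:
                raise ValueError("n_novel_junction_orfs > 0 but Type-1 share is 0")
            n1 = self.n_novel_junction_orfs
            total = int(round(n1 / p1)) if p1 > 0 else 0
        n2 = int(round(p2 * total))
        n3 = int(round(p3 * total))
        n4 = total - n1 - n2 - n3
        if n4 < 0:
            raise ValueError("inconsistent type_proportions / counts")
        return n1, n2, n3, n4


@dataclass
class SegmentRecord:
    """One tile of the CMS contig: where it came from."""

    cms_contig: str
    cms_start: int  # 1-based inclusive
    cms_end: int
    source_line: str  # donor line id, or "novel"
    source_contig: str
    source_start: int
    source_end: int
    copy_index: int
    source_sequence: Optional[str] = None  # stored for novel/modified segments


@dataclass
class ChimeraEvent:
    gene_id: str
    source_gene_id: Optional[str]
    prefix_bp: int
    novel_bp: int
    contig_id: str = ""
    strand: str = "+"


@dataclass
class FrameshiftEvent:
    gene_id: str
    indel_type: str          # "insertion"
    position_nt: int         # 1-based coordinate in the reference gene
    inserted_base: str
    sub_orf_gene_ids: list[str] = field(default_factory=list)


@dataclass
class FusionTruth:
    """The generator's ledger: the target of all recovery tests."""

    segments: list[SegmentRecord] = field(default_factory=list)
    gene_types: dict[str, str] = field(default_factory=dict)
    novel_orf_ids: list[str] = field(default_factory=list)
    chimeras: list[ChimeraEvent] = field(default_factory=list)
    frameshifts: list[FrameshiftEvent] = field(default_factory=list)
    editing_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    def reconstruct(self, donors: dict[str, GenomeRecord]) -> dict[str, str]:
        """Rebuild every CMS contig byte-for-byte from the segment table."""
        contigs: dict[str, list[tuple[int, str]]] = {}
        for seg in self.segments:
            if seg.source_line == "novel":
                seq = seg.source_sequence
            else:
                donor = donors[seg.source_line]
                seq = donor.contig(seg.source_contig).sequence[
                    seg.source_start - 1 : seg.source_end
                ]
            contigs.setdefault(seg.cms_contig, []).append((seg.cms_start, seq))
        out = {}
        for cid, parts in contigs.items():
            parts.sort()
            pos = 1
            chunks = []
            for start, seq in parts:
                if start != pos:
                    raise ValueError(
                        f"segment table does not tile {cid}: gap/overlap at {pos}"
                    )
                chunks.append(seq)
                pos = start + len(seq)
            out[cid] = "".join(chunks)
        return out

    def type_fractions(self) -> dict[str, float]:
        total = len(self.gene_types)
        out = {}
        for t in ("Type1", "Type2", "Type3", "Type4"):
            out[t] = (
                100.0 * sum(1 for v in self.gene_types.values() if v == t) / total
                if total else 0.0
            )
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [asdict(s) for s in self.segments],
                "gene_types": self.gene_types,
                "novel_orf_ids": self.novel_orf_ids,
                "chimeras": [asdict(c) for c in self.chimeras],
                "frameshifts": [asdict(f) for f in self.frameshifts],
                "editing_rates": self.editing_rates,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FusionTruth":
        d = json.loads(text)
        return cls(
            segments=[SegmentRecord(**s) for s in d["segments"]],
            gene_types=d["gene_types"],
            novel_orf_ids=d["novel_orf_ids"],
            chimeras=[ChimeraEvent(**c) for c in d["chimeras"]],
            frameshifts=[FrameshiftEvent(**f) for f in d["frameshifts"]],
            editing_rates=d["editing_rates"],
        )


def _cut_segment(rng, donor: GenomeRecord, ann: GeneAnnotation,
                 seg_range: tuple[int, int]) -> tuple[int, int]:
    """Choose a donor interval (1-based inclusive) containing the gene's
    cassette (guard included) with random flanks summing to the target."""
    contig = donor.contig(ann.contig_id)
    lo, hi = ann.span()
    # include the stop guard, which sits 5' of the gene on its own strand
    if ann.strand == "+":
        lo = max(1, lo - len(GUARD))
    else:
        hi = min(len(contig), hi + len(GUARD))
    span = hi - lo + 1
    target = int(rng.integers(seg_range[0], seg_range[1] + 1))
    target = max(target, span + 2 * MIN_SPACER)
    flank = target - span
    left = int(rng.integers(MIN_SPACER, flank - MIN_SPACER + 1)) if flank > 2 * MIN_SPACER else flank // 2
    s = max(1, lo - left)
    e = min(len(contig), hi + (flank - left))
    return s, e


def simulate_fusion_mitogenome(
    donor_a: GenomeRecord,
    donor_b: GenomeRecord,
    params: FusionParams,
    line_id: str = "CMS1",
) -> tuple[GenomeRecord, FusionTruth]:
    """Assemble a CMS mitogenome as a shuffled, partially duplicated patchwork
    of donor segments plus novel junction ORFs, with a complete truth ledger.

    Gene content realizes ``type_proportions``: Type 2 genes are cut from
    nuclear-donor-unique loci, Type 3 from cytoplasmic-donor-unique loci,
    Type 4 from orthologous loci (the copy taken from a random donor) and
    Type 1 genes are freshly generated novel junction ORFs.
    """
    rng = np.random.default_rng(params.seed)
    if not donor_a.genes or not donor_b.genes:
        raise ValueError("donors must be annotated")
    for donor in (donor_a, donor_b):
        if max(params.segment_length_range) > min(len(c) for c in donor.contigs):
            raise ValueError("segment_length_range exceeds donor contig length")
    n1, n2, n3, n4 = params.class_counts()

    uniq_a = [g for g in donor_a.genes if g.ortholog_id is None]
    uniq_b = [g for g in donor_b.genes if g.ortholog_id is None]
    shared = [g for g in donor_a.genes if g.ortholog_id is not None]
    if n2 > len(uniq_a) or n3 > len(uniq_b) or n4 > len(shared):
        raise ValueError(
            f"donors cannot supply the requested gene classes "
            f"(need {n2} nuclear-unique, {n3} cytoplasmic-unique, {n4} shared)"
        )

    picks: list[tuple[GenomeRecord, GeneAnnotation, str]] = []
    for ann in [uniq_a[i] for i in rng.choice(len(uniq_a), n2, replace=False)]:
        picks.append((donor_a, ann, "Type2"))
    for ann in [uniq_b[i] for i in rng.choice(len(uniq_b), n3, replace=False)]:
        picks.append((donor_b, ann, "Type3"))
    for ann in [shared[i] for i in rng.choice(len(shared), n4, replace=False)]:
        donor = donor_a if rng.random() < 0.5 else donor_b
        ortho = next(g for g in donor.genes if g.gene_id == ann.gene_id)
        picks.append((donor, ortho, "Type4"))

    contig_id = f"{line_id}Mt001"
    pieces: list[dict] = []
    for donor, ann, type_label in picks:
        s, e = _cut_segment(rng, donor, ann, params.segment_length_range)
        pieces.append(
            {
                "seq": donor.contig(ann.contig_id).sequence[s - 1 : e],
                "source_line": donor.line_id,
                "source_contig": ann.contig_id,
                "source_start": s,
                "source_end": e,
                "gene": ann,
                "type": type_label,
            }
        )
    for i in range(n1):
        lo, hi = params.novel_orf_length_range
        nt_len = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        orf = random_gene(rng, nt_len)
        flank = random_sequence(rng, MIN_SPACER)
        pieces.append(
            {
                "seq": GUARD + orf + flank,
                "source_line": "novel",
                "source_contig": "",
                "source_start": 0,
                "source_end": 0,
                "gene": ("novel", f"{line_id}_novelorf{i + 1:02d}", len(orf)),
                "type": "Type1",
            }
        )

    placements: list[tuple[dict, int]] = []
    for piece in pieces:
        copies = 2 if rng.random() < params.duplication_rate else 1
        for k in range(copies):
            placements.append((piece, k))
    order = rng.permutation(len(placements))
    placements = [placements[i] for i in order]

    truth = FusionTruth()
    seq_parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 1  # next cms_start
    for piece, copy_index in placements:
        seg_len = len(piece["seq"])
        seg = SegmentRecord(
            cms_contig=contig_id,
            cms_start=pos,
            cms_end=pos + seg_len - 1,
            source_line=piece["source_line"],
            source_contig=piece["source_contig"],
            source_start=piece["source_start"],
            source_end=piece["source_end"],
            copy_index=copy_index,
            source_sequence=piece["seq"] if piece["source_line"] == "novel" else None,
        )
        truth.segments.append(seg)
        gene = piece["gene"]
        if isinstance(gene, GeneAnnotation):
            offset = pos - piece["source_start"]
            gid = f"{gene.gene_id}__c{copy_index}" if copy_index else gene.gene_id
            gid = f"{line_id}:{gid}"
            annotations.append(
                GeneAnnotation(gid, contig_id, gene.start + offset,
                               gene.end + offset, gene.strand, gene.ortholog_id)
            )
            truth.gene_types[gid] = piece["type"]
        else:
            _, base_id, glen = gene
            gid = f"{base_id}__c{copy_index}" if copy_index else base_id
            gstart0 = pos - 1 + len(GUARD)  # 0-based within contig
            annotations.append(
                GeneAnnotation(gid, contig_id, gstart0 + 1, gstart0 + glen, "+")
            )
            truth.gene_types[gid] = "Type1"
            truth.novel_orf_ids.append(gid)
        seq_parts.append(piece["seq"])
        pos += seg_len

    genome = GenomeRecord(
        line_id, "cms",
        [SequenceRecord(contig_id, "".join(seq_parts), circular=False)],
        annotations, "mitochondrion",
    )
    return genome, truth


def simulate_conserved_chloroplast(
    nuclear_donor: GenomeRecord,
    divergence: float = 0.01,
    seed: int = 0,
    line_id: str = "CMS1",
) -> GenomeRecord:
    """CMS plastome = low-divergence, ORF-preserving copy of the nuclear
    donor's plastome (genes mutated without creating stops, backbone freely).
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    new_contigs = []
    new_genes = []
    for contig in nuclear_donor.contigs:
        seq = list(contig.sequence)
        gene_spans = []
        new_cid = f"{line_id}Cp_{contig.id}"
        for g in nuclear_donor.genes:
            if g.contig_id != contig.id:
                continue
            lo, hi = g.span()
            gene_spans.append((lo, hi, g))
            sub = g.extract(contig)
            mut = mutate_gene(sub, divergence, rng)
            ins = mut if g.strand == "+" else revcomp(mut)
            seq[lo - 1 : hi] = list(ins)
            new_genes.append(
                GeneAnnotation(f"{line_id}:{g.gene_id}", new_cid, g.start,
                               g.end, g.strand, g.ortholog_id)
            )
        covered = np.zeros(len(seq), dtype=bool)
        for lo, hi, _ in gene_spans:
            covered[lo - 1 : hi] = True
        backbone_idx = np.flatnonzero(~covered)
        if divergence > 0 and len(backbone_idx):
            k = rng.binomial(len(backbone_idx), divergence)
            for p in rng.choice(backbone_idx, size=k, replace=False):
                alts = [b for b in BASES if b != seq[p]]
                seq[p] = alts[rng.integers(0, 3)]
        new_contigs.append(SequenceRecord(new_cid, "".join(seq)))
    return GenomeRecord(line_id, "cms", new_contigs, new_genes, "chloroplast")


# ---------------------------------------------------------------------------
# injected gene events


def _junction_offsets(truth: Optional[FusionTruth], contig: SequenceRecord) -> list[int]:
    if truth is None or not truth.segments:
        return [0, len(contig)]
    offs = {0}
    for seg in truth.segments:
        if seg.cms_contig == contig.id:
            offs.add(seg.cms_end)
    return sorted(offs)


def _splice_in(
    genome: GenomeRecord,
    truth: Optional[FusionTruth],
    contig_id: str,
    at0: int,          # 0-based offset: new sequence inserted before this position
    insert_seq: str,
) -> None:
    """Insert a novel segment at a segment junction, shifting coordinates of
    all downstream annotations and truth segments."""
    contig = genome.contig(contig_id)
    shift = len(insert_seq)
    contig.sequence = contig.sequence[:at0] + insert_seq + contig.sequence[at0:]
    for g in genome.genes:
        if g.contig_id != contig_id:
            continue
        lo, hi = g.span()
        if lo - 1 >= at0:
            g.start += shift
            g.end += shift
        elif hi > at0:
            raise ValueError("insertion point falls inside an annotated gene")
    if truth is not None:
        for seg in truth.segments:
            if seg.cms_contig == contig_id and seg.cms_start - 1 >= at0:
                seg.cms_start += shift
                seg.cms_end += shift
        truth.segments.append(
            SegmentRecord(contig_id, at0 + 1, at0 + shift, "novel", "", 0, 0, 0,
                          source_sequence=insert_seq)
        )
        truth.segments.sort(key=lambda s: (s.cms_contig, s.cms_start))


def has_unexpected_orfs(
    sequence: str, expected_spans: set[tuple[int, int]], min_nt: int = 210
) -> bool:
    """True if the sequence carries any ORF >= min_nt (either strand) whose
    (low, high) plus-strand span is not in ``expected_spans``."""
    found = find_orfs(SequenceRecord("chk", sequence), min_nt=min(min_nt, 210))
    for o in found:
        if o.nt_length >= min_nt and o.span() not in expected_spans:
            return True
    return False


def build_chimera(
    source_nt: str,
    prefix_bp: int,
    novel_bp: int,
    rng: np.random.Generator,
    gc: float = 0.45,
    clean_below_nt: int = 210,
) -> str:
    """Chimeric ORF: first ``prefix_bp`` bases of a source gene + ``novel_bp``
    novel bases (terminal stop codon included). The first eight novel bases
    are forced to mismatch the source continuation so the breakpoint is
    exactly recoverable; the whole chimera is kept stop-free in frame, and
    the novel part is resampled until the cassette carries no incidental ORF
    of >= ``clean_below_nt`` coding bases in any other frame or strand (so
    injected loci contribute exactly the genes the truth ledger declares)."""
    total = prefix_bp + novel_bp
    if total % 3 != 0:
        raise ValueError("prefix_bp + novel_bp must be a multiple of 3")
    if prefix_bp > len(source_nt):
        raise ValueError("prefix exceeds source gene length")
    if prefix_bp and prefix_bp < 3:
        raise ValueError("non-zero prefix must be >= 3 (keep the ATG)")
    prefix = source_nt[:prefix_bp] if prefix_bp else "ATG"
    continuation = source_nt[prefix_bp : prefix_bp + 8] if prefix_bp else ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _attempt in range(500):
        # assemble base by base so stop-avoidance and mismatch constraints
        # compose
        out = list(prefix)
        i = 0
        while len(out) < total - 3:
            while True:
                b = str(rng.choice(list(BASES), p=p))
                if i < len(continuation) and b == continuation[i]:
                    continue
                trial = out + [b]
                if len(trial) % 3 == 0 and "".join(trial[-3:]) in STOP_CODONS:
                    continue
                break
            out.append(b)
            i += 1
        stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
        chimera = "".join(out) + stop
        assert len(chimera) == total
        aa = translate(chimera[:-3])  # sanity: a clean ORF
        assert aa.startswith("M") and "*" not in aa
        cassette = TERMINATOR + chimera + TERMINATOR
        # ORF spans exclude the stop codon
        main_span = (len(TERMINATOR) + 1, len(TERMINATOR) + total - 3)
        if not has_unexpected_orfs(cassette, {main_span}, clean_below_nt):
            return chimera
    raise RuntimeError("could not build a chimera free of incidental ORFs")


def inject_chimeric_gene(
    genome: GenomeRecord,
    source_gene: Union[OrfRecord, tuple[str, str]],
    prefix_bp: int,
    novel_bp: int,
    seed: int = 0,
    truth: Optional[FusionTruth] = None,
    gene_id: str = "chimera01",
    strand: str = "+",
    chimera_nt: Optional[str] = None,
) -> ChimeraEvent:
    """Insert a chimeric ORF (known-gene prefix + novel remainder) at a
    random segment junction of the genome; updates genome and truth in place.

    Pass ``chimera_nt`` to reuse a previously built chimera sequence (e.g. to
    plant the identical gene in several CMS lines)."""
    rng = np.random.default_rng(seed)
    if isinstance(source_gene, OrfRecord):
        src_id, src_nt = source_gene.orf_id, source_gene.nt_sequence
    else:
        src_id, src_nt = source_gene
    if chimera_nt is None:
        chimera_nt = build_chimera(src_nt, prefix_bp, novel_bp, rng)
    pad = len(TERMINATOR)
    cassette = TERMINATOR + chimera_nt + TERMINATOR
    if strand == "-":
        cassette = revcomp(cassette)
    contig = genome.contigs[0]
    offs = _junction_offsets(truth, contig)
    at0 = int(offs[rng.integers(0, len(offs))])
    _splice_in(genome, truth, contig.id, at0, cassette)
    glen = len(chimera_nt)
    if strand == "+":
        start, end = at0 + pad + 1, at0 + pad + glen
    else:
        # revcomp cassette keeps the chimera between the two terminators
        start, end = at0 + pad + glen, at0 + pad + 1
    genome.genes.append(GeneAnnotation(gene_id, contig.id, start, end, strand))
    event = ChimeraEvent(
        gene_id=gene_id,
        source_gene_id=src_id if prefix_bp else None,
        prefix_bp=prefix_bp,
        novel_bp=novel_bp,
        contig_id=contig.id,
        strand=strand,
    )
    if truth is not None:
        truth.chimeras.append(event)
        truth.gene_types[gene_id] = "Type1"
    return event


def build_frameshifted_region(
    region: str,
    gene_offset0: int,
    gene_len: int,
    insert_at_codon: int,
    rng: np.random.Generator,
    base: Optional[str] = None,
) -> tuple[str, int, str]:
    """Copy of a (plastid) region with one base inserted after codon
    ``insert_at_codon`` of the gene starting at ``gene_offset0`` (0-based).

    The inserted base differs from both neighbours so the indel position is
    unambiguous. Returns (modified_region, position_nt, base) where
    position_nt is the 1-based gene coordinate of the inserted base."""
    idx = gene_offset0 + 3 * insert_at_codon  # 0-based insertion offset in region
    if not gene_offset0 < idx < gene_offset0 + gene_len:
        raise ValueError("insertion codon outside the gene body")
    left, right = region[idx - 1], region[idx]
    if base is None:
        allowed = [b for b in BASES if b not in (left, right)]
        base = allowed[rng.integers(0, len(allowed))]
    elif base in (left, right):
        raise ValueError("inserted base equals a neighbour: position ambiguous")
    modified = region[:idx] + base + region[idx:]
    return modified, 3 * insert_at_codon + 1, base


def inject_plastid_insertion_with_frameshift(
    mitogenome: GenomeRecord,
    cp_region: str,
    gene_id: str,
    gene_offset0: int,
    gene_len: int,
    insert_at_codon: int,
    seed: int = 0,
    truth: Optional[FusionTruth] = None,
    modified_region: Optional[str] = None,
) -> FrameshiftEvent:
    """Copy a plastid region into the mitogenome with a 1-bp insertion inside
    the gene body, splitting its reading frame into two sub-ORFs.

    Sub-ORFs found in the inserted copy are annotated ``<gene_id>_fs1`` (the
    one retaining the original start) and ``_fs2`` (the downstream one)."""
    rng = np.random.default_rng(seed)
    if modified_region is None:
        modified_region, position_nt, base = build_frameshifted_region(
            cp_region, gene_offset0, gene_len, insert_at_codon, rng
        )
    else:
        position_nt = 3 * insert_at_codon + 1
        base = modified_region[gene_offset0 + 3 * insert_at_codon]
    contig = mitogenome.contigs[0]
    offs = _junction_offsets(truth, contig)
    at0 = int(offs[rng.integers(0, len(offs))])
    pad = len(TERMINATOR)
    _splice_in(mitogenome, truth, contig.id, at0,
               TERMINATOR + modified_region + TERMINATOR)

    # locate the two frame-split sub-ORFs inside the inserted copy: the one
    # retaining the gene's start codon and the one ending at the gene's last
    # sense codon (incidental internal ORFs in other frames are ignored)
    sub = find_orfs(SequenceRecord("region", modified_region), min_nt=75)
    gene_lo = gene_offset0 + 1
    sense_end = gene_offset0 + gene_len + 1 - 3  # insertion adds one base
    plus = [o for o in sub if o.strand == "+"]
    fs1 = next((o for o in plus if o.start == gene_lo), None)
    fs2 = next((o for o in plus if o.end == sense_end and o.start != gene_lo), None)
    sub_ids = []
    for i, o in enumerate([o for o in (fs1, fs2) if o is not None], 1):
        gid = f"{gene_id}_fs{i}"
        # annotations include the stop codon, like every generated gene
        mitogenome.genes.append(
            GeneAnnotation(gid, contig.id, at0 + pad + o.start,
                           at0 + pad + o.end + 3, "+")
        )
        if truth is not None:
            truth.gene_types[gid] = "Type1"
        sub_ids.append(gid)
    event = FrameshiftEvent(
        gene_id=gene_id,
        indel_type="insertion",
        position_nt=position_nt,
        inserted_base=base,
        sub_orf_gene_ids=sub_ids,
    )
    if truth is not None:
        truth.frameshifts.append(event)
    return event


# ---------------------------------------------------------------------------
# amplicon read / pileup simulation

#: per-site true C->U editing proportions, CDS position -> group -> rate.
#: The two-group defaults are the study conditions for a minus-strand gene
#: with four editable sites in codons 10-20; sites 58/47/30 differ between
#: groups, site 39 (third codon position, silent) does not.
DEFAULT_EDITING_PROFILE: dict[int, dict[str, float]] = {
    58: {"fertile": 0.598, "sterile": 0.395},
    47: {"fertile": 0.654, "sterile": 0.507},
    39: {"fertile": 0.52, "sterile": 0.52},
    30: {"fertile": 0.647, "sterile": 0.439},
}


@dataclass
class ReadSimParams:
    coverage: int = 1000
    read_length: int = 151
    per_base_error: float = 0.005
    editing_profile: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EDITING_PROFILE.items()}
    )
    n_replicates_per_group: int = 3
    emit_reads: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for pos, groups in self.editing_profile.items():
            for g, r in groups.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"editing rate {r} at {pos}/{g} not in [0,1]")

    def groups(self) -> list[str]:
        gs: list[str] = []
        for d in self.editing_profile.values():
            for g in d:
                if g not in gs:
                    gs.append(g)
        return sorted(gs)


@dataclass
class AmpliconSim:
    pileup: pd.DataFrame          # PILEUP_COLUMNS schema, plus-strand counts
    reads: Optional[pd.DataFrame]  # sample_id, contig, start, end, sequence
    truth: dict[int, dict[str, float]]
    sample_groups: dict[str, str]  # sample_id -> group ("gdna" for control)
    cmap: "CdsCoordinateMap"


def simulate_amplicon_reads(
    gene: Union[GeneAnnotation, OrfRecord],
    contig: SequenceRecord,
    params: ReadSimParams,
) -> AmpliconSim:
    """Simulate per-replicate cDNA amplicon evidence over one gene plus an
    unedited gDNA control, as plus-strand per-site base counts (default) or
    as individual reads from which the pileup is then tallied.

    Editing is applied per molecule: a read covering a site carries the edit
    with the group's true probability; on a minus-strand gene the coding-
    strand C->U edit is emitted as G->A on the plus strand. Sequencing error
    scatters each base uniformly to the other three."""
    from .editing import CdsCoordinateMap, PILEUP_COLUMNS

    rng = np.random.default_rng(params.seed)
    if isinstance(gene, GeneAnnotation):
        lo, hi = gene.span()
        strand = gene.strand
        anchor = gene.start
    else:
        lo, hi = gene.span()
        strand = gene.strand
        anchor = gene.start
    span = hi - lo + 1
    for pos in params.editing_profile:
        if not 1 <= pos <= span:
            raise ValueError(f"editing position {pos} outside the gene (1..{span})")
    cmap = CdsCoordinateMap(contig.id, strand, anchor, cds_length=span)

    # contig plus-strand position of each editing site, with the plus-strand
    # ref/alt bases implied by a coding-strand C->U edit
    site_plus: dict[int, int] = {}
    for cds_pos in params.editing_profile:
        cpos = anchor - cds_pos + 1 if strand == "-" else anchor + cds_pos - 1
        ref_base = contig.sequence[cpos - 1]
        expect = "G" if strand == "-" else "C"
        if ref_base != expect:
            raise ValueError(
                f"CDS position {cds_pos} is not an editable C on the coding strand"
            )
        site_plus[cds_pos] = cpos
    alt_base = "A" if strand == "-" else "T"
    ref_base_coding = "G" if strand == "-" else "C"

    samples: list[tuple[str, Optional[str]]] = []
    for g in params.groups():
        for r in range(1, params.n_replicates_per_group + 1):
            samples.append((f"{g}_rep{r}", g))
    samples.append(("gDNA", None))

    region = contig.sequence[lo - 1 : hi]
    base_idx = {b: i for i, b in enumerate(BASES)}
    pile_rows = []
    read_rows = []
    for sample_id, group in samples:
        counts = np.zeros((span, 4), dtype=np.int64)
        if params.emit_reads:
            n_reads = max(1, math.ceil(params.coverage * span / params.read_length))
            rl = min(params.read_length, span)
            starts = rng.integers(0, span - rl + 1, size=n_reads)
            for s0 in starts:
                bases = list(region[s0 : s0 + rl])
                if group is not None:
                    for cds_pos, cpos in site_plus.items():
                        rel = cpos - lo - s0
                        rate = params.editing_profile[cds_pos].get(group, 0.0)
                        if 0 <= rel < rl and rng.random() < rate:
                            bases[rel] = alt_base
                if params.per_base_error > 0:
                    errs = np.flatnonzero(
                        rng.random(rl) < params.per_base_error
                    )
                    for e in errs:
                        alts = [b for b in BASES if b != bases[e]]
                        bases[e] = alts[rng.integers(0, 3)]
                for i, b in enumerate(bases):
                    counts[s0 + i, base_idx[b]] += 1
                read_rows.append(
                    (sample_id, contig.id, lo + int(s0), lo + int(s0) + rl - 1,
                     "".join(bases))
                )
        else:
            depth = params.coverage
            edited_at = {
                cpos: rng.binomial(
                    depth, params.editing_profile[cds_pos].get(group, 0.0)
                ) if group is not None else 0
                for cds_pos, cpos in site_plus.items()
            }
            for i in range(span):
                b = region[i]
                row = np.zeros(4, dtype=np.int64)
                cpos = lo + i
                if cpos in edited_at and b == ref_base_coding:
                    k = edited_at[cpos]
                    row[base_idx[alt_base]] += k
                    row[base_idx[b]] += depth - k
                else:
                    row[base_idx[b]] += depth
                if params.per_base_error > 0:
                    moved = np.zeros(4, dtype=np.int64)
                    for j in range(4):
                        if row[j] == 0:
                            continue
                        ne = rng.binomial(row[j], params.per_base_error)
                        if ne:
                            dest = [d for d in range(4) if d != j]
                            split = rng.multinomial(ne, [1 / 3] * 3)
                            row[j] -= ne
                            for d, c in zip(dest, split):
                                moved[d] += c
                    row += moved
                counts[i] += row
        for i in range(span):
            pile_rows.append(
                (contig.id, lo + i, region[i], int(counts[i, 0]),
                 int(counts[i, 1]), int(counts[i, 2]), int(counts[i, 3]),
                 sample_id)
            )

    pileup = pd.DataFrame(pile_rows, columns=PILEUP_COLUMNS)
    reads = (
        pd.DataFrame(
            read_rows, columns=["sample_id", "contig", "start", "end", "sequence"]
        )
        if params.emit_reads else None
    )
    sample_groups = {s: (g if g is not None else "gdna") for s, g in samples}
    return AmpliconSim(
        pileup=pileup,
        reads=reads,
        truth={p: dict(g) for p, g in params.editing_profile.items()},
        sample_groups=sample_groups,
        cmap=cmap,
    )
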
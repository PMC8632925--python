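"""A complete synthetic CMS study with known truth.

:func:`synthetic_study` wires the generators into the full experimental
design the pipeline expects: a nuclear donor and a cytoplasmic donor (with
plastomes), two extra fertile relatives, and three independently fused CMS
lines that all carry the same three injected candidate loci —

* ``orf137like`` — a fully novel ORF present in two copies per CMS line;
* ``orf265like`` — a chimera whose first 59 codons come from a cytoplasmic-
  donor-unique *atp8*-like gene (with editable C sites engineered in codons
  10/13/16/20) and whose remainder is novel, placed on the minus strand;
* ``orf193like``/``orf116like`` — the two sub-ORFs created by copying a
  plastid *cytochrome f*-like region into the mitogenome with a single-base
  insertion after codon 116 of the 310-codon gene.

Anther expression reads cover orf137like (both copies), orf193like and
orf265like but not orf116like, so the screen's expected outcome is exactly
{orf137like x2, orf193like, orf265like}. Amplicon pileups over orf265like
carry the default two-group editing profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import GeneAnnotation, GenomeRecord, SequenceRecord
from .synthetic import (
    GUARD,
    AmpliconSim,
    DonorGenomeSpec,
    FusionParams,
    FusionTruth,
    ReadSimParams,
    build_chimera,
    build_frameshifted_region,
    generate_donor_genomes,
    inject_chimeric_gene,
    inject_plastid_insertion_with_frameshift,
    random_gene,
    random_sense_codon,
    random_sequence,
    set_gene_codons,
    simulate_amplicon_reads,
    simulate_conserved_chloroplast,
    simulate_fusion_mitogenome,
)

CMS_LINES = ("CMS-M", "CMS-O", "CMS-P")

#: codons of the atp8-like source gene carrying editable C sites; CDS
#: positions 58/47/39/30 are codon 20 offset 1 (CTT, L->F when edited),
#: codon 16 offset 2 (TCA, S->L), codon 13 offset 3 (TTC, silent F),
#: codon 10 offset 3 (TTC, silent F).
ATP8_EDIT_CODONS = {10: "TTC", 13: "TTC", 16: "TCA", 20: "CTT"}


def build_cytf_gene(rng: np.random.Generator, n_codons: int = 310) -> str:
    """A plastid gene engineered so that a single T inserted after codon 116
    splits it into sub-ORFs of exactly 116 and 193 amino acids.

    Codon 115 CTG + codon 116 starting A put a TGA stop in the shifted frame
    just upstream of codon 118's ATG; codon 117 starts AA so the inserted T
    completes an immediate TAA stop for the upstream sub-ORF.
    """
    fixed = {115: "CTG", 116: "AAC", 117: "AAC", 118: "ATG"}
    codons = []
    for i in range(1, n_codons + 1):
        codons.append(fixed.get(i) or random_sense_codon(rng))
    return "ATG" + "".join(codons[1:]) + "TAA"


def _clean_cytf_region(
    rng: np.random.Generator, max_attempts: int = 200
) -> tuple[str, int, str]:
    """Flanked cytf region whose frameshifted copy carries exactly the two
    designed sub-ORFs and no incidental ORF >= 210 nt on either strand."""
    from .synthetic import has_unexpected_orfs

    for _ in range(max_attempts):
        cytf = build_cytf_gene(rng)
        left = random_sequence(rng, 300) + GUARD
        right = random_sequence(rng, 300)
        region = left + cytf + right
        offset0 = len(left)
        modified, _, _ = build_frameshifted_region(
            region, offset0, len(cytf), insert_at_codon=116, rng=rng, base="T"
        )
        # designed sub-ORF spans in the modified region (stop codon excluded):
        fs1 = (offset0 + 1, offset0 + 348)
        fs2 = (offset0 + 353, offset0 + 931)
        intact = (offset0 + 1, offset0 + len(cytf) - 3)
        if has_unexpected_orfs(modified, {fs1, fs2}) or has_unexpected_orfs(
            region, {intact}
        ):
            continue
        return region, offset0, cytf
    raise RuntimeError("could not build a clean cytf region")


@dataclass
class StudyBundle:
    donor_a: GenomeRecord              # nuclear donor mitogenome
    donor_b: GenomeRecord              # cytoplasmic donor mitogenome
    fertile_relatives: list[GenomeRecord]
    cms: dict[str, GenomeRecord]
    truths: dict[str, FusionTruth]
    cp_donor_a: GenomeRecord
    cp_donor_b: GenomeRecord
    cp_cms: GenomeRecord
    cytf_region: str                   # intact plastid region (cytf inside)
    cytf_gene_offset0: int
    cytf_gene_len: int
    expression_reads: pd.DataFrame     # focal-line anther read table
    amplicon: AmpliconSim              # editing evidence over orf265like
    focal_line: str = "CMS-P"
    expected_candidates: dict[str, list[str]] = field(default_factory=dict)

    def mito_genomes(self) -> dict[str, GenomeRecord]:
        out = {g.line_id: g for g in [self.donor_a, self.donor_b]}
        for g in self.fertile_relatives:
            out[g.line_id] = g
        out.update(self.cms)
        return out

    def fertile_panel(self) -> dict[str, GenomeRecord]:
        """Criterion-2 genomes: nuclear donor + fertile relatives (the
        cytoplasmic donor is itself fertile but, as in the real screen, is
        not part of the panel)."""
        panel = {self.donor_a.line_id: self.donor_a}
        for g in self.fertile_relatives:
            panel[g.line_id] = g
        return panel

    def line_roles(self) -> dict[str, str]:
        roles = {
            self.donor_a.line_id: "nuclear_donor",
            self.donor_b.line_id: "cytoplasmic_donor",
        }
        for g in self.fertile_relatives:
            roles[g.line_id] = "fertile_relative"
        for line in self.cms:
            roles[line] = "cms"
        return roles


def _mutated_copy(
    genome: GenomeRecord, line_id: str, divergence: float, seed: int,
    role: str = "fertile_relative",
) -> GenomeRecord:
    from .synthetic import mutate_gene, mutate_sequence

    rng = np.random.default_rng(seed)
    new_contigs = []
    genes = []
    for contig in genome.contigs:
        cid = f"{line_id}_c01"
        seq = list(contig.sequence)
        covered = np.zeros(len(seq), dtype=bool)
        for g in genome.genes:
            if g.contig_id != contig.id:
                continue
            lo, hi = g.span()
            mut = mutate_gene(g.extract(contig), divergence, rng)
            from .records import revcomp

            seq[lo - 1 : hi] = list(mut if g.strand == "+" else revcomp(mut))
            covered[lo - 1 : hi] = True
            genes.append(
                GeneAnnotation(f"{line_id}:{g.gene_id}", cid, g.start, g.end,
                               g.strand, g.ortholog_id)
            )
        idx = np.flatnonzero(~covered)
        k = rng.binomial(len(idx), divergence) if divergence > 0 else 0
        for p in rng.choice(idx, size=k, replace=False) if k else []:
            alts = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alts[rng.integers(0, 3)]
        new_contigs.append(SequenceRecord(cid, "".join(seq)))
    return GenomeRecord(line_id, role, new_contigs, genes, genome.organelle)


def _tile_reads(
    contig_id: str, lo: int, hi: int, read_length: int = 151, n_reads: int = 25
) -> list[tuple[str, str, int, int]]:
    span = hi - lo + 1
    rl = min(read_length, span)
    out = []
    for i in range(n_reads):
        frac = i / max(1, n_reads - 1)
        start = lo + int(round(frac * (span - rl)))
        out.append(("anther_rna", contig_id, start, start + rl - 1))
    return out


def synthetic_study(
    seed: int = 0,
    donor_spec: Optional[DonorGenomeSpec] = None,
    fusion_params: Optional[FusionParams] = None,
    read_params: Optional[ReadSimParams] = None,
) -> StudyBundle:
    """Generate the full synthetic study deterministically from one seed."""
    master = np.random.default_rng(seed)
    sub = lambda: int(master.integers(0, 2**31 - 1))

    spec = donor_spec or DonorGenomeSpec(seed=sub())
    donor_a, donor_b = generate_donor_genomes(spec)

    # engineer the atp8-like gene (editable sites) on a cytoplasmic-donor-
    # unique locus, so the chimera prefix is absent from the fertile panel
    atp8_id = next(g.gene_id for g in donor_b.genes if g.gene_id.startswith("uB"))
    set_gene_codons(donor_b, atp8_id, ATP8_EDIT_CODONS)
    atp8_nt = donor_b.gene_sequence(atp8_id)

    fertile = [
        _mutated_copy(donor_a, "LA1670like", 0.01, sub()),
        _mutated_copy(donor_a, "LA1673like", 0.01, sub()),
    ]

    # plastomes: a smaller donor pair plus the engineered cytf region
    cp_spec = DonorGenomeSpec(
        genome_length=18_000, n_genes=12, seed=sub(),
        divergence_between_donors=spec.divergence_between_donors,
    )
    cp_a, cp_b = generate_donor_genomes(
        cp_spec, line_a="nuclearA_cp", line_b="acauleB_cp",
        organelle="chloroplast",
    )
    rng_cytf = np.random.default_rng(sub())
    cytf_region, cytf_offset0, cytf = _clean_cytf_region(rng_cytf)
    cp_contig = cp_a.contigs[0]
    base = len(cp_contig.sequence)
    cp_contig.sequence = cp_contig.sequence + cytf_region
    cp_a.genes.append(
        GeneAnnotation("cytf", cp_contig.id, base + cytf_offset0 + 1,
                       base + cytf_offset0 + len(cytf), "+")
    )
    cp_cms = simulate_conserved_chloroplast(cp_a, divergence=0.01, seed=sub(),
                                            line_id="CMS-P")

    # shared injected sequences: identical across the three CMS lines
    chim_rng = np.random.default_rng(sub())
    orf265_nt = build_chimera(atp8_nt, prefix_bp=177, novel_bp=621, rng=chim_rng)
    orf137_nt = build_chimera("", prefix_bp=0, novel_bp=414, rng=chim_rng)
    fs_rng = np.random.default_rng(sub())
    fs_region, fs_pos, fs_base = build_frameshifted_region(
        cytf_region, cytf_offset0, len(cytf), insert_at_codon=116, rng=fs_rng,
        base="T",
    )

    base_fusion = fusion_params or FusionParams()
    cms: dict[str, GenomeRecord] = {}
    truths: dict[str, FusionTruth] = {}
    for i, line in enumerate(CMS_LINES):
        params = FusionParams(
            segment_length_range=base_fusion.segment_length_range,
            duplication_rate=base_fusion.duplication_rate,
            type_proportions=base_fusion.type_proportions,
            n_novel_junction_orfs=base_fusion.n_novel_junction_orfs,
            n_genes=base_fusion.n_genes,
            novel_orf_length_range=base_fusion.novel_orf_length_range,
            seed=sub(),
        )
        genome, truth = simulate_fusion_mitogenome(donor_a, donor_b, params, line)
        ev_seed = sub()
        inject_chimeric_gene(
            genome, (atp8_id, atp8_nt), 177, 621, seed=ev_seed, truth=truth,
            gene_id="orf265like", strand="-", chimera_nt=orf265_nt,
        )
        inject_chimeric_gene(
            genome, ("", ""), 0, 414, seed=sub(), truth=truth,
            gene_id="orf137like", strand="+", chimera_nt=orf137_nt,
        )
        inject_chimeric_gene(
            genome, ("", ""), 0, 414, seed=sub(), truth=truth,
            gene_id="orf137like__c1", strand="+", chimera_nt=orf137_nt,
        )
        inject_plastid_insertion_with_frameshift(
            genome, cytf_region, "cytf", cytf_offset0, len(cytf),
            insert_at_codon=116, seed=sub(), truth=truth,
            modified_region=fs_region,
        )
        cms[line] = genome
        truths[line] = truth

    focal = "CMS-P"
    genome = cms[focal]
    contig = genome.contigs[0]
    read_rows = []
    expressed_genes = ["orf137like", "orf137like__c1", "orf265like", "cytf_fs2"]
    for gid in expressed_genes:
        ann = next(g for g in genome.genes if g.gene_id == gid)
        lo, hi = ann.span()
        read_rows.extend(_tile_reads(contig.id, lo, hi))
    expression_reads = pd.DataFrame(
        read_rows, columns=["sample_id", "contig", "start", "end"]
    )

    orf265_ann = next(g for g in genome.genes if g.gene_id == "orf265like")
    rp = read_params or ReadSimParams(seed=sub())
    amplicon = simulate_amplicon_reads(orf265_ann, contig, rp)

    expected = {
        line: ["orf137like", "orf137like__c1", "cytf_fs2", "orf265like"]
        for line in CMS_LINES
    }
    return StudyBundle(
        donor_a=donor_a,
        donor_b=donor_b,
        fertile_relatives=fertile,
        cms=cms,
        truths=truths,
        cp_donor_a=cp_a,
        cp_donor_b=cp_b,
        cp_cms=cp_cms,
        cytf_region=cytf_region,
        cytf_gene_offset0=cytf_offset0,
        cytf_gene_len=len(cytf),
        expression_reads=expression_reads,
        amplicon=amplicon,
        focal_line=focal,
        expected_candidates=expected,
    )


def edited_minus_strand_gene(
    seed: int, anchor: int = 1_200, n_codons: int = 265,
) -> tuple[SequenceRecord, GeneAnnotation]:
    """A minus-strand gene with editable C sites in codons 10/13/16/20,
    placed so the first base of its start codon sits at plus-strand position
    ``anchor`` — the geometry of the orf265-style editing analysis."""
    from .synthetic import random_gene

    rng = np.random.default_rng(seed)
    gene = random_gene(rng, 3 * (n_codons + 1))
    for idx, codon in ATP8_EDIT_CODONS.items():
        gene = gene[: 3 * (idx - 1)] + codon + gene[3 * idx :]
    glen = len(gene)
    if anchor < glen + 1:
        raise ValueError("anchor too close to the contig start")
    from .records import revcomp

    left = random_sequence(rng, anchor - glen)
    right = random_sequence(rng, 50)
    contig = SequenceRecord("CMS-PMt010like", left + revcomp(gene) + right)
    ann = GeneAnnotation("orf265like", contig.id, anchor, anchor - glen + 1, "-")
    assert ann.extract(contig) == gene
    return contig, ann


def match_orf(orfs, annotation: GeneAnnotation):
    """The called ORF corresponding to an annotated gene (exact interval)."""
    lo, hi = annotation.span()
    exp_len = hi - lo + 1 - 3  # annotation includes the stop codon
    for o in orfs:
        if (
            o.contig_id == annotation.contig_id
            and o.strand == annotation.strand
            and o.start == annotation.start
            and o.nt_length == exp_len
        ):
            return o
    return None
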
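"""Homology blocks, frameshift and chimera detectors, gene neighborhoods."""

import numpy as np
import pytest

from orgfusion.orfs import translate
from orgfusion.records import GeneAnnotation, OrfRecord, SequenceRecord, revcomp
from orgfusion.structure import (
    decompose_homology_blocks,
    detect_chimera,
    detect_frameshift,
    neighborhood_context,
)
from orgfusion.synthetic import (
    build_chimera,
    build_frameshifted_region,
    random_gene,
    random_sequence,
)


def _boundary_spacer(rng, n, mismatch_fwd="", mismatch_rev=""):
    """Random spacer whose leading bases differ from ``mismatch_fwd`` (the
    subject continuation after the previous segment) and whose trailing bases
    differ from ``mismatch_rev`` (the subject bases preceding the next
    segment, aligned right-to-left), so ungapped extension cannot profitably
    cross the constructed boundary."""
    out = list(random_sequence(rng, n))
    for i, b in enumerate(mismatch_fwd[: min(8, n)]):
        if out[i] == b:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b]
    for i, b in enumerate(reversed(mismatch_rev[-min(8, n):])):
        if out[n - 1 - i] == b:
            out[n - 1 - i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b]
    return "".join(out)


class TestHomologyBlocks:
    def test_exact_copy_single_block(self, rng):
        s = random_sequence(rng, 1_200)
        blocks = decompose_homology_blocks(s, s)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.q_start, b.q_end) == (1, 1_200)
        assert (b.s_start, b.s_end) == (1, 1_200)
        assert b.identity == 1.0 and b.orientation == "+"

    def test_three_constructed_segments_recovered(self, rng):
        """A query stitched from three subject segments with novel spacers
        decomposes into exactly those three blocks with their lengths."""
        subject = random_sequence(rng, 4_682)
        segs = [(101, 1_690), (2_001, 2_488), (3_001, 4_007)]  # 1590/488/1007 bp
        parts = []
        for i, (lo, hi) in enumerate(segs):
            parts.append(subject[lo - 1 : hi])
            nxt_lo = segs[i + 1][0] if i + 1 < len(segs) else None
            parts.append(
                _boundary_spacer(
                    rng, 60,
                    mismatch_fwd=subject[hi : hi + 8],
                    mismatch_rev=subject[nxt_lo - 9 : nxt_lo - 1] if nxt_lo else "",
                )
            )
        query = "".join(parts)
        blocks = decompose_homology_blocks(query, subject, min_block_bp=100)
        assert [b.q_end - b.q_start + 1 for b in blocks] == [1_590, 488, 1_007]
        assert [(b.s_start, b.s_end) for b in blocks] == segs

    def test_inverted_segment_gets_minus_orientation(self, rng):
        subject = random_sequence(rng, 2_000)
        inv = revcomp(subject[1_000:1_400])
        spacer = _boundary_spacer(
            rng, 50,
            mismatch_fwd=subject[500:508],
            # left extension of the inverted block reads revcomp(subject) just
            # past position 1400
            mismatch_rev=revcomp(subject[1_400:1_408]),
        )
        query = subject[:500] + spacer + inv
        blocks = decompose_homology_blocks(query, subject, min_block_bp=100)
        assert len(blocks) == 2
        assert blocks[0].orientation == "+"
        assert blocks[1].orientation == "-"
        assert (blocks[1].s_start, blocks[1].s_end) == (1_001, 1_400)

    def test_swap_symmetry(self, rng):
        subject = random_sequence(rng, 1_500)
        query = subject[200:800] + random_sequence(rng, 100) + subject[900:1_300]
        fwd = decompose_homology_blocks(query, subject)
        rev = decompose_homology_blocks(subject, query)
        assert {(b.q_start, b.q_end, b.s_start, b.s_end) for b in fwd} == {
            (b.s_start, b.s_end, b.q_start, b.q_end) for b in rev
        }

    def test_no_similarity_empty(self, rng):
        a = random_sequence(rng, 800)
        b = random_sequence(rng, 800)
        assert decompose_homology_blocks(a, b, min_block_bp=100) == []

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            decompose_homology_blocks("", "ACGT")


class TestDetectFrameshift:
    def test_engineered_cytf_split_into_116_and_193(self):
        """The 310-codon plastid gene with one T inserted after codon 116
        yields the call at nt 349 and sub-ORFs of 116 and 193 aa."""
        from orgfusion.study import _clean_cytf_region

        rng = np.random.default_rng(20)
        region, offset0, cytf = _clean_cytf_region(rng)
        modified, pos, base = build_frameshifted_region(
            region, offset0, len(cytf), insert_at_codon=116, rng=rng, base="T"
        )
        call = detect_frameshift(modified, ("cytf", cytf))
        assert call is not None and call.indel_type == "insertion"
        assert call.position_nt == 349
        lengths = sorted(
            o.aa_length for o in call.sub_orfs
            if o.aa_length >= 70 and o.strand == "+"
        )
        assert lengths == [116, 193]

    def test_identical_returns_none(self, rng):
        gene = random_gene(rng, 600)
        region = random_sequence(rng, 100) + gene + random_sequence(rng, 100)
        assert detect_frameshift(region, ("g", gene)) is None

    def test_inframe_3bp_insertion_returns_none(self, rng):
        gene = random_gene(rng, 600)
        mod = gene[:300] + "GCA" + gene[300:]
        region = random_sequence(rng, 100) + mod + random_sequence(rng, 100)
        assert detect_frameshift(region, ("g", gene)) is None

    def test_two_indels_reported_complex(self, rng):
        gene = random_gene(rng, 600)
        mod = gene[:150] + "T" + gene[150:450] + "A" + gene[450:]
        # make both inserted bases differ from neighbours to keep them apart
        if gene[149] == "T" or gene[150] == "T":
            mod = gene[:150] + ("C" if gene[150] != "C" and gene[149] != "C" else "G") + gene[150:450] + "A" + gene[450:]
        call = detect_frameshift(random_sequence(rng, 80) + mod, ("g", gene))
        assert call is not None and call.indel_type == "complex"
        assert call.position_nt is None

    def test_single_deletion_called(self, rng):
        gene = random_gene(rng, 600)
        # delete a base whose neighbours differ so the position is unambiguous
        for p in range(300, 400):
            if gene[p - 1] != gene[p] and gene[p + 1] != gene[p]:
                break
        mod = gene[:p] + gene[p + 1 :]
        region = random_sequence(rng, 100) + mod + random_sequence(rng, 100)
        call = detect_frameshift(region, ("g", gene))
        assert call is not None and call.indel_type == "deletion"
        assert call.position_nt == p + 1

    @pytest.mark.parametrize("seed", range(10))
    def test_injection_round_trip_exact(self, seed):
        """detect_frameshift recovers the injected insertion offset exactly
        over random constructions."""
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(120, 350))
        gene = random_gene(rng, 3 * (n_codons + 1))
        region = (
            random_sequence(rng, int(rng.integers(50, 300)))
            + gene
            + random_sequence(rng, int(rng.integers(50, 300)))
        )
        offset0 = region.find(gene)
        codon = int(rng.integers(10, n_codons - 10))
        modified, pos, base = build_frameshifted_region(
            region, offset0, len(gene), codon, rng
        )
        call = detect_frameshift(modified, ("g", gene))
        assert call is not None
        assert call.indel_type == "insertion"
        assert call.position_nt == pos == 3 * codon + 1


class TestDetectChimera:
    def _orf_from(self, nt, orf_id="cand"):
        return OrfRecord(orf_id, "c", 1, len(nt) - 3, "+", nt[:-3],
                         translate(nt[:-3]))

    def test_injected_177bp_prefix_recovered_exactly(self, rng):
        src = random_gene(rng, 240)
        ch = build_chimera(src, 177, 621, rng)
        call = detect_chimera(self._orf_from(ch), [("atp8", src)])
        assert call is not None and call.kind == "chimera"
        assert call.source_gene_id == "atp8"
        assert call.matched_bp == 177
        assert call.match_q_start == 1

    def test_upstream_context_counts_into_match(self, rng):
        """A chimera whose matched region extends into upstream genomic
        context reports the full terminal match length."""
        src = random_gene(rng, 300)
        # chimera ORF starts at an internal ATG of the source (codon 21): the
        # 60 bases of upstream context + the ORF prefix all match the source
        src = src[:60] + "ATG" + src[63:]
        prefix_in_orf = 90
        ctx = src[:60]
        orf_nt = build_chimera(src[60:], prefix_in_orf, 210, rng)
        call = detect_chimera(
            self._orf_from(orf_nt), [("src", src)], upstream_context=ctx
        )
        assert call is not None and call.kind == "chimera"
        assert call.matched_bp == 60 + prefix_in_orf

    def test_fully_novel_orf_no_call(self, rng):
        ch = build_chimera("", 0, 414, rng)
        src = random_gene(rng, 240)
        assert detect_chimera(self._orf_from(ch), [("x", src)]) is None

    def test_full_length_homolog_not_chimera(self, rng):
        gene = random_gene(rng, 300)
        call = detect_chimera(self._orf_from(gene), [("g", gene)])
        assert call is not None and call.kind == "homolog"

    def test_empty_known_set_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_chimera(self._orf_from(random_gene(rng, 300)), [])

    @pytest.mark.parametrize("seed", range(10))
    def test_injection_round_trip_exact(self, seed):
        rng = np.random.default_rng(1000 + seed)
        src = random_gene(rng, int(rng.integers(60, 150)) * 3)
        prefix = 3 * int(rng.integers(25, min(90, len(src) // 3 - 2)))
        novel = 3 * int(rng.integers(60, 200))
        ch = build_chimera(src, prefix, novel, rng)
        call = detect_chimera(self._orf_from(ch), [("src", src)])
        assert call is not None and call.kind == "chimera"
        assert call.source_gene_id == "src"
        assert call.matched_bp == prefix


class TestNeighborhood:
    def _ann(self, gid, start, end, strand="+"):
        return GeneAnnotation(gid, "c", start, end, strand)

    def test_no_neighbors_in_window(self):
        orf = self._ann("b", 5_000, 5_500)
        anns = [self._ann("far", 20_000, 20_500)]
        assert neighborhood_context(orf, anns, window_bp=2_000) == []

    def test_operon_layout_sides(self):
        a = self._ann("A", 1_000, 1_500)
        b = self._ann("B", 2_000, 2_500)
        c = self._ann("C", 3_000, 3_500)
        out = neighborhood_context(b, [a, b, c], window_bp=2_000)
        rel = {f.gene_id: f.relation for f in out}
        assert rel == {"A": "upstream", "C": "downstream"}
        # minus-strand focal gene flips the relations
        b_minus = self._ann("B", 2_500, 2_000, "-")
        rel2 = {
            f.gene_id: f.relation
            for f in neighborhood_context(b_minus, [a, c], window_bp=2_000)
        }
        assert rel2 == {"A": "downstream", "C": "upstream"}

    def test_distances_exact(self):
        a = self._ann("A", 1_000, 1_500)
        b = self._ann("B", 1_800, 2_300)
        (f,) = neighborhood_context(b, [a], window_bp=1_000)
        assert f.distance == 1_800 - 1_500 - 1
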
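"""Clustering, similarity search and Type 1-4 classification."""

import numpy as np
import pytest

from orgfusion.homology import (
    classify_types,
    count_non_overlapping_hits,
    greedy_cluster,
    is_present,
    local_similarity_search,
    pairwise_identity,
    type_positional_map,
)
from orgfusion.records import GenomeRecord, OrfRecord, SequenceRecord, revcomp
from orgfusion.synthetic import random_gene, random_sequence

from conftest import gene_orfs


def _orf(orf_id, nt, line="L1"):
    aa_len = len(nt) // 3
    return OrfRecord(orf_id, "c", 1, len(nt), "+", nt, "M" + "A" * (aa_len - 1),
                     line_id=line)


# --- independent identity oracle via Biopython global-ish alignment --------


def _oracle_identity(a: str, b: str) -> float:
    from Bio import Align

    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps on the long sequence = glocal placement of the short one
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
    aln = aligner.align(short, long_)[0]
    matches = sum(
        1
        for s, l in zip(str(aln[0]), str(aln[1]))
        if s == l and s != "-"
    )
    return matches / len(short)


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        orfs = [_orf(f"o{i}", "ATG" + "GCA" * 30) for i in range(5)]
        clusters = greedy_cluster(orfs)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == [f"o{i}" for i in range(5)]

    def test_threshold_splits_at_85_percent_identity(self):
        rng = np.random.default_rng(0)
        a = random_gene(rng, 300)[:-3]
        b = list(a)
        # mutate 15% of positions deterministically
        idx = np.linspace(5, len(a) - 5, int(0.15 * len(a))).astype(int)
        for p in idx:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        ident = pairwise_identity(a, b)
        assert 0.8 < ident < 0.9
        two = greedy_cluster([_orf("a", a), _orf("b", b)], identity_threshold=0.9)
        one = greedy_cluster([_orf("a", a), _orf("b", b)], identity_threshold=0.8)
        assert len(two) == 2 and len(one) == 1

    def test_identity_against_biopython_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = random_gene(rng, 150)
            b = list(a)
            k = rng.integers(0, 20)
            for p in rng.choice(len(a), size=k, replace=False):
                alts = [x for x in "ACGT" if x != b[p]]
                b[p] = alts[rng.integers(0, 3)]
            b = "".join(b)
            assert pairwise_identity(a, b) == pytest.approx(
                _oracle_identity(a, b), abs=0.02
            )

    def test_contained_substring_identity_one(self):
        rng = np.random.default_rng(4)
        long_ = random_sequence(rng, 600)
        short = long_[100:250]
        assert pairwise_identity(short, long_) == 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_matches_exhaustive_oracle(self, seed):
        """Greedy partition equals an oracle that replays the longest-first
        pass checking every member/representative pair with an independent
        identity function."""
        rng = np.random.default_rng(seed)
        orfs = []
        base = [random_gene(rng, int(rng.integers(40, 120)) * 3) for _ in range(12)]
        for i in range(50):
            src = base[rng.integers(0, len(base))]
            mut = list(src)
            # <=3% substitutions keeps within-cluster identity far above the
            # 0.9 threshold and between-cluster identity far below it, so the
            # independent oracle metric cannot disagree at the boundary
            for p in rng.choice(
                len(src), size=rng.integers(0, max(2, len(src) // 33)),
                replace=False,
            ):
                alts = [x for x in "ACGT" if x != mut[p]]
                mut[p] = alts[rng.integers(0, 3)]
            orfs.append(_orf(f"o{i:02d}", "".join(mut)))
        got = greedy_cluster(orfs, identity_threshold=0.9)

        ordered = sorted(orfs, key=lambda o: (-o.nt_length, o.orf_id))
        reps, members = [], []
        for o in ordered:
            for i, rep in enumerate(reps):
                if _oracle_identity(o.nt_sequence, rep.nt_sequence) >= 0.9:
                    members[i].append(o.orf_id)
                    break
            else:
                reps.append(o)
                members.append([o.orf_id])
        expected = [sorted(m) for m in members]
        assert [sorted(c.member_ids) for c in got] == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        orfs = [_orf(f"o{i}", random_gene(rng, 120)) for i in range(20)]
        a = greedy_cluster(orfs, 0.9)
        b = greedy_cluster(list(reversed(orfs)), 0.9)
        assert [sorted(c.member_ids) for c in a] == [sorted(c.member_ids) for c in b]

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            greedy_cluster([_orf("a", "ATG" + "AAA" * 30)], identity_threshold=1.5)

    def test_representative_is_longest_member(self):
        rng = np.random.default_rng(5)
        long_gene = random_gene(rng, 600)
        short = long_gene[:300]
        clusters = greedy_cluster([_orf("short", short), _orf("long", long_gene)], 0.9)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "long"


class TestLocalSimilaritySearch:
    def test_exact_substring_hit(self, rng):
        subj = random_sequence(rng, 30_000)
        q = subj[10_000:10_250]
        hits = local_similarity_search(q, SequenceRecord("s", subj))
        assert hits
        top = hits[0]
        assert top.identity == 1.0
        assert top.evalue < 1e-50
        assert (top.s_start, top.s_end) == (10_001, 10_250)

    def test_random_queries_never_hit_at_1e50(self):
        """Score distribution oracle: unrelated 300-bp queries against an
        unrelated 30-kb subject never reach E <= 1e-50."""
        rng = np.random.default_rng(42)
        subj = SequenceRecord("s", random_sequence(rng, 30_000))
        for _ in range(100):
            q = random_sequence(rng, 300)
            assert local_similarity_search(q, subj, evalue_max=1e-50) == []

    def test_minus_strand_hit_reported(self, rng):
        subj = random_sequence(rng, 5_000)
        q = revcomp(subj[2_000:2_300])
        hits = local_similarity_search(q, SequenceRecord("s", subj))
        assert hits and hits[0].strand == "-"
        assert (hits[0].s_start, hits[0].s_end) == (2_001, 2_300)

    def test_empty_subject_no_hits(self):
        assert local_similarity_search("ACGT" * 30, SequenceRecord("s", "ACGT")) == []

    def test_copy_number_counts_duplicates(self, rng):
        gene = random_gene(rng, 300)
        filler = [random_sequence(rng, 2_000) for _ in range(3)]
        seq = filler[0] + gene + filler[1] + gene + filler[2]
        genome = GenomeRecord("g", "cms", [SequenceRecord("c1", seq)])
        assert count_non_overlapping_hits(gene, genome) == 2
        other = GenomeRecord("d", "nuclear_donor",
                             [SequenceRecord("c1", filler[0] + filler[2])])
        assert count_non_overlapping_hits(gene, other) == 0

    def test_copy_number_invariant_under_revcomp(self, rng):
        gene = random_gene(rng, 300)
        seq = random_sequence(rng, 1_500) + gene + random_sequence(rng, 1_500)
        fwd = GenomeRecord("g", "cms", [SequenceRecord("c1", seq)])
        rev = GenomeRecord("g", "cms", [SequenceRecord("c1", revcomp(seq))])
        assert (
            count_non_overlapping_hits(gene, fwd)
            == count_non_overlapping_hits(gene, rev)
            == 1
        )


class TestClassifyTypes:
    def _clusters(self, patterns):
        """Build one single-member-per-line cluster per presence pattern."""
        from orgfusion.homology import ClusterAssignment

        clusters = []
        for i, lines in enumerate(patterns):
            clusters.append(
                ClusterAssignment(
                    f"cl{i}", f"orf{i}_0",
                    [f"orf{i}_{j}" for j in range(len(lines))], list(lines), 0.9,
                )
            )
        return clusters

    def test_presence_patterns_map_to_types(self):
        roles = {"cms1": "cms", "nuc": "nuclear_donor", "cyt": "cytoplasmic_donor"}
        clusters = self._clusters(
            [
                ["cms1"],                      # unique -> Type1
                ["cms1", "nuc"],               # nuclear only -> Type2
                ["cms1", "cyt"],               # cytoplasmic only -> Type3
                ["cms1", "nuc", "cyt"],        # both -> Type4
            ]
        )
        labels, table = classify_types(clusters, roles)
        assert labels["orf0_0"] == "Type1"
        assert labels["orf1_0"] == "Type2"
        assert labels["orf2_0"] == "Type3"
        assert labels["orf3_0"] == "Type4"
        row = table.iloc[0]
        assert row[["Type1_pct", "Type2_pct", "Type3_pct", "Type4_pct"]].sum() == \
            pytest.approx(100.0)

    def test_cluster_without_cms_member_is_skipped(self):
        roles = {"cms1": "cms", "nuc": "nuclear_donor", "cyt": "cytoplasmic_donor"}
        clusters = self._clusters([["nuc", "cyt"], ["cms1"]])
        labels, table = classify_types(clusters, roles)
        assert table.attrs["clusters_without_cms"] == 1
        assert set(labels) == {"orf1_0"}

    def test_positional_map_sorted_and_truthful(self, bundle):
        """Type-3 entries of the fused genome fall inside truth segments that
        originate from the cytoplasmic donor."""
        from orgfusion.homology import greedy_cluster

        line = bundle.focal_line
        genome = bundle.cms[line]
        truth = bundle.truths[line]
        orfs = (
            gene_orfs(bundle.donor_a)
            + gene_orfs(bundle.donor_b)
            + gene_orfs(genome)
        )
        clusters = greedy_cluster(orfs, 0.8)
        roles = {
            bundle.donor_a.line_id: "nuclear_donor",
            bundle.donor_b.line_id: "cytoplasmic_donor",
            line: "cms",
        }
        labels, _ = classify_types(clusters, roles)
        posmap = type_positional_map(labels, orfs)
        assert list(posmap["start"]) == sorted(posmap["start"].tolist()) or \
            posmap.sort_values(["contig", "start"]).equals(posmap)
        b_segments = [
            (s.cms_start, s.cms_end)
            for s in truth.segments
            if s.source_line == bundle.donor_b.line_id
        ]
        type3 = posmap[(posmap["type"] == "Type3") & (posmap["line"] == line)]
        for _, row in type3.iterrows():
            assert any(lo <= row["start"] <= hi for lo, hi in b_segments)


def test_presence_by_cluster_and_search_agree_at_low_divergence():
    """Cross-validation: at donor divergence <= 0.05 the clustering route and
    the E-value search route agree on which donor genomes contain each CMS
    gene (default identity threshold 0.9)."""
    from orgfusion.synthetic import (
        DonorGenomeSpec,
        FusionParams,
        generate_donor_genomes,
        simulate_fusion_mitogenome,
    )
    from orgfusion.homology import greedy_cluster

    spec = DonorGenomeSpec(divergence_between_donors=0.05, seed=21)
    a, b = generate_donor_genomes(spec)
    genome, truth = simulate_fusion_mitogenome(a, b, FusionParams(seed=22), "CMS1")
    orfs = gene_orfs(a) + gene_orfs(b) + gene_orfs(genome)
    clusters = greedy_cluster(orfs, 0.9)
    cms_ids = {o.orf_id for o in gene_orfs(genome)}
    by_cluster = {}
    for cl in clusters:
        lines = cl.lines_present()
        for oid, ln in zip(cl.member_ids, cl.member_lines):
            if oid in cms_ids:
                by_cluster[oid] = (a.line_id in lines, b.line_id in lines)
    for o in gene_orfs(genome):
        by_search = (
            is_present(o.nt_sequence, a),
            is_present(o.nt_sequence, b),
        )
        assert by_search == by_cluster[o.orf_id], o.orf_id
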
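"""The synthetic-data generators and their truth ledger."""

import math

import numpy as np
import pytest

from orgfusion.records import GeneAnnotation, SequenceRecord
from orgfusion.synthetic import (
    DonorGenomeSpec,
    FusionParams,
    ReadSimParams,
    build_chimera,
    build_frameshifted_region,
    generate_donor_genomes,
    mutate_sequence,
    random_gene,
    random_sequence,
    simulate_amplicon_reads,
    simulate_conserved_chloroplast,
    simulate_fusion_mitogenome,
)


class TestDonorGenomes:
    def test_zero_divergence_gives_identical_ortholog_sequences(self):
        spec = DonorGenomeSpec(divergence_between_donors=0.0, seed=5)
        a, b = generate_donor_genomes(spec)
        for g in a.genes:
            if g.ortholog_id:
                assert a.gene_sequence(g.gene_id) == b.gene_sequence(g.gene_id)

    def test_substitution_sampler_matches_binomial_oracle(self):
        """divergence 0.10 over a 900-bp gene gives ~90 differences, within
        3 * sqrt(90 * 0.9) of the expectation."""
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(10):
            gene = random_gene(rng, 900)
            mut = mutate_sequence(gene, 0.10, rng)
            assert len(mut) == len(gene)
            diffs.append(sum(1 for x, y in zip(gene, mut) if x != y))
        tol = 3 * math.sqrt(90 * 0.9)
        for d in diffs:
            assert abs(d - 90) <= tol

    def test_seed_determinism_byte_identical(self, tmp_path):
        from orgfusion.io import write_fasta

        spec = DonorGenomeSpec(seed=7)
        out = []
        for run in range(2):
            a, b = generate_donor_genomes(spec)
            pa = tmp_path / f"a{run}.fasta"
            write_fasta(pa, a.contigs)
            out.append(pa.read_bytes())
            assert [g.__dict__ for g in a.genes] == [
                g.__dict__ for g in generate_donor_genomes(spec)[0].genes
            ]
        assert out[0] == out[1]

    def test_incompatible_gene_count_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            spec = DonorGenomeSpec(genome_length=5_000, n_genes=100, seed=0)
            generate_donor_genomes(spec)

    def test_annotations_extract_clean_orfs(self):
        from orgfusion.orfs import translate

        a, b = generate_donor_genomes(DonorGenomeSpec(seed=3))
        for genome in (a, b):
            for g in genome.genes:
                nt = genome.gene_sequence(g.gene_id)
                aa = translate(nt)
                assert aa.startswith("M") and aa.endswith("*")
                assert "*" not in aa[:-1]


class TestFusion:
    def test_degenerate_proportions_all_type4(self):
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=1))
        params = FusionParams(
            duplication_rate=0.0,
            type_proportions=(0.0, 0.0, 0.0, 1.0),
            n_novel_junction_orfs=0,
            n_genes=15,
            seed=2,
        )
        genome, truth = simulate_fusion_mitogenome(a, b, params)
        assert truth.gene_types
        assert set(truth.gene_types.values()) == {"Type4"}

    def test_truth_segments_reconstruct_contigs_byte_for_byte(self):
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=4))
        genome, truth = simulate_fusion_mitogenome(a, b, FusionParams(seed=5))
        rebuilt = truth.reconstruct({a.line_id: a, b.line_id: b})
        for contig in genome.contigs:
            assert rebuilt[contig.id] == contig.sequence

    def test_cms_genome_longer_than_either_donor(self):
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=6))
        genome, _ = simulate_fusion_mitogenome(a, b, FusionParams(seed=7))
        assert genome.total_length > max(a.total_length, b.total_length)

    def test_duplication_rate_scales_length(self):
        """duplication_rate 0.5 gives ~1.5x the unduplicated segment total."""
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=8))
        base_len = 0
        dup_len = 0
        n = 6
        for i in range(n):
            p0 = FusionParams(duplication_rate=0.0, seed=100 + i)
            p5 = FusionParams(duplication_rate=0.5, seed=100 + i)
            base_len += simulate_fusion_mitogenome(a, b, p0)[0].total_length
            dup_len += simulate_fusion_mitogenome(a, b, p5)[0].total_length
        ratio = dup_len / base_len
        assert 1.3 < ratio < 1.7

    def test_segment_range_exceeding_donor_rejected(self):
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=9))
        params = FusionParams(segment_length_range=(40_000, 50_000), seed=1)
        with pytest.raises(ValueError, match="segment"):
            simulate_fusion_mitogenome(a, b, params)

    def test_type_proportions_validation(self):
        with pytest.raises(ValueError):
            FusionParams(type_proportions=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            FusionParams(duplication_rate=1.5)

    def test_determinism(self):
        a, b = generate_donor_genomes(DonorGenomeSpec(seed=10))
        g1, t1 = simulate_fusion_mitogenome(a, b, FusionParams(seed=11))
        g2, t2 = simulate_fusion_mitogenome(a, b, FusionParams(seed=11))
        assert g1.contigs[0].sequence == g2.contigs[0].sequence
        assert t1.to_json() == t2.to_json()


class TestConservedChloroplast:
    def test_zero_divergence_identical(self):
        a, _ = generate_donor_genomes(
            DonorGenomeSpec(genome_length=18_000, n_genes=12, seed=12),
            organelle="chloroplast",
        )
        cp = simulate_conserved_chloroplast(a, divergence=0.0, seed=13)
        assert cp.contigs[0].sequence == a.contigs[0].sequence
        assert cp.role == "cms"

    def test_seed_determinism(self):
        a, _ = generate_donor_genomes(
            DonorGenomeSpec(genome_length=18_000, n_genes=12, seed=12),
            organelle="chloroplast",
        )
        c1 = simulate_conserved_chloroplast(a, 0.01, seed=14)
        c2 = simulate_conserved_chloroplast(a, 0.01, seed=14)
        assert c1.contigs[0].sequence == c2.contigs[0].sequence

    def test_type3_fraction_zero_on_round_trip(self):
        """CMS plastome genes cluster with the nuclear donor: no Type 3."""
        from conftest import gene_orfs
        from orgfusion.homology import classify_types, greedy_cluster

        a, b = generate_donor_genomes(
            DonorGenomeSpec(genome_length=18_000, n_genes=12, seed=15),
            organelle="chloroplast",
        )
        cp = simulate_conserved_chloroplast(a, 0.01, seed=16, line_id="CMS1")
        orfs = gene_orfs(a) + gene_orfs(b) + gene_orfs(cp, "CMS1")
        clusters = greedy_cluster(orfs, 0.8)
        _, table = classify_types(
            clusters,
            {a.line_id: "nuclear_donor", b.line_id: "cytoplasmic_donor",
             "CMS1": "cms"},
        )
        assert table.iloc[0]["Type3_pct"] == 0.0


class TestInjectionBuilders:
    def test_chimera_length_and_translation(self, rng):
        src = random_gene(rng, 240)
        ch = build_chimera(src, 177, 621, rng)
        assert len(ch) == 798
        assert ch[:177] == src[:177]
        from orgfusion.orfs import translate

        aa = translate(ch)
        assert len(aa) == 266 and aa.endswith("*")  # 265 aa + stop

    def test_chimera_breakpoint_mismatch_guard(self, rng):
        src = random_gene(rng, 240)
        for _ in range(5):
            ch = build_chimera(src, 90, 210, rng)
            assert all(ch[90 + i] != src[90 + i] for i in range(8))

    def test_fully_novel_chimera(self, rng):
        ch = build_chimera("", 0, 414, rng)
        assert len(ch) == 414 and ch.startswith("ATG")

    def test_odd_total_rejected(self, rng):
        with pytest.raises(ValueError):
            build_chimera(random_gene(rng, 240), 100, 211, rng)

    def test_frameshift_region_insertion_unambiguous(self, rng):
        gene = random_gene(rng, 933)
        region = random_sequence(rng, 150) + gene + random_sequence(rng, 150)
        mod, pos, base = build_frameshifted_region(region, 150, len(gene), 116, rng)
        assert len(mod) == len(region) + 1
        assert pos == 349
        idx = 150 + 348
        assert mod[idx] == base
        assert base != region[idx - 1] and base != region[idx]

    def test_frameshift_outside_gene_rejected(self, rng):
        gene = random_gene(rng, 300)
        region = random_sequence(rng, 50) + gene + random_sequence(rng, 50)
        with pytest.raises(ValueError):
            build_frameshifted_region(region, 50, len(gene), 150, rng)


class TestAmpliconSim:
    def _gene(self):
        gene_nt = "ATG" + "CCA" * 40 + "TAA"
        contig = SequenceRecord("c", "GGAA" + gene_nt + "TTCC")
        ann = GeneAnnotation("g", "c", 5, 4 + len(gene_nt), "+")
        return ann, contig

    def test_zero_rate_zero_error_measures_exactly_zero(self):
        ann, contig = self._gene()
        params = ReadSimParams(
            coverage=500, per_base_error=0.0,
            editing_profile={5: {"g1": 0.0}}, n_replicates_per_group=2, seed=1,
        )
        sim = simulate_amplicon_reads(ann, contig, params)
        site = sim.pileup[sim.pileup["pos"] == 9]
        assert (site["count_T"] == 0).all()
        assert (site["count_C"] == 500).all()

    def test_rate_estimate_within_binomial_envelope(self):
        """coverage 1,000 at true rate 0.6: estimates within 3 binomial SEs."""
        ann, contig = self._gene()
        for seed in range(5):
            params = ReadSimParams(
                coverage=1000, per_base_error=0.0,
                editing_profile={5: {"g1": 0.6}}, n_replicates_per_group=3,
                seed=seed,
            )
            sim = simulate_amplicon_reads(ann, contig, params)
            site = sim.pileup[
                (sim.pileup["pos"] == 9) & (sim.pileup["sample_id"] != "gDNA")
            ]
            # pooled over the three replicates: 3,000 Bernoulli trials
            n = (site["count_T"] + site["count_C"]).sum()
            rate = site["count_T"].sum() / n
            assert abs(rate - 0.6) <= 3 * math.sqrt(0.6 * 0.4 / n)

    def test_gdna_control_unedited(self):
        ann, contig = self._gene()
        params = ReadSimParams(
            coverage=400, per_base_error=0.0,
            editing_profile={5: {"g1": 0.7}}, seed=3,
        )
        sim = simulate_amplicon_reads(ann, contig, params)
        gd = sim.pileup[sim.pileup["sample_id"] == "gDNA"]
        assert (gd.loc[gd["pos"] == 9, "count_T"] == 0).all()

    def test_position_outside_gene_rejected(self):
        ann, contig = self._gene()
        with pytest.raises(ValueError, match="outside"):
            simulate_amplicon_reads(
                ann, contig,
                ReadSimParams(editing_profile={4000: {"g1": 0.5}}, seed=1),
            )

    def test_non_editable_position_rejected(self):
        ann, contig = self._gene()
        with pytest.raises(ValueError, match="editable"):
            # CDS position 1 is the A of ATG, not a C
            simulate_amplicon_reads(
                ann, contig, ReadSimParams(editing_profile={1: {"g1": 0.5}}, seed=1)
            )

    def test_reads_mode_pileup_conserves_read_bases(self):
        ann, contig = self._gene()
        params = ReadSimParams(
            coverage=100, read_length=50, per_base_error=0.01,
            editing_profile={5: {"g1": 0.5}}, n_replicates_per_group=2,
            emit_reads=True, seed=4,
        )
        sim = simulate_amplicon_reads(ann, contig, params)
        assert sim.reads is not None
        lo, hi = ann.span()
        for sample in sim.reads["sample_id"].unique():
            reads = sim.reads[sim.reads["sample_id"] == sample]
            depth = np.zeros(hi - lo + 1, dtype=int)
            for _, r in reads.iterrows():
                depth[r["start"] - lo : r["end"] - lo + 1] += 1
            pile = sim.pileup[sim.pileup["sample_id"] == sample]
            col_sums = (
                pile[["count_A", "count_C", "count_G", "count_T"]]
                .sum(axis=1)
                .to_numpy()
            )
            assert (col_sums == depth).all()

    def test_minus_strand_edit_appears_as_plus_strand_a(self, bundle):
        """On the minus-strand gene the C->U edit is emitted as G->A in the
        plus-strand counts."""
        sim = bundle.amplicon
        cmap = sim.cmap
        assert cmap.strand == "-"
        pos58 = cmap.start_anchor - 58 + 1
        cdna = sim.pileup[
            (sim.pileup["pos"] == pos58) & (sim.pileup["sample_id"] != "gDNA")
        ]
        assert (cdna["ref_base"] == "G").all()
        assert (cdna["count_A"] > 0).all()

    def test_determinism(self):
        ann, contig = self._gene()
        params = ReadSimParams(editing_profile={5: {"g1": 0.3}}, seed=9)
        s1 = simulate_amplicon_reads(ann, contig, params)
        s2 = simulate_amplicon_reads(ann, contig, params)
        assert s1.pileup.equals(s2.pileup)
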
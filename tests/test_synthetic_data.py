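"""Determinism, ground-truth consistency, and statistical behavior of the simulators."""
import numpy as np
import pytest

from methylscan import cpg_methylation as cpg
from methylscan import divergence_popgen as div
from methylscan import genome_features as gf
from methylscan import synthetic_data as sd
from methylscan.genetic_code import STOP_CODONS, translate_codon


class TestGenomeAnnotation:
    def test_no_genes_no_annotation(self):
        config = sd.SimulationConfig(genome_length=10_000, n_genes=0)
        genomes, genes, truth = sd.simulate_genome_annotation(config, seed=0)
        assert genes == [] and truth.methylated_gene_ids == []
        assert genomes[0].length == 10_000

    def test_same_seed_byte_identical_files(self, tmp_path):
        config = sd.SimulationConfig(
            genome_length=60_000, n_genes=6, cds_codons=(80, 120),
            n_exons=(2, 3), intron_length=(80, 150), utr_length=(30, 60),
        )
        outputs = []
        for run in ("a", "b"):
            genomes, genes, truth = sd.simulate_genome_annotation(config, seed=5)
            fa, gff, tj = (tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3", tmp_path / f"{run}.json")
            gf.write_fasta(((g.contig_id, g.sequence) for g in genomes), fa)
            gf.write_gff3(genes, gff)
            truth.to_json(tj)
            outputs.append((fa.read_bytes(), gff.read_bytes(), tj.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_realized_gc_concentrates(self):
        config = sd.SimulationConfig(genome_length=1_000_000, n_genes=0, background_gc=0.5)
        genomes, _, _ = sd.simulate_genome_annotation(config, seed=1)
        s = cpg.composition_stats(genomes[0].sequence)
        assert 0.49 <= s.gc <= 0.51

    def test_genes_carry_intact_orfs(self, small_sim):
        _, genomes, genes, _ = small_sim
        feats = gf.extract_feature_sequences(genes, genomes)
        for f in feats:
            if f.feature_class != "CDS":
                continue
            assert len(f.sequence) % 3 == 0
            assert f.sequence[:3] == "ATG"
            assert f.sequence[-3:] in STOP_CODONS
            internal = [
                f.sequence[i : i + 3] for i in range(0, len(f.sequence) - 3, 3)
            ]
            assert all(translate_codon(c) != "*" for c in internal)

    def test_genes_spaced_and_disjoint(self, small_sim):
        config, _, genes, _ = small_sim
        spans = sorted(g.transcript_span for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= config.min_intergenic

    def test_infeasible_geometry_rejected(self):
        config = sd.SimulationConfig(genome_length=5_000, n_genes=10)
        with pytest.raises(ValueError, match="infeasible"):
            sd.simulate_genome_annotation(config, seed=0)


class TestDeamination:
    def test_delta_zero_is_identity(self, small_sim):
        _, genomes, genes, truth = small_sim
        mutated, n_edits = sd.apply_methylation_deamination(
            genomes, genes, truth.methylated_gene_ids, 0.0, seed=3
        )
        assert n_edits == 0
        assert [g.sequence for g in mutated] == [g.sequence for g in genomes]

    def test_delta_one_removes_all_cpg_in_methylated_genes(self, small_sim):
        _, genomes, genes, truth = small_sim
        mutated, _ = sd.apply_methylation_deamination(
            genomes, genes, truth.methylated_gene_ids, 1.0, seed=3
        )
        by_contig = {g.contig_id: g.sequence for g in mutated}
        meth = set(truth.methylated_gene_ids)
        for gene in genes:
            if gene.gene_id in meth:
                s, e = gene.transcript_span
                assert "CG" not in by_contig[gene.contig_id][s:e]

    def test_unmethylated_and_intergenic_untouched(self, small_sim):
        _, genomes, genes, truth = small_sim
        mutated, _ = sd.apply_methylation_deamination(
            genomes, genes, truth.methylated_gene_ids, 1.0, seed=3
        )
        meth = set(truth.methylated_gene_ids)
        changed = {
            (g.contig_id, i)
            for g, m in zip(genomes, mutated)
            for i in np.nonzero(
                np.frombuffer(g.sequence.encode(), np.uint8)
                != np.frombuffer(m.sequence.encode(), np.uint8)
            )[0]
        }
        inside = set()
        for gene in genes:
            if gene.gene_id in meth:
                s, e = gene.transcript_span
                inside.update((gene.contig_id, i) for i in range(s, e))
        assert changed <= inside

    def test_half_rate_halves_cpg_count(self, small_sim):
        _, genomes, genes, truth = small_sim
        meth = set(truth.methylated_gene_ids)
        spans = [
            (g.contig_id, *g.transcript_span) for g in genes if g.gene_id in meth
        ]
        by_contig = {g.contig_id: g.sequence for g in genomes}
        before = sum(by_contig[c][s:e].count("CG") for c, s, e in spans)
        counts = []
        for seed in range(10):
            mutated, _ = sd.apply_methylation_deamination(
                genomes, genes, truth.methylated_gene_ids, 0.5, seed=seed
            )
            mc = {g.contig_id: g.sequence for g in mutated}
            counts.append(sum(mc[c][s:e].count("CG") for c, s, e in spans))
        mean = np.mean(counts)
        # binomial expectation with 3-sigma slack
        assert abs(mean - before / 2) < 3 * np.sqrt(before * 0.25 / 10)

    def test_cpg_drops_gpc_control_stays_flat(self, small_sim):
        """Deamination strictly depletes CpG O/E of affected genes while the
        within-replicate GpC comparison against unaffected genes stays
        non-significant (the negative control does not light up)."""
        _, genomes, genes, truth = small_sim
        meth = set(truth.methylated_gene_ids)

        def cds_stats(gs):
            feats = gf.extract_feature_sequences(genes, gs)
            return {
                f.gene_id: cpg.composition_stats(f.sequence, f.gene_id)
                for f in feats
                if f.feature_class == "CDS"
            }

        base = cds_stats(genomes)
        base_cpg = np.mean([base[g].cpg_oe for g in sorted(meth)])
        n_sig = 0
        for seed in range(20):
            mutated, _ = sd.apply_methylation_deamination(
                genomes, genes, truth.methylated_gene_ids, 0.5, seed=seed
            )
            stats = cds_stats(mutated)
            assert np.mean([stats[g].cpg_oe for g in sorted(meth)]) < base_cpg
            res = cpg.compare_to_background(
                [stats[g].gpc_oe for g in sorted(meth)],
                [stats[g].gpc_oe for g in sorted(set(stats) - meth)],
            )
            n_sig += res.pvalue < 0.01
        assert n_sig <= 1

    def test_delta_validation(self, small_sim):
        _, genomes, genes, truth = small_sim
        with pytest.raises(ValueError):
            sd.apply_methylation_deamination(genomes, genes, [], 1.5, seed=0)

    def test_synonymous_only_preserves_protein(self, small_sim):
        _, genomes, genes, truth = small_sim
        mutated, n_edits = sd.apply_methylation_deamination(
            genomes, genes, truth.methylated_gene_ids, 1.0, seed=3, synonymous_only=True
        )
        assert n_edits > 0
        orig = {
            (f.gene_id, f.feature_class): f.sequence
            for f in gf.extract_feature_sequences(genes, genomes)
        }
        new = {
            (f.gene_id, f.feature_class): f.sequence
            for f in gf.extract_feature_sequences(genes, mutated)
        }
        for (gene_id, fc), seq in orig.items():
            if fc != "CDS":
                continue
            mutated_seq = new[(gene_id, fc)]
            protein = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)]
            protein_new = [
                translate_codon(mutated_seq[i : i + 3])
                for i in range(0, len(mutated_seq), 3)
            ]
            assert protein == protein_new


class TestDivergentPair:
    CDS = "ATG" + "GGTACCTTACGA" * 25  # 103 codons, in frame, no stops

    def test_zero_rates_identical(self):
        pair = sd.simulate_divergent_pair(self.CDS, 0.0, 0.0, seed=1)
        assert pair.seq_a == pair.seq_b
        assert pair.truth.substitutions == []

    def test_synonymous_only_gives_zero_ka(self):
        pair = sd.simulate_divergent_pair(self.CDS, 0.2, 0.0, seed=2)
        r = div.ng86_kaks(pair.seq_a, pair.seq_b)
        assert r.ka == 0.0 and r.ks > 0
        assert all(s["class"] == "synonymous" for s in pair.truth.substitutions)

    def test_truth_substitutions_consistent_with_sequences(self):
        pair = sd.simulate_divergent_pair(self.CDS, 0.06, 0.02, seed=3)
        diff_positions = {
            i for i, (a, b) in enumerate(zip(pair.seq_a, pair.seq_b)) if a != b
        }
        assert {s["position"] for s in pair.truth.substitutions} == diff_positions

    def test_planted_synonymous_diffs_recovered_by_ng86(self):
        rng = np.random.default_rng(0)
        cds = "ATG" + sd._random_codons(rng, 300, 0.4)
        pair = sd.simulate_divergent_pair(cds, 0.03, 0.0, seed=13)
        # precondition for exact pathway counting: one hit per codon
        codons_hit = [s["position"] // 3 for s in pair.truth.substitutions]
        assert len(codons_hit) == len(set(codons_hit))
        r = div.ng86_kaks(pair.seq_a, pair.seq_b)
        assert r.syn_diffs == pytest.approx(len(pair.truth.substitutions))
        assert r.nonsyn_diffs == 0.0

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_divergent_pair(self.CDS, 1.5, 0.0, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_divergent_pair("ATGG", 0.1, 0.1, seed=0)


class TestHitTable:
    def test_single_gene_singleton(self):
        from methylscan import gene_family_clustering as fam

        sim = sd.simulate_hit_table([1], seed=0)
        res = fam.cluster_families(fam.build_graph(sim.hits, sim.self_scores))
        assert res.families == [frozenset(sim.self_scores)]

    def test_same_seed_identical_tsv(self, tmp_path):
        blobs = []
        for run in ("a", "b"):
            sim = sd.simulate_hit_table([3, 4], seed=7)
            hits, selfs = tmp_path / f"h{run}.tsv", tmp_path / f"s{run}.tsv"
            sd.write_hits_tsv(sim, hits, selfs)
            blobs.append((hits.read_bytes(), selfs.read_bytes()))
        assert blobs[0] == blobs[1]

    def test_overlapping_score_ranges_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_hit_table([2, 2], seed=0, within_h=(40, 90), between_h=(0, 50))


class TestVariantSim:
    def test_planted_private_counts_recovered(self):
        spec = sd.VariantSimConfig(n_private_a=100, n_private_b=80, n_shared=40)
        sim = sd.simulate_variant_calls(spec, seed=9)
        res = div.private_variants(sim.records, "indivA", "indivB")
        assert res.private_a == 100 and res.private_b == 80
        assert sorted(res.sites_a) == [("sim1", p) for p in sorted(sim.truth.private_a_sites)]

    def test_zero_variants_empty_body(self, tmp_path):
        sim = sd.simulate_variant_calls(
            sd.VariantSimConfig(n_private_a=0, n_private_b=0, n_shared=0), seed=0
        )
        assert sim.records == []
        path = tmp_path / "empty.vcf"
        sd.write_vcf(sim, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_capacity_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_variant_calls(
                sd.VariantSimConfig(contig_length=10, n_private_a=20), seed=0
            )

    def test_all_failing_records_fail_filter(self):
        spec = sd.VariantSimConfig(n_private_a=12, n_private_b=0, n_shared=0, fail_fraction=1.0)
        sim = sd.simulate_variant_calls(spec, seed=4)
        _, failed = div.hard_filter_variants(sim.records)
        assert len(failed) == 12
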
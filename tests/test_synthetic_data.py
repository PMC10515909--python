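import numpy as np
import pytest

from entorip import io_core
from entorip.domainarch import RULESETS, classify_genome_candidates
from entorip.io_core import ValidationError
from entorip.orthoccupancy import classify_genes, classify_orthogroups
from entorip.synthetic_data import (
    PlantedArchitecture, PlantedEnrichment, RepeatFamily,
    SimAnnotationParams, SimGenomeParams, SimOgParams, apply_rip_mutations,
    simulate_domain_annotations, simulate_domain_count_matrix,
    simulate_genome, simulate_orthogroups)


class TestGenomeSim:
    def test_rate_zero_copies_identical_to_master(self):
        params = SimGenomeParams(
            length_bp=50_000, repeat_families=(RepeatFamily("r", 500, 8),),
            rip_rate=0.0, seed=1)
        seqs, truth = simulate_genome(params)
        units = {seqs[0].residues[r.start:r.end] for r in truth.regions}
        assert len(units) == 1

    def test_same_seed_identical_output(self):
        params = SimGenomeParams(
            length_bp=20_000, repeat_families=(RepeatFamily("r", 300, 5),),
            rip_rate=0.3, seed=7)
        s1, t1 = simulate_genome(params)
        s2, t2 = simulate_genome(params)
        assert s1 == s2
        assert t1.mutated_sites == t2.mutated_sites

    def test_gc_fraction_within_sampling_error(self):
        params = SimGenomeParams(length_bp=100_000, gc_fraction=0.5, seed=3)
        seqs, _ = simulate_genome(params)
        gc = sum(seqs[0].residues.count(b) for b in "GC") / 100_000
        # binomial SE = sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * (0.25 / 100_000) ** 0.5

    def test_repeats_never_overlap(self):
        params = SimGenomeParams(
            length_bp=30_000,
            repeat_families=(RepeatFamily("a", 1000, 10),
                             RepeatFamily("b", 500, 10)), seed=2)
        _, truth = simulate_genome(params)
        by_seq = {}
        for r in truth.regions:
            by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
        for spans in by_seq.values():
            spans.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in
                       zip(spans, spans[1:]))

    def test_oversized_repeats_rejected(self):
        with pytest.raises(ValueError):
            SimGenomeParams(length_bp=1000,
                            repeat_families=(RepeatFamily("r", 600, 2),))


class TestRipMutation:
    def test_rate_one_cpa_limit(self):
        mutated, sites = apply_rip_mutations("CACA", [(0, 4)], 1.0, seed=0)
        assert mutated == "TATA"
        assert sites == [0, 2]

    def test_rate_one_tpg_reverse_context(self):
        mutated, sites = apply_rip_mutations("TGTG", [(0, 4)], 1.0, seed=0)
        assert mutated == "TATA"
        assert sites == [1, 3]

    def test_rate_zero_identity(self):
        seq = "CATGCATG"
        mutated, sites = apply_rip_mutations(seq, [(0, 8)], 0.0, seed=0)
        assert mutated == seq and sites == []

    def test_outside_regions_untouched(self):
        mutated, _ = apply_rip_mutations("CACACACA", [(0, 2)], 1.0, seed=0)
        assert mutated[2:] == "CACACA"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValidationError):
            apply_rip_mutations("CACACA", [(0, 4), (2, 6)], 1.0, seed=0)


class TestAnnotationSim:
    def test_no_planted_effects_empty_truth(self):
        _, _, truth = simulate_domain_annotations(SimAnnotationParams(
            n_genomes=2, n_domains=10, baseline_lambda=2, totals=100,
            seed=1))
        assert truth.planted_enrichments == ()
        assert truth.planted_proteins == {}

    def test_planted_architecture_satisfies_rule(self):
        records, totals, truth = simulate_domain_annotations(
            SimAnnotationParams(
                n_genomes=2, n_domains=10, baseline_lambda=2, totals=100,
                planted_architectures=(
                    PlantedArchitecture("G1", "WC1", 2),
                    PlantedArchitecture("G2", "RID_CANDIDATE", 1)),
                seed=5))
        table = classify_genome_candidates(records, RULESETS["all"])
        assert set(table["G1"]["WC1"]) == set(
            truth.planted_proteins[("G1", "WC1")])
        assert set(table["G2"]["RID_CANDIDATE"]) == set(
            truth.planted_proteins[("G2", "RID_CANDIDATE")])
        # decoys match no label
        for genome, decoys in truth.decoy_proteins.items():
            matched = {pid for labels in table[genome].values()
                       for pid in labels}
            assert not matched & set(decoys)

    def test_same_seed_identical_tables(self):
        params = SimAnnotationParams(n_genomes=2, n_domains=20,
                                     baseline_lambda=3, totals=200, seed=8)
        r1, t1, _ = simulate_domain_annotations(params)
        r2, t2, _ = simulate_domain_annotations(params)
        assert r1 == r2 and t1 == t2

    def test_count_matrix_matches_planted_lambda(self):
        matrix, truth = simulate_domain_count_matrix(SimAnnotationParams(
            n_genomes=4, n_domains=300, baseline_lambda=20, totals=5000,
            planted_enrichments=(PlantedEnrichment("SYN00000", "G1", 8.0),),
            seed=11))
        planted = matrix.count("G1", "SYN00000")
        baseline = np.median(matrix.counts)
        assert planted > 4 * baseline  # 8x Poisson mean well separated


class TestOgSim:
    def test_planted_classes_recovered_exactly(self):
        ogs, universe, _, truth = simulate_orthogroups(SimOgParams(
            n_core=20, shared_counts={("EMU", "EMA"): 5,
                                      ("EMU", "EMA", "ZRA"): 3},
            specific_counts={"EMU": 10, "NTH": 2},
            unassigned_counts={"EMU": 6}, seed=13))
        classes = classify_orthogroups(ogs, list(universe))
        assert {k: v.kind for k, v in classes.items()} == dict(
            truth.og_class)
        statuses = {(s.species, s.gene_id): s.status
                    for s in classify_genes(ogs, universe)}
        assert statuses == dict(truth.gene_class)

    def test_all_core_limit(self):
        ogs, universe, _, _ = simulate_orthogroups(SimOgParams(
            n_core=10, seed=1))
        classes = classify_orthogroups(ogs, list(universe))
        assert all(c.kind == "core" for c in classes.values())

    def test_p_zero_one_gives_empty_expression(self):
        _, _, expression, truth = simulate_orthogroups(SimOgParams(
            n_core=5, specific_counts={"EMU": 5}, p_zero_expression=1.0,
            seed=2))
        assert expression == []
        assert all(t == 0 for t in truth.gene_totals.values())

    def test_expression_totals_split_over_27_samples(self):
        _, _, expression, truth = simulate_orthogroups(SimOgParams(
            n_core=5, p_zero_expression=0.0, seed=4))
        by_gene = {}
        for rec in expression:
            by_gene.setdefault(rec.gene_id, []).append(rec.est_counts)
        for gene, counts in by_gene.items():
            assert len(counts) == 27
            assert sum(counts) == pytest.approx(truth.gene_totals[gene])


class TestReaderClosure:
    def test_outputs_parse_through_io_core(self, tmp_path):
        """Every simulator output round-trips through the readers."""
        seqs, _ = simulate_genome(SimGenomeParams(
            length_bp=5000, repeat_families=(RepeatFamily("r", 200, 3),),
            rip_rate=0.2, seed=6))
        fasta = tmp_path / "g.fasta"
        io_core.write_fasta(seqs, fasta)
        assert io_core.read_fasta(fasta) == seqs

        records, totals, _ = simulate_domain_annotations(
            SimAnnotationParams(n_genomes=2, n_domains=5,
                                baseline_lambda=2, totals=50,
                                planted_architectures=(
                                    PlantedArchitecture("G1", "AGO", 1),),
                                seed=6))
        ann = tmp_path / "ann.tsv"
        io_core.write_domain_annotations(records, ann)
        read_back = io_core.read_domain_annotations(ann)
        assert sorted(read_back, key=lambda r: (r.genome_id, r.protein_id,
                                                r.domain_accession)) == \
            sorted(records, key=lambda r: (r.genome_id, r.protein_id,
                                           r.domain_accession))

        ogs, universe, expression, _ = simulate_orthogroups(SimOgParams(
            n_core=4, specific_counts={"EMU": 2}, seed=6))
        ogp = tmp_path / "og.tsv"
        io_core.write_orthogroups(ogs, ogp)
        assert io_core.read_orthogroups(ogp) == ogs
        if expression:
            ep = tmp_path / "e.tsv"
            io_core.write_expression(expression, ep)
            assert io_core.read_expression(ep) == expression
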
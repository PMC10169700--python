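"""Generator contracts: determinism, capacity, planted structure."""

import numpy as np
import pytest

from florinet.promoters import PromoterWindowConfig, promoter_interval
from florinet.seqcodes import revcomp
from florinet.synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    generate_dataset,
    generate_genome_annotation,
    simulate_expression_matrix,
    simulate_reads,
)

SMALL = dict(
    n_chrom=1, chrom_len=40_000, n_genes=20, n_tfs=4, family_size=2,
    family_pool_size=4, n_true_edges=12,
)


class TestGenomeAnnotation:
    def test_contract_and_both_strands(self):
        cfg = SyntheticConfig(seed=1, **SMALL)
        genome, genes = generate_genome_annotation(cfg)
        assert len(genes) == 20 and len(genome) == 1
        assert {g.strand for g in genes} == {"+", "-"}
        # promoters never clipped, genes never overlapping
        window = PromoterWindowConfig()
        intervals = sorted((g.start, g.end) for g in genes)
        assert all(b0 <= a1 for (_, b0), (a1, _) in zip(intervals, intervals[1:]))
        for g in genes:
            lo, hi, clipped = promoter_interval(g, window, cfg.chrom_len)
            assert not clipped and hi - lo == 600

    def test_seeded_determinism_bytes(self):
        cfg = SyntheticConfig(seed=9, **SMALL)
        g1, a1 = generate_genome_annotation(cfg)
        g2, a2 = generate_genome_annotation(cfg)
        assert g1 == g2 and a1 == a2

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="cannot place|promoter clearance"):
            SyntheticConfig(n_genes=1000, n_chrom=1, chrom_len=20_000)


class TestMotifsAndSites:
    def test_max_information_motif_is_point_mass(self):
        cfg = SyntheticConfig(seed=2, motif_information_content=2.0, **SMALL)
        ds = generate_dataset(cfg)
        for m in ds.motifs:
            assert np.allclose(m.matrix.max(axis=1), 1.0)

    def test_planted_sites_inside_promoters_with_strand_contract(self):
        cfg = SyntheticConfig(seed=3, **SMALL)
        ds = generate_dataset(cfg)
        genes = {g.gene_id: g for g in ds.genes}
        chrom = {r.id: r.sequence for r in ds.genome}
        cons = {m.motif_id: m.consensus for m in ds.motifs}
        window = PromoterWindowConfig()
        assert ds.truth.planted_sites
        for gene_id, off, strand, motif_id in ds.truth.planted_sites:
            g = genes[gene_id]
            lo, hi, _ = promoter_interval(g, window, cfg.chrom_len)
            assert 0 <= off <= (hi - lo) - cfg.motif_width
            word = cons[motif_id] if strand == "+" else revcomp(cons[motif_id])
            if g.strand == "+":
                found = chrom[g.chrom][lo + off : lo + off + cfg.motif_width]
            else:
                found = revcomp(chrom[g.chrom][hi - off - cfg.motif_width : hi - off])
            assert found == word

    def test_every_true_edge_tf_has_a_motif(self, dataset):
        for tf, _target, _sign in dataset.truth.true_edges:
            assert tf in dataset.tf_map


class TestExpression:
    def test_dimensions_and_labels(self, dataset):
        cfg = dataset.config
        cm = dataset.counts
        assert cm.counts.shape == (cfg.n_genes, 3 * cfg.replicates_per_condition)
        assert set(cm.conditions) == {"C", "I", "F"}

    def test_noiseless_limit_gives_perfect_rank_correlation(self):
        """With Poisson noise made negligible, every always-coupled pair has
        Spearman rho exactly +/-1 across all samples."""
        from scipy import stats

        cfg = SyntheticConfig(
            seed=4, nb_dispersion=0.0, mean_expression=1e12, baseline_log2_sd=0.0, **SMALL
        )
        ds = generate_dataset(cfg)
        family = ds.truth.differential_family
        counts = ds.counts.counts
        for tf, target, sign in ds.truth.true_edges:
            if tf in family:
                continue  # decoupled in I by design
            rho = stats.spearmanr(counts.loc[tf], counts.loc[target]).statistic
            assert rho == pytest.approx(1.0 if sign == "+" else -1.0, abs=1e-12)

    def test_de_truth_magnitudes(self, dataset):
        lfc_min = np.log2(dataset.config.planted_fold_change) * 0.999
        for comp, table in dataset.truth.de_genes.items():
            assert all(abs(v) >= lfc_min for v in table.values())

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=11, **SMALL)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert a.counts.counts.equals(b.counts.counts)
        assert a.truth.true_edges == b.truth.true_edges


class TestReads:
    def test_total_bases_match_coverage(self):
        cfg = SyntheticConfig(seed=5, coverage=10.0, **SMALL)
        genome, _ = generate_genome_annotation(cfg)
        reads = simulate_reads(cfg, genome)
        total = sum(len(s) for _, s in reads)
        assert abs(total - 10.0 * cfg.chrom_len) < cfg.read_length

    def test_error_free_reads_are_substrings(self):
        cfg = SyntheticConfig(seed=6, coverage=0.5, error_rate=0.0, **SMALL)
        genome, _ = generate_genome_annotation(cfg)
        fwd = genome[0].sequence
        rc = revcomp(fwd)
        for _rid, seq in simulate_reads(cfg, genome)[:50]:
            assert seq in fwd or seq in rc

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=7, coverage=1.0, **SMALL)
        genome, _ = generate_genome_annotation(cfg)
        assert simulate_reads(cfg, genome) == simulate_reads(cfg, genome)

    def test_read_longer_than_chromosome_errors(self):
        cfg = SyntheticConfig(seed=8, read_length=150, **SMALL)
        genome, _ = generate_genome_annotation(cfg)
        short = [type(genome[0])("c", "ACGT" * 10)]
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(cfg, short)


class TestGroundTruthRoundTrip:
    def test_json_round_trip(self, dataset, tmp_path):
        p = tmp_path / "truth.json"
        dataset.truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.true_edges == dataset.truth.true_edges
        assert back.planted_sites == dataset.truth.planted_sites
        assert back.differential_family == dataset.truth.differential_family
        assert back.de_genes.keys() == dataset.truth.de_genes.keys()
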
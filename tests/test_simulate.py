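"""Generator ground truth: determinism, round trips, and statistical targets."""

import math

import numpy as np
import pytest

from canegbs.depth import prob_at_least_k
from canegbs.digest import PSTI, digest, find_cut_sites
from canegbs.simulate import (
    SimConfig,
    simulate_allele_reads,
    simulate_genome,
    simulate_genes,
    simulate_genotypes,
    simulate_region_counts,
    truth_records,
)
from canegbs.variants import DosageClass, classify_dosage


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimConfig(het_rate=1.2)
        with pytest.raises(ValueError):
            SimConfig(het_rate=0.1, sd_fraction=0.2)

    def test_unidentifiable_cnv_fold(self):
        with pytest.raises(ValueError):
            SimConfig(cnv_fraction=0.1, cnv_fold=1.0)

    def test_panel_defaults_cover_three_ploidies(self):
        cfg = SimConfig()
        assert sorted(set(cfg.ploidy.values())) == [6, 8, 12]
        assert len(cfg.ploidy) == 14


class TestGenome:
    def test_fixed_spacing_arithmetic(self):
        cfg = SimConfig(rng_seed=0, n_sequences=1, seq_length=1000,
                        site_spacing="fixed", spacing_mean=100.0)
        genome, sites = simulate_genome(cfg)
        assert len(sites["chr1"]) == 9
        frags = digest(genome, PSTI)
        assert len(frags) == 10

    def test_digest_recovers_exactly_planted_sites(self, small_genome):
        genome, sites = small_genome
        for seq_id, seq in genome.items():
            found = find_cut_sites(seq, PSTI)
            assert found == [p + PSTI.cut_offset for p in sites[seq_id]]

    def test_same_seed_identical_output(self, small_config):
        g1, s1 = simulate_genome(small_config)
        g2, s2 = simulate_genome(small_config)
        assert g1 == g2 and s1 == s2

    def test_too_tight_spacing_rejected(self):
        cfg = SimConfig(n_sequences=1, seq_length=100, spacing_mean=4.0)
        with pytest.raises(ValueError):
            simulate_genome(cfg)


class TestGenes:
    def test_genes_nonoverlapping_within_sequence(self, small_config,
                                                  small_genome):
        genome, _ = small_genome
        genes = simulate_genes(small_config, genome)
        by_seq = {}
        for g in genes:
            by_seq.setdefault(g.seq_id, []).append(g)
        for gl in by_seq.values():
            gl.sort(key=lambda g: g.start)
            for a, b in zip(gl[:-1], gl[1:]):
                assert a.end <= b.start


class TestGenotypes:
    def test_het_rate_zero_all_homozygous(self):
        cfg = SimConfig(rng_seed=1, n_loci=200, het_rate=0.0,
                        sd_fraction=0.0, multi_allelic_fraction=0.0)
        truth = simulate_genotypes(cfg)
        for rec in truth_records(truth):
            for g in rec.genotypes.values():
                assert classify_dosage(g).dosage_class is DosageClass.HOMOZYGOUS

    def test_all_single_dose(self):
        cfg = SimConfig(rng_seed=1, n_loci=200, het_rate=1.0,
                        sd_fraction=1.0, multi_allelic_fraction=0.0)
        truth = simulate_genotypes(cfg)
        for rec in truth_records(truth):
            for g in rec.genotypes.values():
                assert classify_dosage(g).dosage_class is DosageClass.SINGLE_DOSE

    def test_dosages_sum_to_ploidy(self, small_truth):
        for rec in truth_records(small_truth):
            for sample, g in rec.genotypes.items():
                assert sum(g.dosage.values()) == small_truth.ploidy[sample]

    def test_ref_matches_genome_base(self, small_truth, small_genome):
        genome, _ = small_genome
        for locus in small_truth.loci[:50]:
            assert genome[locus.seq_id][locus.pos - 1] == locus.ref

    def test_category_rates_within_binomial_noise(self):
        cfg = SimConfig(rng_seed=31, n_loci=10_000, het_rate=0.4,
                        sd_fraction=0.25, multi_allelic_fraction=0.05,
                        ploidy={"acc": 8}, depth_per_dose={"acc": 6.0})
        truth = simulate_genotypes(cfg)
        n = len(truth.loci)
        counts = {c: 0 for c in DosageClass}
        for rec in truth_records(truth):
            counts[classify_dosage(rec.genotypes["acc"]).dosage_class] += 1
        for cls, p in [
            (DosageClass.SINGLE_DOSE, 0.25),
            (DosageClass.MULTI_ALLELIC, 0.05),
            (DosageClass.HOMOZYGOUS, 0.6),
        ]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[cls] / n - p) <= 3 * se, cls


class TestAlleleReads:
    def test_homozygous_reads_all_reference(self, small_truth):
        for rec in truth_records(small_truth):
            for g in rec.genotypes.values():
                if len([a for a, c in g.dosage.items() if c]) == 1:
                    (allele,) = g.dosage
                    assert g.allele_depths.get(allele, 0) == g.total_depth

    def test_allele_depths_sum_to_total(self, small_truth):
        for rec in truth_records(small_truth):
            for g in rec.genotypes.values():
                assert sum(g.allele_depths.values()) == g.total_depth

    def test_minor_read_fraction_matches_binomial_model(self):
        """Single-dose loci at ploidy 12, fixed depth 56: P(>=2 minor reads)
        within 3 se of the binomial tail — the module-coupling check."""
        n_loci = 10_000
        cfg = SimConfig(
            rng_seed=101, n_loci=n_loci, het_rate=1.0, sd_fraction=1.0,
            multi_allelic_fraction=0.0,
            ploidy={"hyb": 12}, depth_per_dose={"hyb": 56 / 12},
        )
        truth = simulate_genotypes(cfg)
        simulate_allele_reads(truth, cfg, fixed_depth=56)
        hits = 0
        for rec in truth_records(truth):
            g = rec.genotypes["hyb"]
            minor = min(g.dosage, key=lambda a: (g.dosage[a], a))
            if g.allele_depths.get(minor, 0) >= 2:
                hits += 1
        p = prob_at_least_k(56, 1 / 12, 2)
        se = math.sqrt(p * (1 - p) / n_loci)
        assert abs(hits / n_loci - p) <= 3 * se

    def test_mean_minor_depth_single_dose(self):
        cfg = SimConfig(rng_seed=7, n_loci=4000, het_rate=1.0, sd_fraction=1.0,
                        multi_allelic_fraction=0.0,
                        ploidy={"acc": 8}, depth_per_dose={"acc": 6.0})
        truth = simulate_genotypes(cfg)
        simulate_allele_reads(truth, cfg, fixed_depth=48)
        minors = []
        for rec in truth_records(truth):
            g = rec.genotypes["acc"]
            minor = min(g.dosage, key=lambda a: (g.dosage[a], a))
            minors.append(g.allele_depths.get(minor, 0))
        assert np.mean(minors) == pytest.approx(48 / 8, rel=0.05)


class TestRegionCounts:
    def test_column_sums_scale_with_totals(self):
        totals = {"a": 1_000_000, "b": 4_000_000}
        cfg = SimConfig(rng_seed=3, n_regions=2000, pav_fraction=0.0,
                        cnv_fraction=0.0, totals=totals,
                        region_background_mean=100.0)
        m, _ = simulate_region_counts(cfg)
        ratio = m.counts["b"].sum() / m.counts["a"].sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_null_has_effectively_no_zeros(self):
        cfg = SimConfig(rng_seed=4, n_regions=1000, pav_fraction=0.0,
                        cnv_fraction=0.0, region_background_mean=60.0,
                        totals={f"a{i}": 2_000_000 for i in range(4)})
        m, truth = simulate_region_counts(cfg)
        assert (truth.cls == "normal").all()
        assert int((m.counts == 0).sum().sum()) == 0

    def test_truth_classes_materialized(self):
        cfg = SimConfig(rng_seed=6, n_regions=800, pav_fraction=0.15,
                        cnv_fraction=0.05,
                        totals={f"a{i}": 2_000_000 for i in range(4)})
        m, truth = simulate_region_counts(cfg)
        pav_rows = truth[truth.cls == "pav"]
        assert len(pav_rows) > 0
        for row in pav_rows.itertuples():
            for acc in row.affected.split(","):
                assert m.counts.loc[row.region_id, acc] == 0

    def test_determinism(self):
        cfg = SimConfig(rng_seed=12, n_regions=100,
                        totals={"a": 10**6, "b": 10**6})
        m1, t1 = simulate_region_counts(cfg)
        m2, t2 = simulate_region_counts(cfg)
        assert (m1.counts == m2.counts).all().all()
        assert t1.equals(t2)


class TestFileByteDeterminism:
    def test_fasta_bytes_identical(self, small_config, tmp_path):
        from canegbs.simulate import write_genome

        for i in (1, 2):
            genome, sites = simulate_genome(small_config)
            write_genome(genome, sites, tmp_path / f"g{i}.fasta",
                         tmp_path / f"s{i}.bed")
        assert (tmp_path / "g1.fasta").read_bytes() == \
               (tmp_path / "g2.fasta").read_bytes()
        assert (tmp_path / "s1.bed").read_bytes() == \
               (tmp_path / "s2.bed").read_bytes()
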
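"""Dosage classification, caller concordance, depth filtering, Ts/Tv."""

import math

import numpy as np
import pytest

from canegbs.digest import GeneInterval
from canegbs.simulate import (
    SimConfig,
    emit_caller_vcfs,
    simulate_allele_reads,
    simulate_genotypes,
    truth_records,
)
from canegbs.variants import (
    Dosage,
    DosageClass,
    DosageGenotype,
    SnpKey,
    SnpRecord,
    annotate_genic,
    classify_dosage,
    concordance,
    depth_filter,
    load_caller_vcf,
    sample_summary,
    tstv,
)


def _g(sample, ploidy, dosage, depth=50):
    return DosageGenotype(sample_id=sample, ploidy=ploidy, dosage=dosage,
                          total_depth=depth)


class TestClassifyDosage:
    def test_single_dose(self):
        d = classify_dosage(_g("s", 8, {"A": 7, "C": 1}))
        assert d.dosage_class is DosageClass.SINGLE_DOSE
        assert (d.minor_allele, d.major_allele) == ("C", "A")

    def test_multi_dose_with_tie(self):
        d = classify_dosage(_g("s", 6, {"A": 3, "G": 3}))
        assert d.dosage_class is DosageClass.MULTI_DOSE
        assert d.minor_allele == "A"  # lexicographic tie-break

    def test_multi_allelic(self):
        d = classify_dosage(_g("s", 12, {"A": 9, "C": 2, "T": 1}))
        assert d.dosage_class is DosageClass.MULTI_ALLELIC

    def test_homozygous(self):
        d = classify_dosage(_g("s", 6, {"A": 6}))
        assert d.dosage_class is DosageClass.HOMOZYGOUS
        assert not d.is_heterozygous

    def test_dosage_sum_enforced(self):
        with pytest.raises(ValueError):
            DosageGenotype("s", 6, {"A": 3, "C": 1})

    def test_classes_exclusive_exhaustive(self):
        """Every valid two-or-fewer-allele split lands in exactly one class."""
        p = 8
        for c1 in range(0, p + 1):
            dosage = {"A": c1, "C": p - c1}
            dosage = {a: c for a, c in dosage.items() if c}
            d = classify_dosage(_g("s", p, dosage))
            if len(dosage) == 1:
                assert d.dosage_class is DosageClass.HOMOZYGOUS
            elif min(dosage.values()) == 1:
                assert d.dosage_class is DosageClass.SINGLE_DOSE
            else:
                assert d.dosage_class is DosageClass.MULTI_DOSE


class TestConcordance:
    def test_two_caller_example(self):
        res = concordance({"a": {1, 2, 3}, "b": {2, 3, 4}})
        assert res.cells[frozenset({"a", "b"})] == 2
        assert res.union_size == 4
        assert res.cells[frozenset({"a"})] == 1
        assert res.cells[frozenset({"b"})] == 1

    def test_identical_callsets_all_in_full_cell(self):
        keys = set(range(10))
        res = concordance({c: keys for c in "abc"})
        assert res.concordant_all == 10
        assert all(res.per_caller_pct_concordant[c] == 100.0 for c in "abc")

    def test_five_random_callsets_match_bruteforce(self):
        rng = np.random.default_rng(17)
        universe = list(range(2000))
        sets = {
            f"c{i}": {k for k in universe if rng.random() < p}
            for i, p in enumerate([0.76, 0.60, 0.31, 0.31, 0.22])
        }
        res = concordance(sets)
        callers = sorted(sets)
        # brute-force membership-pattern tally
        tally = {}
        for k in set().union(*sets.values()):
            pat = frozenset(c for c in callers if k in sets[c])
            tally[pat] = tally.get(pat, 0) + 1
        for pat, n in tally.items():
            assert res.cells[pat] == n
        assert sum(res.cells.values()) == res.union_size

    def test_cells_partition_union(self):
        rng = np.random.default_rng(23)
        sets = {f"c{i}": set(rng.integers(0, 500, 200).tolist())
                for i in range(4)}
        res = concordance(sets)
        assert sum(res.cells.values()) == res.union_size

    def test_needs_two_callsets(self):
        with pytest.raises(ValueError):
            concordance({"a": {1}})


def _record(seq_id, pos, ref, alt, depths, ploidy=6, alt_dose=1):
    genotypes = {}
    for i, d in enumerate(depths):
        sample = f"s{i}"
        if d is None:
            genotypes[sample] = None
        else:
            genotypes[sample] = DosageGenotype(
                sample, ploidy, {ref: ploidy - alt_dose, alt: alt_dose},
                total_depth=d,
            )
    return SnpRecord(SnpKey(seq_id, pos, ref, frozenset({alt})), genotypes)


class TestDepthFilter:
    def test_all_scope(self):
        keep = _record("c", 1, "A", "G", (40, 36))
        drop = _record("c", 2, "A", "G", (40, 34))
        assert depth_filter([keep, drop], 35) == [keep]

    def test_any_scope(self):
        rec = _record("c", 2, "A", "G", (40, 34))
        assert depth_filter([rec], 35, scope="any") == [rec]

    def test_zero_threshold_is_identity(self):
        recs = [_record("c", i, "A", "G", (10, 20)) for i in range(5)]
        assert depth_filter(recs, 0) == recs

    def test_antitone_nested_survivors(self):
        rng = np.random.default_rng(1)
        recs = [
            _record("c", i, "A", "G", tuple(rng.integers(0, 80, 3)))
            for i in range(100)
        ]
        prev = None
        for t in (0, 20, 40, 60):
            cur = {r.key.pos for r in depth_filter(recs, t)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        depths = rng.integers(0, 80, size=(200, 4))
        recs = [_record("c", i, "A", "G", tuple(row))
                for i, row in enumerate(depths)]
        survivors = depth_filter(recs, 35)
        assert len(survivors) == int((depths >= 35).all(axis=1).sum())

    def test_missing_ignored_by_rule(self):
        rec = _record("c", 1, "A", "G", (40, None))
        assert depth_filter([rec], 35) == [rec]


class TestSampleSummary:
    def test_heterozygosity_fraction(self):
        recs = []
        for i in range(10):
            dosage = {"A": 5, "G": 1} if i < 3 else {"A": 6}
            recs.append(
                SnpRecord(
                    SnpKey("c", i + 1, "A", frozenset({"G"})),
                    {"s": DosageGenotype("s", 6, dosage, 50)},
                )
            )
        s = sample_summary(recs, "s")
        assert s.heterozygosity_pct == 30.0
        assert s.sd_pct == 30.0  # the het loci here are all single dose

    def test_all_homozygous(self):
        recs = [
            SnpRecord(SnpKey("c", i + 1, "A", frozenset({"G"})),
                      {"s": DosageGenotype("s", 6, {"A": 6}, 50)})
            for i in range(4)
        ]
        s = sample_summary(recs, "s")
        assert (s.sd_pct, s.multi_allelic_pct) == (0.0, 0.0)

    def test_sd_fraction_recovered_at_scale(self):
        """Genotypes drawn with SD probability 0.5: sd_pct within 3 se of 50%."""
        cfg = SimConfig(
            rng_seed=13, n_loci=10_000, het_rate=1.0, sd_fraction=0.5,
            multi_allelic_fraction=0.0,
            ploidy={"acc": 8}, depth_per_dose={"acc": 6.0},
        )
        truth = simulate_genotypes(cfg)
        s = sample_summary(truth_records(truth), "acc")
        se = 100 * math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(s.sd_pct - 50.0) <= 3 * se

    def test_no_loci_errors(self):
        with pytest.raises(ValueError):
            sample_summary([], "s")


class TestTsTv:
    def test_balanced_pairs(self):
        recs = [
            _record("c", 1, "A", "G", (50,)),
            _record("c", 2, "C", "T", (50,)),
            _record("c", 3, "A", "C", (50,)),
            _record("c", 4, "G", "T", (50,)),
        ]
        assert tstv(recs) == 1.0

    def test_zero_transversions_is_inf(self):
        recs = [_record("c", 1, "A", "G", (50,)),
                _record("c", 2, "A", "G", (50,))]
        assert math.isinf(tstv(recs))

    def test_per_sample_conditioned_on_alt_carriage(self):
        ts_site = _record("c", 1, "A", "G", (50,))  # s0 carries alt
        tv_site = SnpRecord(
            SnpKey("c", 2, "A", frozenset({"C"})),
            {"s0": DosageGenotype("s0", 6, {"A": 6}, 50)},  # hom ref
        )
        assert math.isinf(tstv([ts_site, tv_site], "s0"))

    def test_generated_ts_fraction_recovered(self):
        """Sites drawn with ts probability 0.624 -> ratio near 1.66."""
        cfg = SimConfig(
            rng_seed=29, n_loci=50_000, ts_fraction=1.66 / 2.66,
            ploidy={"acc": 6}, depth_per_dose={"acc": 6.0},
            het_rate=1.0, sd_fraction=1.0, multi_allelic_fraction=0.0,
        )
        truth = simulate_genotypes(cfg)
        ratio = tstv(truth_records(truth), "acc")
        p = 1.66 / 2.66
        se = math.sqrt(p * (1 - p) / 50_000)
        lo, hi = p - 3 * se, p + 3 * se
        assert lo / (1 - lo) <= ratio <= hi / (1 - hi)


class TestAnnotateGenic:
    def test_coordinate_conversion(self):
        # 1-based pos 19 occupies the 0-based point interval [18, 19)
        rec = _record("c", 19, "A", "G", (50,))
        flags, _ = annotate_genic([rec], [GeneInterval("c", 10, 18)])
        assert flags == [False]  # gene ends just before the variant base
        flags, _ = annotate_genic([rec], [GeneInterval("c", 10, 19)])
        assert flags == [True]  # gene's last base is the variant base
        flags, _ = annotate_genic([rec], [GeneInterval("c", 19, 30)])
        assert flags == [False]  # gene starts just after it

    def test_empty_gene_set(self):
        rec = _record("c", 5, "A", "G", (50,))
        flags, pct = annotate_genic([rec], [])
        assert flags == [False] and pct == 0.0


@pytest.fixture(scope="module")
def emitted(tmp_path_factory):
    cfg = SimConfig(rng_seed=77, n_loci=500,
                    n_callers=3, caller_sensitivity=(0.9, 0.6, 0.3))
    truth = simulate_genotypes(cfg)
    simulate_allele_reads(truth, cfg)
    out = tmp_path_factory.mktemp("vcf")
    paths, truth_path, fp = emit_caller_vcfs(truth, cfg, out)
    return cfg, truth, paths, truth_path, fp


class TestVcfRoundTrip:
    def test_parsed_dosages_equal_generator_truth(self, emitted):
        cfg, truth, _, truth_path, _ = emitted
        records = load_caller_vcf(truth_path, "truth",
                                  ploidy_map=truth.ploidy)
        assert len(records) == len(truth.loci)
        by_pos = {(l.seq_id, l.pos): l for l in truth.loci}
        for key, rec in records.items():
            locus = by_pos[(key.seq_id, key.pos)]
            for sample, g in rec.genotypes.items():
                expect = truth.genotypes[locus.locus_id][sample]
                assert g is not None
                assert g.dosage == expect.dosage
                assert g.total_depth == expect.total_depth
                assert g.allele_depths == expect.allele_depths

    def test_statistics_match_truth_exactly(self, emitted):
        """Het/SD/multi-allelic/TsTv from the VCF equal truth-table values."""
        cfg, truth, _, truth_path, _ = emitted
        vcf_records = list(load_caller_vcf(truth_path, "truth").values())
        direct = truth_records(truth)
        for sample in truth.ploidy:
            a = sample_summary(vcf_records, sample)
            b = sample_summary(direct, sample)
            assert (a.heterozygosity_pct, a.sd_pct,
                    a.multi_allelic_pct) == (b.heterozygosity_pct, b.sd_pct,
                                             b.multi_allelic_pct)
            assert a.tstv == b.tstv

    def test_caller_sizes_track_sensitivity(self, emitted):
        cfg, truth, paths, _, fp = emitted
        n = len(truth.loci)
        n_fp = int(round(cfg.caller_fp_fraction * n))
        for i, (caller, path) in enumerate(sorted(paths.items())):
            calls = load_caller_vcf(path, caller)
            s = cfg.caller_sensitivity[i]
            se = math.sqrt(n * s * (1 - s))
            assert abs((len(calls) - n_fp) - s * n) <= 3 * se

    def test_missing_genotype_parsed_as_none(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="D">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "c\t5\t.\tA\tG\t.\tPASS\t.\tGT:DP\t./.:10\t0/0/0/0/0/1:20\n"
        )
        records = load_caller_vcf(vcf, "x")
        (rec,) = records.values()
        assert rec.genotypes["s1"] is None
        assert rec.genotypes["s2"].dosage == {"A": 5, "G": 1}
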
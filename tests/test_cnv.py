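"""CNV parsing, reciprocal-overlap clustering, the filter cascade and
burden testing, each checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from seednet.cnv import (
    BedInterval,
    CnvCall,
    FilterThresholds,
    burden_test,
    cluster_calls,
    control_frequency,
    filter_calls,
    gene_carriers,
    read_bed,
    read_calls,
    segdup_overlap_fraction,
)

CHROMS = {"chr1": 100_000_000, "chr2": 80_000_000}


def _call(sample, cohort, start, end, chrom="chr1", cnv_type="deletion", zyg="heterozygous"):
    return CnvCall(sample, cohort, chrom, start, end, cnv_type, zyg)


class TestIO:
    def test_bed_half_open(self, tmp_path):
        p = tmp_path / "segdup.bed"
        p.write_text("chr1\t100\t300\tSEGDUP1\n")
        ivs = read_bed(p)
        assert ivs[0].length == 200

    def test_bed_sorted(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t500\t900\tB\nchr1\t100\t300\tA\n")
        ivs = read_bed(p)
        assert [iv.name for iv in ivs] == ["A", "B"]

    def test_inverted_interval_names_line(self, tmp_path):
        p = tmp_path / "calls.tsv"
        header = "sample_id\tcohort\tchrom\tstart\tend\ttype\tzygosity"
        rows = [f"s{i}\tcase\tchr1\t{1000 * i}\t{1000 * i + 500}\tdeletion\theterozygous"
                for i in range(1, 10)]
        rows[5] = "s6\tcase\tchr1\t9000\t8000\tdeletion\theterozygous"  # line 7
        p.write_text("\n".join([header] + rows) + "\n")
        with pytest.raises(ValueError, match="line 7"):
            read_calls(p)

    def test_unknown_cohort_token(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text("sample_id\tcohort\tchrom\tstart\tend\ttype\tzygosity\n"
                     "s1\tpatient\tchr1\t0\t500\tdeletion\theterozygous\n")
        with pytest.raises(ValueError, match="cohort"):
            read_calls(p)

    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text("sample_id\tcohort\tchrom\tstart\tend\ttype\tzygosity\n"
                     "s1\tcase\tchr1\t1\t500\tdeletion\theterozygous\n")
        c = read_calls(p, one_based=True)[0]
        assert (c.start, c.end) == (0, 500)


class TestClustering:
    def test_identical_intervals_cluster(self):
        calls = [_call(f"c{i}", "control", 1_000_000, 1_500_000) for i in range(10)]
        freqs = control_frequency(calls, control_n=8329)
        assert np.allclose(freqs, 10 / 8329)

    def test_single_control_carrier_is_rare(self):
        calls = [_call("case1", "case", 1_000_000, 1_400_000),
                 _call("ctrl1", "control", 1_000_000, 1_400_000)]
        freqs = control_frequency(calls, control_n=8329)
        assert freqs[0] == pytest.approx(1 / 8329)
        assert freqs[0] < 0.001

    def test_case_without_control_cluster_is_zero(self):
        calls = [_call("case1", "case", 1_000_000, 1_400_000),
                 _call("ctrl1", "control", 50_000_000, 50_400_000)]
        freqs = control_frequency(calls, control_n=100)
        assert freqs[0] == 0.0

    def test_types_do_not_cluster_together(self):
        calls = [_call("a", "control", 0, 1000, cnv_type="deletion"),
                 _call("b", "control", 0, 1000, cnv_type="duplication")]
        assert len(set(cluster_calls(calls))) == 2

    def test_single_linkage_chain(self):
        # a-b overlap 50%, b-c overlap 50%, a-c only ~33%: one cluster by chaining
        calls = [_call("a", "control", 0, 1000),
                 _call("b", "control", 500, 1500),
                 _call("c", "control", 1000, 2000)]
        labels = cluster_calls(calls, recip_overlap=0.5)
        assert len(set(labels)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_closure(self, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(120):
            start = int(rng.integers(0, 5_000_000))
            size = int(rng.integers(100_000, 2_000_000))
            cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
            cohort = "control" if rng.random() < 0.6 else "case"
            calls.append(_call(f"s{i}", cohort, start, start + size, cnv_type=cnv_type))
        labels = cluster_calls(calls, recip_overlap=0.5)

        # O(n^2) union-find oracle over all pairs
        parent = list(range(len(calls)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(calls)), 2):
            ci, cj = calls[i], calls[j]
            if ci.chrom != cj.chrom or ci.cnv_type != cj.cnv_type:
                continue
            inter = min(ci.end, cj.end) - max(ci.start, cj.start)
            if inter >= 0.5 * max(ci.length, cj.length):
                parent[find(j)] = find(i)
        oracle = [find(i) for i in range(len(calls))]
        for i, j in itertools.combinations(range(len(calls)), 2):
            assert (labels[i] == labels[j]) == (oracle[i] == oracle[j])

    def test_zero_controls_error(self):
        with pytest.raises(ValueError):
            control_frequency([_call("a", "case", 0, 1000)], control_n=0)


class TestFilterCascade:
    def test_size_rule(self):
        calls = [_call("s1", "case", 1_000_000, 1_250_000)]  # 250 kb
        surv, audit = filter_calls(calls, [], CHROMS, control_n=100)
        assert surv == [] and audit["failed_rule"].tolist() == ["size"]

    def test_segdup_rule_with_merging(self):
        # 400 kb call with two abutting segdups totalling 240 kb (60%)
        calls = [_call("s1", "case", 1_000_000, 1_400_000)]
        segdups = [BedInterval("chr1", 1_000_000, 1_120_000, "SD1"),
                   BedInterval("chr1", 1_100_000, 1_240_000, "SD2")]
        frac = segdup_overlap_fraction(calls[0], {"chr1": [(1_000_000, 1_240_000)]})
        assert frac == pytest.approx(0.6)
        surv, audit = filter_calls(calls, segdups, CHROMS, control_n=100)
        assert audit["failed_rule"].tolist() == ["segdup_overlap"]

    def test_whole_chromosome_rule_first(self):
        calls = [_call("s1", "case", 0, 95_000_000, zyg="unknown")]
        surv, audit = filter_calls(calls, [], CHROMS, control_n=100)
        assert audit["failed_rule"].tolist() == ["whole_chromosome"]

    def test_non_heterozygous_excluded(self):
        calls = [_call("s1", "case", 1_000_000, 1_400_000, zyg="homozygous")]
        _, audit = filter_calls(calls, [], CHROMS, control_n=100)
        assert audit["failed_rule"].tolist() == ["not_interstitial_heterozygous"]

    def test_common_call_removed(self):
        calls = [_call(f"ctrl{i}", "control", 1_000_000, 1_400_000) for i in range(10)]
        calls.append(_call("case1", "case", 1_000_000, 1_400_000))
        surv, audit = filter_calls(calls, [], CHROMS, control_n=8329)
        # 10/8329 = 0.0012 >= 0.001: the whole cluster fails, case call included
        assert surv == []
        assert set(audit["failed_rule"]) == {"control_frequency"}

    def test_contractive_and_order_stable(self):
        rng = np.random.default_rng(5)
        calls = []
        for i in range(60):
            start = int(rng.integers(0, 50_000_000))
            size = int(rng.integers(100_000, 3_000_000))
            zyg = "heterozygous" if rng.random() < 0.9 else "unknown"
            cohort = "case" if rng.random() < 0.5 else "control"
            calls.append(_call(f"s{i}", cohort, start, start + size, zyg=zyg))
        surv1, audit1 = filter_calls(calls, [], CHROMS, control_n=500)
        perm = list(rng.permutation(len(calls)))
        surv2, _ = filter_calls([calls[i] for i in perm], [], CHROMS, control_n=500)
        assert set((c.sample_id, c.start) for c in surv1) == \
               set((c.sample_id, c.start) for c in surv2)
        assert set((c.sample_id, c.start) for c in surv1) <= \
               set((c.sample_id, c.start) for c in calls)
        # every removed call audited exactly once
        assert len(audit1) + len(surv1) == len(calls)

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(11)
        calls = []
        for i in range(80):
            start = int(rng.integers(0, 50_000_000))
            size = int(rng.integers(200_000, 2_000_000))
            cohort = "case" if rng.random() < 0.5 else "control"
            calls.append(_call(f"s{i % 40}", cohort, start, start + size))
        segdups = [BedInterval("chr1", 10_000_000, 11_000_000, "SD")]
        base = FilterThresholds()
        n_base = len(filter_calls(calls, segdups, CHROMS, base, control_n=200)[0])
        tighter = [
            FilterThresholds(min_size_bp=600_000),
            FilterThresholds(max_segdup_overlap=0.1),
            FilterThresholds(max_control_freq=0.0005),
            FilterThresholds(whole_chrom_span_frac=0.01),
        ]
        for th in tighter:
            assert len(filter_calls(calls, segdups, CHROMS, th, control_n=200)[0]) <= n_base


class TestGeneCarriers:
    GENES = [BedInterval("chr1", 1999, 3000, "G1"), BedInterval("chr1", 2000, 3000, "G2")]

    def test_one_bp_overlap_is_carrier(self):
        calls = [_call("s1", "case", 1000, 2000)]
        carriers = gene_carriers(calls, self.GENES)
        assert carriers["G1"]["case"] == {"s1"}

    def test_half_open_adjacency_is_not(self):
        calls = [_call("s1", "case", 1000, 2000)]
        carriers = gene_carriers(calls, self.GENES)
        assert carriers["G2"]["case"] == set()

    def test_sample_counts_once_per_gene(self):
        calls = [_call("s1", "case", 1000, 2500), _call("s1", "case", 1500, 2600)]
        carriers = gene_carriers(calls, self.GENES)
        assert carriers["G1"]["case"] == {"s1"}

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        genes = [BedInterval("chr1", int(s), int(s) + 50_000, f"G{i}")
                 for i, s in enumerate(rng.integers(0, 20_000_000, 15))]
        calls = []
        for i in range(300):
            start = int(rng.integers(0, 20_000_000))
            size = int(rng.integers(10_000, 1_000_000))
            cohort = "case" if rng.random() < 0.5 else "control"
            calls.append(_call(f"s{i % 100}", cohort, start, start + size))
        carriers = gene_carriers(calls, genes)
        for g in genes:
            for cohort in ("case", "control"):
                expected = {
                    c.sample_id for c in calls
                    if c.cohort == cohort
                    and min(c.end, g.end) - max(c.start, g.start) >= 1
                }
                assert carriers[g.name][cohort] == expected


class TestBurden:
    def test_hypergeometric_upper_tail(self):
        carriers = {"G1": {"case": {f"c{i}" for i in range(10)},
                           "control": {f"k{i}" for i in range(2)}}}
        per_gene, _ = burden_test(carriers, 5000, 8329, ["G1"])
        expected = sps.fisher_exact([[10, 4990], [2, 8327]], alternative="greater")[1]
        assert per_gene["G1"].test.p_value == pytest.approx(expected, rel=1e-9)

    def test_zero_carriers_p_one(self):
        carriers = {"G1": {"case": set(), "control": set()}}
        per_gene, combined = burden_test(carriers, 100, 100, ["G1"])
        assert per_gene["G1"].test.p_value == 1.0
        assert combined.test.p_value == 1.0

    def test_combined_counts_sample_once(self):
        carriers = {
            "G1": {"case": {"s1", "s2"}, "control": set()},
            "G2": {"case": {"s2", "s3"}, "control": {"k1"}},
        }
        _, combined = burden_test(carriers, 100, 100, ["G1", "G2"])
        assert combined.case_carriers == 3  # s1, s2, s3
        assert combined.case_carriers <= 2 + 2

    def test_per_gene_coverage_denominators(self):
        carriers = {"G1": {"case": {"s1"}, "control": set()},
                    "G2": {"case": {"s2"}, "control": set()}}
        per_gene, _ = burden_test(carriers, {"G1": 8300, "G2": 58120}, 8329, ["G1", "G2"])
        assert per_gene["G1"].case_n == 8300
        assert per_gene["G2"].case_n == 58120

    def test_carrier_exceeding_denominator_is_error(self):
        carriers = {"G1": {"case": {"s1", "s2"}, "control": set()}}
        with pytest.raises(ValueError):
            burden_test(carriers, 1, 100, ["G1"])
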
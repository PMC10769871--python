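"""Host subtraction, read mapping, CPM presence calls, prevalence testing."""

import numpy as np
import pytest
from helpers import chisq_2x2_oracle

from bilrscreen import profiler, synthetic
from bilrscreen.profiler import SampleProfile
from bilrscreen.reads import ReadSet


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_reads(seqs):
    return ReadSet.from_triples(
        [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]
    )


class TestSubtractHost:
    def test_verbatim_host_read_removed(self):
        rng = np.random.default_rng(0)
        host = random_dna(rng, 2000)
        reads = make_reads([host[100:200], random_dna(rng, 100)])
        kept = profiler.subtract_host(reads, host)
        assert kept.ids == ["r1"]

    def test_random_read_retained(self):
        rng = np.random.default_rng(1)
        host = random_dna(rng, 5000)
        reads = make_reads([random_dna(rng, 100) for _ in range(50)])
        assert len(profiler.subtract_host(reads, host, k=31)) == 50

    def test_reverse_complement_host_read_removed(self):
        rng = np.random.default_rng(2)
        host = random_dna(rng, 2000)
        frag = host[500:650]
        rc = frag[::-1].translate(str.maketrans("ACGT", "TGCA"))
        kept = profiler.subtract_host(make_reads([rc]), host)
        assert len(kept) == 0

    def test_fixture_host_fraction_recovered(self):
        """Error-free host reads are removed exactly; conservation holds."""
        fx = synthetic.generate_metagenome(3, 5000, [0, 0, 0], 0.2, 0.0, seed=4)
        for sid, reads, _, _ in fx.samples:
            kept = profiler.subtract_host(reads, fx.host_ref)
            removed = len(reads) - len(kept)
            expected = fx.truth_host_reads[sid]
            sd = np.sqrt(5000 * 0.2 * 0.8)
            assert abs(removed - expected) <= 3 * sd
            assert removed == expected  # deterministic composition, no errors

    def test_empty_host_rejected(self):
        with pytest.raises(ValueError):
            profiler.subtract_host(make_reads(["ACGT" * 10]), "")


class TestQcSample:
    @pytest.mark.parametrize("n,passes", [(999_999, False), (1_000_000, True), (0, False)])
    def test_million_read_floor(self, n, passes):
        class Counted:
            def __len__(self):
                return n

        assert profiler.qc_sample(Counted()) is passes


class TestMapReads:
    def test_exact_substring_maps(self):
        rng = np.random.default_rng(5)
        gene = random_dna(rng, 900)
        assert profiler.map_reads(make_reads([gene[100:250]]), [gene]) == 1

    def test_reverse_complement_maps(self):
        rng = np.random.default_rng(6)
        gene = random_dna(rng, 900)
        frag = gene[300:450]
        rc = frag[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert profiler.map_reads(make_reads([rc]), [gene]) == 1

    def test_unrelated_read_does_not_map(self):
        rng = np.random.default_rng(7)
        gene = random_dna(rng, 900)
        assert profiler.map_reads(make_reads([random_dna(rng, 150)]), [gene]) == 0

    def test_error_free_fixture_counts_exact(self):
        fx = synthetic.generate_metagenome(
            4, 5000, [0, 1e-3, 5e-3, 0.01], 0.1, 0.0, seed=8
        )
        for sid, reads, _, _ in fx.samples:
            kept = profiler.subtract_host(reads, fx.host_ref)
            assert profiler.map_reads(kept, fx.gene_refs) == fx.truth_gene_reads[sid]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            profiler.map_reads(make_reads(["ACGT" * 40]), [])


class TestCpmAndPresence:
    def test_cpm_arithmetic(self):
        assert profiler.compute_cpm(0, 1_000_000) == 0.0
        assert profiler.compute_cpm(5, 1_000_000) == 5.0
        assert profiler.compute_cpm(123, 2_345_678) == pytest.approx(
            123 / 2_345_678 * 1e6
        )

    def test_cpm_argument_errors(self):
        with pytest.raises(ValueError):
            profiler.compute_cpm(1, 0)
        with pytest.raises(ValueError):
            profiler.compute_cpm(5, 4)

    def test_presence_is_strict(self):
        # exactly five CPM is called absent
        assert profiler.call_presence(5.0) is False
        assert profiler.call_presence(5.01) is True
        assert profiler.call_presence(0.0) is False

    def test_presence_monotone_in_mapped(self):
        cpms = [profiler.compute_cpm(m, 10_000) for m in range(0, 200, 10)]
        calls = [profiler.call_presence(c) for c in cpms]
        assert calls == sorted(calls)


class TestBinByAge:
    def _sample(self, sid, age, present=True):
        return SampleProfile(
            sample_id=sid, total_reads=100, mapped_reads=10 if present else 0,
            cpm=1e5 if present else 0.0, present=present, qc_pass=True,
            cohort="infant", age_days=age,
        )

    def test_half_open_bins(self):
        bins = profiler.bin_by_age(
            [self._sample("a", 0), self._sample("b", 29), self._sample("c", 30)]
        )
        assert bins[0][0] == 2 and bins[1][0] == 1

    def test_missing_age_excluded(self):
        bins = profiler.bin_by_age([self._sample("a", None), self._sample("b", 10)])
        assert sum(n for n, _, _ in bins.values()) == 1

    def test_beyond_range_excluded(self):
        assert profiler.bin_by_age([self._sample("a", 400)]) == {}

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            profiler.bin_by_age([self._sample("a", -1)])

    def test_absence_percentage(self):
        bins = profiler.bin_by_age(
            [self._sample("a", 5, present=False), self._sample("b", 8, present=True)]
        )
        assert bins[0] == (2, 1, 50.0)


class TestPrevalenceTest:
    # frozen from R 4.3.3 prop.test (x=(absent1, absent2), n=(n1, n2))
    R_ORACLE = [
        (5, 100, 10, 200, True, 0.0, 1.0),
        (5, 100, 10, 200, False, 0.0, 1.0),
        (10, 100, 30, 100, True, 11.28125, 0.000782938217891),
        (10, 100, 30, 100, False, 12.5, 0.000406952017445),
        (3, 50, 20, 60, True, 10.7237631184, 0.00105768346758),
        (3, 50, 20, 60, False, 12.321172747, 0.000447849240601),
        (0, 40, 20, 40, True, 24.0666666667, 9.30573029769e-07),
        (0, 40, 20, 40, False, 26.6666666667, 2.41756388112e-07),
        (7, 23, 11, 19, True, 2.18049199085, 0.139769774933),
        (7, 23, 11, 19, False, 3.20366132723, 0.073473612872),
    ]

    @pytest.mark.parametrize("x1,n1,x2,n2,corr,stat,p", R_ORACLE)
    def test_matches_r_prop_test(self, x1, n1, x2, n2, corr, stat, p):
        res = profiler.prevalence_test(x1, n1, x2, n2, continuity_correction=corr)
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n1, n2 = rng.integers(2, 500, size=2)
            x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
            for corr in (False, True):
                res = profiler.prevalence_test(
                    int(x1), int(n1), int(x2), int(n2), continuity_correction=corr
                )
                stat, p = chisq_2x2_oracle(int(x1), int(n1), int(x2), int(n2), corr)
                assert res.statistic == pytest.approx(stat, abs=1e-10)
                assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_symmetric_in_group_order(self):
        a = profiler.prevalence_test(10, 100, 30, 100)
        b = profiler.prevalence_test(30, 100, 10, 100)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            profiler.prevalence_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            profiler.prevalence_test(11, 10, 1, 10)


class TestCohortFilter:
    def _sample(self, sid, cohort, age=None):
        return SampleProfile(
            sample_id=sid, total_reads=100, mapped_reads=1, cpm=1e4,
            present=True, qc_pass=True, cohort=cohort, age_days=age,
        )

    def test_young_healthy_adult_excluded(self):
        groups, audit = profiler.cohort_filter(
            [self._sample("a", "healthy_adult", age=2 * 365)]
        )
        assert groups["healthy_adult"] == []
        assert audit["excluded_healthy_young"] == 1

    def test_ibd_split_into_cd_and_uc(self):
        groups, _ = profiler.cohort_filter(
            [self._sample("a", "ibd_uc"), self._sample("b", "ibd_cd")]
        )
        assert [s.sample_id for s in groups["UC"]] == ["a"]
        assert [s.sample_id for s in groups["CD"]] == ["b"]

    def test_infant_with_age_retained(self):
        groups, _ = profiler.cohort_filter([self._sample("a", "infant", age=20)])
        assert len(groups["infant"]) == 1

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError):
            profiler.cohort_filter([self._sample("a", "martian")])


class TestProfileSample:
    def test_conservation_and_consistency(self):
        fx = synthetic.generate_metagenome(1, 4000, [1e-3], 0.2, 0.005, seed=21)
        sid, reads, _, _ = fx.samples[0]
        p = profiler.profile_sample(
            sid, reads, fx.gene_refs, fx.host_ref, min_reads=1000
        )
        assert p.qc_pass
        assert 0 <= p.mapped_reads <= p.total_reads
        assert p.cpm == pytest.approx(p.mapped_reads / p.total_reads * 1e6)

    def test_qc_failure_blocks_presence(self):
        fx = synthetic.generate_metagenome(1, 500, [0.01], 0.0, 0.0, seed=22)
        sid, reads, _, _ = fx.samples[0]
        p = profiler.profile_sample(
            sid, reads, fx.gene_refs, fx.host_ref, min_reads=10_000
        )
        assert not p.qc_pass and not p.present
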
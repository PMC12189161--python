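"""Peak-caller tests, including the independent window-walk oracle.

The window-walk oracle lives in ``_oracles`` and is shared with the
acceptance suite.
"""
import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_window_walk

from ripsplice.core_io import GeneModel, GenomicInterval
from ripsplice.peaks import (
    CoverageProfile,
    EnrichedPeak,
    Peak,
    PeakCallerParams,
    assign_pvalues,
    build_coverage,
    call_targets,
    enrichment_filter,
    gene_baseline,
    permutation_pvalue,
    retain_peaks,
    scan_candidate_peaks,
)


def make_profile(depth, gene_id="G", offset=0, n_reads=None, read_len=50):
    depth = np.asarray(depth, dtype=float)
    n = int(depth.sum() // read_len) if n_reads is None else n_reads
    return CoverageProfile(gene_id, depth, n_reads=n, offset=offset,
                           read_lengths=(read_len,) * n)


def assert_matches_oracle(depth, params):
    profile = make_profile(depth)
    baseline = gene_baseline(profile, params)
    got = scan_candidate_peaks(profile, params, baseline=baseline)
    want = oracle_window_walk(depth, params, baseline)
    assert len(got) == len(want), f"peak count {len(got)} != oracle {len(want)}"
    for g, o in zip(got, want):
        assert (g.interval.start, g.interval.end) == (o["start"], o["end"])
        assert g.max_depth == o["max"]
        assert g.median_depth == o["median"]


class TestCoverage:
    def _gene(self, length=1000):
        return GeneModel("G", GenomicInterval("c", 0, length, "+"),
                         {"t": [GenomicInterval("c", 0, length, "+")]})

    def test_two_reads_cover_base(self):
        prof = build_coverage([(0, 20), (5, 25)], self._gene())
        assert prof.depth[10] == 2
        assert prof.depth[0] == 1 and prof.depth[24] == 1 and prof.depth[25] == 0

    def test_no_reads_all_zero(self):
        prof = build_coverage([], self._gene())
        assert prof.depth.sum() == 0 and prof.n_reads == 0

    def test_against_bruteforce_overlap_count(self, rng):
        gene = self._gene(1500)
        reads = []
        for _ in range(1000):
            s = int(rng.integers(-30, 1480))
            reads.append((s, s + 50))
        prof = build_coverage(reads, gene)
        brute = np.zeros(1500)
        for s, e in reads:
            for pos in range(max(s, 0), min(e, 1500)):
                brute[pos] += 1
        np.testing.assert_array_equal(prof.depth, brute)

    def test_clipped_reads_counted(self):
        prof = build_coverage([(-10, 40), (990, 1040)], self._gene())
        assert prof.n_clipped == 2
        assert prof.depth[0] == 1 and prof.depth[999] == 1

    def test_depth_mass_conservation(self, rng):
        # fully contained reads: sum(depth) == n_reads * read_length
        gene = self._gene(2000)
        starts = rng.integers(0, 1950, size=200)
        prof = build_coverage([(int(s), int(s) + 50) for s in starts], gene)
        assert prof.depth.sum() == 200 * 50


class TestScanner:
    def test_all_zero_profile(self):
        assert scan_candidate_peaks(make_profile(np.zeros(1000)), PeakCallerParams()) == []

    def test_rectangular_block_matches_oracle(self):
        depth = np.ones(1000)
        depth[100:200] = 100.0
        assert_matches_oracle(depth, PeakCallerParams())

    def test_two_blocks_two_peaks(self):
        depth = np.ones(1500)
        depth[100:200] = 80.0
        depth[400:500] = 80.0
        depth[200:400] = 0.0
        profile = make_profile(depth)
        peaks = scan_candidate_peaks(profile, PeakCallerParams())
        assert len(peaks) == 2
        assert_matches_oracle(depth, PeakCallerParams())

    def test_median_start_clause(self):
        # baseline is high so the fold clause never fires; median > 50 must
        depth = np.full(500, 30.0)
        depth[100:180] = 60.0
        profile = make_profile(depth)
        peaks = scan_candidate_peaks(profile, PeakCallerParams())
        assert len(peaks) == 1
        assert_matches_oracle(depth, PeakCallerParams())

    def test_random_profiles_match_oracle(self, rng):
        params = PeakCallerParams()
        for _ in range(80):
            L = int(rng.integers(40, 1500))
            depth = rng.poisson(1.0, L).astype(float)
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(0, max(L - 60, 1)))
                width = int(rng.integers(20, 200))
                depth[s: s + width] += float(rng.integers(3, 120))
            assert_matches_oracle(depth, params)

    def test_monotone_in_start_fold(self, rng):
        depth = rng.poisson(2.0, 1200).astype(float)
        depth[300:420] += 30
        depth[700:760] += 8
        profile = make_profile(depth)
        counts = [
            len(scan_candidate_peaks(profile, PeakCallerParams(start_fold=f)))
            for f in (1.5, 2.5, 4.0, 8.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_params_validated(self):
        with pytest.raises(ValueError):
            PeakCallerParams(stop_fraction=1.5)
        with pytest.raises(ValueError):
            PeakCallerParams(window=0)
        with pytest.raises(ValueError):
            PeakCallerParams(baseline_method="mode")


class TestPermutation:
    def test_zero_reads_p_one(self):
        profile = make_profile(np.zeros(100), n_reads=0)
        peak = Peak("G", GenomicInterval("c", 0, 50, "+"), 0.0, 0.0)
        assert permutation_pvalue(profile, peak, PeakCallerParams(),
                                  np.random.default_rng(0)) == 1.0

    def test_concentrated_reads_significant(self, rng):
        # every read stacked in one 5 bp window of a 10 kb gene
        n_reads, L = 30, 10_000
        depth = np.zeros(L)
        depth[5000:5050] = n_reads
        profile = CoverageProfile("G", depth, n_reads=n_reads,
                                  read_lengths=(50,) * n_reads)
        peak = Peak("G", GenomicInterval("c", 5000, 5050, "+"), float(n_reads), float(n_reads))
        hits = 0
        for seed in range(20):
            p = permutation_pvalue(profile, peak, PeakCallerParams(),
                                   np.random.default_rng(seed))
            hits += p <= 0.05
        assert hits >= 19

    def test_pvalue_estimator_never_zero(self, rng):
        profile = make_profile(np.ones(500), n_reads=10)
        peak = Peak("G", GenomicInterval("c", 0, 50, "+"), 1e9, 0.0)
        p = permutation_pvalue(profile, peak, PeakCallerParams(), rng)
        assert p == pytest.approx(1 / 501)


class TestRetention:
    def _peak(self, p, depth):
        return Peak("G", GenomicInterval("c", 0, 50, "+"), depth, depth / 2, p_value=p)

    def test_depth_rescue_boundary(self):
        # p=0.2 but max depth 10 -> retained by the depth rule
        out = retain_peaks([self._peak(0.2, 10.0)], PeakCallerParams())
        assert out[0].retained

    def test_p_branch(self):
        out = retain_peaks([self._peak(0.049, 3.0)], PeakCallerParams())
        assert out[0].retained

    def test_neither_branch_dropped(self):
        out = retain_peaks([self._peak(0.2, 9.0)], PeakCallerParams())
        assert not out[0].retained


def _reads_df(intervals):
    return pd.DataFrame(
        [{"gene_id": "G", "chrom": "c", "start": s, "end": e, "strand": "+"}
         for s, e in intervals]
    )


def _filler(n, start=5000):
    # reads far from the peak, to equalize library sizes
    return [(start + 100 * i, start + 100 * i + 50) for i in range(n)]


class TestEnrichment:
    def _peak(self):
        return Peak("G", GenomicInterval("c", 0, 100, "+"), 12.0, 6.0,
                    p_value=0.01, retained=True)

    def test_fourfold_passes(self):
        ip = _reads_df([(10, 60)] * 8 + _filler(2))
        inp = _reads_df([(10, 60)] * 2 + _filler(8))
        out = enrichment_filter([self._peak()], ip, inp, PeakCallerParams())
        assert out[0].enrichment == pytest.approx(4.0)
        assert out[0].is_enriched

    def test_three_point_five_fails(self):
        ip = _reads_df([(10, 60)] * 7 + _filler(3))
        inp = _reads_df([(10, 60)] * 2 + _filler(8))
        out = enrichment_filter([self._peak()], ip, inp, PeakCallerParams())
        assert out[0].enrichment == pytest.approx(3.5)
        assert not out[0].is_enriched

    def test_zero_input_uses_pseudo_floor(self):
        # a 10-read IP peak against an empty input region is enriched
        ip = _reads_df([(10, 60)] * 10 + _filler(10))
        inp = _reads_df(_filler(20))
        out = enrichment_filter([self._peak()], ip, inp, PeakCallerParams())
        assert out[0].input_was_zero
        assert out[0].enrichment == pytest.approx(10.0)  # 10 reads vs 1-read floor
        assert out[0].is_enriched

    def test_empty_ip_library_errors(self):
        with pytest.raises(ValueError, match="IP"):
            enrichment_filter([self._peak()], _reads_df([]), _reads_df(_filler(5)),
                              PeakCallerParams())

    def test_monotone_in_enrich_fold(self):
        ip = _reads_df([(10, 60)] * 8 + _filler(2))
        inp = _reads_df([(10, 60)] * 2 + _filler(8))
        n_enriched = [
            sum(ep.is_enriched for ep in enrichment_filter(
                [self._peak()], ip, inp, PeakCallerParams(enrich_fold=f)))
            for f in (2.0, 4.0, 8.0)
        ]
        assert n_enriched == sorted(n_enriched, reverse=True)


class TestTargets:
    def _ep(self, gene, start, end, retained=True, enriched=True):
        peak = Peak(gene, GenomicInterval("c", start, end, "+"), 20.0, 10.0,
                    p_value=0.01, retained=retained)
        return EnrichedPeak(peak, 10.0, 1.0, 10.0, enriched)

    def test_peak_in_one_rep_only_excluded(self):
        per_rep = {"IP_1": [self._ep("G", 0, 100)], "IP_2": []}
        targets, _ = call_targets(per_rep)
        assert targets == set()

    def test_identical_peak_both_reps_included(self):
        per_rep = {"IP_1": [self._ep("G", 0, 100)], "IP_2": [self._ep("G", 0, 100)]}
        targets, _ = call_targets(per_rep)
        assert targets == {"G"}

    def test_one_bp_overlap_suffices(self):
        per_rep = {"IP_1": [self._ep("G", 0, 100)], "IP_2": [self._ep("G", 99, 200)]}
        assert call_targets(per_rep)[0] == {"G"}

    def test_union_mode(self):
        per_rep = {"IP_1": [self._ep("G", 0, 100)], "IP_2": []}
        assert call_targets(per_rep, mode="union")[0] == {"G"}

    def test_unenriched_peak_excluded(self):
        per_rep = {
            "IP_1": [self._ep("G", 0, 100, enriched=False)],
            "IP_2": [self._ep("G", 0, 100)],
        }
        assert call_targets(per_rep)[0] == set()
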
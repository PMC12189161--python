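import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ripsplice.core_io import GeneModel, GenomicInterval, JunctionCountTable
from ripsplice import splicing
from ripsplice.splicing import (
    SpliceEvent,
    bh_fdr,
    build_splice_graph,
    detect_events,
    event_ratio,
    rase_table,
    summarize_rase,
)

# module-qualified to keep pytest from collecting the library function
ratio_alteration = splicing.test_ratio_alteration

GROUPS = {"a1": "a", "a2": "a", "a3": "a", "b1": "b", "b2": "b", "b3": "b"}


def gene(transcripts, length=2000, strand="+"):
    txs = {
        name: [GenomicInterval("c", s, e, strand) for s, e in exons]
        for name, exons in transcripts.items()
    }
    return GeneModel("G", GenomicInterval("c", 0, length, strand), txs)


def table(rows, groups=GROUPS):
    df = pd.DataFrame(rows, columns=["gene_id", "donor", "acceptor", "sample_id", "count"])
    return JunctionCountTable(df, groups)


class TestSpliceGraph:
    def test_two_exon_gene(self):
        g = gene({"t": [(0, 100), (200, 300)]})
        graph = build_splice_graph(g)
        assert graph.segments == [(0, 100), (200, 300)]
        assert set(graph.junctions) == {(100, 200)}

    def test_novel_junction_flagged(self):
        g = gene({"t": [(0, 100), (200, 300)]})
        t = table([("G", 120, 180, "a1", 5)])
        graph = build_splice_graph(g, t)
        assert (120, 180) in graph.junctions
        assert (120, 180) in graph.novel

    def test_junction_crossing_gene_bounds_rejected(self):
        g = gene({"t": [(0, 100), (200, 300)]}, length=400)
        t = table([("G", 100, 900, "a1", 5)])
        graph = build_splice_graph(g, t)
        assert (100, 900) not in graph.junctions
        assert (100, 900) in graph.rejected

    def test_counts_accumulate(self):
        g = gene({"t": [(0, 100), (200, 300)]})
        t = table([("G", 100, 200, "a1", 5), ("G", 100, 200, "a1", 7)])
        graph = build_splice_graph(g, t)
        assert graph.counts((100, 200), "a1") == 12


class TestClassification:
    def test_canonical_cassette(self):
        g = gene({"t1": [(0, 100), (200, 300), (400, 500)],
                  "t2": [(0, 100), (400, 500)]})
        events = detect_events(build_splice_graph(g))
        assert len(events) == 1
        ev = events[0]
        assert ev.event_type == "cassetteExon"
        assert ev.inclusion == frozenset({(100, 200), (300, 400)})
        assert ev.exclusion == frozenset({(100, 400)})

    def test_multi_exon_skip_is_es(self):
        g = gene({"t1": [(0, 100), (200, 300), (400, 500), (600, 700)],
                  "t2": [(0, 100), (600, 700)]})
        events = detect_events(build_splice_graph(g))
        assert [e.event_type for e in events] == ["ES"]

    def test_two_donors_shared_acceptor_is_a5ss(self):
        g = gene({"t1": [(0, 150), (300, 400)], "t2": [(0, 100), (300, 400)]})
        events = detect_events(build_splice_graph(g))
        assert len(events) == 1
        assert events[0].event_type == "A5SS"
        assert events[0].inclusion == frozenset({(150, 300)})
        assert events[0].exclusion == frozenset({(100, 300)})

    def test_minus_strand_relabels_a5ss_to_a3ss(self):
        g = gene({"t1": [(0, 150), (300, 400)], "t2": [(0, 100), (300, 400)]},
                 strand="-")
        events = detect_events(build_splice_graph(g))
        assert events[0].event_type == "A3SS"

    def test_all_nine_fixture_topologies(self, fixture_models):
        _, models, truth = fixture_models
        seen = set()
        for m in models:
            events = detect_events(build_splice_graph(m))
            want = truth[m.gene_id]
            assert len(events) == 1, f"{m.gene_id}: {events}"
            ev = events[0]
            assert ev.event_type == want["event_type"]
            assert ev.inclusion == frozenset(map(tuple, want["inclusion"]))
            assert ev.exclusion == frozenset(map(tuple, want["exclusion"]))
            seen.add(ev.event_type)
        assert len(seen) == 9

    def test_inclusion_exclusion_disjoint_and_in_graph(self, fixture_models):
        _, models, _ = fixture_models
        for m in models:
            graph = build_splice_graph(m)
            for ev in detect_events(graph):
                assert not (ev.inclusion & ev.exclusion)
                assert (ev.inclusion | ev.exclusion) <= set(graph.junctions)

    def test_input_order_invariance(self, fixture_junctions):
        _, models, _, t = fixture_junctions
        shuffled = JunctionCountTable(
            t.df.sample(frac=1.0, random_state=7).reset_index(drop=True), t.groups
        )
        for m in models[:6]:
            a = detect_events(build_splice_graph(m, t))
            b = detect_events(build_splice_graph(m, shuffled))
            assert sorted(a, key=str) == sorted(b, key=str)

    def test_event_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            SpliceEvent("G", "ES", frozenset({(1, 2)}), frozenset({(1, 2)}), (0, 1))
        with pytest.raises(ValueError, match="non-empty"):
            SpliceEvent("G", "ES", frozenset(), frozenset({(1, 2)}), (0, 1))


class TestRatios:
    def _cassette(self):
        g = gene({"t1": [(0, 100), (200, 300), (400, 500)],
                  "t2": [(0, 100), (400, 500)]})
        ev = detect_events(build_splice_graph(g))[0]
        return g, ev

    def test_ratio_arithmetic(self):
        _, ev = self._cassette()
        t = table(
            [("G", 100, 200, "a1", 15), ("G", 300, 400, "a1", 15),
             ("G", 100, 400, "a1", 10)]
        )
        assert event_ratio(ev, t, "a1") == pytest.approx(0.75)

    def test_ratio_missing_when_no_reads(self):
        _, ev = self._cassette()
        t = table([("G", 100, 200, "a1", 0)])
        assert np.isnan(event_ratio(ev, t, "a1"))

    def test_all_exclusion_ratio_zero(self):
        _, ev = self._cassette()
        t = table([("G", 100, 400, "a1", 20)])
        assert event_ratio(ev, t, "a1") == 0.0


class TestRatioTest:
    def _fixture(self, ratios_a, ratios_b, depth=200):
        # each inclusion junction gets depth*r/2 so the event ratio is exactly r
        g, ev = TestRatios()._cassette()
        rows = []
        for sample, ratio in zip(["a1", "a2", "a3"], list(ratios_a)):
            half = int(round(depth * ratio / 2))
            rows += [("G", 100, 200, sample, half), ("G", 300, 400, sample, half),
                     ("G", 100, 400, sample, depth - 2 * half)]
        for sample, ratio in zip(["b1", "b2", "b3"], list(ratios_b)):
            half = int(round(depth * ratio / 2))
            rows += [("G", 100, 200, sample, half), ("G", 300, 400, sample, half),
                     ("G", 100, 400, sample, depth - 2 * half)]
        return ev, table(rows)

    def test_identical_groups_t_zero_p_one(self):
        ev, t = self._fixture([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        results, skipped = ratio_alteration([ev], t)
        assert not skipped
        assert results[0].t_statistic == 0.0
        assert results[0].p_value == 1.0

    def test_strong_shift_matches_closed_form(self):
        ev, t = self._fixture([0.30, 0.31, 0.29], [0.70, 0.69, 0.71])
        results, _ = ratio_alteration([ev], t)
        res = results[0]
        assert res.p_value < 0.001
        # independent closed-form Welch computation
        a, b = np.array([0.30, 0.31, 0.29]), np.array([0.70, 0.69, 0.71])
        se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
        t_manual = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2 ** 2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        )
        p_manual = 2 * sps.t.sf(abs(t_manual), df)
        assert res.t_statistic == pytest.approx(t_manual)
        assert res.p_value == pytest.approx(p_manual)
        assert res.delta_ratio == pytest.approx(0.4, abs=1e-9)

    def test_student_flag_changes_variant(self):
        ev, t = self._fixture([0.30, 0.35, 0.25], [0.60, 0.75, 0.62])
        welch, _ = ratio_alteration([ev], t, equal_var=False)
        student, _ = ratio_alteration([ev], t, equal_var=True)
        # same data, different df handling
        assert welch[0].p_value != student[0].p_value

    def test_undefined_ratios_skip_event(self):
        g, ev = TestRatios()._cassette()
        rows = [("G", 100, 200, "a1", 10), ("G", 100, 400, "a1", 10)]
        rows += [("G", 100, 200, s, 10) for s in ["b1", "b2", "b3"]]
        rows += [("G", 100, 400, s, 10) for s in ["b1", "b2", "b3"]]
        results, skipped = ratio_alteration([ev], table(rows))
        assert not results
        assert len(skipped) == 1 and "fewer than 2" in skipped[0][1]


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), adj, atol=1e-12)


class TestSummary:
    def test_empty_summary(self):
        s = summarize_rase([])
        assert s["total"] == 0 and (s.drop("total") == 0).all()

    def test_counts_conserved(self, fixture_junctions):
        _, models, truth, t = fixture_junctions
        events = []
        for m in models:
            events.extend(detect_events(build_splice_graph(m, t)))
        results, _ = ratio_alteration(events, t)
        s = summarize_rase(results)
        assert s["total"] == sum(r.significant for r in results)
        assert s.drop("total").sum() == s["total"]

    def test_fixture_counts_match_design(self, fixture_junctions):
        cfg, models, truth, t = fixture_junctions
        events = []
        for m in models:
            events.extend(detect_events(build_splice_graph(m, t)))
        results, _ = ratio_alteration(events, t)
        sig = {r.event.gene_id for r in results if r.significant}
        planted = {d.gene_id for d in cfg.junction_design}
        assert planted <= sig
        s = summarize_rase(results)
        from collections import Counter

        want = Counter(d.event_type for d in cfg.junction_design)
        for etype, n in want.items():
            assert s[etype] >= n

    def test_rase_table_columns(self, fixture_junctions):
        _, models, _, t = fixture_junctions
        events = detect_events(build_splice_graph(models[0], t))
        results, _ = ratio_alteration(events, t)
        df = rase_table(results)
        assert {"gene_id", "event_type", "delta_ratio", "p_value", "fdr",
                "significant"} <= set(df.columns)


class TestEstimatorConsistency:
    def test_ratio_converges_to_psi(self):
        # at depth 1e5 the per-sample ratio is within 0.01 of psi
        from ripsplice.simulate import SimulationConfig, SplicingDesign
        from ripsplice.simulate import simulate_gene_models, simulate_junction_counts

        psi = 0.37
        cfg = SimulationConfig(
            seed=8, n_genes=1,
            junction_design=[SplicingDesign("G001", "cassetteExon", psi, psi, 1e5)],
        )
        models, truth = simulate_gene_models(cfg)
        t = simulate_junction_counts(cfg, models, truth)
        ev = detect_events(build_splice_graph(models[0], t))[0]
        for sample in t.samples:
            assert abs(event_ratio(ev, t, sample) - psi) < 0.01
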
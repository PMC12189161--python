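"""Junction-based alternative-splicing event detection and ratio testing.

Events are classified from splice-junction topology against the annotation.
Nine types are recognised: cassetteExon, ES, A5SS, A3SS, MXE, 5pMXE, 3pMXE,
A5SS&ES and A3SS&ES.  Intron retention is deliberately not implemented: it
needs exon-body coverage, which junction counts cannot provide.

Classification happens in genomic (+) orientation; labels whose meaning is
strand-polar (donor vs acceptor, first vs last exon) are swapped for minus-
strand genes.

The splicing ratio of an event in a sample is
``sum(inclusion counts) / (sum(inclusion) + sum(exclusion))`` — undefined when
the denominator is zero.  Group differences are tested per event with a
two-sample t-test on per-sample ratios (Welch by default) and adjusted with
Benjamini-Hochberg; an event is significant at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ripsplice.core_io import GeneModel, JunctionCountTable

Junction = tuple[int, int]

EVENT_TYPES = (
    "cassetteExon", "ES", "A5SS", "A3SS", "MXE", "5pMXE", "3pMXE",
    "A5SS&ES", "A3SS&ES",
)

_MINUS_STRAND_RELABEL = {
    "A5SS": "A3SS", "A3SS": "A5SS",
    "5pMXE": "3pMXE", "3pMXE": "5pMXE",
    "A5SS&ES": "A3SS&ES", "A3SS&ES": "A5SS&ES",
}


@dataclass(frozen=True)
class SpliceEvent:
    gene_id: str
    event_type: str
    inclusion: frozenset[Junction]
    exclusion: frozenset[Junction]
    region: tuple[int, int]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion or not self.exclusion:
            raise ValueError("inclusion and exclusion junction sets must be non-empty")
        if self.inclusion & self.exclusion:
            raise ValueError("inclusion and exclusion junction sets must be disjoint")


@dataclass
class SpliceGraph:
    """Per-gene exonic segments plus junction edges with per-sample counts."""

    gene: GeneModel
    junctions: dict[Junction, dict[str, int]]      # (donor, acceptor) -> sample counts
    novel: set[Junction] = field(default_factory=set)
    rejected: list[Junction] = field(default_factory=list)  # crossed gene bounds

    @property
    def exons(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.gene.all_exons()]

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Exon-union intervals split at every donor/acceptor boundary."""
        exons = self.exons
        if not exons:
            return []
        # exon union
        union: list[list[int]] = []
        for s, e in sorted(exons):
            if union and s <= union[-1][1]:
                union[-1][1] = max(union[-1][1], e)
            else:
                union.append([s, e])
        boundaries = set()
        for s, e in exons:
            boundaries.update((s, e))
        for d, a in self.junctions:
            boundaries.update((d, a))
        segs = []
        for s, e in union:
            cuts = sorted({b for b in boundaries if s < b < e} | {s, e})
            segs.extend((a, b) for a, b in zip(cuts, cuts[1:]))
        return segs

    def counts(self, junction: Junction, sample: str) -> int:
        return self.junctions.get(junction, {}).get(sample, 0)


def build_splice_graph(model: GeneModel, table: JunctionCountTable | None = None) -> SpliceGraph:
    """Combine annotated junctions with observed junction counts for one gene.

    Observed junctions absent from the annotation are flagged novel; junctions
    crossing the gene bounds are rejected (kept in ``rejected`` for reporting).
    """
    junctions: dict[Junction, dict[str, int]] = {j: {} for j in sorted(model.junctions())}
    novel: set[Junction] = set()
    rejected: list[Junction] = []
    if table is not None:
        observed = table.gene_counts(model.gene_id)
        for (donor, acceptor), sub in observed.groupby(["donor", "acceptor"], sort=True):
            j = (int(donor), int(acceptor))
            if j[0] < model.interval.start or j[1] > model.interval.end:
                rejected.append(j)
                continue
            if j not in junctions:
                junctions[j] = {}
                novel.add(j)
            for _, row in sub.iterrows():
                junctions[j][row["sample_id"]] = (
                    junctions[j].get(row["sample_id"], 0) + int(row["count"])
                )
    return SpliceGraph(model, junctions, novel, rejected)


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------


def _exon_roles(model: GeneModel) -> tuple[set, set, set]:
    """(first, internal, last) exon coordinate sets over all transcripts."""
    first, internal, last = set(), set(), set()
    for exons in model.transcripts.values():
        coords = [(e.start, e.end) for e in exons]
        first.add(coords[0])
        last.add(coords[-1])
        internal.update(coords[1:-1])
    return first, internal, last


def _skip_events(graph: SpliceGraph) -> tuple[list[SpliceEvent], set[Junction]]:
    """Detect exon-skipping events (cassetteExon / ES / A5SS&ES / A3SS&ES).

    For each candidate exclusion junction X, exons lying entirely inside X's
    intron are chained through inclusion junctions from X's donor side to its
    acceptor side.  A chain whose ends match X exactly is a skip (one exon:
    cassetteExon, several: ES); a donor (resp. acceptor) shifted to an
    overlapping exon boundary makes it A5SS&ES (resp. A3SS&ES), in genomic
    orientation.
    """
    gene = graph.gene
    juncs = sorted(graph.junctions)
    exons = sorted({(e.start, e.end) for e in gene.all_exons()})
    by_donor: dict[int, list[Junction]] = {}
    by_acceptor: dict[int, list[Junction]] = {}
    for j in juncs:
        by_donor.setdefault(j[0], []).append(j)
        by_acceptor.setdefault(j[1], []).append(j)
    donor_exons = {d: [e for e in exons if e[1] == d] for d, _ in
                   [(j[0], None) for j in juncs]}
    acceptor_exons = {a: [e for e in exons if e[0] == a] for a in
                      {j[1] for j in juncs}}

    def overlapping(e1: tuple[int, int], e2: tuple[int, int]) -> bool:
        return e1[0] < e2[1] and e2[0] < e1[1]

    events: list[SpliceEvent] = []
    used_exclusions: set[Junction] = set()
    for X in juncs:
        dX, aX = X
        inside = [e for e in exons if e[0] >= dX and e[1] <= aX]
        if not inside:
            continue
        # entry junctions: land on an inside exon, donor exon compatible with X's
        x_donor_exons = donor_exons.get(dX, [])
        x_acceptor_exons = acceptor_exons.get(aX, [])
        inside_starts = {e[0] for e in inside}
        inside_by_start = {e[0]: e for e in inside}
        entries = [
            j for j in juncs
            if j != X and j[1] in inside_starts and (
                j[0] == dX
                or any(
                    overlapping(de, xe)
                    for de in donor_exons.get(j[0], [])
                    for xe in x_donor_exons
                )
            )
        ]
        chain_found = None
        for entry in sorted(entries):
            # walk: inside exon -> junction -> inside exon ... -> exit
            path = [entry]
            exon = inside_by_start[entry[1]]
            visited = {exon}
            while True:
                nxt = [
                    j for j in by_donor.get(exon[1], [])
                    if j != X and (
                        j[1] == aX
                        or any(
                            overlapping(ae, xe)
                            for ae in acceptor_exons.get(j[1], [])
                            for xe in x_acceptor_exons
                        )
                        or j[1] in inside_starts
                    )
                ]
                exits = [j for j in nxt if j[1] not in inside_starts or j[1] == aX]
                hops = [j for j in nxt if j[1] in inside_starts and j[1] != aX]
                if exits:
                    path.append(sorted(exits)[0])
                    chain_found = path
                    break
                if not hops:
                    break
                hop = sorted(hops)[0]
                path.append(hop)
                exon = inside_by_start[hop[1]]
                if exon in visited:
                    break
                visited.add(exon)
            if chain_found:
                break
        if not chain_found:
            continue
        d0 = chain_found[0][0]
        a_f = chain_found[-1][1]
        skipped = [inside_by_start[j[1]] for j in chain_found[:-1]]
        inclusion = frozenset(chain_found)
        exclusion = frozenset([X])
        if inclusion & exclusion:
            continue
        if d0 == dX and a_f == aX:
            etype = "cassetteExon" if len(skipped) == 1 else "ES"
            region = (skipped[0][0], skipped[-1][1])
        elif d0 != dX and a_f == aX:
            etype = "A5SS&ES"
            region = (min(d0, dX), skipped[-1][1])
        elif d0 == dX and a_f != aX:
            etype = "A3SS&ES"
            region = (skipped[0][0], max(a_f, aX))
        else:
            continue  # both ends shifted: left to the remainder
        events.append(SpliceEvent(gene.gene_id, etype, inclusion, exclusion, region))
        used_exclusions.add(X)
    return events, used_exclusions


def _mxe_events(graph: SpliceGraph) -> tuple[list[SpliceEvent], set[Junction]]:
    gene = graph.gene
    juncs = set(graph.junctions)
    first, _internal, last = _exon_roles(gene)
    exons = sorted({(e.start, e.end) for e in gene.all_exons()})
    has_incoming = {e: any(j[1] == e[0] for j in juncs) for e in exons}
    has_outgoing = {e: any(j[0] == e[1] for j in juncs) for e in exons}

    events: list[SpliceEvent] = []
    used: set[Junction] = set()
    for U, V in combinations(exons, 2):
        if U[1] > V[0]:
            continue  # overlapping or out of order
        if (U[1], V[0]) in juncs:
            continue  # the two exons can co-occur
        donors_u = {j[0] for j in juncs if j[1] == U[0]}
        donors_v = {j[0] for j in juncs if j[1] == V[0]}
        acceptors_u = {j[1] for j in juncs if j[0] == U[1]}
        acceptors_v = {j[1] for j in juncs if j[0] == V[1]}
        common_d = sorted(donors_u & donors_v)
        common_a = sorted(a for a in (acceptors_u & acceptors_v) if a > V[1])
        if common_d and common_a:
            d, a = common_d[0], common_a[0]
            inclusion = frozenset({(d, U[0]), (U[1], a)})
            exclusion = frozenset({(d, V[0]), (V[1], a)})
            events.append(
                SpliceEvent(gene.gene_id, "MXE", inclusion, exclusion, (U[0], V[1]))
            )
            used |= inclusion | exclusion
        elif (
            common_a
            and not has_incoming[U] and not has_incoming[V]
            and U in first and V in first
        ):
            a = common_a[0]
            inclusion = frozenset({(U[1], a)})
            exclusion = frozenset({(V[1], a)})
            events.append(
                SpliceEvent(gene.gene_id, "5pMXE", inclusion, exclusion, (U[0], V[1]))
            )
            used |= inclusion | exclusion
        elif (
            common_d
            and not has_outgoing[U] and not has_outgoing[V]
            and U in last and V in last
        ):
            d = common_d[0]
            inclusion = frozenset({(d, U[0])})
            exclusion = frozenset({(d, V[0])})
            events.append(
                SpliceEvent(gene.gene_id, "3pMXE", inclusion, exclusion, (U[0], V[1]))
            )
            used |= inclusion | exclusion
    return events, used


def _altsite_events(graph: SpliceGraph, excluded: set[Junction]) -> list[SpliceEvent]:
    """Pure A5SS/A3SS: two junctions sharing one end, whose varying-end exons
    overlap (alternative boundaries of the same exon)."""
    gene = graph.gene
    juncs = [j for j in sorted(graph.junctions) if j not in excluded]
    exons = sorted({(e.start, e.end) for e in gene.all_exons()})

    def exons_ending_at(d: int) -> list[tuple[int, int]]:
        return [e for e in exons if e[1] == d]

    def exons_starting_at(a: int) -> list[tuple[int, int]]:
        return [e for e in exons if e[0] == a]

    def overlapping(e1, e2) -> bool:
        return e1[0] < e2[1] and e2[0] < e1[1]

    events: list[SpliceEvent] = []
    by_acceptor: dict[int, list[Junction]] = {}
    by_donor: dict[int, list[Junction]] = {}
    for j in juncs:
        by_donor.setdefault(j[0], []).append(j)
        by_acceptor.setdefault(j[1], []).append(j)

    for a, group in sorted(by_acceptor.items()):
        if len(group) < 2:
            continue
        for j1, j2 in combinations(sorted(group), 2):  # j1 donor < j2 donor
            flanks1, flanks2 = exons_ending_at(j1[0]), exons_ending_at(j2[0])
            if any(overlapping(e1, e2) for e1 in flanks1 for e2 in flanks2):
                # larger donor = shorter intron = more exon included
                events.append(
                    SpliceEvent(gene.gene_id, "A5SS", frozenset([j2]), frozenset([j1]),
                                (j1[0], j2[0]))
                )
    for d, group in sorted(by_donor.items()):
        if len(group) < 2:
            continue
        for j1, j2 in combinations(sorted(group), 2):  # j1 acceptor < j2 acceptor
            flanks1, flanks2 = exons_starting_at(j1[1]), exons_starting_at(j2[1])
            if any(overlapping(e1, e2) for e1 in flanks1 for e2 in flanks2):
                events.append(
                    SpliceEvent(gene.gene_id, "A3SS", frozenset([j1]), frozenset([j2]),
                                (j1[1], j2[1]))
                )
    return events


def detect_events(
    graph: SpliceGraph, return_remainder: bool = False
) -> list[SpliceEvent] | tuple[list[SpliceEvent], list[Junction]]:
    """Classify the gene's junction topology into splicing events.

    Junction patterns that fit no rule are returned in the remainder list when
    ``return_remainder`` is set.
    """
    skip_ev, skip_used = _skip_events(graph)
    mxe_ev, mxe_used = _mxe_events(graph)
    alt_ev = _altsite_events(graph, excluded=skip_used | mxe_used)
    events = skip_ev + mxe_ev + alt_ev

    if graph.gene.strand == "-":
        events = [
            SpliceEvent(
                ev.gene_id,
                _MINUS_STRAND_RELABEL.get(ev.event_type, ev.event_type),
                ev.inclusion, ev.exclusion, ev.region,
            )
            for ev in events
        ]
    if not return_remainder:
        return events
    involved = {j for ev in events for j in ev.inclusion | ev.exclusion}
    remainder = [j for j in sorted(graph.junctions) if j not in involved]
    return events, remainder


# ---------------------------------------------------------------------------
# Ratios and differential testing
# ---------------------------------------------------------------------------


def event_ratio(
    event: SpliceEvent, table: JunctionCountTable, sample: str
) -> float:
    """Inclusion fraction of one event in one sample; NaN when no reads."""
    gene_counts = table.gene_counts(event.gene_id)
    sub = gene_counts[gene_counts["sample_id"] == sample]
    lookup = {
        (int(r["donor"]), int(r["acceptor"])): int(r["count"])
        for _, r in sub.iterrows()
    }
    incl = sum(lookup.get(j, 0) for j in event.inclusion)
    excl = sum(lookup.get(j, 0) for j in event.exclusion)
    if incl + excl == 0:
        return float("nan")
    return incl / (incl + excl)


@dataclass
class RatioTestResult:
    event: SpliceEvent
    ratios: dict[str, float]             # per-sample ratios (NaN = undefined)
    group_means: dict[str, float]
    delta_ratio: float
    t_statistic: float
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def _welch_or_student(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance at all
        if a[0] == b[0]:
            return 0.0, 1.0
        return float("inf") if a[0] > b[0] else float("-inf"), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def test_ratio_alteration(
    events: Sequence[SpliceEvent],
    table: JunctionCountTable,
    equal_var: bool = False,
    min_junction_reads: int = 0,
    fdr_cut: float = 0.05,
) -> tuple[list[RatioTestResult], list[tuple[SpliceEvent, str]]]:
    """Two-sample t-test on per-sample splicing ratios, BH-adjusted.

    Welch's t by default (``equal_var=True`` restores pooled-variance
    Student's t).  Events with fewer than two defined ratios in either group
    are skipped; the second return value lists them with the reason.
    """
    groups = table.groups
    group_names = sorted(set(groups.values()))
    g1, g2 = group_names

    # pivot counts once: (gene, donor, acceptor) x sample
    pivot = table.df.pivot_table(
        index=["gene_id", "donor", "acceptor"],
        columns="sample_id",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    samples = sorted(groups)

    def counts_for(gene_id: str, juncs: Iterable[Junction]) -> np.ndarray:
        total = np.zeros(len(samples))
        for d, a in juncs:
            key = (gene_id, d, a)
            if key in pivot.index:
                row = pivot.loc[key]
                total += np.array([row.get(s, 0) for s in samples], dtype=float)
        return total

    results: list[RatioTestResult] = []
    skipped: list[tuple[SpliceEvent, str]] = []
    pvals: list[float] = []
    for ev in events:
        incl = counts_for(ev.gene_id, ev.inclusion)
        excl = counts_for(ev.gene_id, ev.exclusion)
        denom = incl + excl
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(denom >= max(min_junction_reads, 1), incl / denom, np.nan)
        ratio_map = dict(zip(samples, ratios))
        a = np.array([r for s, r in ratio_map.items() if groups[s] == g1 and np.isfinite(r)])
        b = np.array([r for s, r in ratio_map.items() if groups[s] == g2 and np.isfinite(r)])
        if len(a) < 2 or len(b) < 2:
            skipped.append((ev, f"fewer than 2 defined ratios in a group ({len(a)} vs {len(b)})"))
            continue
        t, p = _welch_or_student(a, b, equal_var)
        results.append(
            RatioTestResult(
                event=ev,
                ratios=ratio_map,
                group_means={g1: float(a.mean()), g2: float(b.mean())},
                delta_ratio=float(b.mean() - a.mean()),
                t_statistic=t,
                p_value=p,
            )
        )
        pvals.append(p)

    if results:
        fdrs = bh_fdr(np.array(pvals))
        for res, fdr in zip(results, fdrs):
            res.fdr = float(fdr)
            res.significant = bool(fdr < fdr_cut)
    return results, skipped


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def summarize_rase(results: Sequence[RatioTestResult]) -> pd.Series:
    """Counts of significant events per type, plus the total."""
    counts = {etype: 0 for etype in EVENT_TYPES}
    for res in results:
        if res.significant:
            counts[res.event.event_type] += 1
    counts["total"] = sum(counts.values())
    return pd.Series(counts, name="n_significant")


def rase_table(results: Sequence[RatioTestResult]) -> pd.DataFrame:
    """Flat result table for TSV output."""
    rows = []
    for res in results:
        ev = res.event
        g1, g2 = sorted(res.group_means)
        rows.append(
            {
                "gene_id": ev.gene_id,
                "event_type": ev.event_type,
                "region_start": ev.region[0],
                "region_end": ev.region[1],
                "inclusion_junctions": ";".join(f"{d}-{a}" for d, a in sorted(ev.inclusion)),
                "exclusion_junctions": ";".join(f"{d}-{a}" for d, a in sorted(ev.exclusion)),
                f"mean_ratio_{g1}": res.group_means[g1],
                f"mean_ratio_{g2}": res.group_means[g2],
                "delta_ratio": res.delta_ratio,
                "t": res.t_statistic,
                "p_value": res.p_value,
                "fdr": res.fdr,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
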
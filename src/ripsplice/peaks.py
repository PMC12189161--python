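"""Sliding-window peak calling with a within-gene permutation null.

The scan walks fixed windows (default 5 bp window, 5 bp step).  A candidate
peak starts at the first window of a run of ``run_length`` consecutive
windows whose per-window mean depth each exceed ``start_fold`` times the
gene baseline, or whose pooled per-base median depth exceeds
``median_start``.  The candidate then extends window by window and terminates
when the mean depth over the trailing ``run_length`` windows drops below
``stop_fraction`` of the running peak maximum; the terminating segment is
excluded from the final peak.

Significance comes from repositioning the gene's reads uniformly at random
``n_shuffles`` times and comparing the observed peak maximum depth with the
shuffled maximum-depth distribution.  Peaks are retained when p < ``p_cut``
or maximum depth >= ``depth_rescue``, and called enriched when the
library-normalized IP/input read-count ratio reaches ``enrich_fold``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ripsplice.core_io import GeneModel, GenomicInterval


@dataclass
class PeakCallerParams:
    window: int = 5
    step: int = 5
    start_fold: float = 2.5
    run_length: int = 8
    median_start: float = 50.0
    stop_fraction: float = 0.04
    n_shuffles: int = 500
    p_cut: float = 0.05
    depth_rescue: float = 10.0
    enrich_fold: float = 4.0
    baseline_floor: float = 0.5   # per-base depth floor for the gene baseline
    baseline_method: str = "median"  # "median" (robust to the peaks themselves) | "mean"
    input_pseudo_reads: float = 1.0  # pseudo-floor (reads) for empty-input peaks

    def __post_init__(self) -> None:
        positive = {
            "window": self.window, "step": self.step, "start_fold": self.start_fold,
            "run_length": self.run_length, "median_start": self.median_start,
            "n_shuffles": self.n_shuffles, "depth_rescue": self.depth_rescue,
            "enrich_fold": self.enrich_fold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 < self.stop_fraction < 1:
            raise ValueError(f"stop_fraction must be in (0, 1), got {self.stop_fraction}")
        if not 0 < self.p_cut < 1:
            raise ValueError(f"p_cut must be in (0, 1), got {self.p_cut}")
        if self.baseline_method not in ("median", "mean"):
            raise ValueError(f"baseline_method must be median or mean, got {self.baseline_method!r}")


@dataclass
class CoverageProfile:
    """Per-base read depth over one gene's genomic span."""

    gene_id: str
    depth: np.ndarray
    n_reads: int
    offset: int = 0          # genomic coordinate of depth[0]
    chrom: str = "chrS"
    strand: str = "+"
    read_lengths: tuple[int, ...] = ()
    n_clipped: int = 0       # reads that extended past the gene bounds

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("coverage depth must be non-negative")


@dataclass
class Peak:
    gene_id: str
    interval: GenomicInterval
    max_depth: float
    median_depth: float
    p_value: float = float("nan")
    retained: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.max_depth < self.median_depth:
            raise ValueError("peak max_depth must be >= median_depth")

    @property
    def score(self) -> float:
        """BED score: max depth scaled into [0, 1000]."""
        return min(self.max_depth, 1000.0)


@dataclass
class EnrichedPeak:
    peak: Peak
    ip_count: float          # reads overlapping the peak, per million IP reads
    input_count: float       # reads overlapping the peak, per million input reads
    enrichment: float
    is_enriched: bool
    input_was_zero: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return self.peak.interval

    @property
    def name(self) -> str:
        return self.peak.name

    @property
    def score(self) -> float:
        return self.peak.score


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def build_coverage(reads: pd.DataFrame | Iterable[tuple[int, int]],
                   model: GeneModel) -> CoverageProfile:
    """Per-base depth over the gene from absolute-coordinate read intervals.

    Reads extending past the gene are counted over the overlap only and
    tallied in ``n_clipped``.
    """
    if isinstance(reads, pd.DataFrame):
        pairs = list(zip(reads["start"].astype(int), reads["end"].astype(int)))
    else:
        pairs = [(int(s), int(e)) for s, e in reads]
    g0, g1 = model.interval.start, model.interval.end
    length = g1 - g0
    diff = np.zeros(length + 1, dtype=float)
    n_clipped = 0
    lengths = []
    for start, end in pairs:
        lengths.append(end - start)
        s, e = max(start, g0), min(end, g1)
        if s >= e:
            n_clipped += 1
            continue
        if start < g0 or end > g1:
            n_clipped += 1
        diff[s - g0] += 1
        diff[e - g0] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(
        gene_id=model.gene_id,
        depth=depth,
        n_reads=len(pairs),
        offset=g0,
        chrom=model.interval.chrom,
        strand=model.interval.strand,
        read_lengths=tuple(lengths),
        n_clipped=n_clipped,
    )


def gene_baseline(profile: CoverageProfile, params: PeakCallerParams) -> float:
    """Gene-local baseline depth, floored to avoid zero blowups.

    The median (default) estimates the background level robustly even when a
    strong peak occupies a sizable fraction of the gene; ``mean`` is available
    for the naive definition.
    """
    if profile.depth.size == 0:
        return params.baseline_floor
    stat = np.median if params.baseline_method == "median" else np.mean
    return max(float(stat(profile.depth)), params.baseline_floor)


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------


def scan_candidate_peaks(
    profile: CoverageProfile,
    params: PeakCallerParams,
    baseline: float | None = None,
) -> list[Peak]:
    """Run the sliding-window state machine over one coverage profile."""
    depth = profile.depth
    L = depth.size
    w, step, run = params.window, params.step, params.run_length
    if L < w:
        return []
    n_windows = (L - w) // step + 1
    if baseline is None:
        baseline = gene_baseline(profile, params)
    start_thresh = params.start_fold * baseline

    # per-window mean depth via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    starts = np.arange(n_windows) * step
    win_means = (csum[starts + w] - csum[starts]) / w
    above = win_means > start_thresh

    def segment_bases(w_first: int, w_last: int) -> np.ndarray:
        return depth[w_first * step: w_last * step + w]

    peaks: list[Peak] = []
    i = 0
    while i + run <= n_windows:
        start_by_fold = bool(above[i: i + run].all())
        start_by_median = (
            float(np.median(segment_bases(i, i + run - 1))) > params.median_start
        )
        if not (start_by_fold or start_by_median):
            i += 1
            continue
        # candidate starts at window i; extend from window i+run onwards
        j = i + run
        running_max = float(segment_bases(i, j - 1).max())
        terminated = False
        while j < n_windows:
            running_max = max(running_max, float(segment_bases(j, j).max()))
            trailing_mean = float(segment_bases(j - run + 1, j).mean())
            if trailing_mean < params.stop_fraction * running_max:
                terminated = True
                break
            j += 1
        last_w = (j - run) if terminated else (n_windows - 1)
        body = segment_bases(i, last_w)
        interval = GenomicInterval(
            profile.chrom,
            profile.offset + i * step,
            profile.offset + last_w * step + w,
            profile.strand,
        )
        peaks.append(
            Peak(
                gene_id=profile.gene_id,
                interval=interval,
                max_depth=float(body.max()),
                median_depth=float(np.median(body)),
                name=f"{profile.gene_id}_peak{len(peaks) + 1}",
            )
        )
        i = j + 1 if terminated else n_windows
    return peaks


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def shuffle_max_depths(
    gene_length: int,
    read_lengths: Sequence[int],
    params: PeakCallerParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Maximum per-base depth of each of ``n_shuffles`` uniform repositionings.

    Read count and read lengths are preserved; each read start is uniform over
    the positions keeping the read inside the gene.
    """
    S = params.n_shuffles
    if not read_lengths or gene_length <= 0:
        return np.zeros(S)
    diff = np.zeros((S, gene_length + 1), dtype=np.int32)
    for rl, count in sorted(Counter(int(r) for r in read_lengths).items()):
        rl_eff = min(rl, gene_length)
        starts = rng.integers(0, gene_length - rl_eff + 1, size=(S, count))
        rows = np.repeat(np.arange(S), count)
        flat = starts.ravel()
        np.add.at(diff, (rows, flat), 1)
        np.add.at(diff, (rows, flat + rl_eff), -1)
    depth = np.cumsum(diff[:, :-1], axis=1)
    return depth.max(axis=1).astype(float)


def permutation_pvalue(
    profile: CoverageProfile,
    peak: Peak,
    params: PeakCallerParams,
    rng: np.random.Generator,
    shuffle_stats: np.ndarray | None = None,
) -> float:
    """Permutation p-value for one peak: ``(1 + #{shuffled max >= observed}) / (1 + n)``.

    Zero reads or a zero-depth peak give p = 1 by convention.  Passing
    precomputed ``shuffle_stats`` lets all peaks of a gene share one shuffle
    set.
    """
    if profile.n_reads == 0 or peak.max_depth <= 0:
        return 1.0
    if shuffle_stats is None:
        shuffle_stats = shuffle_max_depths(
            profile.depth.size, profile.read_lengths, params, rng
        )
    n = shuffle_stats.size
    return float((1 + int((shuffle_stats >= peak.max_depth).sum())) / (1 + n))


def assign_pvalues(
    profile: CoverageProfile,
    peaks: list[Peak],
    params: PeakCallerParams,
    rng: np.random.Generator,
) -> list[Peak]:
    """Compute permutation p-values for all peaks of a gene with shared shuffles."""
    if not peaks:
        return []
    stats = None
    if profile.n_reads > 0 and any(p.max_depth > 0 for p in peaks):
        stats = shuffle_max_depths(profile.depth.size, profile.read_lengths, params, rng)
    return [
        dataclasses.replace(
            p, p_value=permutation_pvalue(profile, p, params, rng, stats)
        )
        for p in peaks
    ]


def retain_peaks(peaks: list[Peak], params: PeakCallerParams) -> list[Peak]:
    """Flag peaks retained by the p-value / maximum-depth rescue rule."""
    return [
        dataclasses.replace(
            p,
            retained=bool(p.p_value < params.p_cut or p.max_depth >= params.depth_rescue),
        )
        for p in peaks
    ]


# ---------------------------------------------------------------------------
# Enrichment vs input
# ---------------------------------------------------------------------------


def _overlap_count(reads: pd.DataFrame, interval: GenomicInterval) -> int:
    sel = (
        (reads["chrom"] == interval.chrom)
        & (reads["start"] < interval.end)
        & (reads["end"] > interval.start)
    )
    return int(sel.sum())


def enrichment_filter(
    peaks: list[Peak],
    ip_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    params: PeakCallerParams,
    ip_library_size: int | None = None,
    input_library_size: int | None = None,
) -> list[EnrichedPeak]:
    """Score peaks by library-normalized IP/input read-count ratio.

    Counts are scaled to reads per million of their own library.  An empty
    input count is replaced by the ``input_pseudo_reads`` floor (normalized),
    and the peak flagged ``input_was_zero``.
    """
    ip_n = len(ip_reads) if ip_library_size is None else ip_library_size
    input_n = len(input_reads) if input_library_size is None else input_library_size
    if ip_n == 0:
        raise ValueError("empty IP library: cannot compute enrichment")
    if input_n == 0:
        raise ValueError("empty input library: cannot compute enrichment")
    floor = params.input_pseudo_reads * 1e6 / input_n
    out = []
    for peak in peaks:
        ip_rpm = _overlap_count(ip_reads, peak.interval) * 1e6 / ip_n
        raw_input = _overlap_count(input_reads, peak.interval)
        input_rpm = raw_input * 1e6 / input_n
        enrichment = ip_rpm / max(input_rpm, floor)
        out.append(
            EnrichedPeak(
                peak=peak,
                ip_count=ip_rpm,
                input_count=input_rpm,
                enrichment=enrichment,
                is_enriched=bool(enrichment >= params.enrich_fold),
                input_was_zero=raw_input == 0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Replicate reproducibility and target genes
# ---------------------------------------------------------------------------


def call_targets(
    peaks_per_replicate: Mapping[str, list[EnrichedPeak]],
    mode: str = "intersection",
) -> tuple[set[str], list[EnrichedPeak]]:
    """Target genes from retained, enriched, replicate-reproducible peaks.

    ``intersection`` (default): a peak counts only if it overlaps (>= 1 bp) a
    surviving peak in every other IP replicate.  ``union``: every surviving
    peak counts.  Returns (target gene set, reproducible peaks from the first
    replicate's frame of reference).
    """
    if not peaks_per_replicate:
        raise ValueError("need at least one IP replicate")
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown reproducibility mode {mode!r}")
    surviving = {
        rep: [ep for ep in eps if ep.peak.retained and ep.is_enriched]
        for rep, eps in peaks_per_replicate.items()
    }
    reps = sorted(surviving)
    if mode == "union":
        kept = [ep for rep in reps for ep in surviving[rep]]
        return {ep.peak.gene_id for ep in kept}, kept

    anchor_rep = reps[0]
    reproducible = []
    for ep in surviving[anchor_rep]:
        if all(
            any(ep.interval.overlaps(other.interval) for other in surviving[rep])
            for rep in reps[1:]
        ):
            reproducible.append(ep)
    return {ep.peak.gene_id for ep in reproducible}, reproducible


# ---------------------------------------------------------------------------
# Orchestration over a whole dataset
# ---------------------------------------------------------------------------


def call_peaks(
    models: Sequence[GeneModel],
    ip_tables: Mapping[str, pd.DataFrame],
    input_tables: Mapping[str, pd.DataFrame],
    params: PeakCallerParams,
    rng: np.random.Generator,
    mode: str = "intersection",
) -> tuple[set[str], pd.DataFrame, dict[str, list[EnrichedPeak]]]:
    """Full peak-calling pass: per-replicate scan, permutation test, retention,
    enrichment against pooled input, and replicate-reproducible target calling.

    Returns (target gene set, flat per-peak report table, per-replicate peaks).
    """
    if not ip_tables:
        raise ValueError("empty IP library: no IP replicates supplied")
    pooled_input = (
        pd.concat(list(input_tables.values()), ignore_index=True)
        if input_tables
        else pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    input_n = len(pooled_input)

    per_rep: dict[str, list[EnrichedPeak]] = {}
    rows = []
    for rep in sorted(ip_tables):
        ip_df = ip_tables[rep]
        ip_n = len(ip_df)
        ip_by_gene = dict(tuple(ip_df.groupby("gene_id", sort=False)))
        enriched_all: list[EnrichedPeak] = []
        for model in models:
            gene_reads = ip_by_gene.get(
                model.gene_id,
                ip_df.iloc[0:0],
            )
            profile = build_coverage(gene_reads, model)
            candidates = scan_candidate_peaks(profile, params)
            if not candidates:
                continue
            candidates = assign_pvalues(profile, candidates, params, rng)
            candidates = retain_peaks(candidates, params)
            enriched = enrichment_filter(
                candidates, ip_df, pooled_input, params,
                ip_library_size=ip_n, input_library_size=input_n,
            )
            enriched_all.extend(enriched)
        per_rep[rep] = enriched_all
        for ep in enriched_all:
            rows.append(
                {
                    "replicate": rep,
                    "gene_id": ep.peak.gene_id,
                    "chrom": ep.interval.chrom,
                    "start": ep.interval.start,
                    "end": ep.interval.end,
                    "strand": ep.interval.strand,
                    "max_depth": ep.peak.max_depth,
                    "median_depth": ep.peak.median_depth,
                    "p_value": ep.peak.p_value,
                    "retained": ep.peak.retained,
                    "ip_rpm": ep.ip_count,
                    "input_rpm": ep.input_count,
                    "enrichment": ep.enrichment,
                    "is_enriched": ep.is_enriched,
                }
            )
    targets, _ = call_targets(per_rep, mode=mode)
    report = pd.DataFrame(
        rows,
        columns=[
            "replicate", "gene_id", "chrom", "start", "end", "strand",
            "max_depth", "median_depth", "p_value", "retained",
            "ip_rpm", "input_rpm", "enrichment", "is_enriched",
        ],
    )
    return targets, report, per_rep
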
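"""Synthetic-data generators for every input the pipeline consumes.

Every generator is deterministic under a fixed seed.  The default
configuration plants three IP-only coverage peaks (fold enrichments 5/10/20),
twelve splicing-ratio shifts spanning all nine event types, five
differentially expressed genes, two decay conditions, and exactly one gene
("the overlap gene") carrying a peak, a splicing shift and a DE signal
simultaneously.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ripsplice.core_io import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    JunctionCountTable,
    write_group_map,
    write_gtf,
    write_reads_table,
)

CHROM = "chrS"

EVENT_TYPES = (
    "cassetteExon",
    "ES",
    "A5SS",
    "A3SS",
    "MXE",
    "5pMXE",
    "3pMXE",
    "A5SS&ES",
    "A3SS&ES",
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PlantedPeak:
    gene_id: str
    offset: int          # bp from gene start
    width: int           # bp
    fold: float          # enrichment over local background mass
    ip_only: bool = True

    def __post_init__(self) -> None:
        # fold == 1 is allowed so null-calibration fixtures can be expressed
        if self.fold < 1:
            raise ValueError(f"planted peak fold must be >= 1, got {self.fold}")
        if self.width <= 0 or self.offset < 0:
            raise ValueError("planted peak offset/width must be non-negative/positive")


@dataclass
class SplicingDesign:
    gene_id: str
    event_type: str
    psi1: float          # inclusion ratio, group 1
    psi2: float          # inclusion ratio, group 2
    depth: float         # mean junction-spanning reads per sample

    def __post_init__(self) -> None:
        for psi in (self.psi1, self.psi2):
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"psi must be in [0, 1], got {psi}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass
class DEDesign:
    gene_id: str
    log2fc: float
    mean: float = 1000.0
    dispersion: float = 0.05


@dataclass
class DecayDesign:
    condition: str
    half_life: float     # minutes; math.inf for a no-decay series
    cv: float = 0.05
    n_replicates: int = 3
    time_points: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0)

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half-life must be > 0, got {self.half_life}")
        if any(t < 0 for t in self.time_points):
            raise ValueError("negative time point in decay design")
        if 0.0 not in self.time_points:
            raise ValueError("decay time points must include 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (3000, 4200)
    n_ip_replicates: int = 2
    n_input_replicates: int = 2
    n_group_replicates: int = 3        # per group, junction + count samples
    background_rate: float = 20.0      # expected reads per kb per sample (IP)
    input_background_rate: float | None = 400.0  # input libraries; None -> same as IP
    read_length: int = 50
    base_junction_depth: float = 100.0
    base_count_mean: float = 200.0
    count_dispersion: float = 0.05
    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    junction_design: list[SplicingDesign] = field(default_factory=list)
    de_design: list[DEDesign] = field(default_factory=list)
    decay_design: list[DecayDesign] = field(default_factory=list)
    planted_overlap_gene: str | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def default_config(seed: int = 0) -> SimulationConfig:
    """The smallest fixture exercising every pipeline branch."""
    overlap = "G001"
    splicing = [
        SplicingDesign(overlap, "cassetteExon", 0.20, 0.80, 300.0),
        SplicingDesign("G002", "ES", 0.30, 0.70, 200.0),
        SplicingDesign("G003", "A5SS", 0.30, 0.70, 200.0),
        SplicingDesign("G004", "A3SS", 0.30, 0.70, 200.0),
        SplicingDesign("G005", "MXE", 0.30, 0.70, 200.0),
        SplicingDesign("G006", "5pMXE", 0.30, 0.70, 200.0),
        SplicingDesign("G007", "3pMXE", 0.30, 0.70, 200.0),
        SplicingDesign("G008", "A5SS&ES", 0.30, 0.70, 200.0),
        SplicingDesign("G009", "A3SS&ES", 0.30, 0.70, 200.0),
        SplicingDesign("G010", "cassetteExon", 0.70, 0.30, 200.0),
        SplicingDesign("G011", "ES", 0.70, 0.30, 200.0),
        SplicingDesign("G012", "A5SS", 0.70, 0.30, 200.0),
    ]
    peaks = [
        PlantedPeak(overlap, offset=1500, width=300, fold=20.0),
        PlantedPeak("G013", offset=1300, width=1700, fold=5.0),
        PlantedPeak("G014", offset=1500, width=400, fold=10.0),
    ]
    de = [
        DEDesign(overlap, log2fc=3.0, mean=2000.0, dispersion=0.01),
        DEDesign("G015", log2fc=2.5, mean=2000.0, dispersion=0.01),
        DEDesign("G016", log2fc=-2.5, mean=2000.0, dispersion=0.01),
        DEDesign("G017", log2fc=2.0, mean=2000.0, dispersion=0.01),
        DEDesign("G018", log2fc=-2.0, mean=2000.0, dispersion=0.01),
    ]
    decay = [
        DecayDesign("control", half_life=60.31),
        DecayDesign("knockdown", half_life=47.82),
    ]
    return SimulationConfig(
        seed=seed,
        planted_peaks=peaks,
        junction_design=splicing,
        de_design=de,
        decay_design=decay,
        planted_overlap_gene=overlap,
    )


# ---------------------------------------------------------------------------
# Gene-topology builders
#
# All builders work in + orientation with gene-local coordinates; each returns
# (transcripts, truth) where truth records the event type and its
# inclusion/exclusion junction sets.  Junctions are intronic half-open
# intervals (donor = upstream exon end, acceptor = downstream exon start).
# ---------------------------------------------------------------------------


def _lens(rng: np.random.Generator, n: int, lo: int = 80, hi: int = 150) -> list[int]:
    return [int(v) for v in rng.integers(lo, hi + 1, size=n)]


def _introns(rng: np.random.Generator, n: int) -> list[int]:
    return [int(v) for v in rng.integers(60, 121, size=n)]


def _chain(pieces: list[int]) -> list[tuple[int, int]]:
    """Alternating exon/intron lengths -> exon coordinate pairs."""
    coords, pos = [], 0
    for i, ln in enumerate(pieces):
        if i % 2 == 0:
            coords.append((pos, pos + ln))
        pos += ln
    return coords


def _build_cassette(rng):
    e = _lens(rng, 3)
    i = _introns(rng, 2)
    (e1, e2, e3) = _chain([e[0], i[0], e[1], i[1], e[2]])
    txs = {"t1": [e1, e2, e3], "t2": [e1, e3]}
    truth = {
        "event_type": "cassetteExon",
        "inclusion": [(e1[1], e2[0]), (e2[1], e3[0])],
        "exclusion": [(e1[1], e3[0])],
        "region": (e2[0], e2[1]),
    }
    return txs, truth


def _build_es(rng):
    e = _lens(rng, 4)
    i = _introns(rng, 3)
    (e1, e2, e3, e4) = _chain([e[0], i[0], e[1], i[1], e[2], i[2], e[3]])
    txs = {"t1": [e1, e2, e3, e4], "t2": [e1, e4]}
    truth = {
        "event_type": "ES",
        "inclusion": [(e1[1], e2[0]), (e2[1], e3[0]), (e3[1], e4[0])],
        "exclusion": [(e1[1], e4[0])],
        "region": (e2[0], e3[1]),
    }
    return txs, truth


def _build_a5ss(rng):
    e = _lens(rng, 3)
    i = _introns(rng, 2)
    shift = int(rng.integers(30, 61))
    (e1_long, e2, e3) = _chain([e[0] + shift, i[0], e[1], i[1], e[2]])
    e1_short = (e1_long[0], e1_long[1] - shift)
    txs = {"t1": [e1_long, e2, e3], "t2": [e1_short, e2, e3]}
    truth = {
        "event_type": "A5SS",
        "inclusion": [(e1_long[1], e2[0])],
        "exclusion": [(e1_short[1], e2[0])],
        "region": (e1_short[1], e1_long[1]),
    }
    return txs, truth


def _build_a3ss(rng):
    e = _lens(rng, 3)
    i = _introns(rng, 2)
    shift = int(rng.integers(30, 61))
    (e1, e2_long, e3) = _chain([e[0], i[0], e[1] + shift, i[1], e[2]])
    e2_short = (e2_long[0] + shift, e2_long[1])
    txs = {"t1": [e1, e2_long, e3], "t2": [e1, e2_short, e3]}
    truth = {
        "event_type": "A3SS",
        "inclusion": [(e1[1], e2_long[0])],
        "exclusion": [(e1[1], e2_short[0])],
        "region": (e2_long[0], e2_short[0]),
    }
    return txs, truth


def _build_mxe(rng):
    e = _lens(rng, 4)
    i = _introns(rng, 3)
    (e1, ea, eb, e4) = _chain([e[0], i[0], e[1], i[1], e[2], i[2], e[3]])
    txs = {"t1": [e1, ea, e4], "t2": [e1, eb, e4]}
    truth = {
        "event_type": "MXE",
        "inclusion": [(e1[1], ea[0]), (ea[1], e4[0])],
        "exclusion": [(e1[1], eb[0]), (eb[1], e4[0])],
        "region": (ea[0], eb[1]),
    }
    return txs, truth


def _build_5pmxe(rng):
    e = _lens(rng, 4)
    i = _introns(rng, 3)
    (ea, eb, e2, e3) = _chain([e[0], i[0], e[1], i[1], e[2], i[2], e[3]])
    txs = {"t1": [ea, e2, e3], "t2": [eb, e2, e3]}
    truth = {
        "event_type": "5pMXE",
        "inclusion": [(ea[1], e2[0])],
        "exclusion": [(eb[1], e2[0])],
        "region": (ea[0], eb[1]),
    }
    return txs, truth


def _build_3pmxe(rng):
    e = _lens(rng, 4)
    i = _introns(rng, 3)
    (e1, e2, ea, eb) = _chain([e[0], i[0], e[1], i[1], e[2], i[2], e[3]])
    txs = {"t1": [e1, e2, ea], "t2": [e1, e2, eb]}
    truth = {
        "event_type": "3pMXE",
        "inclusion": [(e2[1], ea[0])],
        "exclusion": [(e2[1], eb[0])],
        "region": (ea[0], eb[1]),
    }
    return txs, truth


def _build_a5ss_es(rng):
    e = _lens(rng, 3)
    i = _introns(rng, 2)
    shift = int(rng.integers(30, 61))
    (e1_long, e2, e3) = _chain([e[0] + shift, i[0], e[1], i[1], e[2]])
    e1_short = (e1_long[0], e1_long[1] - shift)
    # exclusion skips e2 AND uses the shifted (short) donor
    txs = {"t1": [e1_long, e2, e3], "t2": [e1_short, e3]}
    truth = {
        "event_type": "A5SS&ES",
        "inclusion": [(e1_long[1], e2[0]), (e2[1], e3[0])],
        "exclusion": [(e1_short[1], e3[0])],
        "region": (e1_short[1], e2[1]),
    }
    return txs, truth


def _build_a3ss_es(rng):
    e = _lens(rng, 3)
    i = _introns(rng, 2)
    shift = int(rng.integers(30, 61))
    (e1, e2, e3_long) = _chain([e[0], i[0], e[1], i[1], e[2] + shift])
    e3_short = (e3_long[0] + shift, e3_long[1])
    # exclusion skips e2 AND lands on the shifted (short) acceptor
    txs = {"t1": [e1, e2, e3_long], "t2": [e1, e3_short]}
    truth = {
        "event_type": "A3SS&ES",
        "inclusion": [(e1[1], e2[0]), (e2[1], e3_long[0])],
        "exclusion": [(e1[1], e3_short[0])],
        "region": (e2[0], e3_short[0]),
    }
    return txs, truth


_BUILDERS = {
    "cassetteExon": _build_cassette,
    "ES": _build_es,
    "A5SS": _build_a5ss,
    "A3SS": _build_a3ss,
    "MXE": _build_mxe,
    "5pMXE": _build_5pmxe,
    "3pMXE": _build_3pmxe,
    "A5SS&ES": _build_a5ss_es,
    "A3SS&ES": _build_a3ss_es,
}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def simulate_gene_models(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict]:
    """Build a toy chromosome of non-overlapping genes.

    Genes named in ``junction_design`` get the topology of their designed
    event type; all remaining genes get a cassette-exon topology so that every
    gene carries exactly one (possibly null) testable event.  Returns the
    models plus a per-gene ground-truth dict with absolute coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = _gene_ids(config.n_genes)
    design_by_gene = {d.gene_id: d for d in config.junction_design}
    unknown = set(design_by_gene) - set(ids)
    if unknown:
        raise ValueError(f"junction_design names genes beyond n_genes: {sorted(unknown)}")

    lo, hi = config.gene_length_range
    models: list[GeneModel] = []
    truth: dict[str, dict] = {}
    offset = 1000
    for gene_id in ids:
        etype = design_by_gene[gene_id].event_type if gene_id in design_by_gene else "cassetteExon"
        txs_local, ev_local = _BUILDERS[etype](rng)
        topo_span = max(e[1] for exons in txs_local.values() for e in exons)
        # pad with a trailing non-exonic stretch so genes can host peaks
        pad_lo, pad_hi = max(lo - topo_span, 200), hi - topo_span
        if pad_hi <= pad_lo:
            raise ValueError(
                f"gene_length_range {config.gene_length_range} too small to host "
                f"the {etype} topology ({topo_span + 200} bp needed)"
            )
        length = topo_span + int(rng.integers(pad_lo, pad_hi))
        interval = GenomicInterval(CHROM, offset, offset + length, "+")
        transcripts = {
            f"{gene_id}.{tx}": [
                GenomicInterval(CHROM, offset + s, offset + e, "+") for s, e in exons
            ]
            for tx, exons in txs_local.items()
        }
        models.append(GeneModel(gene_id, interval, transcripts))
        truth[gene_id] = {
            "event_type": ev_local["event_type"],
            "inclusion": [(offset + d, offset + a) for d, a in ev_local["inclusion"]],
            "exclusion": [(offset + d, offset + a) for d, a in ev_local["exclusion"]],
            "region": (offset + ev_local["region"][0], offset + ev_local["region"][1]),
            "planted": gene_id in design_by_gene,
        }
        offset += length + 500
    return models, truth


def simulate_rip_reads(
    config: SimulationConfig,
    models: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate IP and input read-interval tables.

    Background reads are placed uniformly within each gene at
    ``Poisson(background_rate x gene_kb)`` per sample.  Planted peaks add
    ``Poisson(fold x background_rate x peak_kb)`` reads confined to the peak
    window — in IP samples only when ``ip_only`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    by_gene = {m.gene_id: m for m in models}
    for peak in config.planted_peaks:
        if peak.gene_id not in by_gene:
            raise ValueError(f"planted peak on unknown gene {peak.gene_id}")
        gene = by_gene[peak.gene_id]
        if peak.offset + peak.width > gene.length:
            raise ValueError(
                f"planted peak {peak.offset}+{peak.width} outside gene "
                f"{peak.gene_id} ({gene.length} bp)"
            )
        if peak.width < config.read_length:
            raise ValueError("planted peak narrower than the read length")

    samples = [f"IP_{i + 1}" for i in range(config.n_ip_replicates)] + [
        f"INPUT_{i + 1}" for i in range(config.n_input_replicates)
    ]
    peaks_by_gene: dict[str, list[PlantedPeak]] = {}
    for peak in config.planted_peaks:
        peaks_by_gene.setdefault(peak.gene_id, []).append(peak)

    rl = config.read_length
    input_rate = (
        config.background_rate
        if config.input_background_rate is None
        else config.input_background_rate
    )
    tables: dict[str, pd.DataFrame] = {}
    for sample in samples:
        is_ip = sample.startswith("IP_")
        bg_rate = config.background_rate if is_ip else input_rate
        rows: list[tuple[str, str, int, int, str]] = []
        for gene in models:
            span = gene.length
            n_bg = rng.poisson(bg_rate * span / 1000.0)
            if span > rl and n_bg > 0:
                starts = rng.integers(gene.interval.start, gene.interval.end - rl,
                                      size=n_bg)
                rows.extend(
                    (gene.gene_id, CHROM, int(s), int(s) + rl, gene.strand)
                    for s in starts
                )
            for peak in peaks_by_gene.get(gene.gene_id, ()):
                if peak.ip_only and not is_ip:
                    continue
                # floored at one read so peaks exist even on zero background
                local_mass = max(config.background_rate * peak.width / 1000.0, 1.0)
                n_pk = rng.poisson(peak.fold * local_mass)
                if n_pk > 0:
                    p_start = gene.interval.start + peak.offset
                    starts = rng.integers(p_start, p_start + peak.width - rl + 1,
                                          size=n_pk)
                    rows.extend(
                        (gene.gene_id, CHROM, int(s), int(s) + rl, gene.strand)
                        for s in starts
                    )
        tables[sample] = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    return tables


def simulate_junction_counts(
    config: SimulationConfig,
    models: list[GeneModel],
    truth: dict,
    rng: np.random.Generator | None = None,
) -> JunctionCountTable:
    """Simulate a two-group junction count table with planted ratio shifts.

    For each gene's event and each sample, the junction-spanning read total is
    drawn Poisson(depth) and split Binomial(total, psi_group) between the
    inclusion and exclusion junction sets; non-event junctions get independent
    Poisson(depth) counts.  Genes without a planted design use the same psi in
    both groups (a null event).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    design_by_gene = {d.gene_id: d for d in config.junction_design}
    k = config.n_group_replicates
    samples = [(f"ctrl_{i + 1}", "ctrl") for i in range(k)] + [
        (f"oe_{i + 1}", "oe") for i in range(k)
    ]
    groups = dict(samples)

    rows: list[tuple[str, int, int, str, int]] = []
    for gene in models:
        ev = truth[gene.gene_id]
        incl = [tuple(j) for j in ev["inclusion"]]
        excl = [tuple(j) for j in ev["exclusion"]]
        if gene.gene_id in design_by_gene:
            d = design_by_gene[gene.gene_id]
            psi = {"ctrl": d.psi1, "oe": d.psi2}
            depth = d.depth
        else:
            null_psi = float(rng.uniform(0.3, 0.7))
            psi = {"ctrl": null_psi, "oe": null_psi}
            depth = config.base_junction_depth
        other = sorted(gene.junctions() - set(incl) - set(excl))
        for sample_id, group in samples:
            total = rng.poisson(depth)
            n_incl = rng.binomial(total, psi[group]) if total > 0 else 0
            n_excl = total - n_incl
            for juncs, n in ((incl, n_incl), (excl, n_excl)):
                split = rng.multinomial(n, [1.0 / len(juncs)] * len(juncs))
                for (donor, acceptor), c in zip(juncs, split):
                    rows.append((gene.gene_id, donor, acceptor, sample_id, int(c)))
            for donor, acceptor in other:
                rows.append(
                    (gene.gene_id, donor, acceptor, sample_id, int(rng.poisson(depth)))
                )
    df = pd.DataFrame(rows, columns=["gene_id", "donor", "acceptor", "sample_id", "count"])
    return JunctionCountTable(df, groups)


def simulate_counts(
    config: SimulationConfig,
    models: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Simulate a negative-binomial count matrix with planted DE genes.

    NB counts via gamma-Poisson mixing: mean mu, variance mu + dispersion*mu^2.
    Group-2 ("oe") means are mu * 2**log2fc for designed genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    de_by_gene = {d.gene_id: d for d in config.de_design}
    k = config.n_group_replicates
    samples = [(f"ctrl_{i + 1}", "ctrl") for i in range(k)] + [
        (f"oe_{i + 1}", "oe") for i in range(k)
    ]
    groups = dict(samples)

    data: dict[str, np.ndarray] = {}
    gene_ids = [m.gene_id for m in models]
    base_means = config.base_count_mean * rng.lognormal(0.0, 0.5, size=len(gene_ids))
    counts = np.zeros((len(gene_ids), len(samples)), dtype=int)
    for gi, gene_id in enumerate(gene_ids):
        if gene_id in de_by_gene:
            d = de_by_gene[gene_id]
            mu1, disp = d.mean, d.dispersion
            mu2 = d.mean * 2.0 ** d.log2fc
        else:
            mu1 = mu2 = float(base_means[gi])
            disp = config.count_dispersion
        for si, (_, group) in enumerate(samples):
            mu = mu1 if group == "ctrl" else mu2
            if disp < 1e-12:
                lam = mu
            else:
                lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
            counts[gi, si] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[s for s, _ in samples])
    return CountMatrix(df, groups)


def simulate_decay(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate actinomycin-D chase time courses.

    ``rel_abundance(t) = exp(-ln2 * t / H) * noise`` with multiplicative
    lognormal noise of the configured CV (median 1).  The t=0 rows carry their
    own noisy draw; downstream fitting renormalizes per replicate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    rows = []
    for design in config.decay_design:
        sigma = float(np.sqrt(np.log1p(design.cv ** 2)))
        for rep in range(1, design.n_replicates + 1):
            for t in design.time_points:
                if np.isinf(design.half_life):
                    signal = 1.0
                else:
                    signal = float(np.exp(-np.log(2.0) * t / design.half_life))
                noise = float(rng.lognormal(0.0, sigma)) if design.cv > 0 else 1.0
                rows.append((design.condition, f"r{rep}", float(t), signal * noise))
    return pd.DataFrame(rows, columns=["condition", "replicate", "time_min", "rel_abundance"])


# ---------------------------------------------------------------------------
# Full fixture emission
# ---------------------------------------------------------------------------


def build_manifest(config: SimulationConfig, models: list[GeneModel], truth: dict) -> dict:
    by_gene = {m.gene_id: m for m in models}
    return {
        "seed": config.seed,
        "genes": [m.gene_id for m in models],
        "overlap_gene": config.planted_overlap_gene,
        "peaks": [
            {
                "gene_id": p.gene_id,
                "start": by_gene[p.gene_id].interval.start + p.offset,
                "end": by_gene[p.gene_id].interval.start + p.offset + p.width,
                "fold": p.fold,
                "ip_only": p.ip_only,
            }
            for p in config.planted_peaks
        ],
        "splicing": [
            {
                "gene_id": d.gene_id,
                "event_type": d.event_type,
                "psi1": d.psi1,
                "psi2": d.psi2,
                "depth": d.depth,
                "inclusion": [list(j) for j in truth[d.gene_id]["inclusion"]],
                "exclusion": [list(j) for j in truth[d.gene_id]["exclusion"]],
            }
            for d in config.junction_design
        ],
        "de": [dataclasses.asdict(d) for d in config.de_design],
        "decay": [dataclasses.asdict(d) for d in config.decay_design],
    }


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input under ``outdir``; returns the manifest.

    Emits: models.gtf, reads_<sample>.tsv, junctions.tsv, counts.tsv,
    decay.tsv, groups.json and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    models, truth = simulate_gene_models(config, rng)
    reads = simulate_rip_reads(config, models, rng)
    junctions = simulate_junction_counts(config, models, truth, rng)
    counts = simulate_counts(config, models, rng)
    decay = simulate_decay(config, rng)

    write_gtf(models, outdir / "models.gtf")
    for sample, table in reads.items():
        write_reads_table(table, outdir / f"reads_{sample}.tsv")
    junctions.df.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    counts.df.to_csv(outdir / "counts.tsv", sep="\t")
    decay.to_csv(outdir / "decay.tsv", sep="\t", index=False)
    write_group_map(junctions.groups, outdir / "groups.json")

    manifest = build_manifest(config, models, truth)
    manifest["read_samples"] = sorted(reads)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
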
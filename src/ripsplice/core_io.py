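"""Domain types and readers/writers for the formats used across the pipeline.

Internal coordinates are uniformly 0-based half-open (BED convention).  GTF is
1-based inclusive on disk; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _union_length(intervals: Iterable[GenomicInterval]) -> int:
    spans = sorted((iv.start, iv.end) for iv in intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in spans:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


@dataclass
class GeneModel:
    """An annotated gene: genomic span plus per-transcript exon chains.

    Exons within each transcript are stored sorted by genomic coordinate and
    must be non-overlapping; all exons must lie inside ``interval``.
    """

    gene_id: str
    interval: GenomicInterval
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for tx_id, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tx_id} of {self.gene_id} has no exons")
            prev_end = -1
            for exon in exons:
                if exon.start < prev_end:
                    raise ValueError(
                        f"exons of transcript {tx_id} overlap or are unsorted"
                    )
                if not self.interval.contains(exon):
                    raise ValueError(
                        f"exon {exon} of transcript {tx_id} outside gene "
                        f"interval {self.interval}"
                    )
                prev_end = exon.end
        if self.interval.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.interval.strand!r}")

    @property
    def exonic_length(self) -> int:
        """Length of the union of all exons across transcripts (bp)."""
        exons = [e for tx in self.transcripts.values() for e in tx]
        if not exons:
            return 0
        return _union_length(exons)

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    def all_exons(self) -> list[GenomicInterval]:
        """Unique exon intervals across transcripts, sorted genomically."""
        seen = {(e.start, e.end): e for tx in self.transcripts.values() for e in tx}
        return [seen[k] for k in sorted(seen)]

    def junctions(self) -> set[tuple[int, int]]:
        """Annotated junctions as intronic half-open intervals ``(donor, acceptor)``.

        ``donor`` is the first intronic base (= upstream exon end), ``acceptor``
        is one past the last intronic base (= downstream exon start).
        """
        juncs: set[tuple[int, int]] = set()
        for exons in self.transcripts.values():
            for a, b in zip(exons, exons[1:]):
                juncs.add((a.end, b.start))
        return juncs


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF2.2 file into :class:`GeneModel` objects.

    Only ``exon`` features are structurally required; ``gene``/``transcript``
    lines are tolerated.  1-based inclusive coordinates are converted to
    0-based half-open.  Malformed lines raise :class:`FormatError` naming the
    line number.
    """
    exons: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_spans: dict[str, GenomicInterval] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "gene"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}: line {lineno}: {feature} without gene_id")
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if gene_id not in exons:
                exons[gene_id] = {}
                gene_order.append(gene_id)
            if feature == "gene":
                gene_spans[gene_id] = iv
                continue
            tx_id = attributes.get("transcript_id")
            if not tx_id:
                raise FormatError(f"{path}: line {lineno}: exon without transcript_id")
            exons[gene_id].setdefault(tx_id, []).append(iv)

    models = []
    for gene_id in gene_order:
        txs = {
            tx: sorted(ivs, key=lambda iv: iv.start)
            for tx, ivs in exons[gene_id].items()
        }
        all_ivs = [iv for ivs in txs.values() for iv in ivs]
        if not all_ivs:
            raise FormatError(f"gene {gene_id}: no exon features")
        chroms = {iv.chrom for iv in all_ivs}
        strands = {iv.strand for iv in all_ivs}
        if len(chroms) != 1:
            raise FormatError(f"gene {gene_id}: exons span multiple chromosomes")
        if len(strands) != 1:
            raise FormatError(f"gene {gene_id}: exons on multiple strands")
        # the gene feature (when present) may extend past the exon span
        exon_span = GenomicInterval(
            chroms.pop(),
            min(iv.start for iv in all_ivs),
            max(iv.end for iv in all_ivs),
            strands.pop(),
        )
        interval = gene_spans.get(gene_id, exon_span)
        if not interval.contains(exon_span):
            raise FormatError(
                f"gene {gene_id}: exons extend past the annotated gene span"
            )
        models.append(GeneModel(gene_id, interval, txs))
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF2.2 (gene/transcript/exon features)."""
    with open(path, "w") as fh:
        for gene in models:
            iv = gene.interval
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{iv.chrom}\tripsplice\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for tx_id, exons in gene.transcripts.items():
                tx_attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
                tx_start = min(e.start for e in exons)
                tx_end = max(e.end for e in exons)
                fh.write(
                    f"{iv.chrom}\tripsplice\ttranscript\t{tx_start + 1}\t{tx_end}\t.\t"
                    f"{iv.strand}\t.\t{tx_attrs}\n"
                )
                for exon in exons:
                    fh.write(
                        f"{iv.chrom}\tripsplice\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{iv.strand}\t.\t{tx_attrs}\n"
                    )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(records: Sequence, path: str | Path, track_name: str | None = None) -> None:
    """Write BED6 lines for peak-like records.

    Each record must expose ``interval`` (:class:`GenomicInterval`), ``name``
    and ``score``; the score is clamped to [0, 1000] per the BED spec.
    """
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track name="{track_name}"\n')
        for rec in records:
            iv: GenomicInterval = rec.interval
            score = int(round(min(max(rec.score, 0), 1000)))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{score}\t{iv.strand}\n"
            )


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str
    score: float


def read_bed(path: str | Path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 BED fields")
            chrom, start, end, name, score, strand = fields[:6]
            records.append(
                BedRecord(GenomicInterval(chrom, int(start), int(end), strand), name, float(score))
            )
    return records


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def read_coverage_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into dense per-base depth arrays per chromosome.

    Positions not covered by any record have depth 0.  Overlapping records are
    ambiguous and rejected.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, start_s, end_s, value_s = fields
            start, end, value = int(start_s), int(end_s), float(value_s)
            if end <= start or start < 0:
                raise FormatError(f"{path}: line {lineno}: bad interval [{start}, {end})")
            spans.setdefault(chrom, []).append((start, end, value))

    profiles: dict[str, np.ndarray] = {}
    for chrom, recs in spans.items():
        recs.sort()
        prev_end = 0
        for start, end, _ in recs:
            if start < prev_end:
                raise FormatError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {start}"
                )
            prev_end = end
        depth = np.zeros(max(e for _, e, _ in recs), dtype=float)
        for start, end, value in recs:
            depth[start:end] = value
        profiles[chrom] = depth
    return profiles


def write_coverage_bedgraph(profiles: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write dense depth arrays as run-length-compressed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(profiles):
            depth = np.asarray(profiles[chrom])
            if depth.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [depth.size]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    out = int(v) if float(v).is_integer() else v
                    fh.write(f"{chrom}\t{s}\t{e}\t{out}\n")


# ---------------------------------------------------------------------------
# Tabular containers
# ---------------------------------------------------------------------------


@dataclass
class JunctionCountTable:
    """Junction read counts keyed by (gene_id, donor, acceptor, sample_id).

    ``df`` columns: gene_id, donor, acceptor, sample_id, count.  ``groups``
    maps each sample to one of exactly two group labels.
    """

    df: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        required = ["gene_id", "donor", "acceptor", "sample_id", "count"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"junction table missing columns: {missing}")
        if (self.df["count"] < 0).any():
            bad = self.df.index[self.df["count"] < 0][0]
            raise FormatError(f"junction table row {bad}: negative count")
        if (self.df["donor"] >= self.df["acceptor"]).any():
            bad = self.df.index[self.df["donor"] >= self.df["acceptor"]][0]
            raise FormatError(f"junction table row {bad}: donor must be < acceptor")
        unknown = set(self.df["sample_id"]) - set(self.groups)
        if unknown:
            raise FormatError(f"samples missing from group map: {sorted(unknown)}")
        if len(set(self.groups.values())) != 2:
            raise FormatError(
                f"group map must define exactly two groups, got {sorted(set(self.groups.values()))}"
            )

    @property
    def samples(self) -> list[str]:
        return sorted(self.groups)

    def count(self, gene_id: str, donor: int, acceptor: int, sample_id: str) -> int:
        sel = self.df[
            (self.df["gene_id"] == gene_id)
            & (self.df["donor"] == donor)
            & (self.df["acceptor"] == acceptor)
            & (self.df["sample_id"] == sample_id)
        ]
        return int(sel["count"].sum())

    def gene_counts(self, gene_id: str) -> pd.DataFrame:
        return self.df[self.df["gene_id"] == gene_id]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer fragment counts."""

    df: pd.DataFrame  # index: gene_id, columns: sample ids
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise FormatError("count matrix contains negative entries")
        zero_cols = [c for c in self.df.columns if self.df[c].sum() == 0]
        if zero_cols:
            raise FormatError(f"count matrix has zero-sum sample columns: {zero_cols}")
        unknown = set(self.df.columns) - set(self.groups)
        if unknown:
            raise FormatError(f"samples missing from group map: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def library_sizes(self) -> pd.Series:
        return self.df.sum(axis=0)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read the sample -> group JSON sidecar."""
    with open(path) as fh:
        groups = json.load(fh)
    if not isinstance(groups, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in groups.items()
    ):
        raise FormatError(f"{path}: group map must be a flat string->string JSON object")
    return groups


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(groups), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_junction_table(path: str | Path, groups: Mapping[str, str]) -> JunctionCountTable:
    """Read the junction TSV (gene_id/donor/acceptor/sample_id/count)."""
    df = _read_tsv(path, {"gene_id": str, "donor": int, "acceptor": int,
                          "sample_id": str, "count": int})
    return JunctionCountTable(df, dict(groups))


def read_count_matrix(path: str | Path, groups: Mapping[str, str]) -> CountMatrix:
    """Read the count TSV (gene_id + one integer column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: count matrix must have a gene_id column")
    df = df.set_index("gene_id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric counts in sample column {col}")
    return CountMatrix(df, dict(groups))


def read_decay_table(path: str | Path) -> pd.DataFrame:
    """Read the decay TSV (condition/replicate/time_min/rel_abundance)."""
    df = _read_tsv(
        path,
        {"condition": str, "replicate": str, "time_min": float, "rel_abundance": float},
    )
    if (df["time_min"] < 0).any():
        bad = df.index[df["time_min"] < 0][0]
        raise FormatError(f"{path}: row {bad}: negative time point")
    if (df["rel_abundance"] <= 0).any():
        bad = df.index[df["rel_abundance"] <= 0][0]
        raise FormatError(f"{path}: row {bad}: rel_abundance must be > 0")
    return df


def _read_tsv(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col, typ in schema.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col} not coercible to {typ.__name__}") from exc
    return df


def write_reads_table(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample read-interval table (gene_id/chrom/start/end/strand)."""
    reads.to_csv(path, sep="\t", index=False)


def read_reads_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, {"gene_id": str, "chrom": str, "start": int, "end": int,
                          "strand": str})
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise FormatError(f"{path}: row {bad}: empty or inverted read interval")
    return df
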
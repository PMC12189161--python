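"""Three-way evidence intersection and the end-to-end pipeline driver.

Candidate direct targets are genes appearing in all three evidence sets:
differentially expressed genes, genes with at least one significant splicing
event, and peak target genes.  The candidate ranking (peak enrichment, then
|delta ratio|, then |log2FC|) is an artifact convenience, not a claim from
the source analysis, and is labeled as such in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ripsplice import core_io, decay as decay_mod, expression, peaks as peaks_mod, splicing
from ripsplice.core_io import write_bed, write_group_map
from ripsplice.simulate import SimulationConfig, default_config, simulate_all


@dataclass
class EvidenceSets:
    deg_genes: set[str]
    rase_genes: set[str]
    peak_genes: set[str]
    annotation: set[str] | None = None

    def __post_init__(self) -> None:
        if self.annotation is not None:
            stray = (self.deg_genes | self.rase_genes | self.peak_genes) - self.annotation
            if stray:
                warnings.warn(
                    f"evidence genes absent from the annotation (retained): {sorted(stray)[:5]}"
                )


@dataclass
class IntegrationReport:
    region_counts: dict[str, int]         # 7 exclusive Venn regions
    candidates: list[str]                 # triple intersection, ranked
    ranking_note: str = (
        "candidate ranking (enrichment, |delta_ratio|, |log2fc|) is an artifact "
        "addition, not part of the source analysis"
    )
    scores: pd.DataFrame | None = field(default=None, repr=False)


def intersect_evidence(
    sets: EvidenceSets,
    peak_report: pd.DataFrame | None = None,
    rase_results: pd.DataFrame | None = None,
    de_table: pd.DataFrame | None = None,
) -> IntegrationReport:
    """Exact set algebra over the three evidence sets.

    Region keys name the member sets: e.g. ``deg_only``, ``deg_rase``,
    ``deg_rase_peak``.  When the upstream result tables are supplied, triple-
    intersection candidates are ranked by (max peak enrichment, max
    |delta_ratio|, |log2fc|), descending.
    """
    d, r, p = sets.deg_genes, sets.rase_genes, sets.peak_genes
    regions = {
        "deg_only": len(d - r - p),
        "rase_only": len(r - d - p),
        "peak_only": len(p - d - r),
        "deg_rase": len((d & r) - p),
        "deg_peak": len((d & p) - r),
        "rase_peak": len((r & p) - d),
        "deg_rase_peak": len(d & r & p),
    }
    triple = sorted(d & r & p)

    scores = None
    if triple:
        enr = {g: 0.0 for g in triple}
        dr = {g: 0.0 for g in triple}
        fc = {g: 0.0 for g in triple}
        if peak_report is not None and len(peak_report):
            sub = peak_report[peak_report["gene_id"].isin(triple)]
            enr.update(sub.groupby("gene_id")["enrichment"].max().to_dict())
        if rase_results is not None and len(rase_results):
            sub = rase_results[rase_results["gene_id"].isin(triple)]
            dr.update(sub.groupby("gene_id")["delta_ratio"].apply(lambda s: s.abs().max()).to_dict())
        if de_table is not None and len(de_table):
            sub = de_table.loc[de_table.index.intersection(triple)]
            fc.update(sub["log2fc"].abs().to_dict())
        scores = pd.DataFrame(
            {
                "gene_id": triple,
                "peak_enrichment": [enr[g] for g in triple],
                "abs_delta_ratio": [dr[g] for g in triple],
                "abs_log2fc": [fc[g] for g in triple],
            }
        ).sort_values(
            ["peak_enrichment", "abs_delta_ratio", "abs_log2fc", "gene_id"],
            ascending=[False, False, False, True],
        ).reset_index(drop=True)
        triple = list(scores["gene_id"])

    return IntegrationReport(region_counts=regions, candidates=triple, scores=scores)


def venn_table(report: IntegrationReport) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(report.region_counts.items()), columns=["region", "n_genes"]
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    targets: set[str]
    peak_report: pd.DataFrame
    rase_results: list
    rase_table: pd.DataFrame
    rase_summary: pd.Series
    de_table: pd.DataFrame
    decay_fits: pd.DataFrame
    report: IntegrationReport
    manifest: dict


def run_pipeline(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
    params: peaks_mod.PeakCallerParams | None = None,
) -> PipelineResult:
    """simulate -> callpeaks -> splice -> expr -> decay -> integrate.

    With no config, the default fixture at ``seed`` is used.  When ``outdir``
    is given, all stage outputs and a run manifest are written there.
    """
    if config is None:
        config = default_config(seed if seed is not None else 0)
    elif seed is not None:
        config.seed = seed
    params = params or peaks_mod.PeakCallerParams()

    import tempfile

    own_tmp = None
    if outdir is None:
        own_tmp = tempfile.TemporaryDirectory()
        outdir = own_tmp.name
    outdir = Path(outdir)
    try:
        manifest = simulate_all(config, outdir)
        models = core_io.read_gtf(outdir / "models.gtf")
        groups = core_io.read_group_map(outdir / "groups.json")
        ip_tables = {
            s: core_io.read_reads_table(outdir / f"reads_{s}.tsv")
            for s in manifest["read_samples"] if s.startswith("IP_")
        }
        input_tables = {
            s: core_io.read_reads_table(outdir / f"reads_{s}.tsv")
            for s in manifest["read_samples"] if s.startswith("INPUT_")
        }
        junctions = core_io.read_junction_table(outdir / "junctions.tsv", groups)
        counts = core_io.read_count_matrix(outdir / "counts.tsv", groups)
        decay_table = core_io.read_decay_table(outdir / "decay.tsv")

        rng = np.random.default_rng(config.seed + 10)
        targets, peak_report, per_rep = peaks_mod.call_peaks(
            models, ip_tables, input_tables, params, rng
        )

        events = []
        for model in models:
            graph = splicing.build_splice_graph(model, junctions)
            events.extend(splicing.detect_events(graph))
        results, _skipped = splicing.test_ratio_alteration(events, junctions)
        rase_df = splicing.rase_table(results)
        rase_genes = {r.event.gene_id for r in results if r.significant}
        summary = splicing.summarize_rase(results)

        de_table = expression.differential_expression(counts)
        deg = expression.deg_gene_set(de_table)

        decay_fits = decay_mod.fit_all_conditions(decay_table)

        sets = EvidenceSets(deg, rase_genes, targets, annotation={m.gene_id for m in models})
        report = intersect_evidence(sets, peak_report, rase_df, de_table)

        if own_tmp is None:
            peak_report.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
            _, reproducible = peaks_mod.call_targets(per_rep)
            write_bed(reproducible, outdir / "peaks.bed")
            rase_df.to_csv(outdir / "rase.tsv", sep="\t", index=False)
            summary.to_csv(outdir / "rase_counts.tsv", sep="\t")
            de_table.to_csv(outdir / "deg.tsv", sep="\t")
            decay_fits.to_csv(outdir / "halflife.tsv", sep="\t", index=False)
            venn_table(report).to_csv(outdir / "venn.tsv", sep="\t", index=False)
            pd.DataFrame({"gene_id": report.candidates}).to_csv(
                outdir / "candidates.tsv", sep="\t", index=False
            )
            run_manifest = {
                "seed": config.seed,
                "de_method": de_table.attrs.get("method"),
                "peak_params": vars(params),
                "stages": {
                    "peaks": "peaks.tsv",
                    "rase": "rase.tsv",
                    "deg": "deg.tsv",
                    "decay": "halflife.tsv",
                    "venn": "venn.tsv",
                    "candidates": "candidates.tsv",
                },
                "ranking_note": report.ranking_note,
            }
            with open(outdir / "run_manifest.json", "w") as fh:
                json.dump(run_manifest, fh, indent=1, default=str)
                fh.write("\n")
    finally:
        if own_tmp is not None:
            own_tmp.cleanup()

    return PipelineResult(
        targets=targets,
        peak_report=peak_report,
        rase_results=results,
        rase_table=rase_df,
        rase_summary=summary,
        de_table=de_table,
        decay_fits=decay_fits,
        report=report,
        manifest=manifest,
    )
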
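"""End-to-end orchestration: simulate/load → detect → DE → classify → survive.

Each stage writes its tables under the output directory and contributes to a
machine-readable summary whose counts are recomputable from those tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import detect, diffexp, risk
from .annotation import (
    ExpressionStudy,
    GenomeAnnotation,
    ProbeSelectionRegion,
    read_expression_study,
    read_gtf,
    read_psr_bed,
)
from .diffexp import AnalysisParams, Comparison, CONTINUUM_CELLS, VennCell
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("tspsr")


@dataclass
class PipelineConfig:
    out_dir: Path
    params: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: Optional[SimulationConfig] = None  # None -> load from paths below
    gtf: Optional[Path] = None
    bed: Optional[Path] = None
    meta: Optional[Path] = None
    matrix: Optional[Path] = None
    samples: Optional[Path] = None


@dataclass
class ReportSummary:
    catalog: dict
    de_counts: dict[str, int]
    venn_counts: dict[str, int]
    continuum_transcripts: list[str]
    concordance: dict
    coding_split: dict[str, int]
    fully_tested_resolution: dict[str, int]
    risk: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True, default=str)


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[GenomeAnnotation, list[ProbeSelectionRegion], ExpressionStudy]:
    if cfg.simulation is not None:
        sim = simulate_study(cfg.simulation)
        sim.write(Path(cfg.out_dir) / "fixtures")
        return sim.annotation, sim.psrs, sim.study
    missing = [
        name
        for name, p in (
            ("gtf", cfg.gtf),
            ("bed", cfg.bed),
            ("meta", cfg.meta),
            ("matrix", cfg.matrix),
            ("samples", cfg.samples),
        )
        if p is None
    ]
    if missing:
        raise ValueError(f"no simulation configured and missing inputs: {missing}")
    annotation = read_gtf(cfg.gtf)
    psrs = read_psr_bed(cfg.bed, cfg.meta)
    study = read_expression_study(
        cfg.matrix, cfg.samples, cfg.params.background_level, {p.psr_id for p in psrs}
    )
    return annotation, psrs, study


def run_pipeline(cfg: PipelineConfig) -> ReportSummary:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.params

    annotation, psrs, study = _load_inputs(cfg)
    log.info("inputs: %d genes, %d transcripts, %d PSRs, groups %s",
             len(annotation.genes), annotation.n_transcripts, len(psrs),
             study.group_sizes())

    # --- stage: TS-PSR detection
    catalog = detect.classify_psrs(psrs, annotation)
    detect.write_catalog(catalog, annotation, out)
    summary = detect.catalog_summary(catalog)
    log.info("catalog: %s", summary["status"])

    # --- stage: feature selection + per-comparison DE
    kept = sorted(catalog.kept_psr_ids() & set(study.matrix.index))
    analyzed = diffexp.background_filter(study, kept, params)
    log.info("background filter: %d kept PSRs -> %d analyzed", len(kept), len(analyzed))
    psr_to_tx = {p: t for p, t in catalog.psr_to_transcript().items() if p in set(analyzed)}
    tx_to_gene = annotation.transcript_parent()

    results: dict[Comparison, diffexp.ComparisonResult] = {}
    calls: dict[Comparison, dict[str, diffexp.TranscriptCall]] = {}
    for comp in Comparison:
        res = diffexp.compare_groups(study, analyzed, comp, params)
        res.table.to_csv(out / f"psr_results_{comp.value}.tsv", sep="\t", index_label="psr_id")
        results[comp] = res
        calls[comp] = diffexp.select_representative(res, psr_to_tx)
        log.info("%s: %d DE PSRs", comp.value, int(res.table["de"].sum()))

    tx_calls, venn_counts = diffexp.venn_categorize(
        calls[Comparison.NvsP], calls[Comparison.PvsM], calls[Comparison.NvsM], tx_to_gene
    )
    _write_transcript_calls(tx_calls, out / "transcript_calls.tsv")
    continuum = [
        c.transcript_id for c in tx_calls if c.continuum_category in CONTINUUM_CELLS
    ]

    de_anywhere = [c for c in tx_calls if c.continuum_category is not VennCell.NONE]
    biotype = {
        t.transcript_id: t.biotype
        for g in annotation.genes.values()
        for t in g.transcripts.values()
    }
    coding_split = {
        "coding": sum(1 for c in de_anywhere if biotype[c.transcript_id] == "protein_coding"),
        "noncoding": sum(1 for c in de_anywhere if biotype[c.transcript_id] != "protein_coding"),
    }

    concordance = diffexp.direction_concordance(tx_calls)
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "n_de_transcripts": g.n_de_transcripts,
                "concordant": int(g.concordant),
                "n_discordant_pairs": len(g.discordant_pairs),
            }
            for g in concordance
        ]
    ).to_csv(out / "gene_concordance.tsv", sep="\t", index=False)

    # --- stage: gene-level comparison on fully tested genes
    gene_matrix = diffexp.summarize_gene_level(
        study.matrix.loc[analyzed], {p: tx_to_gene[t] for p, t in psr_to_tx.items()}
    )
    fully_tested_multi = {
        g
        for g in catalog.fully_tested
        if catalog.gene_category[g] is not detect.GeneCategory.SINGLE_TRANSCRIPT
    }
    ft_de_tx = {
        c.gene_id
        for c in de_anywhere
        if c.gene_id in fully_tested_multi
    }
    gene_de: set[str] = set()
    if len(gene_matrix):
        gene_study = ExpressionStudy(
            matrix=gene_matrix, samples=study.samples, background_level=study.background_level
        )
        for comp in Comparison:
            res = diffexp.compare_groups(gene_study, list(gene_matrix.index), comp, params)
            gene_de |= set(res.de_ids())
    fully_tested_resolution = {
        "n_fully_tested_genes": len(fully_tested_multi),
        "n_with_de_transcript": len(ft_de_tx),
        "n_resolved_at_gene_level": len(ft_de_tx & gene_de),
    }

    # --- stage: risk stratification (primary samples must carry BCR data)
    risk_summary: dict = {}
    try:
        strat = risk.stratify(study, results[Comparison.NvsM], top_n=params.top_n_features)
        strat.predicted_class.rename("predicted_class").to_csv(
            out / "predicted_class.tsv", sep="\t", index_label="sample_id"
        )
        km_rows = []
        for group, table in strat.km.items():
            t = table.copy()
            t.insert(0, "group", group)
            km_rows.append(t)
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        risk_summary = {
            "n_metastasis_like": int((strat.predicted_class == risk.METASTASIS_LIKE).sum()),
            "n_normal_like": int((strat.predicted_class == risk.NORMAL_LIKE).sum()),
            "logrank": strat.logrank,
            "logistic": [
                {
                    "covariate": s.covariate,
                    "odds_ratio": s.odds_ratio,
                    "ci95": list(s.ci95),
                    "p": s.p,
                    "separation": s.separation,
                }
                for s in strat.logistic
            ],
        }
    except ValueError as exc:
        log.warning("risk stratification skipped: %s", exc)
        risk_summary = {"skipped": str(exc)}

    report = ReportSummary(
        catalog=summary,
        de_counts={
            comp.value: int(results[comp].table["de"].sum()) for comp in Comparison
        },
        venn_counts=venn_counts,
        continuum_transcripts=sorted(continuum),
        concordance={
            "n_genes_multi_de": len(concordance),
            "n_concordant": sum(1 for g in concordance if g.concordant),
        },
        coding_split=coding_split,
        fully_tested_resolution=fully_tested_resolution,
        risk=risk_summary,
    )
    (out / "summary.json").write_text(report.to_json())
    emit_group_medians(study, tx_calls, psr_to_tx, out / "group_medians.tsv")
    return report


def _write_transcript_calls(
    tx_calls: list[diffexp.TranscriptDECall], path: Path
) -> None:
    rows = []
    for c in tx_calls:
        row: dict = {
            "transcript_id": c.transcript_id,
            "gene_id": c.gene_id,
            "continuum_category": c.continuum_category.value,
        }
        for comp, call in c.per_comparison.items():
            row[f"{comp.value}_psr"] = call.psr_id
            row[f"{comp.value}_p"] = call.p
            row[f"{comp.value}_q"] = call.q
            row[f"{comp.value}_mfd"] = call.mfd
            row[f"{comp.value}_de"] = int(call.de)
            row[f"{comp.value}_direction"] = call.direction.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def emit_group_medians(
    study: ExpressionStudy,
    tx_calls: list[diffexp.TranscriptDECall],
    psr_to_tx: dict[str, str],
    path: Path,
) -> pd.DataFrame:
    """Per-group median expression of each DE transcript's representative PSRs
    (the table behind stage-progression heat maps)."""
    de_tx = {c.transcript_id for c in tx_calls if c.continuum_category is not VennCell.NONE}
    rows = []
    for c in tx_calls:
        if c.transcript_id not in de_tx:
            continue
        psr = c.per_comparison[Comparison.NvsM].psr_id
        rec = {"transcript_id": c.transcript_id, "psr_id": psr}
        for group in ("NORMAL", "PRIMARY", "METASTASIS"):
            rec[group] = float(study.matrix.loc[psr, study.group_ids(group)].median())
        rows.append(rec)
    table = pd.DataFrame(rows, columns=["transcript_id", "psr_id", "NORMAL", "PRIMARY", "METASTASIS"])
    table.to_csv(path, sep="\t", index=False)
    return table
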
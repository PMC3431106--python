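"""Transcript-specific PSR detection.

A probe selection region (PSR) is *transcript specific* when it intersects the
exons of exactly one annotated transcript on its own strand.  The exclusion
cascade applied to every PSR, in order:

1. probes do not align uniquely to the genome (``reliable`` flag unset);
2. not in the class-1 (non-cross-hybridizing) probe class;
3. not exonic at all, or exonic for two or more distinct transcripts;
4. intersects the exon hull of two or more same-strand genes (e.g. a PSR
   sitting inside another gene's intron);
5. the owning gene has only one annotated transcript, so the measurement is
   not isoform resolving;
6. the owning gene has several transcripts but only one of them retains any
   candidate PSR after steps 1–4, so no within-gene contrast is possible.

Survivors are the TS-PSRs used for transcript-level differential expression.
Testability in steps 5–6 is counted *after* the probe-level and multi-gene
filters: a transcript whose only unique PSR is unreliable cannot be tested.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .annotation import GenomeAnnotation, ProbeSelectionRegion


class PsrStatus(str, Enum):
    KEPT = "KEPT"
    EXCLUDED_NOT_EXONIC = "EXCLUDED_NOT_EXONIC"
    EXCLUDED_MULTI_TRANSCRIPT = "EXCLUDED_MULTI_TRANSCRIPT"
    EXCLUDED_UNRELIABLE = "EXCLUDED_UNRELIABLE"
    EXCLUDED_CROSSHYB = "EXCLUDED_CROSSHYB"
    EXCLUDED_SINGLE_TRANSCRIPT_GENE = "EXCLUDED_SINGLE_TRANSCRIPT_GENE"
    EXCLUDED_ONE_TESTABLE_GENE = "EXCLUDED_ONE_TESTABLE_GENE"
    EXCLUDED_MULTI_GENE_OVERLAP = "EXCLUDED_MULTI_GENE_OVERLAP"


class GeneCategory(str, Enum):
    SINGLE_TRANSCRIPT = "SINGLE_TRANSCRIPT"
    ONE_TESTABLE = "ONE_TESTABLE"
    MULTI_TESTABLE = "MULTI_TESTABLE"


class OverlapKind(str, Enum):
    UNIQUE = "UNIQUE"
    MULTI = "MULTI"
    NONE = "NONE"


@dataclass(frozen=True)
class OverlapCall:
    kind: OverlapKind
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None


@dataclass(frozen=True)
class TsPsrDisposition:
    psr_id: str
    status: PsrStatus
    # set whenever the PSR hits the exons of exactly one transcript,
    # regardless of why it may have been excluded
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None


@dataclass
class TsPsrCatalog:
    dispositions: list[TsPsrDisposition]
    gene_category: dict[str, GeneCategory]
    fully_tested: set[str]
    kept_by_transcript: dict[str, set[str]] = field(default_factory=dict)

    def by_status(self) -> dict[PsrStatus, int]:
        counts = Counter(d.status for d in self.dispositions)
        return {s: counts.get(s, 0) for s in PsrStatus}

    def kept_psr_ids(self) -> set[str]:
        return {d.psr_id for d in self.dispositions if d.status is PsrStatus.KEPT}

    def psr_to_transcript(self) -> dict[str, str]:
        """Transcript assignment for KEPT PSRs only."""
        return {
            d.psr_id: d.transcript_id
            for d in self.dispositions
            if d.status is PsrStatus.KEPT
        }


def find_unique_exonic_overlap(
    psr: ProbeSelectionRegion, annotation: GenomeAnnotation
) -> OverlapCall:
    """Resolve a PSR against same-strand exons.

    ``UNIQUE`` when the exons of exactly one transcript intersect it (partial
    overlap counts), ``MULTI`` for two or more distinct transcripts, ``NONE``
    when no exon intersects.
    """
    hits = annotation.query_exons(psr.chrom, psr.strand, psr.start, psr.end)
    transcripts = {tx for _, tx in hits}
    if not transcripts:
        return OverlapCall(OverlapKind.NONE)
    if len(transcripts) > 1:
        return OverlapCall(OverlapKind.MULTI)
    (gene_id, tx_id), = ((g, t) for g, t in hits)
    return OverlapCall(OverlapKind.UNIQUE, transcript_id=tx_id, gene_id=gene_id)


def classify_psrs(
    psrs: Iterable[ProbeSelectionRegion], annotation: GenomeAnnotation
) -> TsPsrCatalog:
    """Apply the exclusion cascade and derive per-gene testability."""
    psrs = list(psrs)
    known_chroms = {g.chrom for g in annotation.genes.values()}

    overlaps: dict[str, OverlapCall] = {}
    for p in psrs:
        if p.chrom not in known_chroms:
            warnings.warn(f"PSR {p.psr_id}: chromosome {p.chrom} absent from annotation")
            overlaps[p.psr_id] = OverlapCall(OverlapKind.NONE)
        else:
            overlaps[p.psr_id] = find_unique_exonic_overlap(p, annotation)

    # steps 1-4: probe-level and structural filters, yielding per-gene candidates
    prelim: dict[str, PsrStatus] = {}
    candidates_by_gene: dict[str, list[tuple[ProbeSelectionRegion, OverlapCall]]] = (
        defaultdict(list)
    )
    for p in psrs:
        call = overlaps[p.psr_id]
        if not p.reliable:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_UNRELIABLE
        elif not p.crosshyb_class1:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_CROSSHYB
        elif call.kind is OverlapKind.NONE:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_NOT_EXONIC
        elif call.kind is OverlapKind.MULTI:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_MULTI_TRANSCRIPT
        elif (
            len(annotation.query_gene_spans(p.chrom, p.strand, p.start, p.end)) >= 2
        ):
            prelim[p.psr_id] = PsrStatus.EXCLUDED_MULTI_GENE_OVERLAP
        else:
            candidates_by_gene[call.gene_id].append((p, call))

    # steps 5-6: gene-level testability among step-1-4 survivors
    testable_by_gene: dict[str, set[str]] = {
        gid: {c.transcript_id for _, c in pairs}
        for gid, pairs in candidates_by_gene.items()
    }
    dispositions: list[TsPsrDisposition] = []
    kept_by_transcript: dict[str, set[str]] = defaultdict(set)
    final: dict[str, PsrStatus] = dict(prelim)
    for gid, pairs in candidates_by_gene.items():
        n_tx = len(annotation.genes[gid].transcripts)
        if n_tx == 1:
            status = PsrStatus.EXCLUDED_SINGLE_TRANSCRIPT_GENE
        elif len(testable_by_gene[gid]) == 1:
            status = PsrStatus.EXCLUDED_ONE_TESTABLE_GENE
        else:
            status = PsrStatus.KEPT
        for p, call in pairs:
            final[p.psr_id] = status
            if status is PsrStatus.KEPT:
                kept_by_transcript[call.transcript_id].add(p.psr_id)

    for p in psrs:
        call = overlaps[p.psr_id]
        dispositions.append(
            TsPsrDisposition(
                psr_id=p.psr_id,
                status=final[p.psr_id],
                transcript_id=call.transcript_id,
                gene_id=call.gene_id,
            )
        )

    gene_category: dict[str, GeneCategory] = {}
    fully_tested: set[str] = set()
    for gid, gene in annotation.genes.items():
        n_tx = len(gene.transcripts)
        testable = testable_by_gene.get(gid, set())
        if n_tx == 1:
            gene_category[gid] = GeneCategory.SINGLE_TRANSCRIPT
        elif len(testable) >= 2:
            gene_category[gid] = GeneCategory.MULTI_TESTABLE
        else:
            gene_category[gid] = GeneCategory.ONE_TESTABLE
        if testable and testable == set(gene.transcripts):
            fully_tested.add(gid)

    return TsPsrCatalog(
        dispositions=dispositions,
        gene_category=gene_category,
        fully_tested=fully_tested,
        kept_by_transcript=dict(kept_by_transcript),
    )


def catalog_summary(catalog: TsPsrCatalog) -> dict:
    """Count table over dispositions, gene categories and fully-tested genes."""
    status_counts = {s.value: n for s, n in catalog.by_status().items()}
    category_counts = Counter(c.value for c in catalog.gene_category.values())
    kept = catalog.kept_psr_ids()
    return {
        "n_psrs": len(catalog.dispositions),
        "status": status_counts,
        "gene_category": {c.value: category_counts.get(c.value, 0) for c in GeneCategory},
        "n_kept": len(kept),
        "n_kept_transcripts": len(catalog.kept_by_transcript),
        "n_kept_genes": len(
            {
                d.gene_id
                for d in catalog.dispositions
                if d.status is PsrStatus.KEPT
            }
        ),
        "n_fully_tested_genes": len(catalog.fully_tested),
        "n_fully_tested_multi_transcript": len(
            {
                g
                for g in catalog.fully_tested
                if catalog.gene_category[g] is not GeneCategory.SINGLE_TRANSCRIPT
            }
        ),
    }


def write_catalog(
    catalog: TsPsrCatalog, annotation: GenomeAnnotation, out_dir: str | Path
) -> None:
    """Emit the PSR-level and gene-level disposition tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "psr_id": d.psr_id,
                "status": d.status.value,
                "transcript_id": d.transcript_id or "",
                "gene_id": d.gene_id or "",
            }
            for d in catalog.dispositions
        ]
    ).to_csv(out_dir / "psr_dispositions.tsv", sep="\t", index=False)

    testable_count = defaultdict(int)
    for tx, psr_ids in catalog.kept_by_transcript.items():
        if psr_ids:
            testable_count[tx] = len(psr_ids)
    parent = annotation.transcript_parent()
    kept_tx_by_gene = defaultdict(set)
    for tx in catalog.kept_by_transcript:
        kept_tx_by_gene[parent[tx]].add(tx)
    pd.DataFrame(
        [
            {
                "gene_id": gid,
                "n_transcripts": len(annotation.genes[gid].transcripts),
                "n_testable_transcripts": len(kept_tx_by_gene.get(gid, set())),
                "category": catalog.gene_category[gid].value,
                "fully_tested": int(gid in catalog.fully_tested),
            }
            for gid in sorted(annotation.genes)
        ]
    ).to_csv(out_dir / "gene_categories.tsv", sep="\t", index=False)
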
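"""Genome annotation, probe and expression I/O.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
conversion to/from the 1-based inclusive GTF convention happens only at the
file boundary.  Overlap throughout the package means an intersection of at
least one base on the same strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from intervaltree import IntervalTree

PROTEIN_CODING = "protein_coding"
NONCODING = "noncoding"

GROUPS = ("NORMAL", "PRIMARY", "METASTASIS")


class AnnotationError(ValueError):
    """Raised when an input file violates the annotation data model."""


@dataclass
class Transcript:
    transcript_id: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def span(self) -> tuple[int, int]:
        """Min-to-max exon hull over all transcripts (introns included)."""
        starts, ends = zip(*(t.span() for t in self.transcripts.values()))
        return min(starts), max(ends)


class GenomeAnnotation:
    """Gene → transcript → exon hierarchy with strand-aware interval indexes.

    The exon index maps a query interval to the ``(gene_id, transcript_id)``
    pairs whose exons it intersects; the span index maps it to the genes whose
    exon hull it intersects.  Both are strand specific.
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._validate()
        self._exon_index: dict[tuple[str, str], IntervalTree] | None = None
        self._span_index: dict[tuple[str, str], IntervalTree] | None = None

    def _validate(self) -> None:
        seen_tx: dict[str, str] = {}
        for g in self.genes.values():
            if g.strand not in "+-":
                raise AnnotationError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            if not g.transcripts:
                raise AnnotationError(f"gene {g.gene_id} has no transcripts")
            for t in g.transcripts.values():
                if t.transcript_id in seen_tx:
                    raise AnnotationError(
                        f"transcript {t.transcript_id} assigned to both "
                        f"{seen_tx[t.transcript_id]} and {g.gene_id}"
                    )
                seen_tx[t.transcript_id] = g.gene_id
                if not t.exons:
                    raise AnnotationError(f"transcript {t.transcript_id} has no exons")
                for s, e in t.exons:
                    if not s < e:
                        raise AnnotationError(
                            f"transcript {t.transcript_id}: exon [{s},{e}) is empty"
                        )

    # -- lookups ---------------------------------------------------------

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def transcript_parent(self) -> dict[str, str]:
        return {
            t: g.gene_id for g in self.genes.values() for t in g.transcripts
        }

    def _build_indexes(self) -> None:
        exon_idx: dict[tuple[str, str], IntervalTree] = {}
        span_idx: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            key = (g.chrom, g.strand)
            span_idx.setdefault(key, IntervalTree())[slice(*g.span())] = g.gene_id
            tree = exon_idx.setdefault(key, IntervalTree())
            for t in g.transcripts.values():
                for s, e in t.exons:
                    tree[s:e] = (g.gene_id, t.transcript_id)
        self._exon_index = exon_idx
        self._span_index = span_idx

    def query_exons(
        self, chrom: str, strand: str, start: int, end: int
    ) -> set[tuple[str, str]]:
        """(gene_id, transcript_id) pairs with a same-strand exon hitting [start,end)."""
        if self._exon_index is None:
            self._build_indexes()
        tree = self._exon_index.get((chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def query_gene_spans(
        self, chrom: str, strand: str, start: int, end: int
    ) -> set[str]:
        """Genes whose same-strand exon hull intersects [start,end)."""
        if self._span_index is None:
            self._build_indexes()
        tree = self._span_index.get((chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


@dataclass(frozen=True)
class ProbeSelectionRegion:
    """Genomic footprint of one exon-array probe set plus its probe metadata."""

    psr_id: str
    chrom: str
    strand: str
    start: int
    end: int
    reliable: bool
    crosshyb_class1: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"PSR {self.psr_id}: [{self.start},{self.end}) empty")
        if self.strand not in "+-":
            raise AnnotationError(f"PSR {self.psr_id}: bad strand {self.strand!r}")


@dataclass
class SampleRecord:
    sample_id: str
    group: str
    bcr_time: Optional[float] = None
    bcr_event: Optional[bool] = None
    nomogram_prob: Optional[float] = None


@dataclass
class ExpressionStudy:
    """Normalized log2 PSR-by-sample matrix with the three-group sample sheet."""

    matrix: pd.DataFrame  # rows: psr_id, columns: sample_id
    samples: list[SampleRecord]
    background_level: float

    def __post_init__(self) -> None:
        by_id = {s.sample_id: s for s in self.samples}
        if len(by_id) != len(self.samples):
            raise AnnotationError("duplicate sample ids in sample sheet")
        missing = set(self.matrix.columns) - set(by_id)
        if missing:
            raise AnnotationError(f"matrix samples not in sheet: {sorted(missing)}")
        extra = set(by_id) - set(self.matrix.columns)
        if extra:
            raise AnnotationError(f"sheet samples not in matrix: {sorted(extra)}")
        for s in self.samples:
            if s.group not in GROUPS:
                raise AnnotationError(f"sample {s.sample_id}: unknown group {s.group}")
            if s.group == "PRIMARY" and (s.bcr_time is None or s.bcr_event is None):
                raise AnnotationError(
                    f"PRIMARY sample {s.sample_id} lacks bcr_time/bcr_event"
                )
            if s.bcr_time is not None and s.bcr_time < 0:
                raise AnnotationError(f"sample {s.sample_id}: negative bcr_time")
            if s.nomogram_prob is not None and not 0 <= s.nomogram_prob <= 1:
                raise AnnotationError(f"sample {s.sample_id}: nomogram_prob outside [0,1]")
        if self.matrix.isna().any().any():
            raise AnnotationError("expression matrix contains missing values")

    def group_ids(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.group_ids(g)) for g in GROUPS}

    def primary_records(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.group == "PRIMARY"]


# ---------------------------------------------------------------------------
# GTF


def _prescan_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from None
            if fields[2] == "exon" and end < start:
                raise AnnotationError(f"{path}:{lineno}: exon end {end} < start {start}")


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read a GTF into the internal hierarchy.

    Exon records carrying ``gene_id``/``transcript_id`` attributes define the
    hierarchy; ``gene``/``transcript`` records are permitted and ignored.
    GTF's 1-based inclusive coordinates become 0-based half-open
    (``start-1``, ``end`` unchanged).  Any ``transcript_biotype`` other than
    ``protein_coding`` is collapsed to ``noncoding``; a missing attribute
    defaults to ``protein_coding``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks {exc} attribute"
            ) from None
        biotype_raw = feat.attributes.get("transcript_biotype", [PROTEIN_CODING])[0]
        biotype = PROTEIN_CODING if biotype_raw == PROTEIN_CODING else NONCODING
        gene = genes.setdefault(gene_id, Gene(gene_id, feat.seqid, feat.strand))
        if (feat.seqid, feat.strand) != (gene.chrom, gene.strand):
            raise AnnotationError(
                f"exon of {tx_id} at {feat.seqid}{feat.strand} disagrees with "
                f"gene {gene_id} at {gene.chrom}{gene.strand}"
            )
        tx = gene.transcripts.setdefault(tx_id, Transcript(tx_id, biotype))
        tx.exons.append((feat.start - 1, feat.end))  # 1-based incl -> 0-based half-open
    for g in genes.values():
        for t in g.transcripts.values():
            t.exons.sort()
    return GenomeAnnotation(genes.values())


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon records (round-trip inverse of :func:`read_gtf`)."""
    lines = []
    for gene_id in sorted(annotation.genes):
        g = annotation.genes[gene_id]
        for tx_id in sorted(g.transcripts):
            t = g.transcripts[tx_id]
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            for s, e in t.exons:
                lines.append(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# PSR BED + metadata


def read_psr_bed(path: str | Path, metadata_path: str | Path) -> list[ProbeSelectionRegion]:
    """Read BED6 probe coordinates joined with the reliability metadata table.

    The metadata TSV must carry a row for every PSR (columns ``psr_id``,
    ``reliable``, ``crosshyb_class1`` with 0/1 values); a PSR without metadata
    is an error, never a default.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "psr_id", "score", "strand"],
        dtype={"chrom": str, "psr_id": str},
    )
    if bed["psr_id"].duplicated().any():
        dup = bed.loc[bed["psr_id"].duplicated(), "psr_id"].iloc[0]
        raise AnnotationError(f"duplicate psr_id {dup} in BED")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"psr_id": str})
    for col in ("psr_id", "reliable", "crosshyb_class1"):
        if col not in meta.columns:
            raise AnnotationError(f"metadata lacks column {col}")
    if meta["psr_id"].duplicated().any():
        dup = meta.loc[meta["psr_id"].duplicated(), "psr_id"].iloc[0]
        raise AnnotationError(f"duplicate psr_id {dup} in metadata")
    meta = meta.set_index("psr_id")
    psrs = []
    for row in bed.itertuples(index=False):
        if row.psr_id not in meta.index:
            raise AnnotationError(f"{row.psr_id} lacks metadata")
        m = meta.loc[row.psr_id]
        psrs.append(
            ProbeSelectionRegion(
                psr_id=row.psr_id,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                reliable=bool(int(m["reliable"])),
                crosshyb_class1=bool(int(m["crosshyb_class1"])),
            )
        )
    return psrs


def write_psr_bed(
    psrs: list[ProbeSelectionRegion], path: str | Path, metadata_path: str | Path
) -> None:
    with open(path, "w") as fh:
        for p in psrs:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.psr_id}\t0\t{p.strand}\n")
    with open(metadata_path, "w") as fh:
        fh.write("psr_id\treliable\tcrosshyb_class1\n")
        for p in psrs:
            fh.write(f"{p.psr_id}\t{int(p.reliable)}\t{int(p.crosshyb_class1)}\n")


# ---------------------------------------------------------------------------
# Expression study

_SHEET_COLS = ["sample_id", "group", "bcr_time", "bcr_event", "nomogram_prob"]


def read_expression_study(
    matrix_path: str | Path,
    samples_path: str | Path,
    background_level: float,
    known_psr_ids: Optional[set[str]] = None,
) -> ExpressionStudy:
    """Read a log2 expression TSV (rows PSRs, columns samples) and sample sheet."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    bad = matrix.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = next(zip(*bad.isna().values.nonzero()))
        raise AnnotationError(
            f"non-numeric expression at row {matrix.index[r]!r}, column {matrix.columns[c]!r}"
        )
    matrix = bad.astype(float)
    if known_psr_ids is not None:
        unknown = set(matrix.index) - known_psr_ids
        if unknown:
            raise AnnotationError(f"matrix rows not among known PSRs: {sorted(unknown)[:5]}")
    # numeric sheet columns parsed via float() for exact round trips
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    missing_cols = set(_SHEET_COLS) - set(sheet.columns)
    if missing_cols:
        raise AnnotationError(f"sample sheet lacks columns {sorted(missing_cols)}")
    samples = []
    for row in sheet.itertuples(index=False):
        samples.append(
            SampleRecord(
                sample_id=row.sample_id,
                group=row.group,
                bcr_time=None if pd.isna(row.bcr_time) else float(row.bcr_time),
                bcr_event=None if pd.isna(row.bcr_event) else bool(int(row.bcr_event)),
                nomogram_prob=None if pd.isna(row.nomogram_prob) else float(row.nomogram_prob),
            )
        )
    study = ExpressionStudy(matrix=matrix, samples=samples, background_level=background_level)
    sizes = study.group_sizes()
    if min(sizes.values()) == 0:
        warnings.warn(f"empty group in study: {sizes}")
    return study


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, samples_path: str | Path
) -> None:
    # default float repr keeps the round trip exact
    study.matrix.to_csv(matrix_path, sep="\t", index_label="psr_id")
    rows = []
    for s in study.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "bcr_time": "" if s.bcr_time is None else repr(s.bcr_time),
                "bcr_event": "" if s.bcr_event is None else int(s.bcr_event),
                "nomogram_prob": "" if s.nomogram_prob is None else repr(s.nomogram_prob),
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLS).to_csv(samples_path, sep="\t", index=False)
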
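"""Transcript-level differential expression across disease-stage contrasts.

Three pairwise contrasts span the progression continuum of the cohort design
(normal adjacent → primary tumor → metastasis):

* ``NvsP`` — normal adjacent vs primary (fold reported as primary/normal),
* ``PvsM`` — primary vs metastasis (metastasis/primary),
* ``NvsM`` — normal adjacent vs metastasis (metastasis/normal).

A PSR is called differentially expressed in a contrast when its BH-adjusted
pooled-t p-value falls below the FDR threshold and its median fold difference
(MFD) is at least the fold threshold in either direction.  The MFD is the
linear-scale ratio of group medians, ``2**(median_B - median_A)`` on log2
data, so the stagewise folds compose multiplicatively:
``mfd(N→P) * mfd(P→M) == mfd(N→M)`` exactly, row by row.

Per transcript and contrast, the significant TS-PSR with the lowest p-value
represents the transcript (ties broken by larger |log2 MFD|, then id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExpressionStudy


class Comparison(str, Enum):
    NvsP = "NvsP"
    PvsM = "PvsM"
    NvsM = "NvsM"

    @property
    def groups(self) -> tuple[str, str]:
        """(earlier stage, later stage); MFD is later over earlier."""
        return {
            Comparison.NvsP: ("NORMAL", "PRIMARY"),
            Comparison.PvsM: ("PRIMARY", "METASTASIS"),
            Comparison.NvsM: ("NORMAL", "METASTASIS"),
        }[self]


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


class VennCell(str, Enum):
    """Membership pattern across the three pairwise contrasts."""

    NvsP_ONLY = "NvsP_only"
    PvsM_ONLY = "PvsM_only"
    NvsM_ONLY = "NvsM_only"
    NvsP_PvsM = "NvsP_PvsM"  # the primary-stage pair: DE flanking primary, not N vs M
    NvsP_NvsM = "NvsP_NvsM"
    PvsM_NvsM = "PvsM_NvsM"
    ALL_THREE = "all_three"
    NONE = "none"


#: cells interpreted as a continuum of disease progression
CONTINUUM_CELLS = (VennCell.ALL_THREE, VennCell.NvsP_PvsM)


@dataclass
class AnalysisParams:
    fdr_threshold: float = 0.05
    mfd_threshold: float = 1.2
    top_n_features: int = 100
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0,1)")
        if self.mfd_threshold < 1:
            raise ValueError("mfd_threshold must be >= 1")
        if self.top_n_features < 1:
            raise ValueError("top_n_features must be positive")


@dataclass
class ComparisonResult:
    comparison: Comparison
    table: pd.DataFrame  # index psr_id; columns t, p, q, mfd, de, direction
    params: AnalysisParams

    def de_ids(self) -> list[str]:
        return list(self.table.index[self.table["de"]])


@dataclass
class TranscriptCall:
    """Representative-PSR call for one transcript in one contrast."""

    transcript_id: str
    psr_id: str
    t: float
    p: float
    q: float
    mfd: float
    de: bool
    direction: Direction


@dataclass
class TranscriptDECall:
    transcript_id: str
    gene_id: str
    per_comparison: dict[Comparison, TranscriptCall]
    continuum_category: VennCell = VennCell.NONE


# ---------------------------------------------------------------------------
# elementary statistics


def background_filter(
    study: ExpressionStudy, psr_ids: Iterable[str], params: AnalysisParams
) -> list[str]:
    """Drop PSRs whose median is below background in all three tissue groups."""
    psr_ids = [p for p in psr_ids if p in study.matrix.index]
    sub = study.matrix.loc[psr_ids]
    below_all = np.ones(len(sub), dtype=bool)
    for group in ("NORMAL", "PRIMARY", "METASTASIS"):
        ids = study.group_ids(group)
        if not ids:
            raise ValueError(f"group {group} is empty")
        below_all &= sub[ids].median(axis=1).to_numpy() < params.background_level
    return [p for p, drop in zip(psr_ids, below_all) if not drop]


def row_ttest(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Rowwise two-sample pooled-variance t-test (two-sided).

    Rows with zero pooled variance get t=0, p=1 with a warning, matching the
    convention that a constant feature carries no evidence.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples for the pooled t-test")
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} rows with zero pooled variance; t=0, p=1")
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"t": t, "p": p}, index=matrix.index)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def median_fold_difference(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Linear-scale ratio of group medians (B over A) for log2 data."""
    if not len(group_a) or not len(group_b):
        raise ValueError("groups must be nonempty")
    med_a = matrix[list(group_a)].median(axis=1)
    med_b = matrix[list(group_b)].median(axis=1)
    return np.exp2(med_b - med_a).rename("mfd")


def call_de(stats_table: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Attach de/direction flags to a t/p/q/mfd table."""
    out = stats_table.copy()
    sig = out["q"] < params.fdr_threshold
    fold = (out["mfd"] >= params.mfd_threshold) | (out["mfd"] <= 1.0 / params.mfd_threshold)
    out["de"] = sig & fold
    out["direction"] = np.where(
        out["de"] & (out["mfd"] > 1),
        Direction.UP.value,
        np.where(out["de"] & (out["mfd"] < 1), Direction.DOWN.value, Direction.NONE.value),
    )
    return out


def compare_groups(
    study: ExpressionStudy,
    psr_ids: Sequence[str],
    comparison: Comparison,
    params: AnalysisParams,
) -> ComparisonResult:
    """Full per-PSR analysis of one pairwise contrast."""
    earlier, later = comparison.groups
    ids_a, ids_b = study.group_ids(earlier), study.group_ids(later)
    sub = study.matrix.loc[list(psr_ids)]
    table = row_ttest(sub, ids_a, ids_b)
    table["q"] = adjust_fdr(table["p"].to_numpy())
    table["mfd"] = median_fold_difference(sub, ids_a, ids_b)
    table = call_de(table, params)
    return ComparisonResult(comparison=comparison, table=table, params=params)


# ---------------------------------------------------------------------------
# transcript-level calls


def _representative_row(rows: pd.DataFrame) -> pd.Series:
    """Lowest p, ties by larger |log2 mfd|, then lexicographic psr_id."""
    key = pd.DataFrame(
        {
            "_p": rows["p"].to_numpy(),
            "_neg_abs_lfc": -np.abs(np.log2(rows["mfd"].to_numpy())),
            "_id": list(rows.index),
        },
        index=range(len(rows)),
    )
    best = rows.index[key.sort_values(["_p", "_neg_abs_lfc", "_id"]).index[0]]
    return rows.loc[best]


def select_representative(
    result: ComparisonResult, psr_to_transcript: Mapping[str, str]
) -> dict[str, TranscriptCall]:
    """Per-transcript representative call for one contrast.

    Among a transcript's significant PSRs the lowest-p one represents it; if
    none is significant the lowest-p PSR overall is reported with de=False.
    """
    table = result.table
    calls: dict[str, TranscriptCall] = {}
    tx_series = pd.Series(
        {p: psr_to_transcript[p] for p in table.index if p in psr_to_transcript}
    )
    for tx, psr_ids in tx_series.groupby(tx_series).groups.items():
        rows = table.loc[list(psr_ids)]
        sig = rows[rows["de"]]
        row = _representative_row(sig if len(sig) else rows)
        calls[tx] = TranscriptCall(
            transcript_id=tx,
            psr_id=str(row.name),
            t=float(row["t"]),
            p=float(row["p"]),
            q=float(row["q"]),
            mfd=float(row["mfd"]),
            de=bool(row["de"]),
            direction=Direction(row["direction"]),
        )
    return calls


def venn_categorize(
    calls_nvsp: Mapping[str, TranscriptCall],
    calls_pvsm: Mapping[str, TranscriptCall],
    calls_nvsm: Mapping[str, TranscriptCall],
    transcript_to_gene: Mapping[str, str],
) -> tuple[list[TranscriptDECall], dict[str, int]]:
    """Assign each transcript its Venn cell across the three contrasts.

    Returns all transcript calls (cell ``none`` for never-DE transcripts) and
    the count per cell over DE-anywhere transcripts.
    """
    universes = [set(calls_nvsp), set(calls_pvsm), set(calls_nvsm)]
    if not universes[0] == universes[1] == universes[2]:
        raise ValueError("transcript universes differ between comparisons")
    out: list[TranscriptDECall] = []
    counts = {cell.value: 0 for cell in VennCell if cell is not VennCell.NONE}
    for tx in sorted(universes[0]):
        per = {
            Comparison.NvsP: calls_nvsp[tx],
            Comparison.PvsM: calls_pvsm[tx],
            Comparison.NvsM: calls_nvsm[tx],
        }
        cell = venn_cell(per[Comparison.NvsP].de, per[Comparison.PvsM].de, per[Comparison.NvsM].de)
        if cell is not VennCell.NONE:
            counts[cell.value] += 1
        out.append(
            TranscriptDECall(
                transcript_id=tx,
                gene_id=transcript_to_gene[tx],
                per_comparison=per,
                continuum_category=cell,
            )
        )
    return out, counts


def venn_cell(de_nvsp: bool, de_pvsm: bool, de_nvsm: bool) -> VennCell:
    """Map three DE flags to their Venn cell."""
    pattern = (de_nvsp, de_pvsm, de_nvsm)
    return {
        (True, True, True): VennCell.ALL_THREE,
        (True, True, False): VennCell.NvsP_PvsM,
        (True, False, True): VennCell.NvsP_NvsM,
        (False, True, True): VennCell.PvsM_NvsM,
        (True, False, False): VennCell.NvsP_ONLY,
        (False, True, False): VennCell.PvsM_ONLY,
        (False, False, True): VennCell.NvsM_ONLY,
        (False, False, False): VennCell.NONE,
    }[pattern]


@dataclass
class GeneConcordance:
    gene_id: str
    n_de_transcripts: int
    concordant: bool
    discordant_pairs: list[tuple[str, str, Comparison]] = field(default_factory=list)


def direction_concordance(calls: Sequence[TranscriptDECall]) -> list[GeneConcordance]:
    """Within-gene direction agreement among DE sibling transcripts.

    Only genes with at least two DE-anywhere transcripts enter the
    denominator.  A gene is concordant when, within every contrast, all of
    its DE siblings move the same way.
    """
    by_gene: dict[str, list[TranscriptDECall]] = {}
    for c in calls:
        if c.continuum_category is not VennCell.NONE or any(
            tc.de for tc in c.per_comparison.values()
        ):
            by_gene.setdefault(c.gene_id, []).append(c)
    out = []
    for gene_id in sorted(by_gene):
        siblings = by_gene[gene_id]
        if len(siblings) < 2:
            continue
        discordant: list[tuple[str, str, Comparison]] = []
        for comp in Comparison:
            de_sibs = [s for s in siblings if s.per_comparison[comp].de]
            for i in range(len(de_sibs)):
                for j in range(i + 1, len(de_sibs)):
                    di = de_sibs[i].per_comparison[comp].direction
                    dj = de_sibs[j].per_comparison[comp].direction
                    if di is not dj:
                        discordant.append(
                            (de_sibs[i].transcript_id, de_sibs[j].transcript_id, comp)
                        )
        out.append(
            GeneConcordance(
                gene_id=gene_id,
                n_de_transcripts=len(siblings),
                concordant=not discordant,
                discordant_pairs=discordant,
            )
        )
    return out


def summarize_gene_level(
    matrix: pd.DataFrame, psr_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse PSR rows to a gene-by-sample matrix of per-sample medians.

    A deliberately simple consensus-gene summarization used to contrast
    transcript-level resolution with gene-level calls.
    """
    rows = [p for p in matrix.index if p in psr_to_gene]
    genes = pd.Series({p: psr_to_gene[p] for p in rows})
    return matrix.loc[rows].groupby(genes).median()
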
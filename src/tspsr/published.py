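"""Reference values reported for the GSE21034 HuEx prostate-cancer cohort.

The progression study on that cohort (29 normal adjacent, 131 primary,
19 metastatic arrays) reports, for the 28 transcripts differentially
expressed along the progression continuum, the stagewise median fold
differences: primary/normal, metastasis/primary and metastasis/normal
(``None`` where the normal-vs-metastasis contrast was not significant).
These printed values are inputs here: they let the continuum/Venn logic and
the multiplicative closure of the fold statistic be exercised against an
external reference without the original arrays.
"""

from __future__ import annotations

from .diffexp import VennCell, venn_cell

#: cohort design: arrays per tissue group
GROUP_SIZES = {"NORMAL": 29, "PRIMARY": 131, "METASTASIS": 19}

#: transcripts / genes reported differentially expressed anywhere,
#: and how many of the transcripts are non-coding
REPORTED_DE_TRANSCRIPTS = 881
REPORTED_DE_GENES = 680
REPORTED_NONCODING_DE = 371

#: transcript -> (mfd primary/normal, mfd metastasis/primary, mfd metastasis/normal)
CONTINUUM_FOLD_TABLE: dict[str, tuple[float, float, float | None]] = {
    # significant in all three pairwise contrasts
    "ACOT11-001": (0.79, 0.77, 0.61),
    "AOX1-001": (0.79, 0.56, 0.44),
    "C19orf46-002": (1.24, 1.23, 1.53),
    "C8orf84-001": (0.76, 0.75, 0.57),
    "COCH-202": (0.76, 0.83, 0.63),
    "CTA-55I10.1-001": (0.83, 0.68, 0.56),
    "DMD-024": (0.74, 0.82, 0.60),
    "FGF10-002": (0.83, 0.64, 0.53),
    "FGFR2-008": (0.76, 0.79, 0.60),
    "FGFR2-016": (0.74, 0.67, 0.49),
    "GABRE-006": (0.79, 0.83, 0.66),
    "GNAL-001": (0.82, 0.69, 0.57),
    "GNAO1-002": (0.78, 0.75, 0.58),
    "HEATR8-006": (0.80, 0.80, 0.64),
    "ISL1-002": (0.80, 0.81, 0.65),
    "NR2F2-202": (0.82, 0.82, 0.68),
    "PCP4-004": (0.81, 0.72, 0.58),
    "PDE5A-005": (0.74, 0.79, 0.59),
    "PDZRN4-202": (0.80, 0.71, 0.57),
    "RSRC2-017": (1.27, 1.28, 1.63),
    "TGM4-001": (0.68, 0.62, 0.42),
    "TSPAN2-001": (0.80, 0.77, 0.61),
    # significant flanking the primary stage only (not normal vs metastasis)
    "ABCC4-004": (1.35, 0.81, None),
    "ALK-001": (1.24, 0.83, None),
    "ATP1A1-002": (1.23, 0.71, None),
    "NAMPT-006": (1.34, 0.73, None),
    "NAMPT-007": (1.75, 0.57, None),
    "RP11-627G23.1-004": (1.38, 0.78, None),
}


def fold_passes_threshold(mfd: float, mfd_threshold: float = 1.2) -> bool:
    """Symmetric fold rule: mfd >= threshold or <= 1/threshold."""
    return mfd >= mfd_threshold or mfd <= 1.0 / mfd_threshold


def categorize_reference_folds(
    mfd_threshold: float = 1.2,
) -> dict[str, VennCell]:
    """Venn cell per reference transcript from its printed stagewise folds.

    A printed fold means the contrast was significant at the study's FDR; it
    must also clear the symmetric fold rule.  ``None`` means not significant.
    """
    cells = {}
    for tx, (f_np, f_pm, f_nm) in CONTINUUM_FOLD_TABLE.items():
        de_np = f_np is not None and fold_passes_threshold(f_np, mfd_threshold)
        de_pm = f_pm is not None and fold_passes_threshold(f_pm, mfd_threshold)
        de_nm = f_nm is not None and fold_passes_threshold(f_nm, mfd_threshold)
        cells[tx] = venn_cell(de_np, de_pm, de_nm)
    return cells


def closure_errors() -> dict[str, tuple[float, float, float]]:
    """Per fully-significant transcript: (product of stagewise folds,
    printed normal-vs-metastasis fold, rounding-propagation bound).

    The fold statistic is a ratio of medians, so stagewise folds compose
    multiplicatively; the printed values being rounded to two decimals, the
    product can differ from the printed third column by at most
    ``0.005*(a+b) + 0.005`` (plus a vanishing second-order term).
    """
    out = {}
    for tx, (a, b, c) in CONTINUUM_FOLD_TABLE.items():
        if c is None:
            continue
        bound = 0.005 * (a + b) + 0.005 + 2.5e-5
        out[tx] = (a * b, c, bound)
    return out
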
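"""Synthetic annotation, probe, expression and clinical data generator.

The generator emulates the statistical structure the analysis assumes for a
three-group exon-array cohort (normal adjacent / primary tumor / metastasis,
29/131/19 arrays by default): a gene → transcript → exon hierarchy with
shared and transcript-unique exons plus planted pathological loci
(single-transcript genes, genes with a single testable transcript, genes
nested in another gene's intron on either strand, fully tested genes);
probe selection regions with reliability and cross-hybridization flags;
normalized log2 intensities with per-PSR affinities, additive Gaussian noise,
a background-censored probe fraction and planted stagewise fold changes on
transcript-specific PSRs; and an exponential time-to-recurrence outcome in
which a latent high-risk subset of primaries carries a hazard multiplier and
a metastasis-like expression profile on the planted progression features.

Every stage draws from a child seed of the single configured seed, so stages
are independently reproducible and a fixed seed gives byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import (
    ExpressionStudy,
    Gene,
    GenomeAnnotation,
    ProbeSelectionRegion,
    SampleRecord,
    Transcript,
    write_expression_study,
    write_gtf,
    write_psr_bed,
    NONCODING,
    PROTEIN_CODING,
)
from .detect import GeneCategory, PsrStatus
from .diffexp import VennCell, venn_cell

#: default planted stagewise folds (name, fold primary/normal, fold
#: metastasis/primary); deregulation is weighted toward the late transition,
#: mirroring a metastasis-dominant progression continuum
DEFAULT_PATTERNS: tuple[tuple[str, float, float], ...] = (
    ("all_three_up", 1.25, 1.40),
    ("all_three_down", 0.80, 0.71),
    ("primary_pair", 1.50, 1 / 1.50),
    ("nvsm_only", 1.19, 1.19),
    ("nvsp_nvsm", 1.60, 1.00),
    ("pvsm_nvsm", 1.00, 1.60),
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_genes: int = 60
    transcripts_per_gene_probs: tuple[float, ...] = (0.45, 0.30, 0.15, 0.07, 0.03)
    exons_per_transcript: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 2000)
    intergenic_gap: tuple[int, int] = (5000, 20000)
    shared_exon_fraction: float = 0.5
    max_psrs_per_exon: int = 2
    psr_length: tuple[int, int] = (25, 120)
    frac_unreliable: float = 0.15
    frac_non_class1: float = 0.10
    n_intergenic_psrs: int = 15
    frac_noncoding_transcripts: float = 0.3
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NORMAL": 29, "PRIMARY": 131, "METASTASIS": 19}
    )
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    background_level: float = 5.0
    frac_background: float = 0.10
    noise_sd: float = 0.5
    planted_patterns: tuple[tuple[str, float, float], ...] = DEFAULT_PATTERNS
    planted_per_pattern: int = 4
    frac_high_risk: float = 0.20
    baseline_hazard: float = 0.012  # per month
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.4
    nomogram_intercept: float = -1.2
    nomogram_risk_coef: float = 1.5
    nomogram_noise_sd: float = 0.8
    seed: int = 17

    def __post_init__(self) -> None:
        for frac in (
            self.shared_exon_fraction,
            self.frac_unreliable,
            self.frac_non_class1,
            self.frac_background,
            self.frac_high_risk,
            self.censoring_rate,
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0,1]")
        if min(self.group_sizes.values()) < 2:
            raise ValueError("each group needs >= 2 samples")
        for _, f1, f2 in self.planted_patterns:
            if f1 <= 0 or f2 <= 0:
                raise ValueError("planted folds must be positive")

    def child_seeds(self) -> dict[str, np.random.Generator]:
        ann, expr, clin = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "annotation": np.random.default_rng(ann),
            "expression": np.random.default_rng(expr),
            "clinical": np.random.default_rng(clin),
        }


@dataclass
class PlantedEffect:
    pattern: str
    fold_np: float
    fold_pm: float

    @property
    def fold_nm(self) -> float:
        return self.fold_np * self.fold_pm

    def expected_cell(self, mfd_threshold: float = 1.2) -> VennCell:
        """Venn cell the planted folds imply under the symmetric fold rule."""

        def passes(f: float) -> bool:
            return f >= mfd_threshold or f <= 1.0 / mfd_threshold

        return venn_cell(passes(self.fold_np), passes(self.fold_pm), passes(self.fold_nm))


@dataclass
class GroundTruth:
    psr_status: dict[str, PsrStatus] = field(default_factory=dict)
    psr_transcript: dict[str, str] = field(default_factory=dict)  # unique-overlap tx
    gene_category: dict[str, GeneCategory] = field(default_factory=dict)
    fully_tested: set[str] = field(default_factory=set)
    planted: dict[str, PlantedEffect] = field(default_factory=dict)
    background_censored: set[str] = field(default_factory=set)
    high_risk: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "psr_status": {k: v.value for k, v in sorted(self.psr_status.items())},
                "psr_transcript": dict(sorted(self.psr_transcript.items())),
                "gene_category": {
                    k: v.value for k, v in sorted(self.gene_category.items())
                },
                "fully_tested": sorted(self.fully_tested),
                "planted": {k: asdict(v) for k, v in sorted(self.planted.items())},
                "background_censored": sorted(self.background_censored),
                "high_risk": dict(sorted(self.high_risk.items())),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# annotation + probes


def _make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    cursor: int,
    n_tx: int,
    unique_per_tx: list[int],
    n_shared: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    biotypes: Optional[list[str]] = None,
) -> tuple[Gene, int]:
    """Lay out a gene as a sorted run of exon slots, each slot either shared by
    all transcripts or unique to one; returns the gene and the new cursor."""
    n_slots = n_shared + sum(unique_per_tx)
    slots = []
    pos = cursor
    for _ in range(n_slots):
        length = int(rng.integers(*cfg.exon_length))
        slots.append((pos, pos + length))
        pos += length + int(rng.integers(*cfg.intron_length))
    owners: list[int] = [-1] * n_shared  # -1 = shared by every transcript
    for t_idx, n_u in enumerate(unique_per_tx):
        owners += [t_idx] * n_u
    order = rng.permutation(n_slots)
    gene = Gene(gene_id, chrom, strand)
    if biotypes is None:
        biotypes = [
            NONCODING if rng.random() < cfg.frac_noncoding_transcripts else PROTEIN_CODING
            for _ in range(n_tx)
        ]
    for t_idx in range(n_tx):
        exons = sorted(
            slots[slot]
            for slot, owner in zip(order, owners)
            if owner in (-1, t_idx)
        )
        tx = Transcript(f"{gene_id}-T{t_idx + 1}", biotypes[t_idx], exons)
        gene.transcripts[tx.transcript_id] = tx
    return gene, pos


def simulate_annotation(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeAnnotation, list[ProbeSelectionRegion], GroundTruth]:
    """Generate the annotation, probes and structural ground truth.

    Random gene loci are laid out without overlap; a fixed set of planted
    pathological loci exercises every branch of the exclusion cascade.
    """
    rng = rng if rng is not None else config.child_seeds()["annotation"]
    chrom = "chrS1"
    cursor = 1000
    genes: list[Gene] = []
    n_tx_choices = np.arange(1, len(config.transcripts_per_gene_probs) + 1)
    probs = np.asarray(config.transcripts_per_gene_probs, dtype=float)
    probs = probs / probs.sum()
    for i in range(config.n_genes):
        n_tx = int(rng.choice(n_tx_choices, p=probs))
        lo, hi = config.exons_per_transcript
        n_exons = int(rng.integers(lo, hi + 1))
        n_shared = max(1, int(round(n_exons * config.shared_exon_fraction)))
        unique_per_tx = [
            int(rng.integers(0, max(1, n_exons - n_shared) + 1)) for _ in range(n_tx)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gene, cursor = _make_gene(
            f"G{i + 1:03d}", chrom, strand, cursor, n_tx, unique_per_tx, n_shared, config, rng
        )
        genes.append(gene)
        cursor += int(rng.integers(*config.intergenic_gap))

    planted_genes: list[Gene] = []

    # single-transcript gene: its unique-exon PSRs are structurally untestable
    g, cursor = _make_gene(
        "GP_SINGLE", chrom, "+", cursor, 1, [2], 1, config, rng, [PROTEIN_CODING]
    )
    planted_genes.append(g)
    cursor += 6000

    # two transcripts, only one with a unique exon region
    g, cursor = _make_gene(
        "GP_ONETEST", chrom, "+", cursor, 2, [2, 0], 2, config, rng,
        [PROTEIN_CODING, NONCODING],
    )
    planted_genes.append(g)
    cursor += 6000

    # host gene with a wide intron, nested gene inside it on the same strand:
    # the nested gene's PSRs sit in the host's exon hull and are filtered
    for tag, nested_strand in (("A", "+"), ("B", "-")):
        host = Gene(f"GP_HOST{tag}", chrom, "+")
        e1 = (cursor, cursor + 200)
        intron_start = cursor + 200 + 500
        e2_start = cursor + 200 + 12000
        host.transcripts[f"GP_HOST{tag}-T1"] = Transcript(
            f"GP_HOST{tag}-T1", PROTEIN_CODING, [e1, (e2_start, e2_start + 200)]
        )
        planted_genes.append(host)
        nested, _ = _make_gene(
            f"GP_NEST{tag}", chrom, nested_strand, intron_start, 2, [1, 1], 1, config, rng,
            [PROTEIN_CODING, PROTEIN_CODING],
        )
        planted_genes.append(nested)
        cursor = e2_start + 200 + 6000

    # fully tested gene: every transcript keeps a unique, clean PSR
    g, cursor = _make_gene(
        "GP_FULL", chrom, "+", cursor, 3, [1, 1, 1], 1, config, rng,
        [PROTEIN_CODING, PROTEIN_CODING, NONCODING],
    )
    planted_genes.append(g)

    all_genes = genes + planted_genes
    annotation = GenomeAnnotation(all_genes)

    # PSRs: place inside every distinct exon slot; planted loci get clean flags
    planted_ids = {g.gene_id for g in planted_genes}
    psrs: list[ProbeSelectionRegion] = []
    counter = 0
    for g in all_genes:
        slots = sorted({(s, e) for t in g.transcripts.values() for (s, e) in t.exons})
        for s, e in slots:
            n_here = int(rng.integers(1, config.max_psrs_per_exon + 1))
            for _ in range(n_here):
                length = min(int(rng.integers(*config.psr_length)), e - s)
                start = int(rng.integers(s, e - length + 1))
                counter += 1
                clean = g.gene_id in planted_ids
                psrs.append(
                    ProbeSelectionRegion(
                        psr_id=f"PSR_{counter:05d}",
                        chrom=chrom,
                        strand=g.strand,
                        start=start,
                        end=start + length,
                        reliable=clean or rng.random() >= config.frac_unreliable,
                        crosshyb_class1=clean or rng.random() >= config.frac_non_class1,
                    )
                )
    # intergenic probes land upstream of the first locus
    for _ in range(config.n_intergenic_psrs):
        length = int(rng.integers(*config.psr_length))
        start = int(rng.integers(0, 900 - length))
        counter += 1
        psrs.append(
            ProbeSelectionRegion(
                psr_id=f"PSR_{counter:05d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + length,
                reliable=True,
                crosshyb_class1=True,
            )
        )

    truth = GroundTruth()
    _brute_force_truth(psrs, annotation, truth)
    return annotation, psrs, truth


def _brute_force_truth(
    psrs: list[ProbeSelectionRegion],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
) -> None:
    """Straightforward all-pairs scan implementing the exclusion cascade.

    Written without interval indexes so it can serve as the independent
    oracle for the production classifier.
    """

    def hits(p: ProbeSelectionRegion) -> set[tuple[str, str]]:
        found = set()
        for g in annotation.genes.values():
            if g.chrom != p.chrom or g.strand != p.strand:
                continue
            for t in g.transcripts.values():
                for s, e in t.exons:
                    if s < p.end and p.start < e:
                        found.add((g.gene_id, t.transcript_id))
        return found

    def span_genes(p: ProbeSelectionRegion) -> set[str]:
        found = set()
        for g in annotation.genes.values():
            if g.chrom != p.chrom or g.strand != p.strand:
                continue
            s, e = g.span()
            if s < p.end and p.start < e:
                found.add(g.gene_id)
        return found

    prelim: dict[str, PsrStatus] = {}
    candidates: dict[str, list[tuple[str, str]]] = {}
    for p in psrs:
        h = hits(p)
        transcripts = {t for _, t in h}
        if len(transcripts) == 1:
            ((gid, tid),) = h
            truth.psr_transcript[p.psr_id] = tid
        if not p.reliable:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_UNRELIABLE
        elif not p.crosshyb_class1:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_CROSSHYB
        elif not transcripts:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_NOT_EXONIC
        elif len(transcripts) > 1:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_MULTI_TRANSCRIPT
        elif len(span_genes(p)) >= 2:
            prelim[p.psr_id] = PsrStatus.EXCLUDED_MULTI_GENE_OVERLAP
        else:
            ((gid, tid),) = h
            candidates.setdefault(gid, []).append((p.psr_id, tid))

    testable = {gid: {t for _, t in pairs} for gid, pairs in candidates.items()}
    for gid, pairs in candidates.items():
        n_tx = len(annotation.genes[gid].transcripts)
        if n_tx == 1:
            status = PsrStatus.EXCLUDED_SINGLE_TRANSCRIPT_GENE
        elif len(testable[gid]) == 1:
            status = PsrStatus.EXCLUDED_ONE_TESTABLE_GENE
        else:
            status = PsrStatus.KEPT
        for pid, _ in pairs:
            prelim[pid] = status
    truth.psr_status = prelim

    for gid, gene in annotation.genes.items():
        n_tx = len(gene.transcripts)
        t = testable.get(gid, set())
        if n_tx == 1:
            truth.gene_category[gid] = GeneCategory.SINGLE_TRANSCRIPT
        elif len(t) >= 2:
            truth.gene_category[gid] = GeneCategory.MULTI_TESTABLE
        else:
            truth.gene_category[gid] = GeneCategory.ONE_TESTABLE
        if t and t == set(gene.transcripts):
            truth.fully_tested.add(gid)


# ---------------------------------------------------------------------------
# expression + clinical


def _sample_ids(config: SimulationConfig) -> list[SampleRecord]:
    records = []
    for group, prefix in (("NORMAL", "N"), ("PRIMARY", "P"), ("METASTASIS", "M")):
        for i in range(config.group_sizes[group]):
            records.append(SampleRecord(f"{prefix}{i + 1:03d}", group))
    return records


def simulate_expression(
    annotation: GenomeAnnotation,
    psrs: list[ProbeSelectionRegion],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[SampleRecord]]:
    """Generate the log2 matrix and bare sample sheet; plants fold changes on
    the PSRs of KEPT transcripts and marks a background-censored probe set."""
    rng = rng if rng is not None else config.child_seeds()["expression"]
    samples = _sample_ids(config)
    sample_ids = [s.sample_id for s in samples]
    groups = np.array([s.group for s in samples])

    kept_tx = sorted(
        {
            truth.psr_transcript[pid]
            for pid, st in truth.psr_status.items()
            if st is PsrStatus.KEPT
        }
    )
    wanted = len(config.planted_patterns) * config.planted_per_pattern
    chosen = list(kept_tx)
    rng.shuffle(chosen)
    chosen = chosen[:wanted]
    for i, tx in enumerate(sorted(chosen)):
        name, f1, f2 = config.planted_patterns[i % len(config.planted_patterns)]
        truth.planted[tx] = PlantedEffect(name, f1, f2)

    planted_psr_tx = {
        pid: tx
        for pid, tx in truth.psr_transcript.items()
        if tx in truth.planted
    }

    # latent high-risk primaries look metastatic on the planted features
    primary_ids = [s.sample_id for s in samples if s.group == "PRIMARY"]
    n_high = int(round(config.frac_high_risk * len(primary_ids)))
    high = set(rng.choice(primary_ids, size=n_high, replace=False).tolist())
    truth.high_risk = {sid: sid in high for sid in primary_ids}

    psr_ids = [p.psr_id for p in psrs]
    affinity = rng.normal(config.baseline_mean, config.baseline_sd, size=len(psrs))
    bg_eligible = [
        i for i, p in enumerate(psrs) if p.psr_id not in planted_psr_tx
    ]
    n_bg = int(round(config.frac_background * len(psrs)))
    bg_idx = rng.choice(bg_eligible, size=min(n_bg, len(bg_eligible)), replace=False)
    for i in bg_idx:
        affinity[i] = config.background_level - 1.5 - abs(rng.normal(0, 0.3))
        truth.background_censored.add(psrs[i].psr_id)

    is_high = np.array([sid in high for sid in sample_ids])
    delta = np.zeros((len(psrs), len(samples)))
    for i, p in enumerate(psrs):
        tx = planted_psr_tx.get(p.psr_id)
        if tx is None:
            continue
        eff = truth.planted[tx]
        d_primary = math.log2(eff.fold_np)
        d_met = math.log2(eff.fold_np) + math.log2(eff.fold_pm)
        row = np.where(
            groups == "PRIMARY",
            np.where(is_high, d_met, d_primary),
            np.where(groups == "METASTASIS", d_met, 0.0),
        )
        delta[i] = row

    noise = rng.normal(0.0, config.noise_sd, size=(len(psrs), len(samples)))
    matrix = pd.DataFrame(
        affinity[:, None] + delta + noise, index=psr_ids, columns=sample_ids
    )
    return matrix, samples


def simulate_clinical(
    samples: list[SampleRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SampleRecord]:
    """Fill BCR time/event and nomogram probability for the primary samples.

    Event times are exponential with the high-risk hazard multiplier;
    censoring is an independent exponential calibrated so that, at the
    baseline hazard, the configured fraction of subjects is censored.
    """
    rng = rng if rng is not None else config.child_seeds()["clinical"]
    c = config.censoring_rate
    censor_rate = config.baseline_hazard * c / (1 - c) if c > 0 else 0.0
    for s in samples:
        if s.group != "PRIMARY":
            continue
        hr = config.hazard_ratio if truth.high_risk.get(s.sample_id) else 1.0
        t_event = rng.exponential(1.0 / (config.baseline_hazard * hr))
        t_cens = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else math.inf
        s.bcr_time = float(min(t_event, t_cens))
        s.bcr_event = bool(t_event <= t_cens)
        lin = (
            config.nomogram_intercept
            + config.nomogram_risk_coef * (1.0 if truth.high_risk.get(s.sample_id) else 0.0)
            + rng.normal(0.0, config.nomogram_noise_sd)
        )
        s.nomogram_prob = float(1.0 / (1.0 + math.exp(-lin)))
    return samples


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: GenomeAnnotation
    psrs: list[ProbeSelectionRegion]
    study: ExpressionStudy
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / "annotation.gtf",
            "bed": out / "psrs.bed",
            "meta": out / "psr_metadata.tsv",
            "matrix": out / "expression.tsv",
            "samples": out / "samples.tsv",
            "truth": out / "truth.json",
        }
        write_gtf(self.annotation, paths["gtf"])
        write_psr_bed(self.psrs, paths["bed"], paths["meta"])
        write_expression_study(self.study, paths["matrix"], paths["samples"])
        paths["truth"].write_text(self.truth.to_json())
        return paths


def simulate_study(config: Optional[SimulationConfig] = None) -> SimulatedStudy:
    """Run all three stages under the configured seed."""
    config = config if config is not None else SimulationConfig()
    rngs = config.child_seeds()
    annotation, psrs, truth = simulate_annotation(config, rngs["annotation"])
    matrix, samples = simulate_expression(annotation, psrs, truth, config, rngs["expression"])
    samples = simulate_clinical(samples, truth, config, rngs["clinical"])
    study = ExpressionStudy(
        matrix=matrix, samples=samples, background_level=config.background_level
    )
    return SimulatedStudy(
        config=config, annotation=annotation, psrs=psrs, study=study, truth=truth
    )
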
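"""Calibration experiments: oracle agreement, error control and power.

Each function runs the full generator + pipeline machinery under seeded
replicates and returns a rate.  Problem sizes are kept at desk scale
(tens of genes, a few hundred probes) while group sizes default to the
29/131/19 cohort design so the power properties are commensurate with it.
"""

from __future__ import annotations

import math

import numpy as np

from .detect import classify_psrs
from .diffexp import AnalysisParams, Comparison, compare_groups, select_representative
from .risk import logrank
from .simulate import (
    GroundTruth,
    SimulationConfig,
    _sample_ids,
    simulate_annotation,
    simulate_clinical,
    simulate_study,
)


def classifier_oracle_agreement(n_genomes: int = 100, base_seed: int = 0) -> float:
    """Fraction of PSRs, over random toy genomes, whose cascade status from
    the indexed classifier equals the generator's quadratic-scan truth."""
    agree = total = 0
    for i in range(n_genomes):
        cfg = SimulationConfig(
            n_genes=8,
            seed=base_seed + i,
            group_sizes={"NORMAL": 2, "PRIMARY": 2, "METASTASIS": 2},
        )
        annotation, psrs, truth = simulate_annotation(cfg)
        catalog = classify_psrs(psrs, annotation)
        for d in catalog.dispositions:
            total += 1
            agree += d.status is truth.psr_status[d.psr_id]
        if catalog.fully_tested != truth.fully_tested:
            return agree / total  # count mismatch as disagreement
    return agree / total


def _nvsm_transcript_calls(sim, params: AnalysisParams):
    catalog = classify_psrs(sim.psrs, sim.annotation)
    from .diffexp import background_filter

    kept = sorted(catalog.kept_psr_ids())
    analyzed = background_filter(sim.study, kept, params)
    psr_to_tx = {
        p: t for p, t in catalog.psr_to_transcript().items() if p in set(analyzed)
    }
    res = compare_groups(sim.study, analyzed, Comparison.NvsM, params)
    return select_representative(res, psr_to_tx)


def null_de_false_call_rate(n_seeds: int = 20, base_seed: int = 1000) -> float:
    """Pooled fraction of transcripts falsely called DE (N vs M) when no
    effect is planted; should stay at or below the FDR target."""
    false = total = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=30, seed=base_seed + i, planted_patterns=(), planted_per_pattern=0
        )
        sim = simulate_study(cfg)
        params = AnalysisParams(background_level=cfg.background_level)
        calls = _nvsm_transcript_calls(sim, params)
        total += len(calls)
        false += sum(c.de for c in calls.values())
    return false / total if total else 0.0


def planted_power_nvsm(
    fold: float = 1.6, n_seeds: int = 20, base_seed: int = 2000
) -> float:
    """Pooled recovery rate, in the N-vs-M contrast, of transcripts planted
    with the given net linear fold (split evenly across the two stages)."""
    stage = math.sqrt(fold)
    recovered = total = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=40,
            seed=base_seed + i,
            planted_patterns=(("planted_nvsm", stage, stage),),
            planted_per_pattern=40,
        )
        sim = simulate_study(cfg)
        params = AnalysisParams(background_level=cfg.background_level)
        calls = _nvsm_transcript_calls(sim, params)
        for tx in sim.truth.planted:
            if tx in calls:
                total += 1
                recovered += calls[tx].de
    return recovered / total if total else 0.0


def logrank_power(
    hazard_ratio: float = 3.0,
    n_seeds: int = 100,
    base_seed: int = 3000,
    n_primaries: int = 131,
    frac_high_risk: float = 0.2,
) -> float:
    """Fraction of seeded clinical cohorts in which the two risk classes
    separate at p < 0.05 by the log-rank test."""
    rejections = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + i,
            hazard_ratio=hazard_ratio,
            frac_high_risk=frac_high_risk,
            group_sizes={"NORMAL": 2, "PRIMARY": n_primaries, "METASTASIS": 2},
        )
        rngs = cfg.child_seeds()
        samples = _sample_ids(cfg)
        truth = GroundTruth()
        prim = [s.sample_id for s in samples if s.group == "PRIMARY"]
        rng = rngs["expression"]
        n_high = int(round(frac_high_risk * len(prim)))
        high = set(rng.choice(prim, size=n_high, replace=False).tolist())
        truth.high_risk = {sid: sid in high for sid in prim}
        simulate_clinical(samples, truth, cfg, rngs["clinical"])
        recs = [s for s in samples if s.group == "PRIMARY"]
        out = logrank(
            [s.bcr_time for s in recs],
            [s.bcr_event for s in recs],
            ["metastasis_like" if truth.high_risk[s.sample_id] else "normal_like" for s in recs],
        )
        rejections += out["p"] < 0.05
    return rejections / n_seeds
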
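#!/usr/bin/env python
"""Nearest-prototype risk stratification of the primary tumors.

Trains the k=1 Euclidean classifier on the normal-adjacent + metastatic
samples over the top t-ranked DE features of the normal-vs-metastasis
contrast, labels every primary normal-like or metastasis-like, and evaluates
the split on the BCR endpoint: Kaplan-Meier curves, the log-rank test, and
a logistic model of the BCR event adjusted for the nomogram class.
"""

import json
from pathlib import Path

from tspsr.annotation import read_expression_study, read_psr_bed
from tspsr.diffexp import AnalysisParams, Comparison, ComparisonResult
from tspsr.risk import METASTASIS_LIKE, stratify
from tspsr.simulate import SimulationConfig

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(seed=17)
    psrs = read_psr_bed(ROOT / "sim" / "psrs.bed", ROOT / "sim" / "psr_metadata.tsv")
    study = read_expression_study(
        ROOT / "sim" / "expression.tsv", ROOT / "sim" / "samples.tsv",
        cfg.background_level, {p.psr_id for p in psrs},
    )
    table = pd.read_csv(ROOT / "diffexp" / "psr_results_NvsM.tsv", sep="\t",
                        index_col="psr_id")
    table["de"] = table["de"].astype(bool)
    res = ComparisonResult(Comparison.NvsM, table, AnalysisParams())

    strat = stratify(study, res, top_n=100)
    out = ROOT / "risk"
    out.mkdir(parents=True, exist_ok=True)
    strat.predicted_class.to_csv(out / "predicted_class.tsv", sep="\t",
                                 index_label="sample_id")
    truth = json.loads((ROOT / "sim" / "truth.json").read_text())
    high = truth["high_risk"]
    pred_pos = strat.predicted_class == METASTASIS_LIKE
    tp = sum(1 for sid, v in high.items() if v and pred_pos[sid])
    print(f"features used: {len(strat.features)}")
    print(f"metastasis-like: {int(pred_pos.sum())}/{len(pred_pos)} primaries "
          f"({tp}/{sum(high.values())} true high-risk recovered)")
    print(f"log-rank: chi2={strat.logrank['chi_square']:.2f} p={strat.logrank['p']:.4g}")
    for s in strat.logistic:
        print(f"  {s.covariate}: OR={s.odds_ratio:.2f} "
              f"CI95=[{s.ci95[0]:.2f}, {s.ci95[1]:.2f}] p={s.p:.4g}")
    (out / "evaluation.json").write_text(json.dumps(
        {"logrank": strat.logrank,
         "logistic": [{"covariate": s.covariate, "odds_ratio": s.odds_ratio,
                       "ci95": list(s.ci95), "p": s.p} for s in strat.logistic]},
        indent=1))


if __name__ == "__main__":
    main()
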
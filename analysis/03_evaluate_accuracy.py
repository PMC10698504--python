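"""Score the baseline predictions against fitness: precision-recall
AUC (the headline metric), ROC AUC, balanced and overall accuracy at
the fitness < -2 threshold, the nonfunctional-gene null model, the
per-carbon AUC breakdown and the ranked misprediction candidates.

Reads results/baseline/; writes results/evaluation/.
"""

from pathlib import Path

import pandas as pd

from gemeval import pipeline
from gemeval.evaluation import pad_null, pr_auc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    table = pd.read_csv(ROOT / "baseline" / "predictions.tsv", sep="\t")
    out = ROOT / "evaluation"
    report, ranking = pipeline.evaluate_predictions(table, out_dir=out)
    print(f"uncorrected model: PR-AUC {report.auc_pr:.3f}, "
          f"ROC-AUC {report.auc_roc:.3f}, "
          f"balanced accuracy {report.balanced_accuracy:.3f}, "
          f"overall accuracy {report.overall_accuracy:.3f} "
          f"(TP/FP/TN/FN = {report.confusion})")

    n = report.n_records
    padded = pr_auc(pad_null(table, 2 * n))
    print("null model (100% extra nonfunctional genes): "
          f"PR-AUC {report.auc_pr:.3f} -> {padded.auc_pr:.3f} "
          f"(shift {abs(padded.auc_pr - report.auc_pr):.3f}), overall "
          f"accuracy {report.overall_accuracy:.3f} -> "
          f"{padded.overall_accuracy:.3f} "
          f"(shift {abs(padded.overall_accuracy - report.overall_accuracy):.3f})"
          " - PR-AUC is the robust metric")

    worst = sorted(report.per_carbon.items(), key=lambda kv: kv[1])[:3]
    print("lowest per-carbon AUCs:",
          ", ".join(f"{c}={a:.3f}" for c, a in worst))
    print("top false-negative candidates (high fitness, predicted "
          "essential):", ", ".join(ranking.false_negative_genes[:5]))
    print("top false-positive candidates (low fitness, predicted growth):",
          ", ".join(ranking.false_positive_genes[:5]))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
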
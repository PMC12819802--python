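"""LOOCV linear-SVM classification of AD vs HC from gradient features.

Uses the parcels that passed the group contrast (q < 0.05) as features;
each fold standardizes on its training subjects only. Reports the
confusion matrix, percent metrics, rank AUC, and the weight-based feature
ranking.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gradstates.classify import loocv_classify, roc_points


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--gradients", default="results/gradients/gradient_scores.tsv")
    ap.add_argument("--contrasts", default="results/stats/gradient_contrasts.tsv")
    ap.add_argument("--subjects", default="results/cohort/subjects.tsv")
    ap.add_argument("--out-dir", default="results/classify")
    ap.add_argument("--C", type=float, default=1.0)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = pd.read_csv(args.subjects, sep="\t").set_index("subject_id")
    scores = pd.read_csv(args.gradients, sep="\t")
    contrasts = pd.read_csv(args.contrasts, sep="\t")

    sig = contrasts[contrasts["q"] < 0.05]["feature"].astype(int).tolist()
    if not sig:
        # fall back to the strongest contrasts so the classifier stays defined
        sig = contrasts.reindex(np.abs(contrasts["t"]).sort_values()[::-1].index)[
            "feature"].astype(int).head(5).tolist()
        print("no q<0.05 parcels; using the 5 strongest contrasts instead")
    wide = scores.pivot(index="subject_id", columns="parcel", values="g1")
    wide = wide.loc[subjects.index, sig]

    rep = loocv_classify(wide.to_numpy(), subjects["group"].to_numpy(),
                         C=args.C,
                         feature_names=[f"parcel{p}_g1" for p in sig])
    (out / "report.json").write_text(json.dumps({
        "features": sig, "folds": rep.folds,
        "confusion": {"tp": rep.tp, "fn": rep.fn, "tn": rep.tn, "fp": rep.fp},
        "accuracy_pct": rep.accuracy, "precision_pct": rep.precision,
        "sensitivity_pct": rep.sensitivity, "specificity_pct": rep.specificity,
        "auc": rep.auc,
        "feature_ranking": rep.feature_ranking,
    }, indent=2))
    np.savetxt(out / "roc_points.tsv", roc_points(rep.scores, rep.labels),
               delimiter="\t", header="fpr\ttpr", comments="")

    print(f"LOOCV over {rep.folds} folds, {len(sig)} gradient features")
    print(f"confusion TP={rep.tp} FN={rep.fn} TN={rep.tn} FP={rep.fp}")
    print(f"accuracy {rep.accuracy:.2f}%  sensitivity {rep.sensitivity:.2f}%  "
          f"specificity {rep.specificity:.2f}%  AUC {rep.auc:.3f}")
    print(f"top feature: {rep.feature_ranking[0][0]}")


if __name__ == "__main__":
    main()
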
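#!/usr/bin/env python
"""Leave-one-out prediction of survival group and KPS change.

Reads the connectivity features (02) and clinical records (01), classifies
long-vs-short survival (cutoff 15 months, long coded 1) with a Gaussian-
kernel SVM under leave-one-out cross-validation, and predicts the 6-month
KPS change with both a Gaussian-kernel SVR and a linear model on identical
folds.  Writes results/prediction.json.
"""

import json
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from perifc import cohort_stats as cs  # noqa: E402
from perifc import outcome_predict as op  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
CUTOFF_MONTHS = 15.0


def main() -> None:
    rec = pd.read_csv(os.path.join(RESULTS, "cohort_records.tsv"), sep="\t")
    feat = pd.read_csv(os.path.join(RESULTS, "features.tsv"), sep="\t")
    df = rec.merge(feat, on="id", validate="one_to_one")
    X = df[list(op.FEATURE_NAMES_SUMMARY5)].to_numpy()

    labels = (
        (df.survival_months >= CUTOFF_MONTHS) | df.alive.astype(bool)
    ).astype(int).to_numpy()
    cls = op.loocv_classify(X, labels)
    print(
        f"LOOCV survival classification: accuracy {100 * cls.accuracy:.0f}%  "
        f"(TPR {100 * cls.tpr:.0f}%, TNR {100 * cls.tnr:.0f}%, "
        f"FPR {100 * cls.fpr:.0f}%, FNR {100 * cls.fnr:.0f}%)"
    )

    changes, keep = [], []
    for i, row in enumerate(rec.itertuples()):
        r = cs.SubjectRecord(
            id=row.id,
            age_years=float(row.age_years),
            sex=row.sex,
            who_grade=row.who_grade,
            tumor_volume_ml=float(row.tumor_volume_ml),
            survival_months=float(row.survival_months),
            alive=bool(row.alive),
            kps_pre=int(row.kps_pre),
            kps_6mo=None if pd.isna(row.kps_6mo) else int(row.kps_6mo),
        )
        dk = cs.kps_change(r)
        if dk is not None:
            keep.append(i)
            changes.append(float(dk))

    out = {"classification": cls.to_dict()}
    for model in ("svm_rbf", "linear"):
        rep = op.loocv_regress(X[keep], changes, model=model)
        out[f"regression_{model}"] = rep.to_dict()
        print(
            f"LOOCV KPS regression ({model}): |error| "
            f"{rep.abs_error_mean:.2f} +/- {rep.abs_error_sd:.2f}, "
            f"Spearman rho(true, pred) = {rep.spearman_rho_true_vs_pred:.3f}"
        )

    with open(os.path.join(RESULTS, "prediction.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    print("wrote results/prediction.json")


if __name__ == "__main__":
    main()
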
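#!/usr/bin/env python
"""Group statistics: survival-group comparison and KPS-outcome association.

Reads the cohort records (01) and the recovered subject metrics (02), splits
the cohort at the median observed survival, and reports the Kolmogorov-
Smirnov screen, two-tailed Mann-Whitney U (exact at this sample size),
Cohen's d, the Spearman correlation between the connectivity metric and the
6-month KPS change, and the multivariate OLS outcome model.  Writes
results/group_stats.json.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from perifc import cohort_stats as cs  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def load_records() -> list[cs.SubjectRecord]:
    rec = pd.read_csv(os.path.join(RESULTS, "cohort_records.tsv"), sep="\t")
    met = pd.read_csv(os.path.join(RESULTS, "subject_metrics.tsv"), sep="\t")
    df = rec.merge(met[["id", "subject_metric"]], on="id", validate="one_to_one")
    out = []
    for row in df.itertuples():
        out.append(
            cs.SubjectRecord(
                id=row.id,
                age_years=float(row.age_years),
                sex=row.sex,
                who_grade=row.who_grade,
                tumor_volume_ml=float(row.tumor_volume_ml),
                survival_months=float(row.survival_months),
                alive=bool(row.alive),
                kps_pre=int(row.kps_pre),
                kps_6mo=None if pd.isna(row.kps_6mo) else int(row.kps_6mo),
                subject_metric=float(row.subject_metric),
            )
        )
    return out


def main() -> None:
    records = load_records()
    gc = cs.compare_survival_groups(records)
    d = gc.to_dict()
    print(
        f"median-survival split at {d['median_months']:.1f} mo: "
        f"{d['n_short']} short vs {d['n_long']} long"
    )
    print(
        f"  metric short {d['mean_metric_short']:+.4f} +/- {d['sd_metric_short']:.4f}, "
        f"long {d['mean_metric_long']:+.4f} +/- {d['sd_metric_long']:.4f}"
    )
    print(
        f"  Mann-Whitney U={d['u_stat']:.0f}, two-tailed p={d['p_two_tailed']:.4f}; "
        f"Cohen's d={d['cohens_d']:.2f}"
    )

    xs, ys = [], []
    for r in records:
        dk = cs.kps_change(r)
        if dk is not None:
            xs.append(r.subject_metric)
            ys.append(float(dk))
    rho, p = cs.spearman(xs, ys)
    print(f"  Spearman rho(metric, KPS change) = {rho:.3f} (p={p:.2g}, n={len(xs)})")

    model = cs.fit_outcome_model(records)
    conn_p = model.table.loc["connectivity", "p"]
    print(
        f"  OLS outcome model: R^2={model.r_squared:.3f} "
        f"(adj {model.r_squared_adj:.3f}), F-test p={model.f_pvalue:.3g}; "
        f"connectivity coefficient p={conn_p:.3g}"
    )

    out = {
        "group_comparison": d,
        "spearman": {"rho": rho, "p": p, "n": len(xs)},
        "outcome_model": model.to_dict(),
    }
    with open(os.path.join(RESULTS, "group_stats.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    print("wrote results/group_stats.json")


if __name__ == "__main__":
    main()
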
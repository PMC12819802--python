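"""Group inference: gradient and state-metric contrasts, clinical links.

Contrasts per-parcel gradient-1 scores between AD and HC with age and sex
as covariates, controls discoveries with network-wise BH-FDR plus
max-statistic permutation (family-wise), compares FO/MDT/NT per state
between groups, and correlates significant parcels' gradient scores with
the clinical covariate using a normality-screened Pearson/Spearman choice.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from gradstates import stats as st


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--gradients", default="results/gradients/gradient_scores.tsv")
    ap.add_argument("--metrics", default="results/dfc/state_metrics.tsv")
    ap.add_argument("--subjects", default="results/cohort/subjects.tsv")
    ap.add_argument("--out-dir", default="results/stats")
    ap.add_argument("--perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = pd.read_csv(args.subjects, sep="\t").set_index("subject_id")
    scores = pd.read_csv(args.gradients, sep="\t")

    wide = scores.pivot(index="subject_id", columns="parcel", values="g1")
    wide = wide.loc[subjects.index]
    groups = subjects["group"].to_numpy()
    covs = np.column_stack([subjects["age"],
                            (subjects["sex"] == "F").astype(float)])
    networks = scores.drop_duplicates("parcel").set_index("parcel")["network"]

    res = st.adjusted_group_contrast(wide.to_numpy(), groups,
                                     covariates=covs, baseline="HC",
                                     feature_names=[str(p) for p in wide.columns])
    res["network"] = networks.loc[wide.columns].to_numpy()
    res["q"] = st.fdr_bh_by_network(res["p"].to_numpy(), res["network"])
    res["p_fwe"] = st.maxstat_permutation(wide.to_numpy(), groups,
                                          covariates=covs, n_perm=args.perm,
                                          seed=args.seed, baseline="HC")
    res.to_csv(out / "gradient_contrasts.tsv", sep="\t", index=False)
    sig = res[res["q"] < 0.05]
    print(f"gradient-1 contrasts (AD - HC, age/sex adjusted): "
          f"{len(sig)}/{len(res)} parcels at q<0.05, "
          f"{(res['p_fwe'] < 0.05).sum()} family-wise significant")

    metrics = pd.read_csv(args.metrics, sep="\t")
    rows = []
    for (state, col) in [(s, c) for s in sorted(metrics["state"].unique())
                         for c in ("fo", "mdt_windows", "nt")]:
        sub = metrics[metrics["state"] == state].set_index("subject_id")
        sub = sub.loc[[s for s in subjects.index if s in sub.index]]
        vals = sub[col].to_numpy(float)
        ok = ~np.isnan(vals)
        grp = subjects.loc[sub.index[ok], "group"]
        if ok.sum() < 6 or grp.value_counts().min() < 3:
            continue  # unvisited-state MDT excluded pairwise
        r = st.adjusted_group_contrast(vals[ok, None], grp, baseline="HC")
        rows.append({"state": state, "metric": col, "t": r.loc[0, "t"],
                     "p": r.loc[0, "p"]})
    state_res = pd.DataFrame(rows)
    if len(state_res):
        state_res["q"] = st.fdr_bh(state_res["p"].to_numpy())
        state_res.to_csv(out / "state_metric_contrasts.tsv", sep="\t",
                         index=False)
        hits = state_res[state_res["p"] < 0.05]
        print(f"state-metric contrasts: {len(hits)} of {len(state_res)} at "
              f"p<0.05"
              + (f" ({', '.join(f'state {r.state} {r.metric}' for r in hits.itertuples())})"
                 if len(hits) else ""))
    else:
        print("state-metric contrasts skipped: no subjects matched between "
              "the metrics table and the subject table")

    # clinical correlation in the AD group for the top contrast parcel
    if "ttau" in subjects.columns and len(sig):
        top = sig.iloc[np.argmax(np.abs(sig["t"]).to_numpy())]["feature"]
        ad = subjects[subjects["group"] == "AD"]
        feat = wide.loc[ad.index, int(top)].to_numpy()
        method = st.choose_correlation_method(feat, ad["ttau"].to_numpy())
        corr = st.correlate_clinical(feat, ad["ttau"].to_numpy(), method)
        pd.DataFrame([{"feature": top, "variable": "ttau",
                       "method": corr.method, "r": corr.r, "p": corr.p,
                       "n": corr.n}]).to_csv(out / "clinical_correlations.tsv",
                                             sep="\t", index=False)
        print(f"parcel {top} g1 vs T-Tau in AD: {corr.method} r={corr.r:.3f} "
              f"(p={corr.p:.4f}, n={corr.n})")


if __name__ == "__main__":
    main()
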
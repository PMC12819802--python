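"""Dynamic connectivity states: windows, k scan, state fit, temporal metrics.

Slides 50-TR windows (step 1) over each cleaned series, pools the Fisher-z
edge vectors across subjects, scans k with the elbow+silhouette rule, fits
the chosen k-means state model, and writes per-subject window labels, the
centroids, and the FO/MDT/NT table.

Note: fast-switching cohorts (the default generator chain) mix states
within a window; pass stickier chains at simulation time when the goal is
window-level state recovery.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gradstates import dfc
from gradstates.prep import read_parcel_timeseries


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", default="results/clean")
    ap.add_argument("--meta", default="results/cohort/parcels.tsv")
    ap.add_argument("--out-dir", default="results/dfc")
    ap.add_argument("--window", type=int, default=50)
    ap.add_argument("--step", type=int, default=1)
    ap.add_argument("--k", default="auto")
    ap.add_argument("--k-range", type=int, nargs=2, default=(2, 8))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--restarts", type=int, default=50)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dfc.WindowSpec(length=args.window, step=args.step)

    series = []
    tr = 2.0
    for path in sorted(Path(args.in_dir).glob("*_timeseries.tsv")):
        sid = path.name.replace("_timeseries.tsv", "")
        ts = read_parcel_timeseries(path, args.meta, subject_id=sid)
        sw = dfc.sliding_window_fc(ts, spec)
        series.append(sw)
        tr = ts.tr_seconds
    pooled, counts = dfc.pool_windows(series)
    print(f"{len(series)} subjects, {pooled.shape[0]} pooled windows of "
          f"{pooled.shape[1]} edges (L={spec.length}, step={spec.step})")

    if args.k == "auto":
        scan = dfc.cluster_quality_scan(pooled, counts,
                                        k_range=tuple(args.k_range),
                                        seed=args.seed, n_restarts=10)
        k = scan.chosen_k
        scan.as_frame().to_csv(out / "k_scan.tsv", sep="\t", index=False)
        print(f"k scan {args.k_range}: chosen k = {k} ({scan.rule})")
    else:
        k = int(args.k)

    model = dfc.fit_states(pooled, counts, k, seed=args.seed,
                           n_restarts=args.restarts)
    np.savetxt(out / "centroids.tsv", model.centroids, delimiter="\t")
    pd.DataFrame({
        "subject_id": np.repeat([s for s, _ in counts], [n for _, n in counts]),
        "window": np.concatenate([np.arange(n) for _, n in counts]),
        "state": np.concatenate([model.labels[s] + 1 for s, _ in counts]),
    }).to_csv(out / "window_labels.tsv", sep="\t", index=False)

    metrics = dfc.metrics_table(model, spec, tr)
    metrics.to_csv(out / "state_metrics.tsv", sep="\t", index=False)

    occupancy = metrics.groupby("state")["fo"].mean()
    (out / "summary.json").write_text(json.dumps({
        "k": k, "sse": model.sse,
        "occupancy_percent": (100 * occupancy).round(2).to_dict(),
    }, indent=2))
    print(f"k = {k} states; total occupancy "
          f"{(100 * occupancy).round(2).to_dict()} %")
    print(f"labels/metrics -> {out}")


if __name__ == "__main__":
    main()
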
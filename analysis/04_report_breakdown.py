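#!/usr/bin/env python
"""Summarise the degradation curves: trends and breakdown levels per family.

Reads ``results/degradation_curves.csv`` (from 03_run_degradation_experiment),
writes ``results/breakdown_summary.csv`` and, if matplotlib is available,
``results/degradation_curves.png``.
"""

import argparse
import os

import numpy as np
import pandas as pd
from scipy import stats

from wearsim.experiment import find_breakdown_level


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--curves", type=str, default="results/degradation_curves.csv")
    ap.add_argument("--out", type=str, default="results/breakdown_summary.csv")
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    res = pd.read_csv(args.curves)
    base = float(res["baseline_rmse"].iloc[0])
    unp = res[res.level < 0].iloc[0]

    rows = []
    for fam, d in res[res.level >= 0].groupby("family"):
        d = d.sort_values("level")
        bp = find_breakdown_level(d.level.to_numpy(), d.mean_rmse.to_numpy(), base)
        rho = stats.spearmanr(d.level, d.mean_rmse).statistic
        rows.append(
            {
                "family": fam,
                "spearman_level_rmse": rho,
                "max_mean_rmse": d.mean_rmse.max(),
                "breakdown_level": np.nan if bp is None else bp,
                "reaches_baseline": bp is not None,
            }
        )
    summary = pd.DataFrame(rows)
    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    summary.to_csv(args.out, index=False)
    print(f"baseline RMSE {base:.4f}; unperturbed {unp.mean_rmse:.4f}")
    print(summary.to_string(index=False))
    print(f"wrote {args.out}")

    if args.plot:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            print("matplotlib unavailable; skipping plot")
            return
        fams = [f for f in ("noise", "missing", "bias", "combined") if f in set(res.family)]
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
        for ax, fam in zip(axes.ravel(), fams):
            d = res[(res.family == fam) & (res.level >= 0)].sort_values("level")
            ax.errorbar(d.level, d.mean_rmse, yerr=d.se_rmse, fmt="o-", ms=3)
            ax.axhline(base, color="r", ls="--", label="baseline")
            ax.axhline(unp.mean_rmse, color="g", ls=":", label="unperturbed")
            ax.set_title(fam)
            ax.set_xlabel("perturbation level")
            ax.set_ylabel("mean RMSE (CCI units)")
        axes[0, 0].legend()
        fig.tight_layout()
        png = os.path.join(os.path.dirname(args.out) or ".", "degradation_curves.png")
        fig.savefig(png, dpi=120)
        print(f"wrote {png}")


if __name__ == "__main__":
    main()
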
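"""All maturation statistics on the volume-pipeline cohort tables:
lateralization t-tests, metric-vs-PMA Pearson trends, adult-vs-neonate
contrasts with Cohen's d, and the branch-wise Mahalanobis analysis
(Wilcoxon across branches, Spearman against PMA, maturity ranking).

Reads results/cohort/, writes results/stats/.
"""

import json
from pathlib import Path

import pandas as pd

from slf_maturation import maturation_stats as ms

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)
    neo = pd.read_csv(ROOT / "cohort" / "neonates.tsv", sep="\t")
    adult = pd.read_csv(ROOT / "cohort" / "adults.tsv", sep="\t")

    lat = ms.lateralization_report(neo)
    lat.to_csv(out / "lateralization.tsv", sep="\t", index=False)
    n_lat = int((lat.p < 0.05).sum())
    print(f"lateralization: {n_lat}/18 uncorrected p < 0.05 (generator is symmetric)")

    trends = ms.trend_report(neo)
    trends.to_csv(out / "age_trends.tsv", sep="\t", index=False)
    sig = trends[trends.significant]
    print(
        f"age trends: {len(sig)}/18 significant at p < 0.008; "
        f"directions: " + ", ".join(
            f"{m}:{'+' if trends[trends.metric == m].r.mean() > 0 else '-'}"
            for m in ms.METRICS
        )
    )

    contrasts = ms.contrast_report(neo, adult)
    contrasts.to_csv(out / "group_contrasts.tsv", sep="\t", index=False)
    by_metric = contrasts.groupby("metric").abs_d.mean()
    print(
        "group contrasts: mean |d| per metric: "
        + ", ".join(f"{m}={by_metric[m]:.1f}" for m in ms.METRICS)
    )

    report = ms.maturation_analysis(neo, adult)
    report.distances.to_csv(out / "mahalanobis.tsv", sep="\t", index=False)
    summary = {
        "ranking_least_mature_first": list(report.ranking),
        "mean_m": {b: float(report.distances[b].mean()) for b in ms.BUNDLES},
        "wilcoxon": {
            f"{a}_vs_{b}": v for (a, b), v in report.wilcoxon.items()
        },
        "spearman_m_vs_pma": report.spearman,
        "alpha": report.alpha,
    }
    with open(out / "maturation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("\nmean Mahalanobis distance per branch:")
    for b in ms.BUNDLES:
        print(f"  {b}: {summary['mean_m'][b]:.2f}")
    print(f"least mature branch: {report.ranking[0]}")
    for pair, v in summary["wilcoxon"].items():
        print(f"  Wilcoxon {pair}: p = {v['p']:.2e} (alpha = 0.01)")
    for b, v in report.spearman.items():
        print(f"  Spearman M vs PMA {b}: rho = {v['rho']:.3f}")


if __name__ == "__main__":
    main()
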
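"""Statistical battery on the simulated cohort table.

Reads results/smoke/cohort.csv (run 02 first) and reruns the full battery:
profile one-way ANOVAs with Tukey post-hocs, the paired sulci-vs-gyri
comparison with Cohen's d, the two-way mixed ANOVA (profile × region), the
kinematics-to-sulcal-strain Pearson table and the joint OLS regressions.

Writes results/stats/report.md plus CSV tables.
"""

import dataclasses
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from sulcalstrain import stats as cs

IN = Path("results/smoke/cohort.csv")
OUT = Path("results/stats")


def main() -> None:
    if not IN.exists():
        raise SystemExit(f"{IN} not found — run analysis/02 first")
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(IN)
    report = cs.cohort_report(table)

    (OUT / "report.md").write_text(report["markdown"])
    if "correlations" in report:
        pd.DataFrame([dataclasses.asdict(c) for c in report["correlations"]]
                     ).to_csv(OUT / "correlations.csv", index=False)
    for resp, reg in report.get("regression", {}).items():
        reg.params.to_csv(OUT / f"regression_{resp}.csv", index=False)
    for name, res in report.get("anova", {}).items():
        res.posthoc.to_csv(OUT / f"posthoc_{name}.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, metric, unit in ((axes[0], "strain", ""),
                             (axes[1], "strain_rate", " (1/s)")):
        agg = table.groupby("profile")[
            [f"sulcal_mean_{metric}", f"gyral_mean_{metric}"]].mean()
        agg.plot.bar(ax=ax, rot=0, color=["#b23a48", "#457b9d"])
        ax.set_title(f"mean {metric}{unit} by profile and region")
        ax.legend(["sulcal", "gyral"])
    fig.tight_layout()
    fig.savefig(OUT / "region_by_profile.png", dpi=120)

    print(report["markdown"])
    print(f"wrote {OUT}/report.md, CSV tables and region_by_profile.png")


if __name__ == "__main__":
    main()
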
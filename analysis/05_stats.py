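"""Treatment-comparison statistics on the simulated field trial.

Mirrors the study's comparisons: plot-level growth rates centered to the
panel mean and tested with one-sample t-tests per treatment (does drought
shift shoot/root growth?), and a Type II two-way ANOVA
(genotype x treatment) with a Tukey HSD compact letter display on the
plot-level root growth rates.
"""

import argparse
from pathlib import Path

import pandas as pd

from rootshift.growth_rates import compute_trait_growth_rate
from rootshift.phenotype_io import MeasurementSchedule, read_pheno_table, select_window
from rootshift.stats_reporting import (
    compact_letter_display,
    one_sample_t,
    tukey_hsd,
    two_way_anova_typeII,
)


def plot_rates(obs, schedule, trait):
    pairs, _ = select_window(obs, schedule, "M2", "M3", trait)
    rates = compute_trait_growth_rate(pairs)
    return rates.groupby(
        ["genotype_id", "treatment", "plot_id"], as_index=False
    )["rate"].mean()


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs = read_pheno_table(args.data / "phenotypes.csv")
    schedule = MeasurementSchedule.from_file(args.data / "schedule.yaml")

    # one-sample t of each treatment's plot rates against the compartment mean
    rows = []
    for compartment, trait in (("shoot", "leaf_length_total"), ("root", "crown_root_count")):
        rates = plot_rates(obs, schedule, trait)
        overall = rates["rate"].mean()
        for treatment, grp in rates.groupby("treatment"):
            res = one_sample_t(grp["rate"], mu=overall)
            rows.append(
                {
                    "compartment": compartment,
                    "treatment": treatment,
                    "mean_rate": grp["rate"].mean(),
                    "panel_mean": overall,
                    "t": res.statistic,
                    "df": res.df,
                    "pvalue": res.pvalue,
                    "n": res.n,
                }
            )
    ttests = pd.DataFrame(rows)
    ttests.to_csv(args.out / "ttests.csv", index=False)
    print("one-sample t of treatment plot rates vs the panel mean (M2->M3):")
    print(ttests.round(4).to_string(index=False))

    # Type II ANOVA + Tukey on plot-level root rates
    root = plot_rates(obs, schedule, "crown_root_count")
    anova = two_way_anova_typeII(root["rate"], root["genotype_id"], root["treatment"])
    anova.to_csv(args.out / "anova_root_rate.csv", index=False)
    print("\nType II ANOVA on plot-level rootGR (genotype x treatment):")
    print(anova.round(4).to_string(index=False))

    means = root.groupby("treatment")["rate"].mean().to_dict()
    ns = root.groupby("treatment")["rate"].size().to_dict()
    resid = sum(
        ((g["rate"] - g["rate"].mean()) ** 2).sum() for _, g in root.groupby("treatment")
    )
    df_resid = len(root) - len(means)
    comparisons = tukey_hsd(means, resid / df_resid, ns, df_resid)
    comparisons.to_csv(args.out / "tukey_root_rate.csv", index=False)
    letters = compact_letter_display(comparisons, means)
    print("\nTukey HSD on rootGR by treatment:")
    print(comparisons.round(4).to_string(index=False))
    print(f"letters: {letters}")


if __name__ == "__main__":
    main()
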
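"""Compute shoot and root growth rates over the recovery window (M2 -> M3)
and rank genotypes by the Water Recovery Index.

Reads results/data/phenotypes.csv (run 01_simulate.py first), writes the
line-level growth rates and the ranked WRI table, and reports how well the
ranking recovers the planted strategy.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy import stats as sps

from rootshift.growth_rates import aggregate_rates, compute_trait_growth_rate
from rootshift.phenotype_io import MeasurementSchedule, read_pheno_table, select_window
from rootshift.wri import compute_wri_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--window", default="M2:M3")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs = read_pheno_table(args.data / "phenotypes.csv")
    schedule = MeasurementSchedule.from_file(args.data / "schedule.yaml")
    window = tuple(args.window.split(":"))

    lines = []
    for compartment, trait in (("shoot", "leaf_length_total"), ("root", "crown_root_count")):
        pairs, dropped = select_window(obs, schedule, window[0], window[1], trait)
        rates = compute_trait_growth_rate(pairs)
        lines.append(aggregate_rates(rates, compartment, window))
        print(f"{compartment}: {len(pairs)} plant pairs, {dropped} dropped")
    line_rates = pd.concat(lines, ignore_index=True)
    line_rates.to_csv(args.out / "growth_rates.csv", index=False)

    wri = compute_wri_table(obs, schedule, window)
    wri.to_csv(args.out / "wri.csv", index=False)
    print(f"\nWRI over {args.window} for {len(wri)} genotypes:")
    print(wri.head(3).to_string(index=False))
    print("...")
    print(wri.tail(3).to_string(index=False))

    truth_path = args.data / "truth_field.csv"
    if truth_path.exists():
        merged = wri.merge(pd.read_csv(truth_path), on="genotype_id")
        rho = sps.spearmanr(merged["strategy"], merged["wri"]).statistic
        print(f"\nSpearman(planted strategy, WRI) = {rho:.3f}")


if __name__ == "__main__":
    main()
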
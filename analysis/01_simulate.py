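"""Generate the synthetic study data: field phenotypes, three-season GWAS
summary tables with planted cross-season peaks, and glasshouse root systems
under well-watered / drought / recovered conditions.

Writes the tables plus their latent truth under results/data/.
"""

import argparse
from pathlib import Path

import pandas as pd

from rootshift.phenotype_io import write_pheno_table
from rootshift.synthetic_data import (
    FieldSimConfig,
    GwasSimConfig,
    PlantedPeak,
    RootSimConfig,
    gen_field_phenotypes,
    gen_gwas_tables,
    gen_root_system,
)

PLANTED_PEAKS = (
    PlantedPeak("1", 4_000_000, ("2017", "2018"), 4.5),
    PlantedPeak("1", 12_000_000, ("2018", "2019"), 4.0),
    PlantedPeak("2", 8_000_000, ("2017", "2019"), 5.0),
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    field_cfg = FieldSimConfig(seed=args.seed)
    obs, field_truth = gen_field_phenotypes(field_cfg)
    write_pheno_table(obs, args.out / "phenotypes.csv")
    field_truth.to_csv(args.out / "truth_field.csv", index=False)
    field_cfg.schedule.to_file(args.out / "schedule.yaml")
    print(
        f"field trial: {len(obs)} observations "
        f"({field_cfg.n_genotypes} genotypes x 2 treatments x "
        f"{field_cfg.n_plots} plots x {field_cfg.n_plants} plants, M1-M4)"
    )

    gwas_cfg = GwasSimConfig(seed=args.seed, planted_peaks=PLANTED_PEAKS)
    hits, gwas_truth = gen_gwas_tables(gwas_cfg)
    hits.to_csv(args.out / "gwas_hits.csv", index=False)
    gwas_truth.to_csv(args.out / "truth_gwas.csv", index=False)
    print(
        f"gwas: {len(hits)} summary rows over {len(gwas_cfg.seasons)} seasons, "
        f"{len(PLANTED_PEAKS)} planted cross-season peaks"
    )

    root_cfg = RootSimConfig(seed=args.seed)
    frames = []
    for condition in ("well_watered", "drought", "recovered"):
        seg, truth = gen_root_system(root_cfg, condition, plant_id=condition)
        frames.append(seg)
        print(
            f"roots [{condition}]: {len(seg)} segments, "
            f"S/L/axial proportions {truth['prop_S']:.2f}/{truth['prop_L']:.2f}/"
            f"{truth['prop_axial']:.2f}"
        )
    pd.concat(frames, ignore_index=True).to_csv(args.out / "root_segments.csv", index=False)


if __name__ == "__main__":
    main()
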
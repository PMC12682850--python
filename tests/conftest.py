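import numpy as np
import pandas as pd
import pytest

from rootshift.phenotype_io import FIELD_SCHEDULE


@pytest.fixture
def tiny_pheno() -> pd.DataFrame:
    """One genotype, both treatments, one plot, one plant, leaf length at M2/M3."""
    rows = []
    for treatment in ("drought", "well_watered"):
        for label in ("M2", "M3"):
            das = FIELD_SCHEDULE.das_of(treatment, label)
            value = 30.0 if label == "M2" else 36.0
            rows.append(("G01", treatment, "B1", "P1", "pl1", das, "leaf_length_total", value))
    return pd.DataFrame(
        rows,
        columns=[
            "genotype_id",
            "treatment",
            "block_id",
            "plot_id",
            "plant_id",
            "das",
            "trait",
            "value",
        ],
    )


def random_pheno_table(rng: np.random.Generator, n_genotypes: int = 3) -> pd.DataFrame:
    """Small random but valid tidy phenotype table (unique keys by construction)."""
    rows = []
    for g in range(n_genotypes):
        for treatment in ("drought", "well_watered"):
            for plot in range(1, 3):
                for das in (29, 34):
                    for trait in ("leaf_length_total", "crown_root_count"):
                        value = (
                            float(rng.integers(0, 30))
                            if trait == "crown_root_count"
                            else float(np.round(rng.uniform(0, 80), 6))
                        )
                        rows.append(
                            (
                                f"G{g:02d}",
                                treatment,
                                f"B{plot}",
                                f"G{g:02d}-{treatment[:2]}-P{plot}",
                                "pl1",
                                das,
                                trait,
                                value,
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype_id",
            "treatment",
            "block_id",
            "plot_id",
            "plant_id",
            "das",
            "trait",
            "value",
        ],
    )
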
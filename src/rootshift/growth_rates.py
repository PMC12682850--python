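"""Relative and per-trait growth rates with plant -> plot -> line averaging.

The relative growth rate (RGR) of shoot biomass between two destructive
harvests is ``(ln SDW2 - ln SDW1) / dt`` in g new growth per g existing
plant per day, the standard measure of how fast a plant regrows after
re-watering relative to its size. Per-compartment growth rates (shootGR
from total leaf length, rootGR from crown root number) are simple
differences per day and may legitimately be negative, since destructive
sampling measures different plants at each timepoint.

Aggregation follows the field design: plants are averaged within plot,
then plot means are averaged per line (unweighted two-stage mean).
Spatial (block) variation is removed by additive block-centering — an
approximation, exact on balanced designs, to a mixed-model least-squares
mean; outputs are labelled "block-adjusted".
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "compute_rgr",
    "compute_trait_growth_rate",
    "aggregate_rates",
    "block_adjust_rgr",
]


def compute_rgr(sdw1, sdw2, dt):
    """RGR = (ln(sdw2) - ln(sdw1)) / dt, elementwise over arrays.

    Weights must be strictly positive (a zero dry weight is a data error,
    not a small plant) and ``dt`` strictly positive.
    """
    sdw1 = np.asarray(sdw1, dtype=float)
    sdw2 = np.asarray(sdw2, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(sdw1 <= 0) or np.any(sdw2 <= 0):
        raise ValueError("shoot dry weights must be strictly positive")
    if np.any(dt <= 0):
        raise ValueError("dt must be strictly positive")
    out = (np.log(sdw2) - np.log(sdw1)) / dt
    return float(out) if out.ndim == 0 else out


def compute_trait_growth_rate(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-plant rate ``(value_end - value_start) / dt`` in trait units per day.

    ``pairs`` is the output of :func:`rootshift.phenotype_io.select_window`.
    Negative rates are preserved.
    """
    out = pairs.copy()
    out["rate"] = (out["value_end"] - out["value_start"]) / out["dt"]
    return out


def aggregate_rates(
    plant_rates: pd.DataFrame,
    compartment: str,
    window: Tuple[str, str],
) -> pd.DataFrame:
    """Two-stage unweighted mean: plants within plot, then plots within line.

    Returns one record per genotype x treatment with the line-mean ``rate``
    and the ``n_plots`` / ``n_plants`` actually used.
    """
    if plant_rates.empty:
        raise ValueError("no plant rates to aggregate")
    plot = (
        plant_rates.groupby(["genotype_id", "treatment", "plot_id"], as_index=False)
        .agg(rate=("rate", "mean"), n_plants=("rate", "size"))
    )
    line = (
        plot.groupby(["genotype_id", "treatment"], as_index=False)
        .agg(rate=("rate", "mean"), n_plots=("plot_id", "nunique"), n_plants=("n_plants", "sum"))
    )
    line["compartment"] = compartment
    line["window"] = f"{window[0]}:{window[1]}"
    return line[
        ["genotype_id", "treatment", "compartment", "window", "rate", "n_plots", "n_plants"]
    ]


def block_adjust_rgr(records: pd.DataFrame, value_col: str = "rgr") -> pd.DataFrame:
    """Remove additive block effects, then average per genotype.

    Each observation is centered by its block's deviation from the grand
    mean; genotype means of the centered values are returned. On a balanced
    design this equals the raw genotype means; with a single block it is the
    identity (a notice is emitted). The grand mean is conserved.
    """
    required = {"genotype_id", "block_id", value_col}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    grand = records[value_col].mean()
    if records["block_id"].nunique() == 1:
        warnings.warn("single block: block adjustment is the identity", stacklevel=2)
        adjusted = records[value_col]
    else:
        block_dev = records.groupby("block_id")[value_col].transform("mean") - grand
        adjusted = records[value_col] - block_dev
    out = (
        records.assign(**{value_col: adjusted})
        .groupby("genotype_id", as_index=False)[value_col]
        .mean()
    )
    return out
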
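"""The Water Recovery Index (WRI): shoot-vs-root investment after re-watering.

The WRI ranks rice lines by how strongly they shift growth towards crown
roots (relative to leaf elongation) when water returns after a drought.
The construction, per treatment:

1. line-level shoot and root growth rates over a window spanning the end
   of drought to early recovery (default M2 -> M3);
2. rescale each (treatment, compartment) vector of line means linearly to
   [1, 100] so that negative rates (possible with destructive sampling)
   become positive and comparable;
3. SRGR = ln(rescaled shootGR / rescaled rootGR) per line and treatment
   (the log makes the ratio symmetric and roughly normal);
4. WRI = SRGR(drought) - SRGR(well-watered).

More negative WRI means stronger relative investment in crown-root growth
during recovery ("conservative" strategy); WRI near zero means the line
grows similarly with and without the drought episode ("less-conservative").
WRI values are comparable only within one experiment — they depend on the
age and stage of the plants measured.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from .growth_rates import aggregate_rates, compute_trait_growth_rate
from .phenotype_io import FIELD_SCHEDULE, MeasurementSchedule, select_window

__all__ = [
    "rescale_1_100",
    "compute_srgr",
    "compute_wri",
    "rank_strategies",
    "compute_wri_table",
]


def rescale_1_100(values) -> np.ndarray:
    """Affine map of a vector onto [1, 100]: ``x -> 1 + 99 (x - min)/(max - min)``.

    Order-preserving; a constant vector maps to the interval midpoint 50.5
    so that downstream log-ratios stay defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rescale an empty collection")
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot rescale non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 50.5)
    # grouping matters: (x - lo)/(hi - lo) is exactly 1 for the maximum, so
    # the endpoints land on exactly 1 and 100; clip guards interior one-ulp spill
    return np.clip(1.0 + 99.0 * ((x - lo) / (hi - lo)), 1.0, 100.0)


def compute_srgr(rescaled_shoot, rescaled_root):
    """SRGR = ln(rescaled shootGR / rescaled rootGR); zero iff the inputs tie.

    Both inputs must already be on the [1, 100] scale (hence positive).
    """
    s = np.asarray(rescaled_shoot, dtype=float)
    r = np.asarray(rescaled_root, dtype=float)
    for name, v in (("rescaled_shoot", s), ("rescaled_root", r)):
        if np.any((v < 1.0) | (v > 100.0)):
            raise ValueError(f"{name} must lie in [1, 100]")
    out = np.log(s / r)
    return float(out) if out.ndim == 0 else out


def compute_wri(srgr_drought, srgr_well_watered):
    """WRI = SRGR(drought) - SRGR(well-watered).

    More negative values indicate stronger relative crown-root investment
    during drought recovery.
    """
    d = np.asarray(srgr_drought, dtype=float)
    w = np.asarray(srgr_well_watered, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(~np.isfinite(w)):
        raise ValueError("SRGR inputs must be finite")
    out = d - w
    return float(out) if out.ndim == 0 else out


def rank_strategies(wri_records: pd.DataFrame) -> pd.DataFrame:
    """Sort genotypes by WRI ascending and attach strategy ranks/labels.

    Rank 1 is the most negative WRI. Ties break lexicographically by
    genotype_id for determinism. The extremes are labelled "conservative"
    (lowest WRI) and "less-conservative" (highest).
    """
    if len(wri_records) < 2:
        raise ValueError("need at least two genotypes to rank strategies")
    out = wri_records.sort_values(
        ["wri", "genotype_id"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["strategy_rank"] = np.arange(1, len(out) + 1)
    labels = [""] * len(out)
    labels[0] = "conservative"
    labels[-1] = "less-conservative"
    out["strategy_label"] = labels
    return out


def compute_wri_table(
    obs: pd.DataFrame,
    schedule: MeasurementSchedule = FIELD_SCHEDULE,
    window: Tuple[str, str] = ("M2", "M3"),
    shoot_trait: str = "leaf_length_total",
    root_trait: str = "crown_root_count",
) -> pd.DataFrame:
    """Full WRI pipeline from a tidy phenotype table.

    Runs endpoint pairing, per-plant rates, two-stage line averaging,
    per-(treatment, compartment) rescaling of line means, SRGR, and the
    drought-minus-control difference. Genotypes missing either treatment
    are excluded with a warning.

    Returns a ranked table with columns ``genotype_id, srgr_drought,
    srgr_well_watered, wri, strategy_rank, strategy_label``.
    """
    lines = []
    for compartment, trait in (("shoot", shoot_trait), ("root", root_trait)):
        pairs, _ = select_window(obs, schedule, window[0], window[1], trait)
        rates = compute_trait_growth_rate(pairs)
        lines.append(aggregate_rates(rates, compartment, window))
    line_rates = pd.concat(lines, ignore_index=True)

    # Rescale across genotype-level means within each (treatment, compartment).
    line_rates["rescaled"] = line_rates.groupby(["treatment", "compartment"])[
        "rate"
    ].transform(rescale_1_100)

    wide = line_rates.pivot_table(
        index=["genotype_id", "treatment"], columns="compartment", values="rescaled"
    ).reset_index()
    wide["srgr"] = compute_srgr(wide["shoot"].to_numpy(), wide["root"].to_numpy())
    srgr = wide.pivot(index="genotype_id", columns="treatment", values="srgr")

    missing = srgr.index[srgr.isna().any(axis=1)]
    if len(missing):
        warnings.warn(
            f"excluding genotype(s) missing a treatment: {', '.join(map(str, missing))}",
            stacklevel=2,
        )
        srgr = srgr.drop(index=missing)

    out = pd.DataFrame(
        {
            "genotype_id": srgr.index,
            "srgr_drought": srgr["drought"].to_numpy(),
            "srgr_well_watered": srgr["well_watered"].to_numpy(),
        }
    )
    out["wri"] = compute_wri(
        out["srgr_drought"].to_numpy(), out["srgr_well_watered"].to_numpy()
    )
    return rank_strategies(out)
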
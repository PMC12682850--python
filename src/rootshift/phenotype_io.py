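"""Tidy phenotype tables, measurement schedules, and endpoint pairing.

The field design this package analyses measures each plant repeatedly at a
small number of destructive/non-destructive timepoints labelled M1..M4
(M1 before drought, M2 at the end of drought, M3 in early recovery, M4 about
one week after re-watering). All times are expressed in days after sowing
(DAS). Because the control treatment's M2/M3 measurements happen one day
later than the drought treatment's, each treatment carries its own label to
DAS mapping (:class:`MeasurementSchedule`), and every time interval is
computed from the treatment's own schedule.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with
one row per measured value, columns ``genotype_id, treatment, block_id,
plot_id, plant_id, das, trait, value``. Missing values are absent rows,
never sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PHENO_COLUMNS",
    "KEY_COLUMNS",
    "TRAITS",
    "TREATMENTS",
    "LABELS",
    "FIELD_SCHEDULE",
    "PhenoSchemaError",
    "PhenoValidationError",
    "ScheduleError",
    "MeasurementSchedule",
    "validate_pheno",
    "read_pheno_table",
    "write_pheno_table",
    "select_window",
]

PHENO_COLUMNS = [
    "genotype_id",
    "treatment",
    "block_id",
    "plot_id",
    "plant_id",
    "das",
    "trait",
    "value",
]

#: Columns that together identify a single measurement (block_id is a
#: property of the plot, not part of the key).
KEY_COLUMNS = ["genotype_id", "treatment", "plot_id", "plant_id", "das", "trait"]

TREATMENTS = ("drought", "well_watered")

#: Trait vocabulary with fixed units; no unit conversion happens anywhere.
TRAITS = {
    "leaf_length_total": "cm",
    "crown_root_count": "count",
    "shoot_dry_weight": "g",
    "root_dry_weight": "g",
    "root_length_total": "cm",
    "leaf_area": "cm2",
}

#: Traits whose values must be non-negative.
_NONNEG_TRAITS = frozenset(TRAITS)

LABELS = ("M1", "M2", "M3", "M4")


class PhenoSchemaError(ValueError):
    """A required column is missing or mis-typed."""


class PhenoValidationError(ValueError):
    """A row violates a data-model invariant (reported with its source line)."""


class ScheduleError(ValueError):
    """A measurement schedule is inconsistent (non-increasing DAS, dt <= 0)."""


@dataclass(frozen=True)
class MeasurementSchedule:
    """Label -> DAS mapping, kept separately per treatment.

    Parameters
    ----------
    das
        ``{treatment: {label: das}}``. Labels must be a prefix-closed subset
        of ``M1..M4`` with strictly increasing DAS within each treatment.
    """

    das: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for treatment, mapping in self.das.items():
            if treatment not in TREATMENTS:
                raise ScheduleError(f"unknown treatment {treatment!r}")
            ordered = [mapping[lab] for lab in LABELS if lab in mapping]
            if any(b <= a for a, b in zip(ordered, ordered[1:])):
                raise ScheduleError(
                    f"DAS must strictly increase M1<M2<M3<M4 for {treatment!r}: {mapping}"
                )

    def das_of(self, treatment: str, label: str) -> int:
        try:
            return int(self.das[treatment][label])
        except KeyError as exc:
            raise ScheduleError(
                f"label {label!r} not scheduled for treatment {treatment!r}"
            ) from exc

    def delta_t(self, treatment: str, start_label: str, end_label: str) -> int:
        """Days between two labels under one treatment's own schedule."""
        dt = self.das_of(treatment, end_label) - self.das_of(treatment, start_label)
        if dt <= 0:
            raise ScheduleError(
                f"non-positive interval {start_label}->{end_label} for {treatment!r}"
            )
        return dt

    @classmethod
    def from_file(cls, path: str | Path) -> "MeasurementSchedule":
        """Load a plain-text key-value (YAML) schedule: treatment -> label -> DAS."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls({t: {k: int(v) for k, v in m.items()} for t, m in raw.items()})

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({t: dict(m) for t, m in self.das.items()}, fh)
        return path


#: The recovery field experiment's schedule: drought measured at 29/34/37/42
#: DAS, control at 29/35/38/42 (M2/M3 delayed by one day).
FIELD_SCHEDULE = MeasurementSchedule(
    {
        "drought": {"M1": 29, "M2": 34, "M3": 37, "M4": 42},
        "well_watered": {"M1": 29, "M2": 35, "M3": 38, "M4": 42},
    }
)


def validate_pheno(obs: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy phenotype table against the data-model invariants.

    Returns the table (with ``das`` as integer dtype) if valid; raises
    :class:`PhenoSchemaError` or :class:`PhenoValidationError` otherwise.
    Row numbers in messages are 1-based data rows (header excluded).
    """
    missing = [c for c in PHENO_COLUMNS if c not in obs.columns]
    if missing:
        raise PhenoSchemaError(f"missing required column(s): {', '.join(missing)}")
    obs = obs.loc[:, PHENO_COLUMNS].copy()

    value = pd.to_numeric(obs["value"], errors="coerce")
    bad = obs.index[value.isna() | ~np.isfinite(value)]
    if len(bad):
        raise PhenoValidationError(
            f"non-numeric or non-finite value at data row(s) {_rows(obs, bad)}"
        )
    obs["value"] = value.astype(float)

    das = pd.to_numeric(obs["das"], errors="coerce")
    bad = obs.index[das.isna() | (das != das.round()) | (das < 0)]
    if len(bad):
        raise PhenoValidationError(
            f"das must be a non-negative integer; bad row(s) {_rows(obs, bad)}"
        )
    obs["das"] = das.astype(int)

    bad = obs.index[~obs["treatment"].isin(TREATMENTS)]
    if len(bad):
        raise PhenoValidationError(f"unknown treatment at row(s) {_rows(obs, bad)}")
    bad = obs.index[~obs["trait"].isin(TRAITS)]
    if len(bad):
        raise PhenoValidationError(f"unknown trait at row(s) {_rows(obs, bad)}")

    crn = obs["trait"] == "crown_root_count"
    v = obs["value"]
    bad = obs.index[crn & ((v < 0) | (v != v.round()))]
    if len(bad):
        raise PhenoValidationError(
            f"crown_root_count must be a non-negative integer; bad row(s) {_rows(obs, bad)}"
        )
    bad = obs.index[obs["trait"].isin(_NONNEG_TRAITS) & (v < 0)]
    if len(bad):
        raise PhenoValidationError(f"negative trait value at row(s) {_rows(obs, bad)}")

    dup = obs.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        raise PhenoValidationError(
            "duplicate (genotype, treatment, plot, plant, das, trait) key at "
            f"row(s) {_rows(obs, obs.index[dup])}"
        )
    return obs


def _rows(obs: pd.DataFrame, idx) -> str:
    positions = [obs.index.get_loc(i) + 1 for i in list(idx)[:10]]
    tail = ", ..." if len(idx) > 10 else ""
    return ", ".join(str(p) for p in positions) + tail


def read_pheno_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy phenotype CSV.

    The header must name all required columns; extra columns are dropped.
    """
    path = Path(path)
    obs = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS[:4]} | {"block_id": str})
    return validate_pheno(obs)


def write_pheno_table(obs: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated phenotype table as CSV with fixed column order."""
    obs = validate_pheno(obs)
    path = Path(path)
    obs.to_csv(path, index=False)
    return path


def select_window(
    obs: pd.DataFrame,
    schedule: MeasurementSchedule,
    start_label: str,
    end_label: str,
    trait: str,
) -> Tuple[pd.DataFrame, int]:
    """Pair each plant's trait values at two schedule labels.

    For every (genotype, treatment, plot, plant) that has the trait measured
    at both the start and end label of its treatment's own schedule, emit one
    row with ``value_start``, ``value_end`` and ``dt`` (days). Plants lacking
    either endpoint are dropped and counted.

    Returns
    -------
    (pairs, n_dropped)
        ``pairs`` has columns ``genotype_id, treatment, block_id, plot_id,
        plant_id, value_start, value_end, dt``.
    """
    if trait not in TRAITS:
        raise PhenoValidationError(f"unknown trait {trait!r}")
    sub = obs[obs["trait"] == trait]
    frames = []
    n_dropped = 0
    keys = ["genotype_id", "treatment", "block_id", "plot_id", "plant_id"]
    for treatment in sorted(sub["treatment"].unique()):
        dt = schedule.delta_t(treatment, start_label, end_label)
        d0 = schedule.das_of(treatment, start_label)
        d1 = schedule.das_of(treatment, end_label)
        t_sub = sub[sub["treatment"] == treatment]
        start = t_sub[t_sub["das"] == d0][keys + ["value"]].rename(
            columns={"value": "value_start"}
        )
        end = t_sub[t_sub["das"] == d1][keys + ["value"]].rename(
            columns={"value": "value_end"}
        )
        merged = start.merge(end, on=keys, how="outer")
        incomplete = merged["value_start"].isna() | merged["value_end"].isna()
        n_dropped += int(incomplete.sum())
        merged = merged[~incomplete].copy()
        merged["dt"] = dt
        frames.append(merged)
    if frames:
        pairs = pd.concat(frames, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=keys + ["value_start", "value_end", "dt"])
    return pairs, n_dropped
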
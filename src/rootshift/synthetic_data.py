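"""Synthetic field, GWAS, and root-system data with planted, known truth.

No phenotype or genotype data accompany the study design this package
analyses, so every pipeline stage is exercised on generated data that
emulates the experimental designs:

* a recovery field trial — 20 genotypes x 2 treatments x 4 replicate plots
  x 2 marked plants, measured at four timepoints (drought 29/34/37/42 DAS,
  control 29/35/38/42), with a latent per-genotype *strategy* in [0, 1]
  (0 = conservative: shoot growth strongly suppressed by drought and crown
  root production strongly boosted after re-watering; 1 = less-conservative:
  little treatment contrast);
* three seasons of GWAS summary tables with planted cross-season peaks over
  a uniform p-value background;
* glasshouse root systems whose S-type/L-type/axial composition shifts
  under drought (fewer S-type, proportionally more L-type laterals, more
  second-order S-type) and reverts at recovery.

Every generator is a pure function of its config (including the seed) and
returns the data together with the latent truth needed to score downstream
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .phenotype_io import FIELD_SCHEDULE, MeasurementSchedule, validate_pheno

__all__ = [
    "FieldSimConfig",
    "PlantedPeak",
    "GwasSimConfig",
    "RootSimConfig",
    "gen_field_phenotypes",
    "gen_gwas_tables",
    "gen_root_system",
    "glasshouse_watering_target",
]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


def _sigma_log(cv: float) -> float:
    """Log-sd of a mean-one lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = _sigma_log(cv)
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


# ---------------------------------------------------------------------------
# Field trial
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSimConfig:
    """Recovery-field-trial generator settings.

    Effect sizes interpolate linearly in the strategy ``s``: the drought
    shoot-rate factor is ``shoot_suppression + (1 - shoot_suppression) s``
    (0.5x for the most conservative line, 1.0x for the least) and the
    post-re-watering root-rate factor is ``root_boost + (1 - root_boost) s``
    (1.5x down to 1.0x). Baselines describe a vegetative rice stand around
    29 DAS: 40 cm total leaf length growing 2 cm/d, ~15 crown roots adding
    5 roots/d when well watered (tillering-stage nodal root production).

    Noise is multiplicative and mean-one lognormal, structured as
    whole-plant effects: a genotype-level vigor factor (diverse accessions
    genuinely differ), a plot x window factor (soil patches affect the
    whole plot), and a plant x window factor (establishment differences
    affect the whole plant). All three multiply shoot and root rates of
    the same plant alike — both traits are recorded on the same marked
    plants — which is what lets the treatment contrast, rather than
    sampling noise, dominate the rescaled shoot:root ratio.
    """

    n_genotypes: int = 20
    n_plots: int = 4
    n_plants: int = 2
    schedule: MeasurementSchedule = FIELD_SCHEDULE
    strategy: Optional[Tuple[float, ...]] = None  # default: evenly spaced in [0, 1]
    shoot_suppression: float = 0.5
    root_boost: float = 1.5
    drought_root_suppression: float = 0.6  # rootGR factor under drought before re-watering
    leaf_base_cm: float = 40.0
    leaf_rate_cm_d: float = 2.0
    root_base_count: float = 15.0
    root_rate_d: float = 5.0
    genotype_cv: float = 0.05
    plot_cv: float = 0.10
    plant_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_plots, self.n_plants) < 1:
            raise ConfigError("counts must be >= 1")
        if min(self.shoot_suppression, self.root_boost, self.drought_root_suppression) <= 0:
            raise ConfigError("effect factors must be > 0")
        if min(self.genotype_cv, self.plot_cv, self.plant_cv) < 0:
            raise ConfigError("CVs must be >= 0")
        if self.strategy is not None:
            s = np.asarray(self.strategy, dtype=float)
            if len(s) != self.n_genotypes or np.any((s < 0) | (s > 1)):
                raise ConfigError("strategy must give one value in [0, 1] per genotype")


_WINDOWS = (("M1", "M2"), ("M2", "M3"), ("M3", "M4"))


def _true_rates(cfg: FieldSimConfig, s: np.ndarray, vigor: np.ndarray) -> Dict:
    """Noise-free per-window rates, keyed (treatment, compartment, window)."""
    shoot_fac = cfg.shoot_suppression + (1 - cfg.shoot_suppression) * s
    boost_fac = cfg.root_boost + (1 - cfg.root_boost) * s
    supp_fac = cfg.drought_root_suppression + (1 - cfg.drought_root_suppression) * s
    rates = {}
    for w in _WINDOWS:
        rates[("well_watered", "shoot", w)] = cfg.leaf_rate_cm_d * vigor
        rates[("well_watered", "root", w)] = cfg.root_rate_d * vigor
        rates[("drought", "shoot", w)] = cfg.leaf_rate_cm_d * vigor * shoot_fac
    rates[("drought", "root", ("M1", "M2"))] = cfg.root_rate_d * vigor * supp_fac
    for w in (("M2", "M3"), ("M3", "M4")):
        rates[("drought", "root", w)] = cfg.root_rate_d * vigor * boost_fac
    return rates


def gen_field_phenotypes(cfg: FieldSimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the recovery field trial.

    Leaf length grows piecewise-linearly between the four measurement
    labels; crown-root counts do the same but are rounded to integers at
    each timepoint (counts are integers by definition). Multiplicative
    mean-one lognormal noise enters at genotype, plot x window, and
    plant x window level.

    Returns
    -------
    (observations, truth)
        ``observations`` is a validated tidy phenotype table (with the
        default config: 2560 rows). ``truth`` has one row per genotype with
        the latent strategy, vigor, and the noise-free M2->M3 rates per
        treatment and compartment.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genotypes
    genotypes = [f"G{i + 1:02d}" for i in range(n)]
    s = (
        np.asarray(cfg.strategy, dtype=float)
        if cfg.strategy is not None
        else (np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5]))
    )
    vigor = _lognormal_mean1(rng, cfg.genotype_cv, n)
    rates = _true_rates(cfg, s, vigor)

    traits = (("leaf_length_total", "shoot"), ("crown_root_count", "root"))
    rows = []
    for gi, g in enumerate(genotypes):
        for treatment in ("drought", "well_watered"):
            labels = ["M1", "M2", "M3", "M4"]
            das = [cfg.schedule.das_of(treatment, lab) for lab in labels]
            for plot in range(1, cfg.n_plots + 1):
                block = f"B{plot}"
                plot_id = f"{g}-{treatment[:2]}-P{plot}"
                # whole-plot factor per window, common to both compartments
                plot_noise = {w: _lognormal_mean1(rng, cfg.plot_cv, None) for w in _WINDOWS}
                for plant in range(1, cfg.n_plants + 1):
                    plant_id = f"{plot_id}-pl{plant}"
                    # whole-plant factor per window; both traits are measured
                    # on the same marked plant
                    plant_noise = {
                        w: _lognormal_mean1(rng, cfg.plant_cv, None) for w in _WINDOWS
                    }
                    for trait, comp in traits:
                        base = (
                            cfg.leaf_base_cm if comp == "shoot" else cfg.root_base_count
                        ) * vigor[gi] * _lognormal_mean1(rng, cfg.plant_cv, None)
                        values = [base]
                        for w, (d0, d1) in zip(_WINDOWS, zip(das, das[1:])):
                            rate = (
                                rates[(treatment, comp, w)][gi]
                                * plot_noise[w]
                                * plant_noise[w]
                            )
                            values.append(values[-1] + rate * (d1 - d0))
                        for lab_das, v in zip(das, values):
                            if trait == "crown_root_count":
                                v = max(0.0, float(np.round(v)))
                            rows.append(
                                (g, treatment, block, plot_id, plant_id, lab_das, trait, v)
                            )
    obs = pd.DataFrame(
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
    truth = pd.DataFrame(
        {
            "genotype_id": genotypes,
            "strategy": s,
            "vigor": vigor,
            "shoot_rate_drought_M2M3": rates[("drought", "shoot", ("M2", "M3"))],
            "root_rate_drought_M2M3": rates[("drought", "root", ("M2", "M3"))],
            "shoot_rate_ww_M2M3": rates[("well_watered", "shoot", ("M2", "M3"))],
            "root_rate_ww_M2M3": rates[("well_watered", "root", ("M2", "M3"))],
        }
    )
    return validate_pheno(obs), truth


# ---------------------------------------------------------------------------
# GWAS summary tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPeak:
    chrom: str
    pos: int
    seasons: Tuple[str, ...]
    neglog10p: float = 4.0


@dataclass(frozen=True)
class GwasSimConfig:
    """Per-season GWAS summary-table generator settings.

    Background SNPs get p-values uniform on (background_min_p, 1); setting
    ``background_min_p > 1e-3`` guarantees no background SNP survives the
    -log10(p) >= 3 filter. Planted peak positions are jittered across
    seasons by at most window/4 each way, so realized positions within one
    peak stay within window/2 of each other and always chain into one
    cluster.
    """

    seasons: Tuple[str, ...] = ("2017", "2018", "2019")
    chromosomes: Tuple[str, ...] = ("1", "2")
    n_snps_per_chrom: int = 200
    chrom_length_bp: int = 30_000_000
    planted_peaks: Tuple[PlantedPeak, ...] = ()
    window_bp: int = 100_000
    background_min_p: float = 0.0
    assert_separation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.seasons) < 2:
            raise ConfigError("need >= 2 seasons")
        if not (0 <= self.background_min_p < 1):
            raise ConfigError("background_min_p must lie in [0, 1)")
        for pk in self.planted_peaks:
            if pk.chrom not in self.chromosomes:
                raise ConfigError(f"planted peak on unknown chromosome {pk.chrom!r}")
            if any(s not in self.seasons for s in pk.seasons):
                raise ConfigError("planted peak names an unknown season")
        if self.assert_separation:
            by_chrom: Dict[str, list] = {}
            for pk in self.planted_peaks:
                by_chrom.setdefault(pk.chrom, []).append(pk.pos)
            for chrom, positions in by_chrom.items():
                positions = sorted(positions)
                for a, b in zip(positions, positions[1:]):
                    if b - a <= 2 * self.window_bp:
                        raise ConfigError(
                            f"planted peaks on chrom {chrom} closer than 2x window"
                        )


def gen_gwas_tables(cfg: GwasSimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate multi-season GWAS summary tables.

    Returns the combined hit table (``season,snp_id,chrom,pos,pvalue,maf``)
    and a truth table listing each planted peak's realized cross-season
    interval.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for season in cfg.seasons:
        for chrom in cfg.chromosomes:
            pos = rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_snps_per_chrom)
            pval = rng.uniform(cfg.background_min_p, 1.0, size=cfg.n_snps_per_chrom)
            maf = rng.uniform(0.0, 0.5, size=cfg.n_snps_per_chrom)
            for j in range(cfg.n_snps_per_chrom):
                rows.append(
                    (season, f"bg_{season}_{chrom}_{j}", chrom, int(pos[j]), float(pval[j]), float(maf[j]))
                )
    truth_rows = []
    jmax = cfg.window_bp // 4
    for k, pk in enumerate(cfg.planted_peaks):
        realized = []
        for season in pk.seasons:
            p = 10.0 ** (-(pk.neglog10p + rng.uniform(0.0, 0.5)))
            jit = int(rng.integers(-jmax, jmax + 1))
            pos = max(1, pk.pos + jit)
            realized.append(pos)
            rows.append(
                (season, f"peak{k}_{season}", pk.chrom, pos, p, float(rng.uniform(0.1, 0.5)))
            )
        truth_rows.append(
            {
                "peak_id": k,
                "chrom": pk.chrom,
                "start": min(realized),
                "end": max(realized),
                "seasons": ";".join(pk.seasons),
                "neglog10p": pk.neglog10p,
            }
        )
    hits = pd.DataFrame(
        rows, columns=["season", "snp_id", "chrom", "pos", "pvalue", "maf"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["peak_id", "chrom", "start", "end", "seasons", "neglog10p"]
    )
    return hits, truth


# ---------------------------------------------------------------------------
# Root systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootSimConfig:
    """Glasshouse root-system generator settings.

    Axial roots are chains of segments; each internal chain segment bears
    one lateral, the terminal segment is a bare tip. First-order S-type and
    L-type laterals attach to axial segments; each L-type lateral is itself
    a chain bearing ``second_order_s_per_l`` second-order S-type laterals.
    S-type lateral lengths are lognormal with a small log-sd (determinate
    growth); L-type lengths are broader. Diameters are drawn strictly
    inside their class band.

    Drought multiplies the S-lateral count down, the L-lateral count up,
    and second-order S production up; the ``recovered`` condition reuses
    the well-watered parameters (drought-induced shifts are reversible).
    """

    n_axial: int = 5
    s_per_axial: int = 20
    l_per_axial: int = 8
    second_order_s_per_l: int = 2
    s_length_median_mm: float = 7.0
    #: second-order S-type laterals are shorter than first-order ones
    s2_length_median_mm: float = 3.5
    s_length_sigma: float = 0.2
    l_length_median_mm: float = 30.0
    l_length_sigma: float = 0.4
    axial_length_mm: float = 150.0
    s_diam_band: Tuple[float, float] = (0.05, 0.15)
    l_diam_band: Tuple[float, float] = (0.16, 0.37)
    axial_diam_band: Tuple[float, float] = (0.40, 1.00)
    drought_s_factor: float = 0.5
    drought_l_factor: float = 1.25
    drought_second_order_factor: float = 1.5
    boundaries: Tuple[float, float] = (0.15, 0.37)
    seed: int = 0

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not (0 < self.s_diam_band[0] < self.s_diam_band[1] <= b1):
            raise ConfigError("S diameter band must lie within (0, b1]")
        if not (b1 < self.l_diam_band[0] < self.l_diam_band[1] <= b2):
            raise ConfigError("L diameter band must lie within (b1, b2]")
        if not (b2 < self.axial_diam_band[0] < self.axial_diam_band[1]):
            raise ConfigError("axial diameter band must lie above b2")
        if self.n_axial < 1:
            raise ConfigError("need at least one axial root")


CONDITIONS = ("well_watered", "drought", "recovered")


def gen_root_system(
    cfg: RootSimConfig, condition: str = "well_watered", plant_id: str = "P1"
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate one root system as a segment table plus bookkeeping truth.

    The truth dict records per-class total lengths (summed as generated),
    the number of S-type laterals, their sample-mean length, and the
    distribution mean ``median * exp(sigma^2 / 2)``.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    drought = condition == "drought"
    n_s = max(0, int(round(cfg.s_per_axial * (cfg.drought_s_factor if drought else 1.0))))
    n_l = max(0, int(round(cfg.l_per_axial * (cfg.drought_l_factor if drought else 1.0))))
    n_2nd = max(
        0,
        int(
            round(
                cfg.second_order_s_per_l
                * (cfg.drought_second_order_factor if drought else 1.0)
            )
        ),
    )

    rng = np.random.default_rng(cfg.seed)
    rows = []
    s_lengths = []
    totals = {"S_type": 0.0, "L_type": 0.0, "axial": 0.0}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"seg{counter[0]:05d}"

    def draw_len(median: float, sigma: float) -> float:
        return float(rng.lognormal(mean=np.log(median), sigma=sigma))

    def add_segment(parent: Optional[str], length: float, band: Tuple[float, float], cls: str) -> str:
        sid = new_id()
        d = float(rng.uniform(band[0], band[1]))
        rows.append((plant_id, sid, parent, length, d))
        totals[cls] += length
        return sid

    n_first = [0]
    n_second = [0]

    def add_s_lateral(parent: str, second_order: bool = False) -> None:
        median = cfg.s2_length_median_mm if second_order else cfg.s_length_median_mm
        (n_second if second_order else n_first)[0] += 1
        length = draw_len(median, cfg.s_length_sigma)
        s_lengths.append(length)
        add_segment(parent, length, cfg.s_diam_band, "S_type")

    for _ in range(cfg.n_axial):
        n_attach = n_s + n_l
        n_chain = n_attach + 1
        seg_len = cfg.axial_length_mm / n_chain
        # each internal axial chain segment bears one lateral; shuffled order
        kinds = np.array(["S"] * n_s + ["L"] * n_l)
        rng.shuffle(kinds)
        parent: Optional[str] = None
        for kind in kinds:
            parent = add_segment(parent, seg_len, cfg.axial_diam_band, "axial")
            if kind == "S":
                add_s_lateral(parent)
            else:
                l_total = draw_len(cfg.l_length_median_mm, cfg.l_length_sigma)
                l_chain = n_2nd + 1
                l_seg_len = l_total / l_chain
                l_parent = parent
                for j in range(l_chain):
                    l_parent = add_segment(l_parent, l_seg_len, cfg.l_diam_band, "L_type")
                    if j < n_2nd:
                        add_s_lateral(l_parent, second_order=True)
        add_segment(parent, seg_len, cfg.axial_diam_band, "axial")  # terminal tip

    segments = pd.DataFrame(
        rows,
        columns=["plant_id", "segment_id", "parent_segment_id", "length_mm", "diameter_mm"],
    )
    total = totals["S_type"] + totals["L_type"] + totals["axial"]
    truth = {
        "condition": condition,
        "n_s_laterals": len(s_lengths),
        "length_S": totals["S_type"],
        "length_L": totals["L_type"],
        "length_axial": totals["axial"],
        "length_total": total,
        "prop_S": totals["S_type"] / total if total else np.nan,
        "prop_L": totals["L_type"] / total if total else np.nan,
        "prop_axial": totals["axial"] / total if total else np.nan,
        "mean_s_length_sample": float(np.mean(s_lengths)) if s_lengths else np.nan,
        # distribution mean of a lateral drawn uniformly from those generated
        # (first- and second-order pooled, as in WinRHIZO-style link analysis)
        "mean_s_length_true": (
            (
                n_first[0] * cfg.s_length_median_mm
                + n_second[0] * cfg.s2_length_median_mm
            )
            / (n_first[0] + n_second[0])
            * float(np.exp(cfg.s_length_sigma**2 / 2))
            if (n_first[0] + n_second[0])
            else np.nan
        ),
        "n_first_order_s": n_first[0],
        "n_second_order_s": n_second[0],
    }
    return segments, truth


# ---------------------------------------------------------------------------
# Glasshouse watering target
# ---------------------------------------------------------------------------


def glasshouse_watering_target(max_whc_pct: float, fraction: float) -> float:
    """Target gravimetric water content (% w/w) as a fraction of maximum WHC.

    E.g. watering a soil of 22.3 % w/w maximum water-holding capacity to
    75 % WHC targets 16.725 % w/w.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if max_whc_pct <= 0:
        raise ValueError("max_whc_pct must be positive")
    return fraction * max_whc_pct
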
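"""Treatment-comparison statistics and end-to-end pipeline orchestration.

Implements the comparisons used throughout the analysis: growth rates
mean-centered for display, one-sample t-tests of centered or differenced
rates against zero, Type II two-way ANOVA (genotype x treatment) and Tukey
HSD post-hoc comparisons with a compact letter display. Tests are
two-sided; no multiple-testing correction is applied beyond Tukey.

The one-sample t and Tukey HSD are computed from their closed forms using
scipy distributions, so that well-vetted third-party routines remain
available as independent cross-checks; the Type II ANOVA delegates to
statsmodels behind a fixed tidy contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "center_to_zero_mean",
    "one_sample_t",
    "two_way_anova_typeII",
    "tukey_hsd",
    "compact_letter_display",
    "run_pipeline",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    group: str
    statistic: float
    df: float
    pvalue: float
    n: int


def center_to_zero_mean(values) -> np.ndarray:
    """Subtract the mean; used to visualize genotypic deviations in rates."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot center an empty collection")
    return x - x.mean()


def one_sample_t(values, mu: float = 0.0, group: str = "") -> TestResult:
    """Two-sided one-sample t-test: t = (mean - mu) / (sd / sqrt(n)), df = n - 1.

    Zero sample variance yields an undefined-result marker (NaN statistic
    and p-value) rather than an exception.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult("one_sample_t", group, np.nan, n - 1, np.nan, n)
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult("one_sample_t", group, float(t), float(n - 1), float(p), int(n))


def two_way_anova_typeII(
    response, factor_genotype, factor_treatment
) -> pd.DataFrame:
    """Type II two-way ANOVA with interaction, tidy output.

    Returns one row per term (genotype, treatment, interaction, residual)
    with sum_sq, df, F and p. On balanced designs Type II equals the
    sequential (Type I) decomposition. A constant response yields NaN F
    (undefined-result marker). Factors with fewer than two levels, or a
    design without residual degrees of freedom, raise a ValueError naming
    the problem.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "genotype": np.asarray(factor_genotype, dtype=str),
            "treatment": np.asarray(factor_treatment, dtype=str),
        }
    )
    for fac in ("genotype", "treatment"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    if df["y"].nunique() == 1:
        # constant response: every effect is undefined (0/0 F ratio)
        terms = ["genotype", "treatment", "genotype:treatment", "residual"]
        return pd.DataFrame(
            {"term": terms, "sum_sq": 0.0, "df": np.nan, "F": np.nan, "pvalue": np.nan}
        )
    model = smf.ols("y ~ C(genotype) * C(treatment)", data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom (need replicates)")
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(genotype)": "genotype",
            "C(treatment)": "treatment",
            "C(genotype):C(treatment)": "genotype:treatment",
            "Residual": "residual",
        }
    )
    out = table.reset_index().rename(
        columns={"index": "term", "PR(>F)": "pvalue", "F": "F"}
    )
    return out[["term", "sum_sq", "df", "F", "pvalue"]]


def tukey_hsd(
    means: Mapping[str, float],
    mse: float,
    n: Mapping[str, int] | int,
    df_resid: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Uses the studentized range distribution: for groups i, j the statistic
    is ``q = |m_i - m_j| / sqrt(mse/2 (1/n_i + 1/n_j))`` with adjusted
    p-value ``P(Q_{k, df} >= q)``. Returns one row per unordered pair plus
    a ``reject`` flag at ``alpha``. Use :func:`compact_letter_display` for
    letters.
    """
    groups = sorted(means)
    if len(groups) < 2:
        return pd.DataFrame(
            columns=["group1", "group2", "diff", "q", "p_adj", "reject"]
        )
    if isinstance(n, int):
        n = {g: n for g in groups}
    k = len(groups)
    rows = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            diff = means[gj] - means[gi]
            se = np.sqrt(mse / 2.0 * (1.0 / n[gi] + 1.0 / n[gj]))
            q = abs(diff) / se if se > 0 else np.inf
            p_adj = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            rows.append((gi, gj, diff, q, p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["group1", "group2", "diff", "q", "p_adj", "reject"])


def compact_letter_display(
    comparisons: pd.DataFrame, means: Mapping[str, float]
) -> Dict[str, str]:
    """Letters such that groups sharing a letter are not significantly different.

    Standard insert-and-absorb construction over the ``reject`` column of a
    :func:`tukey_hsd` table. Letters are assigned in descending order of
    group mean.
    """
    groups = sorted(means, key=lambda g: -means[g])
    sets = [set(groups)]
    for _, row in comparisons[comparisons["reject"]].iterrows():
        a, b = row["group1"], row["group2"]
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    # order letter columns by the best (highest-mean) member they contain
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for idx, s in enumerate(sets):
        ch = chr(ord("a") + idx)
        for g in groups:
            if g in s:
                letters[g] += ch
    return letters


def run_pipeline(config: dict | str | Path) -> Path:
    """Run simulate -> growth rates -> WRI (plus optional co-location and
    root stages) from a config dict or YAML file; write CSVs, a run log and
    a plain-text summary under the configured output directory.

    Config keys: ``seed`` (int), ``out_dir`` (path), optional ``field``
    (FieldSimConfig overrides), ``window`` ("M2:M3"), ``coloc``
    (``enabled`` plus GwasSimConfig overrides and planted peak tuples),
    ``roots`` (``enabled`` plus RootSimConfig overrides). Reruns with the
    same config produce byte-identical CSVs. Any stage failure aborts with
    the stage name in the exception message.
    """
    import yaml

    from .gwas_coloc import clusters_to_frame, filter_hits, find_colocations
    from .root_architecture import link_analysis, summarize_root_types
    from .synthetic_data import (
        FieldSimConfig,
        GwasSimConfig,
        PlantedPeak,
        RootSimConfig,
        gen_field_phenotypes,
        gen_gwas_tables,
        gen_root_system,
    )
    from .wri import compute_wri_table

    if not isinstance(config, dict):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "rootshift_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {seed}", f"out_dir: {out_dir}"]

    def _stage(name):
        log_lines.append(f"stage: {name}")

    try:
        _stage("simulate_field")
        field_cfg = FieldSimConfig(seed=seed, **config.get("field", {}))
        obs, truth = gen_field_phenotypes(field_cfg)
        obs.to_csv(out_dir / "phenotypes.csv", index=False)
        truth.to_csv(out_dir / "truth_field.csv", index=False)

        _stage("wri")
        window = tuple(config.get("window", "M2:M3").split(":"))
        wri_table = compute_wri_table(obs, field_cfg.schedule, window)
        wri_table.to_csv(out_dir / "wri.csv", index=False)
        summary = [
            f"{len(wri_table)} genotypes ranked by WRI over window {':'.join(window)}",
            f"most conservative: {wri_table.iloc[0]['genotype_id']} "
            f"(WRI={wri_table.iloc[0]['wri']:.3f})",
            f"least conservative: {wri_table.iloc[-1]['genotype_id']} "
            f"(WRI={wri_table.iloc[-1]['wri']:.3f})",
        ]

        coloc_cfg = config.get("coloc", {})
        if coloc_cfg.get("enabled", False):
            _stage("coloc")
            opts = {k: v for k, v in coloc_cfg.items() if k not in {"enabled", "planted_peaks"}}
            peaks = tuple(
                PlantedPeak(str(c), int(p), tuple(ss), float(m))
                for c, p, ss, m in coloc_cfg.get("planted_peaks", [])
            )
            gcfg = GwasSimConfig(seed=seed, planted_peaks=peaks, **opts)
            hits, gwas_truth = gen_gwas_tables(gcfg)
            hits.to_csv(out_dir / "gwas_hits.csv", index=False)
            gwas_truth.to_csv(out_dir / "truth_gwas.csv", index=False)
            kept, _ = filter_hits(hits)
            clusters = find_colocations(kept, gcfg.window_bp)
            clusters_to_frame(clusters).to_csv(out_dir / "coloc_clusters.csv", index=False)
            summary.append(f"{len(clusters)} co-located GWAS peak cluster(s)")

        roots_cfg = config.get("roots", {})
        if roots_cfg.get("enabled", False):
            _stage("roots")
            opts = {k: v for k, v in roots_cfg.items() if k != "enabled"}
            rcfg = RootSimConfig(seed=seed, **opts)
            frames, link_rows = [], []
            for condition in ("well_watered", "drought", "recovered"):
                seg, _ = gen_root_system(rcfg, condition, plant_id=condition)
                frames.append(seg)
                link = link_analysis(seg, rcfg.boundaries)
                link_rows.append(
                    {
                        "condition": condition,
                        "external_links": link.external_links,
                        "internal_links": link.internal_links,
                        "mean_s_lateral_length_mm": link.mean_s_lateral_length_mm,
                    }
                )
            seg_all = pd.concat(frames, ignore_index=True)
            seg_all.to_csv(out_dir / "root_segments.csv", index=False)
            summarize_root_types(seg_all, by=("plant_id",), boundaries=rcfg.boundaries).to_csv(
                out_dir / "root_type_summary.csv", index=False
            )
            pd.DataFrame(link_rows).to_csv(out_dir / "root_links.csv", index=False)
            summary.append("root-architecture summaries written")
    except Exception as exc:  # annotate with the failing stage
        stage = log_lines[-1].removeprefix("stage: ")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    return out_dir
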
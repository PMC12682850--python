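"""Multi-season GWAS summary filtering, peak co-location, and gene windows.

Works on per-season association summary tables (SNP, chromosome, position,
p-value, optional minor-allele frequency) — it does not re-fit the
association model. Peaks observed in different seasons are considered
co-located when they fall on the same chromosome within a fixed genomic
window (default 100 kb): positions are clustered by single linkage with an
inclusive distance threshold, and clusters are kept only when they span at
least two distinct seasons. Candidate genes are pulled from an annotation
within a flanking window around a cluster interval or a single SNP.

Conventions: "logP" is -log10(p); the -log10(p) >= 3 filter is inclusive,
the genome-wide significance flag p < 1e-4 is strict; coordinates are
1-based inclusive (GFF3 convention); no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GWAS_COLUMNS",
    "ColocCluster",
    "read_gwas_table",
    "filter_hits",
    "flag_significant",
    "find_colocations",
    "clusters_to_frame",
    "read_gene_annotation",
    "genes_in_window",
]

GWAS_COLUMNS = ["season", "snp_id", "chrom", "pos", "pvalue"]
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "description"]

#: Slack applied when comparing -log10(p) against the filter threshold, so
#: that p-values printed at the decimal boundary (e.g. 1e-3 vs threshold 3)
#: are retained regardless of binary rounding.
_LOG10_EPS = 1e-9


@dataclass(frozen=True)
class ColocCluster:
    """A set of hits from >= 2 seasons co-locating on one chromosome.

    ``interval`` spans the member positions; every member lies within
    ``window_bp`` of at least one other member (single linkage).
    """

    chrom: str
    interval: Tuple[int, int]
    window_bp: int
    members: pd.DataFrame = field(repr=False)

    @property
    def seasons(self) -> Tuple[str, ...]:
        return tuple(sorted(self.members["season"].unique()))

    @property
    def n_hits(self) -> int:
        return len(self.members)


def read_gwas_table(path: str | Path, season: str | None = None) -> pd.DataFrame:
    """Read one GWAS summary CSV (``season,snp_id,chrom,pos,pvalue[,maf]``).

    ``season`` overrides/supplies the season column (handy when each file
    holds one season without a season column).
    """
    df = pd.read_csv(path, dtype={"chrom": str, "snp_id": str})
    if season is not None:
        df["season"] = season
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table missing column(s): {', '.join(missing)}")
    return validate_hits(df)


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    hits = hits.copy()
    hits["pos"] = pd.to_numeric(hits["pos"])
    hits["pvalue"] = pd.to_numeric(hits["pvalue"])
    if (hits["pos"] < 1).any():
        raise ValueError("positions must be >= 1 (1-based coordinates)")
    if ((hits["pvalue"] <= 0) | (hits["pvalue"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if "maf" in hits.columns:
        maf = pd.to_numeric(hits["maf"])
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValueError("MAF must lie in [0, 0.5]")
        hits["maf"] = maf
    hits["chrom"] = hits["chrom"].astype(str)
    return hits


def filter_hits(
    hits: pd.DataFrame,
    min_neglog10p: float = 3.0,
    min_maf: float = 0.05,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Retain hits with -log10(p) >= threshold (inclusive) and adequate MAF.

    Hits with no MAF column (or missing MAF) pass the MAF criterion.
    Returns the retained hits and counts removed per criterion.
    """
    neglogp = -np.log10(hits["pvalue"].to_numpy(dtype=float))
    keep_p = neglogp >= min_neglog10p - _LOG10_EPS
    if "maf" in hits.columns:
        maf = hits["maf"].to_numpy(dtype=float)
        keep_maf = np.isnan(maf) | (maf >= min_maf)
    else:
        keep_maf = np.ones(len(hits), dtype=bool)
    removed = {
        "low_neglog10p": int((~keep_p).sum()),
        "low_maf": int((keep_p & ~keep_maf).sum()),
    }
    return hits[keep_p & keep_maf].copy(), removed


def flag_significant(hits: pd.DataFrame, alpha: float = 1e-4) -> pd.DataFrame:
    """Flag genome-wide significance with the strict rule p < alpha."""
    out = hits.copy()
    out["significant"] = out["pvalue"].to_numpy(dtype=float) < alpha
    return out


def find_colocations(hits: pd.DataFrame, window_bp: int = 100_000) -> List[ColocCluster]:
    """Single-linkage co-location clustering of (already filtered) hits.

    Per chromosome, hits whose positions chain together with gaps
    <= ``window_bp`` (inclusive) form one cluster; clusters spanning >= 2
    distinct seasons are reported, ordered by (chrom, interval start).
    On sorted positions, consecutive-gap chaining is exactly single-linkage
    clustering in one dimension.
    """
    hits = hits.copy()
    hits["season"] = hits["season"].astype(str)
    hits["chrom"] = hits["chrom"].astype(str)
    clusters: List[ColocCluster] = []
    for chrom in sorted(hits["chrom"].unique()):
        sub = hits[hits["chrom"] == chrom].sort_values(
            ["pos", "season", "snp_id"], kind="mergesort"
        )
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for a, b in zip(starts, ends):
            members = sub.iloc[a:b]
            if members["season"].nunique() < 2:
                continue
            clusters.append(
                ColocCluster(
                    chrom=chrom,
                    interval=(int(pos[a]), int(pos[b - 1])),
                    window_bp=int(window_bp),
                    members=members.reset_index(drop=True),
                )
            )
    return clusters


def clusters_to_frame(clusters: Sequence[ColocCluster]) -> pd.DataFrame:
    """Tabular view of clusters for CSV output."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.interval[0] for c in clusters],
            "end": [c.interval[1] for c in clusters],
            "n_hits": [c.n_hits for c in clusters],
            "n_seasons": [len(c.seasons) for c in clusters],
            "seasons": [";".join(c.seasons) for c in clusters],
        }
    )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation from GFF3 (``gene`` features) or minimal CSV.

    CSV columns: ``gene_id,chrom,start,end,description``. Coordinates are
    1-based inclusive either way.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = [
            {
                "gene_id": feat.attributes.get("ID", [feat.id])[0],
                "chrom": str(feat.seqid),
                "start": int(feat.start),
                "end": int(feat.end),
                "description": feat.attributes.get("description", [""])[0],
            }
            for feat in db.features_of_type("gene")
        ]
        ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    else:
        ann = pd.read_csv(path, dtype={"chrom": str})
        missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns and c != "description"]
        if missing:
            raise ValueError(f"annotation missing column(s): {', '.join(missing)}")
        if "description" not in ann.columns:
            ann["description"] = ""
    if (ann["start"] > ann["end"]).any():
        raise ValueError("gene start must be <= end")
    return ann.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def genes_in_window(
    target,
    annotation: pd.DataFrame,
    flank_bp: int = 100_000,
) -> pd.DataFrame:
    """Genes overlapping a flanked interval around a cluster or a single SNP.

    ``target`` may be a :class:`ColocCluster`, a ``(chrom, start, end)``
    triple, or a ``(chrom, pos)`` pair. Overlap is on closed intervals:
    a gene ending exactly at ``start - flank_bp`` is included.
    """
    if isinstance(target, ColocCluster):
        chrom, (lo, hi) = target.chrom, target.interval
    elif len(target) == 3:
        chrom, lo, hi = target
    elif len(target) == 2:
        chrom, lo = target
        hi = lo
    else:
        raise TypeError("target must be a ColocCluster, (chrom, start, end) or (chrom, pos)")
    lo, hi = int(lo) - int(flank_bp), int(hi) + int(flank_bp)
    mask = (
        (annotation["chrom"].astype(str) == str(chrom))
        & (annotation["start"] <= hi)
        & (annotation["end"] >= lo)
    )
    return annotation[mask].reset_index(drop=True)
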
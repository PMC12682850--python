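"""Root-architecture summaries: diameter classes, link analysis, root order.

Rice root systems contain three morphologically distinct classes separable
by segment diameter: S-type lateral roots (thin, short, determinate,
unbranched), L-type lateral roots (thicker, longer, capable of bearing
second-order S-type laterals), and the axial seminal/crown roots. The
default class boundaries are 0.15 mm and 0.37 mm with closed upper bounds
(d <= 0.15 is S-type, 0.15 < d <= 0.37 is L-type, d > 0.37 is axial).

A root system is a forest of segments: each segment has a length, a
diameter, and an optional parent; forest roots are the bases of axial
roots. Link analysis counts external links (segments with no children,
i.e. tips) and internal links (segments with children), and estimates the
mean S-type lateral root length as total S-class length divided by the
number of S-class tips — exact when every S lateral is a single unbranched
segment, which matches the determinate growth habit of S-type laterals.

Lateral order: a lateral whose parent chain reaches an axial segment
without passing an L-class segment is first-order; one branching from an
L-class segment is second-order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BOUNDARIES",
    "SEGMENT_COLUMNS",
    "LinkSummary",
    "classify_diameter",
    "classify_segments",
    "summarize_root_types",
    "link_analysis",
    "assign_lr_order",
    "aggregate_longevity",
]

#: (S/L boundary, L/axial boundary) in mm, closed above.
DEFAULT_BOUNDARIES = (0.15, 0.37)

SEGMENT_COLUMNS = ["plant_id", "segment_id", "parent_segment_id", "length_mm", "diameter_mm"]

CLASSES = ("S_type", "L_type", "axial")


class RootTopologyError(ValueError):
    """The parent links do not form a valid forest."""


def classify_diameter(diameter, boundaries: Tuple[float, float] = DEFAULT_BOUNDARIES):
    """Diameter (mm) -> class with closed upper bounds at both cut points.

    d <= b1 is S_type, b1 < d <= b2 is L_type, d > b2 is axial.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("diameters must be positive and finite")
    b1, b2 = boundaries
    out = np.select([d <= b1, d <= b2], ["S_type", "L_type"], default="axial")
    return str(out[()]) if out.ndim == 0 else out


def classify_segments(
    segments: pd.DataFrame, boundaries: Tuple[float, float] = DEFAULT_BOUNDARIES
) -> pd.DataFrame:
    """Attach a ``root_class`` column derived from ``diameter_mm``."""
    out = segments.copy()
    out["root_class"] = classify_diameter(out["diameter_mm"].to_numpy(), boundaries)
    return out


def summarize_root_types(
    segments: pd.DataFrame,
    by: Sequence[str] = ("plant_id",),
    boundaries: Tuple[float, float] = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Per-group class lengths and proportions.

    Class lengths are plain sums of member segment lengths, so they add up
    to the total input length exactly (same floating summation order).
    Groups with zero total length get NaN proportions and
    ``proportions_defined == False``.
    """
    seg = classify_segments(segments, boundaries)
    by = list(by)
    rows = []
    for key, grp in seg.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lengths = {c: float(grp.loc[grp["root_class"] == c, "length_mm"].sum()) for c in CLASSES}
        total = lengths["S_type"] + lengths["L_type"] + lengths["axial"]
        row = dict(zip(by, key))
        row.update(
            length_S=lengths["S_type"],
            length_L=lengths["L_type"],
            length_axial=lengths["axial"],
            length_total=total,
        )
        if total > 0:
            row.update(
                prop_S=lengths["S_type"] / total,
                prop_L=lengths["L_type"] / total,
                prop_axial=lengths["axial"] / total,
                proportions_defined=True,
            )
        else:
            row.update(prop_S=np.nan, prop_L=np.nan, prop_axial=np.nan, proportions_defined=False)
        rows.append(row)
    return pd.DataFrame(rows)


def _parent_map(segments: pd.DataFrame) -> Dict[str, Optional[str]]:
    """Validated segment -> parent mapping; raises on cycles/dangling links."""
    ids = segments["segment_id"].astype(str)
    if ids.duplicated().any():
        raise RootTopologyError("duplicate segment ids")
    parent_raw = segments["parent_segment_id"]
    parents: Dict[str, Optional[str]] = {}
    for sid, pid in zip(ids, parent_raw):
        if pid is None or (isinstance(pid, float) and np.isnan(pid)) or pid == "":
            parents[sid] = None
        else:
            parents[sid] = str(pid)
    known = set(parents)
    for sid, pid in parents.items():
        if pid is not None and pid not in known:
            raise RootTopologyError(f"segment {sid} references unknown parent {pid}")
    # cycle check by path-walking with memoised depth
    state: Dict[str, int] = {}  # 0 = in progress, 1 = done
    for sid in parents:
        path = []
        cur: Optional[str] = sid
        while cur is not None and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise RootTopologyError(f"cycle in root topology at segment {cur}")
            state[cur] = 0
            path.append(cur)
            cur = parents[cur]
        for p in path:
            state[p] = 1
    return parents


@dataclass(frozen=True)
class LinkSummary:
    """Link counts and the tip-count estimate of mean S-type lateral length.

    ``mean_s_lateral_length_mm`` is None when the system has no S-class
    tips (undefined-result marker rather than 0 or NaN arithmetic).
    """

    external_links: int
    internal_links: int
    n_s_tips: int
    total_s_length_mm: float
    mean_s_lateral_length_mm: Optional[float]


def link_analysis(
    segments: pd.DataFrame, boundaries: Tuple[float, float] = DEFAULT_BOUNDARIES
) -> LinkSummary:
    """External/internal link counts and mean S-type lateral root length.

    External links are tip segments (no children); internal links have at
    least one child. The mean S-type lateral length is total S-class length
    divided by the number of S-class tips.
    """
    seg = classify_segments(segments, boundaries)
    parents = _parent_map(seg)
    has_child = {pid for pid in parents.values() if pid is not None}
    ids = seg["segment_id"].astype(str).to_numpy()
    is_tip = np.array([sid not in has_child for sid in ids])
    classes = seg["root_class"].to_numpy()
    lengths = seg["length_mm"].to_numpy(dtype=float)
    s_mask = classes == "S_type"
    n_s_tips = int((is_tip & s_mask).sum())
    total_s = float(lengths[s_mask].sum())
    return LinkSummary(
        external_links=int(is_tip.sum()),
        internal_links=int((~is_tip).sum()),
        n_s_tips=n_s_tips,
        total_s_length_mm=total_s,
        mean_s_lateral_length_mm=(total_s / n_s_tips) if n_s_tips else None,
    )


def assign_lr_order(
    segments: pd.DataFrame, boundaries: Tuple[float, float] = DEFAULT_BOUNDARIES
) -> pd.DataFrame:
    """Assign {first, second} order to lateral segments; axials get NA.

    Walking up the parent chain (skipping ancestors of the segment's own
    class, i.e. the rest of its own lateral chain): reaching an axial
    segment first makes the lateral first-order; meeting an L-class segment
    first makes it second-order. A lateral stored as a forest root (no
    classified parent to walk to) is a structural error.
    """
    seg = classify_segments(segments, boundaries)
    parents = _parent_map(seg)
    cls = dict(zip(seg["segment_id"].astype(str), seg["root_class"]))

    cache: Dict[str, Optional[str]] = {}

    def order_of(sid: str) -> Optional[str]:
        if sid in cache:
            return cache[sid]
        c = cls[sid]
        if c == "axial":
            cache[sid] = None
            return None
        cur = parents[sid]
        while cur is not None:
            cc = cls[cur]
            if cc == "axial":
                cache[sid] = "first"
                return "first"
            if cc == "L_type" and c != "L_type":
                cache[sid] = "second"
                return "second"
            cur = parents[cur]
        raise RootTopologyError(f"lateral segment {sid} has no classified axial ancestor")

    out = seg.copy()
    out["lr_order"] = [order_of(str(s)) for s in out["segment_id"]]
    return out


def aggregate_longevity(
    scores: pd.DataFrame,
    by: Sequence[str] = ("root_class",),
    root_key: Sequence[str] = ("plant_id", "root_class"),
) -> pd.DataFrame:
    """Two-stage mean of 0-5 longevity staining scores.

    Photos are averaged within each root (identified by ``root_key``, plus
    ``root_id`` if present), then roots are averaged within each ``by``
    group. Scores outside {0..5} are rejected; empty groups simply do not
    appear. Returns mean score with photo and root counts.
    """
    s = scores.copy()
    v = pd.to_numeric(s["score"])
    if ((v < 0) | (v > 5) | (v != v.round())).any():
        raise ValueError("scores must be integers in 0..5 (six intensities)")
    root_key = list(root_key) + (["root_id"] if "root_id" in s.columns else [])
    per_root = s.groupby(root_key, as_index=False).agg(
        root_mean=("score", "mean"), n_photos=("score", "size")
    )
    out = per_root.groupby(list(by), as_index=False).agg(
        mean_score=("root_mean", "mean"),
        n_roots=("root_mean", "size"),
        n_photos=("n_photos", "sum"),
    )
    return out
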
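"""Normalized 2D clone-size distributions and per-animal clone summaries.

The central object is the table of relative frequencies over (basal,
suprabasal) clone sizes for one condition and chase time, together with the
residual (difference) heatmaps used to compare conditions, the geometric
median clone size, and per-animal observable summaries.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass

import numpy as np

from .progenitor_model import CloneRecord, ObservableSummary

__all__ = [
    "CloneSizeHistogram2D",
    "FILTER_RULES",
    "filter_clones",
    "build_histogram2d",
    "residual_histogram",
    "geometric_median",
    "coordinatewise_geometric_mean",
    "clone_summaries",
]

logger = logging.getLogger(__name__)

FILTER_RULES = ("all", "at_least_one_cell", "at_least_one_basal")


@dataclass
class CloneSizeHistogram2D:
    """Relative clone-size frequencies indexed by (m basal, n suprabasal).

    ``f[m, n]`` covers sizes 0..m_max x 0..n_max; clones beyond the maxima
    are pooled into ``overflow_mass`` (fraction of clones) so entries sum to
    ``1 - overflow_mass``.
    """

    f: np.ndarray
    n_clones: int
    filter: str
    condition: str = ""
    t_days: float = float("nan")
    overflow_mass: float = 0.0

    @property
    def m_max(self) -> int:
        return self.f.shape[0] - 1

    @property
    def n_max(self) -> int:
        return self.f.shape[1] - 1


def filter_clones(records: list[CloneRecord], rule: str) -> list[CloneRecord]:
    """Subset clone records by inclusion rule, preserving order.

    ``all`` keeps everything, ``at_least_one_cell`` drops (0, 0) records and
    ``at_least_one_basal`` keeps clones with m >= 1.
    """
    if rule not in FILTER_RULES:
        raise ValueError(f"unknown filter rule {rule!r}; expected one of {FILTER_RULES}")
    if rule == "all":
        kept = list(records)
    elif rule == "at_least_one_cell":
        kept = [rec for rec in records if rec.m + rec.n >= 1]
    else:
        kept = [rec for rec in records if rec.m >= 1]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter %s removed %d of %d clone records", rule, removed, len(records))
    return kept


def build_histogram2d(records: list[CloneRecord], m_max: int, n_max: int,
                      rule: str = "all", condition: str = "",
                      t_days: float = float("nan")) -> CloneSizeHistogram2D:
    """Normalized 2D histogram of clone sizes after applying the filter rule."""
    kept = filter_clones(records, rule)
    if not kept:
        raise ValueError(f"no clone records survive filter {rule!r}")
    f = np.zeros((m_max + 1, n_max + 1))
    overflow = 0
    for rec in kept:
        if rec.m <= m_max and rec.n <= n_max:
            f[rec.m, rec.n] += 1
        else:
            overflow += 1
    n = len(kept)
    return CloneSizeHistogram2D(f=f / n, n_clones=n, filter=rule,
                                condition=condition, t_days=t_days,
                                overflow_mass=overflow / n)


def residual_histogram(h1: CloneSizeHistogram2D, h2: CloneSizeHistogram2D) -> np.ndarray:
    """Elementwise difference ``h1.f - h2.f`` of two compatible histograms."""
    if h1.f.shape != h2.f.shape:
        raise ValueError(f"histogram geometries differ: {h1.f.shape} vs {h2.f.shape}")
    if h1.filter != h2.filter:
        raise ValueError(f"histogram filters differ: {h1.filter!r} vs {h2.filter!r}")
    return h1.f - h2.f


def geometric_median(points, tol: float = 1e-9, max_iter: int = 1000) -> tuple[float, float]:
    """Spatial median: the point minimizing the summed Euclidean distances.

    Weiszfeld iteration with the Vardi-Zhang safeguard for iterates that
    coincide with a data point, so the result is well defined on integer
    clone sizes with ties.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a nonempty list of (m, n) pairs")
    if pts.shape[0] == 1:
        return (float(pts[0, 0]), float(pts[0, 1]))
    uniq, counts = np.unique(pts, axis=0, return_counts=True)
    if uniq.shape[0] == 1:
        return (float(uniq[0, 0]), float(uniq[0, 1]))
    x = pts.mean(axis=0)
    for _ in range(max_iter):
        diff = uniq - x
        dist = np.hypot(diff[:, 0], diff[:, 1])
        at = dist < 1e-12
        if at.any():
            # Vardi-Zhang: x sits on a data point with multiplicity eta
            eta = counts[at].sum()
            away = ~at
            w = counts[away] / dist[away]
            T = (uniq[away] * w[:, None]).sum(axis=0) / w.sum()
            R = (uniq[away] * w[:, None] - x * w[:, None]).sum(axis=0)
            r_norm = np.hypot(R[0], R[1])
            if r_norm <= eta:
                break
            step = max(0.0, 1.0 - eta / r_norm)
            x_new = step * T + min(1.0, eta / r_norm) * x
        else:
            w = counts / dist
            x_new = (uniq * w[:, None]).sum(axis=0) / w.sum()
        if np.hypot(*(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return (float(x[0]), float(x[1]))


def coordinatewise_geometric_mean(points, pseudocount: float = 1.0) -> tuple[float, float]:
    """Per-axis geometric mean of (m + c, n + c) minus c — the alternative
    reading of "geometric median clone size" (see package docs)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a nonempty list of (m, n) pairs")
    gm = np.exp(np.log(pts + pseudocount).mean(axis=0)) - pseudocount
    return (float(gm[0]), float(gm[1]))


def clone_summaries(records: list[CloneRecord]) -> "OrderedDict[str, ObservableSummary]":
    """Per-animal clone summaries, keyed by animal id in first-seen order.

    mean basal size uses clones with at least one basal cell; the suprabasal
    fraction is the pooled cell-level share sum(n) / sum(m + n); the floating
    fraction is the share of clones with no basal cell among clones with at
    least one cell.  Animals whose groups are empty after these restrictions
    are omitted with a warning.
    """
    groups: "OrderedDict[str, list[CloneRecord]]" = OrderedDict()
    for rec in records:
        groups.setdefault(rec.animal_id, []).append(rec)
    out: "OrderedDict[str, ObservableSummary]" = OrderedDict()
    for animal, recs in groups.items():
        alive = [r for r in recs if r.m + r.n >= 1]
        basal = [r for r in recs if r.m >= 1]
        if not alive:
            logger.warning("animal %s has no clones with at least one cell; omitted", animal)
            continue
        total_cells = sum(r.m + r.n for r in alive)
        supra_cells = sum(r.n for r in alive)
        mean_basal = float(np.mean([r.m for r in basal])) if basal else 0.0
        mean_total = float(np.mean([r.m + r.n for r in alive]))
        out[animal] = ObservableSummary(
            mean_basal=mean_basal,
            mean_total=mean_total,
            suprabasal_fraction=supra_cells / total_cells if total_cells else 0.0,
            floating_fraction=sum(1 for r in alive if r.m == 0) / len(alive),
            conditioning="per_animal",
        )
    return out


def size_counter(records: list[CloneRecord]) -> Counter:
    """Multiset of (m, n) clone sizes — handy for quick comparisons in tests."""
    return Counter((rec.m, rec.n) for rec in records)
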
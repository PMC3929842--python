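"""Differential-expression statistics on the information network.

Per-gene, per-contrast microarray statistics (signed linear fold-change,
raw p, Benjamini–Hochberg adjusted p) are attached to gene concepts.  A
*contrast* is a mutant-vs-wild-type comparison at one developmental stage
(labels V14, V20, A48, S48 in the reference design).  Replicate p-values
can be combined with Stouffer's unweighted z-transformation; genes are
filtered with the inclusive thresholds |fold-change| >= 4 (DEG) or >= 8
(strong DEG) at adjusted p <= 0.05.

Fold-changes here are SIGNED LINEAR ratios: +20.25 means 20.25-fold up,
-3.25 means 3.25-fold down.  Thresholds always compare |fold|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .graph_core import InformationGraph

__all__ = [
    "ExpressionRecord",
    "StoufferResult",
    "AnnotationReport",
    "P_FLOOR",
    "DEG_MIN_FOLD",
    "STRONG_MIN_FOLD",
    "DEG_MAX_ADJP",
    "stouffer_combine",
    "bh_adjust",
    "filter_deg",
    "annotate_expression",
    "glyph_attributes",
]

P_FLOOR = 1e-300
DEG_MIN_FOLD = 4.0
STRONG_MIN_FOLD = 8.0
DEG_MAX_ADJP = 0.05


@dataclass
class ExpressionRecord:
    """One gene x contrast statistic row."""

    gene_accession: str
    contrast: str
    fold_change: float  # signed linear fold, never 0
    p_value: float      # raw p in (0, 1]
    adj_p: float | None = None  # BH-adjusted p; None until adjusted

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"{self.gene_accession}: fold_change must be nonzero")
        self.p_value = float(min(max(self.p_value, P_FLOOR), 1.0))
        if self.adj_p is not None:
            self.adj_p = float(min(max(self.adj_p, P_FLOOR), 1.0))


@dataclass
class StoufferResult:
    z: float
    combined_p: float


@dataclass
class AnnotationReport:
    annotated: int
    unmatched: int


def stouffer_combine(p_values, directions) -> StoufferResult:
    """Combine replicate two-sided p-values with Stouffer's z-transformation.

    Each p_i is converted to a signed z via z_i = sign_i * Phi^-1(1 - p_i/2)
    (sign from the fold-change direction of that replicate); the combined
    statistic is the unweighted z = sum(z_i) / sqrt(k), reported with its
    two-sided p = 2 * (1 - Phi(|z|)).
    """
    p = np.asarray(list(p_values), dtype=float)
    signs = np.asarray(list(directions), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if p.shape != signs.shape:
        raise ValueError("p_values and directions must have equal length")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    signs = np.sign(signs)
    if np.any(signs == 0):
        raise ValueError("directions must be nonzero")
    p = np.clip(p, P_FLOOR, 1.0)
    z_i = signs * _st.norm.isf(p / 2.0)
    z = float(z_i.sum() / math.sqrt(p.size))
    combined_p = float(min(1.0, 2.0 * _st.norm.sf(abs(z))))
    return StoufferResult(z=z, combined_p=combined_p)


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    q_(i) = p_(i) * m / i on the ascending order statistics, made monotone
    non-decreasing by a cumulative minimum from the largest rank down, then
    capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def filter_deg(records, contrast: str, min_fold: float = DEG_MIN_FOLD,
               max_adjp: float = DEG_MAX_ADJP) -> set[str]:
    """Gene accessions passing |fold| >= min_fold and adj_p <= max_adjp.

    Both comparisons are inclusive.  An unknown contrast yields an empty
    set with a warning rather than an error.
    """
    if min_fold <= 0 or max_adjp <= 0:
        raise ValueError("thresholds must be positive")
    records = list(records)
    known = {r.contrast for r in records}
    if contrast not in known:
        warnings.warn(f"contrast {contrast!r} not present in records",
                      stacklevel=2)
        return set()
    out = set()
    for r in records:
        if r.contrast != contrast or r.adj_p is None:
            continue
        if abs(r.fold_change) >= min_fold and r.adj_p <= max_adjp:
            out.add(r.gene_accession)
    return out


def annotate_expression(graph: InformationGraph, records, contrast: str
                        ) -> AnnotationReport:
    """Attach fold_change.<contrast> / adj_p.<contrast> attributes to genes.

    Re-annotating the same contrast overwrites the attributes in place;
    records for accessions absent from the graph are counted, not dropped
    silently.
    """
    annotated = unmatched = 0
    for r in records:
        if r.contrast != contrast:
            continue
        cid = graph.find("Gene", r.gene_accession)
        if cid is None:
            unmatched += 1
            continue
        graph.set_attribute(cid, f"fold_change.{contrast}", r.fold_change)
        if r.adj_p is not None:
            graph.set_attribute(cid, f"adj_p.{contrast}", r.adj_p)
        annotated += 1
    if unmatched:
        warnings.warn(f"{unmatched} expression records matched no gene concept",
                      stacklevel=2)
    return AnnotationReport(annotated=annotated, unmatched=unmatched)


def glyph_attributes(fold_change: float, base: float = 10.0
                     ) -> tuple[float, str]:
    """Display size and colour class for a gene glyph.

    size = base * log2(|fold| + 1), strictly increasing in |fold|;
    colour is "up" for induced and "down" for repressed genes.
    """
    if fold_change == 0:
        raise ValueError("fold_change must be nonzero")
    size = base * math.log2(abs(fold_change) + 1.0)
    color = "up" if fold_change > 0 else "down"
    return size, color
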
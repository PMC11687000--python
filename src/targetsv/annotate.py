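"""Functional-annotation windows around prioritised variants.

Short structural variants can act at a distance on nearby regulatory
elements, so each prioritised locus is examined inside a symmetric window
(±2.5 kb by default, a plausible effect range for STRs and transposable
elements) against BED-like annotation tracks: enhancers, transcription
factor binding sites, CTCF sites, eQTLs, transcription start sites,
promoters, miRNA binding sites and GWAS-catalogue hits.

Distances are signed: 0 for features overlapping the locus itself, negative
for features upstream in coordinate order, positive downstream. The anchor
is the nearest locus edge by default (``midpoint`` is available: published
"~x kb away" figures are often midpoint-anchored).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._utils import interval_overlap, normalise_chrom
from .harmonize import VariantLocus

DEFAULT_WINDOW = 2_500


class FeatureClass(str, Enum):
    ENHANCER_DISTAL = "enhancer_distal"
    ENHANCER_PROXIMAL = "enhancer_proximal"
    PROMOTER = "promoter"
    TFBS = "TFBS"
    CTCF = "CTCF"
    EQTL = "eQTL"
    TSS = "TSS"
    MIRNA_SITE = "miRNA_site"
    GWAS_HIT = "GWAS_hit"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "FeatureClass":
        """Closed-vocabulary lookup with an ``other`` catch-all."""
        try:
            return cls(label)
        except ValueError:
            by_lower = {m.value.lower(): m for m in cls}
            return by_lower.get(str(label).lower(), cls.OTHER)


@dataclass(frozen=True)
class AnnotationFeature:
    """One BED-like functional feature."""

    chrom: str
    start: int
    end: int
    feature_class: FeatureClass
    label: str = ""
    track: str = ""
    strand: Optional[str] = None  # carried if present, ignored for overlap

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        object.__setattr__(self, "feature_class", FeatureClass.parse(self.feature_class))
        if not self.start < self.end:
            raise ValueError("feature needs start < end")


@dataclass(frozen=True)
class WindowHit:
    feature: AnnotationFeature
    distance: int  # signed bp; 0 iff overlapping the locus
    overlaps: bool


@dataclass
class WindowReport:
    locus_id: str
    window: int
    hits: list[WindowHit]

    def classes_present(self) -> set[FeatureClass]:
        return {h.feature.feature_class for h in self.hits}


def read_annotation_bed(path, track: str = "",
                        default_class: FeatureClass | str = FeatureClass.OTHER,
                        ) -> list[AnnotationFeature]:
    """Read a BED4+ track; column 4 is the feature class (or ``default_class``)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            cls = FeatureClass.parse(f[3]) if len(f) > 3 else FeatureClass.parse(
                str(default_class))
            feats.append(AnnotationFeature(
                chrom=f[0], start=int(f[1]), end=int(f[2]), feature_class=cls,
                label=f[3] if len(f) > 3 else "",
                strand=f[5] if len(f) > 5 else None, track=track))
    return feats


class TrackIndex:
    """Interval-tree index of annotation features, per chromosome."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self._trees: dict[str, IntervalTree] = {}
        self.n_features = 0
        for f in features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
            self.n_features += 1

    def query(self, chrom: str, start: int, end: int) -> list[AnnotationFeature]:
        tree = self._trees.get(normalise_chrom(chrom))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda f: (f.start, f.end, f.feature_class.value, f.label))


def signed_distance(locus_start: int, locus_end: int, feature: AnnotationFeature,
                    anchor: Literal["edge", "midpoint"] = "edge") -> int:
    """Signed bp distance from a locus to a feature.

    0 when the intervals overlap; otherwise negative when the feature lies
    upstream (before the locus in coordinate order), positive downstream.
    ``edge`` measures the gap between nearest interval edges; ``midpoint``
    measures from the locus midpoint to the nearest feature edge.
    """
    if interval_overlap(locus_start, locus_end, feature.start, feature.end) > 0:
        return 0
    if anchor == "midpoint":
        mid = (locus_start + locus_end) // 2
        if feature.end <= mid:
            return feature.end - mid  # negative, upstream
        return feature.start - mid
    if feature.end <= locus_start:
        return feature.end - locus_start  # negative gap upstream
    return feature.start - locus_end      # positive gap downstream


def window_overlap(locus: VariantLocus, tracks: TrackIndex,
                   window: int = DEFAULT_WINDOW,
                   anchor: Literal["edge", "midpoint"] = "edge") -> WindowReport:
    """All features intersecting [locus.start − window, locus.end + window).

    Every hit's |distance| <= window under the edge anchor, and distance is
    0 exactly when the feature overlaps the locus itself.
    """
    q_start = max(0, locus.start - window)
    q_end = locus.end + window
    hits = []
    for f in tracks.query(locus.chrom, q_start, q_end):
        d = signed_distance(locus.start, locus.end, f, anchor=anchor)
        hits.append(WindowHit(feature=f, distance=d, overlaps=(d == 0)))
    return WindowReport(locus_id=locus.locus_id, window=window, hits=hits)


def summarise_annotations(reports: Sequence[WindowReport]) -> pd.DataFrame:
    """Per-class fraction of loci whose window holds >= 1 feature of the class.

    Returns a table with columns ``feature_class``, ``n_loci`` (with a hit)
    and ``fraction`` (of all loci reported); fractions are in [0, 1] and all
    zero when no tracks were loaded.
    """
    n = len(reports)
    rows = []
    for fc in FeatureClass:
        hit = sum(1 for r in reports if fc in r.classes_present())
        rows.append({"feature_class": fc.value, "n_loci": hit,
                     "fraction": (hit / n) if n else 0.0})
    return pd.DataFrame(rows)


def window_report_table(reports: Sequence[WindowReport]) -> pd.DataFrame:
    """Flat per-hit table (supplementary-table layout)."""
    rows = []
    for r in reports:
        for h in r.hits:
            rows.append({
                "locus_id": r.locus_id, "window": r.window,
                "feature_class": h.feature.feature_class.value,
                "label": h.feature.label, "track": h.feature.track,
                "chrom": h.feature.chrom, "start": h.feature.start,
                "end": h.feature.end, "distance": h.distance,
                "overlaps": h.overlaps,
            })
    return pd.DataFrame(rows, columns=["locus_id", "window", "feature_class",
                                       "label", "track", "chrom", "start",
                                       "end", "distance", "overlaps"])
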
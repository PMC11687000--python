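"""Staged prioritisation cascade for harmonised variant calls.

The cascade narrows the full multi-caller call set down to a shortlist of
structural variants plausibly contributing to a GWAS signal, in a fixed
order with a complete audit trail:

1. target-region overlap (calls outside the sequenced windows are removed);
2. caller quality >= 9 on each caller's native scale (locus-table STR calls
   carry no quality and are exempt, flagged ``qual-exempt``);
3. variant class — SNVs removed; insertions/deletions kept only when
   strictly longer than 10 bp; STR and TE loci kept regardless of length;
4. predicted HIGH functional impact AND no existing rsID (under-characterised
   variants); loci with no annotation row are quarantined, never silently
   dropped;
5. overlap with a high-LD block around the lead SNP; target regions that
   declare no blocks pass their loci through flagged ``lenient``.

Stages can be disabled (never reordered); disabling a stage yields a
superset of the full cascade's output. Every stage's audit satisfies
n_in = n_out + number of exclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._utils import interval_overlap, normalise_chrom
from .callset import Caller, QUAL_EXEMPT_CALLERS, VarClass, VariantCall
from .harmonize import (
    BAMEvidence,
    VariantLocus,
    cluster_calls,
    concordance_table,
)
from .regions import GenomicRegion


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


_IMPACT_RANK = {Impact.HIGH: 3, Impact.MODERATE: 2, Impact.LOW: 1,
                Impact.MODIFIER: 0}


@dataclass(frozen=True)
class ImpactAnnotation:
    """Functional-impact row for a variant interval (VEP-style, reduced
    to the worst impact across transcripts)."""

    chrom: str
    start: int
    end: int
    impact: Impact
    rsid: Optional[str] = None
    consequence: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        object.__setattr__(self, "impact", Impact(self.impact))
        rsid = self.rsid
        if rsid is not None and (pd.isna(rsid) or str(rsid) in ("", ".")):
            object.__setattr__(self, "rsid", None)


def read_impacts_tsv(path) -> list[ImpactAnnotation]:
    """Read impact annotations from TSV: chrom, start, end, impact[, rsid, consequence]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    return [
        ImpactAnnotation(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            impact=Impact(str(r.impact).upper()),
            rsid=getattr(r, "rsid", None),
            consequence=str(getattr(r, "consequence", "")))
        for r in df.itertuples()
    ]


@dataclass
class FilterConfig:
    """All cascade thresholds, with the study defaults."""

    qual_min: float = 9.0
    indel_min_len: int = 10          # strict: indels must be > this long
    required_impact: Impact = Impact.HIGH
    require_no_rsid: bool = True
    annotation_window: int = 2_500
    max_breakpoint_dist: int = 500
    min_reciprocal_overlap: float = 0.5
    count_unresolved_as_present: bool = False
    disabled_stages: frozenset = frozenset()

    def __post_init__(self):
        if self.qual_min < 0 or self.indel_min_len < 0 or self.annotation_window < 0:
            raise ValueError("thresholds must be non-negative")
        self.disabled_stages = frozenset(self.disabled_stages)
        unknown = self.disabled_stages - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stage names: {sorted(unknown)}")


STAGE_NAMES = ("region", "quality", "class", "impact", "ld")


@dataclass
class StageAudit:
    stage: str
    n_in: int
    n_out: int
    exclusions: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_in == self.n_out + len(self.exclusions), self.stage


@dataclass
class PrioritisationAudit:
    stages: list[StageAudit] = field(default_factory=list)
    quarantined: dict[str, str] = field(default_factory=dict)

    def add(self, stage: StageAudit) -> None:
        stage.check()
        self.stages.append(stage)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.stage, s.n_in, s.n_out) for s in self.stages]

    def to_json(self) -> str:
        return json.dumps(
            {"stages": [asdict(s) for s in self.stages],
             "quarantined": self.quarantined},
            indent=2, sort_keys=True)


def _call_id(c: VariantCall) -> str:
    return f"{c.caller.value}:{c.sample}:{c.chrom}:{c.start}:{c.source_record}"


# ---------------------------------------------------------------------------
# Stages


def stage1_region_filter(calls: Sequence[VariantCall],
                         regions: Sequence[GenomicRegion],
                         audit: Optional[PrioritisationAudit] = None,
                         ) -> list[VariantCall]:
    """Keep calls whose interval overlaps a target region by >= 1 bp."""
    st = StageAudit("region", n_in=len(calls), n_out=0)
    kept = []
    for c in calls:
        if any(r.overlap(c.chrom, c.start, c.end) > 0 for r in regions):
            kept.append(c)
        else:
            st.exclusions[_call_id(c)] = "outside target regions"
    st.n_out = len(kept)
    if audit is not None:
        audit.add(st)
    return kept


def stage2_quality_filter(calls: Sequence[VariantCall], qual_min: float = 9.0,
                          audit: Optional[PrioritisationAudit] = None,
                          ) -> list[VariantCall]:
    """Keep calls with caller-native quality >= ``qual_min``.

    Calls from sources that emit no quality (STR locus tables, BAM
    inspection) are kept and flagged ``qual-exempt``.
    """
    st = StageAudit("quality", n_in=len(calls), n_out=0)
    kept = []
    for c in calls:
        if c.caller in QUAL_EXEMPT_CALLERS or c.qual is None:
            kept.append(c)
            st.flags[_call_id(c)] = "qual-exempt"
        elif c.qual >= qual_min:
            kept.append(c)
        else:
            st.exclusions[_call_id(c)] = f"qual {c.qual:g} < {qual_min:g}"
    st.n_out = len(kept)
    if audit is not None:
        audit.add(st)
    return kept


def stage3_class_filter(loci: Sequence[VariantLocus], indel_min_len: int = 10,
                        audit: Optional[PrioritisationAudit] = None,
                        ) -> list[VariantLocus]:
    """Remove SNVs; keep indels only when strictly longer than ``indel_min_len``.

    STR and TE loci pass regardless of length. An indel locus's length is
    the largest allele length (or reference span for deletions) any caller
    reported.
    """
    st = StageAudit("class", n_in=len(loci), n_out=0)
    kept = []
    for locus in loci:
        if locus.var_class is VarClass.SNV:
            st.exclusions[locus.locus_id] = "SNV"
            continue
        if locus.var_class in (VarClass.INS, VarClass.DEL, VarClass.COMPLEX):
            span = locus.end - locus.start
            alt_len = max((c.max_alt_len() for c in locus.member_calls), default=0)
            length = max(span if locus.var_class is not VarClass.INS else 0, alt_len)
            if length <= indel_min_len:
                st.exclusions[locus.locus_id] = (
                    f"indel length {length} <= {indel_min_len}")
                continue
        kept.append(locus)
    st.n_out = len(kept)
    if audit is not None:
        audit.add(st)
    return kept


def annotate_loci(loci: Sequence[VariantLocus],
                  annotations: Sequence[ImpactAnnotation],
                  ) -> dict[str, Optional[ImpactAnnotation]]:
    """Attach the worst-impact annotation overlapping each locus (or None)."""
    out: dict[str, Optional[ImpactAnnotation]] = {}
    for locus in loci:
        hits = [a for a in annotations
                if a.chrom == locus.chrom
                and interval_overlap(a.start, a.end, locus.start, locus.end) > 0]
        if not hits:
            out[locus.locus_id] = None
            continue
        worst = max(hits, key=lambda a: _IMPACT_RANK[a.impact])
        rsids = [a.rsid for a in hits if a.rsid]
        out[locus.locus_id] = ImpactAnnotation(
            chrom=worst.chrom, start=worst.start, end=worst.end,
            impact=worst.impact, rsid=rsids[0] if rsids else None,
            consequence=worst.consequence)
    return out


def stage4_impact_filter(loci: Sequence[VariantLocus],
                         annotations: Sequence[ImpactAnnotation],
                         required_impact: Impact = Impact.HIGH,
                         require_no_rsid: bool = True,
                         audit: Optional[PrioritisationAudit] = None,
                         ) -> list[VariantLocus]:
    """Keep loci annotated with the required impact and (optionally) no rsID.

    Loci with no overlapping annotation row are routed to the audit's
    quarantine bin ("needs-annotation") rather than silently dropped.
    """
    st = StageAudit("impact", n_in=len(loci), n_out=0)
    attached = annotate_loci(loci, annotations)
    kept = []
    for locus in loci:
        ann = attached[locus.locus_id]
        if ann is None:
            st.exclusions[locus.locus_id] = "needs-annotation"
            if audit is not None:
                audit.quarantined[locus.locus_id] = "needs-annotation"
            continue
        if ann.impact is not required_impact:
            st.exclusions[locus.locus_id] = f"impact {ann.impact.value}"
            continue
        if require_no_rsid and ann.rsid:
            st.exclusions[locus.locus_id] = f"existing rsID {ann.rsid}"
            continue
        kept.append(locus)
    st.n_out = len(kept)
    if audit is not None:
        audit.add(st)
    return kept


def stage5_ld_filter(loci: Sequence[VariantLocus],
                     ld_blocks: Sequence[GenomicRegion],
                     target_regions: Sequence[GenomicRegion] = (),
                     audit: Optional[PrioritisationAudit] = None,
                     ) -> list[VariantLocus]:
    """Keep loci overlapping a high-LD block by >= 1 bp.

    A target region that declares no LD blocks passes all of its loci
    through with a ``lenient`` flag (regions with weak GWAS signal get a
    more lenient treatment rather than losing every variant).
    """
    st = StageAudit("ld", n_in=len(loci), n_out=0)

    def region_of(locus: VariantLocus) -> Optional[GenomicRegion]:
        for r in target_regions:
            if r.overlap(locus.chrom, locus.start, locus.end) > 0:
                return r
        return None

    regions_with_blocks = {
        r.name for r in target_regions
        if any(r.overlap(b.chrom, b.start, b.end) > 0 for b in ld_blocks)
    }
    kept = []
    for locus in loci:
        if any(b.overlap(locus.chrom, locus.start, locus.end) > 0 for b in ld_blocks):
            kept.append(locus)
            continue
        region = region_of(locus)
        if region is not None and region.name not in regions_with_blocks:
            kept.append(locus)
            st.flags[locus.locus_id] = "lenient"
            continue
        st.exclusions[locus.locus_id] = "outside LD blocks"
    st.n_out = len(kept)
    if audit is not None:
        audit.add(st)
    return kept


# ---------------------------------------------------------------------------
# Full cascade


@dataclass
class CascadeResult:
    loci: list[VariantLocus]
    audit: PrioritisationAudit
    table: pd.DataFrame


def run_cascade(calls: Sequence[VariantCall],
                config: FilterConfig,
                annotations: Sequence[ImpactAnnotation],
                ld_blocks: Sequence[GenomicRegion],
                target_regions: Sequence[GenomicRegion],
                bam_evidence: Sequence[BAMEvidence] = (),
                ) -> CascadeResult:
    """Run the five filter stages in order and build the shortlist table.

    The cascade is deterministic (seed-free): identical inputs give
    identical audits and tables. Stages named in ``config.disabled_stages``
    are skipped, which can only enlarge the output.
    """
    audit = PrioritisationAudit()

    def enabled(name: str) -> bool:
        return name not in config.disabled_stages

    stage_calls = list(calls)
    if enabled("region"):
        stage_calls = stage1_region_filter(stage_calls, target_regions, audit)
    if enabled("quality"):
        stage_calls = stage2_quality_filter(stage_calls, config.qual_min, audit)

    loci = cluster_calls(stage_calls,
                         max_breakpoint_dist=config.max_breakpoint_dist,
                         min_reciprocal_overlap=config.min_reciprocal_overlap)
    if enabled("class"):
        loci = stage3_class_filter(loci, config.indel_min_len, audit)
    if enabled("impact"):
        loci = stage4_impact_filter(loci, annotations, config.required_impact,
                                    config.require_no_rsid, audit)
    if enabled("ld"):
        loci = stage5_ld_filter(loci, ld_blocks, target_regions, audit)

    table = concordance_table(loci, bam_evidence=bam_evidence)
    return CascadeResult(loci=list(loci), audit=audit, table=table)
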
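"""Adaptive-sampling enrichment QC.

Targeted (Read Until) nanopore sequencing ejects molecules that do not match
the supplied target regions, so the key QC question is how strongly the
targets were enriched relative to the rest of the genome. This module
computes, from per-read alignment summaries:

* the live read filter applied during sequencing (minimum read quality and
  length),
* on/off-target classification against the target BED, and
* per-sample and cohort-level statistics — average read length, average
  read quality (Phred, derived from per-read mean error probability) and
  average fold coverage — in the layout of a sequencing-run QC table.

Read quality is aggregated in probability space: a read's Q score is
``-10 log10(mean per-base error probability)``, and a sample's average
quality converts the *mean error probability* across reads back to Phred
(the platform convention; an arithmetic-mean-of-Q alternative is available
via ``qual_aggregation="phred_mean"``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import interval_overlap, normalise_chrom, round_half_up
from .regions import GenomicRegion

#: Live read-filter defaults: reads below Q9 or shorter than 500 bp are
#: removed during sequencing.
DEFAULT_MIN_QUAL = 9.0
DEFAULT_MIN_LEN = 500


@dataclass(frozen=True)
class ReadSummary:
    """Per-read alignment summary (sequencing-summary shape)."""

    read_id: str
    sample: str
    chrom: Optional[str]  # None = unmapped
    mapped_start: int
    mapped_end: int
    read_len: int
    mean_err: float  # mean per-base error probability

    def __post_init__(self):
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not (0 < self.mean_err <= 1):
            raise ValueError(f"mean_err must be in (0, 1], got {self.mean_err}")
        if self.chrom is not None:
            object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
            if not (0 <= self.mapped_start < self.mapped_end):
                raise ValueError("invalid mapped interval")

    @property
    def qual(self) -> float:
        return phred_from_error(self.mean_err)


@dataclass
class EnrichmentStats:
    """Per-sample on- or off-target QC statistics."""

    sample: str
    scope: Literal["on_target", "off_target"]
    n_reads: int
    avg_len: Optional[float]
    avg_qual: Optional[float]
    avg_cov: Optional[float]


@dataclass
class CohortStats:
    """Cohort mean and standard error per QC column (SE = s / sqrt(n), s with n-1)."""

    n_samples: int
    mean: dict[str, float]
    se: dict[str, float]


def phred_from_error(p: float) -> float:
    """Phred quality from an error probability: Q = -10 log10(p)."""
    if not (0 < p <= 1):
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def error_from_phred(q: float) -> float:
    """Error probability from a Phred quality: p = 10^(-Q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def filter_reads(reads: Iterable[ReadSummary], min_q: float = DEFAULT_MIN_QUAL,
                 min_len: int = DEFAULT_MIN_LEN) -> tuple[list[ReadSummary], list[ReadSummary]]:
    """Apply the live sequencing read filter.

    Reads are kept iff quality >= ``min_q`` AND length >= ``min_len``
    (both boundaries inclusive: the filter removes reads *below* Q9 and
    *below* 500 bp).
    """
    kept, removed = [], []
    for r in reads:
        (kept if r.qual >= min_q and r.read_len >= min_len else removed).append(r)
    return kept, removed


def classify_on_target(read: ReadSummary, regions: Sequence[GenomicRegion]) -> bool:
    """True iff the mapped interval overlaps any target region by >= 1 bp.

    Unmapped reads are off-target by definition.
    """
    if read.chrom is None:
        return False
    return any(
        r.overlap(read.chrom, read.mapped_start, read.mapped_end) > 0
        for r in regions
    )


def _aligned_bases_in_regions(read: ReadSummary, regions: Sequence[GenomicRegion]) -> int:
    if read.chrom is None:
        return 0
    return sum(r.overlap(read.chrom, read.mapped_start, read.mapped_end)
               for r in regions)


def sample_stats(reads: Sequence[ReadSummary], regions: Sequence[GenomicRegion],
                 scope: Literal["on_target", "off_target"],
                 genome_size: Optional[float] = None,
                 qual_aggregation: Literal["error_mean", "phred_mean"] = "error_mean",
                 ) -> EnrichmentStats:
    """Per-sample QC statistics for one scope (on- or off-target reads).

    * ``avg_len``: mean read length of the scope's reads.
    * ``avg_qual``: Phred of the mean per-read error probability
      (or the arithmetic mean of per-read Q with ``phred_mean``).
    * ``avg_cov``: on-target — aligned bases falling *inside* the regions
      divided by total region span (only the inside part of a straddling
      read counts); off-target — aligned bases outside the regions divided
      by (``genome_size`` − total region span). ``genome_size`` is required
      for the off-target scope and left ``None`` flags coverage as
      undefined.

    With zero reads in scope all means are ``None`` and ``n_reads`` is 0.
    """
    if len({r.sample for r in reads}) > 1:
        raise ValueError("sample_stats expects reads from a single sample")
    on = scope == "on_target"
    in_scope = [r for r in reads if classify_on_target(r, regions) == on]

    # Coverage is base-level over ALL reads: a read straddling a region edge
    # contributes its inside bases on-target and its outside bases
    # off-target, so the two scopes conserve total aligned bases.
    region_span = sum(r.width for r in regions)
    if on:
        denom: Optional[float] = float(region_span)
        aligned = sum(_aligned_bases_in_regions(r, regions) for r in reads)
    else:
        denom = (genome_size - region_span) if genome_size else None
        aligned = sum(
            max(0, r.mapped_end - r.mapped_start) - _aligned_bases_in_regions(r, regions)
            for r in reads if r.chrom is not None
        )

    if not in_scope:
        return EnrichmentStats(
            sample=reads[0].sample if reads else "", scope=scope,
            n_reads=0, avg_len=None, avg_qual=None, avg_cov=None)

    avg_len = float(np.mean([r.read_len for r in in_scope]))
    if qual_aggregation == "error_mean":
        avg_qual = phred_from_error(float(np.mean([r.mean_err for r in in_scope])))
    else:
        avg_qual = float(np.mean([r.qual for r in in_scope]))
    avg_cov = aligned / denom if denom else None
    return EnrichmentStats(sample=in_scope[0].sample, scope=scope,
                           n_reads=len(in_scope), avg_len=avg_len,
                           avg_qual=avg_qual, avg_cov=avg_cov)


def cohort_summary(values: pd.DataFrame) -> CohortStats:
    """Cohort mean and standard error for each numeric QC column.

    SE uses the sample standard deviation (denominator n−1) over the n
    samples: SE = s / sqrt(n). Requires n >= 2; a constant column has SE 0.
    """
    numeric = values.select_dtypes("number")
    n = len(numeric)
    if n < 2:
        raise ValueError(f"cohort_summary needs >= 2 samples, got {n}")
    mean = {c: float(numeric[c].mean()) for c in numeric.columns}
    se = {c: float(numeric[c].std(ddof=1) / math.sqrt(n)) for c in numeric.columns}
    return CohortStats(n_samples=n, mean=mean, se=se)


# ---------------------------------------------------------------------------
# Table I/O and report formatting

READS_TSV_COLUMNS = ["read_id", "sample", "chrom", "start", "end",
                     "length", "mean_err"]


def read_reads_tsv(path) -> list[ReadSummary]:
    """Read per-read summaries from TSV (``chrom`` '*' or empty = unmapped)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(READS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    reads = []
    for row in df.itertuples():
        chrom = None if (pd.isna(row.chrom) or row.chrom in ("*", "")) else row.chrom
        reads.append(ReadSummary(
            read_id=str(row.read_id), sample=str(row.sample), chrom=chrom,
            mapped_start=int(row.start) if chrom else 0,
            mapped_end=int(row.end) if chrom else 1,
            read_len=int(row.length), mean_err=float(row.mean_err)))
    return reads


def write_reads_tsv(reads: Sequence[ReadSummary], path) -> None:
    rows = [{
        "read_id": r.read_id, "sample": r.sample,
        "chrom": r.chrom or "*",
        "start": r.mapped_start if r.chrom else 0,
        "end": r.mapped_end if r.chrom else 0,
        "length": r.read_len, "mean_err": r.mean_err,
    } for r in reads]
    pd.DataFrame(rows, columns=READS_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def enrichment_table(reads: Sequence[ReadSummary], regions: Sequence[GenomicRegion],
                     genome_size: Optional[float] = None,
                     qual_aggregation: Literal["error_mean", "phred_mean"] = "error_mean",
                     ) -> pd.DataFrame:
    """Per-sample QC table with on/off-target columns (run-QC layout)."""
    by_sample: dict[str, list[ReadSummary]] = {}
    for r in reads:
        by_sample.setdefault(r.sample, []).append(r)
    rows = []
    for sample in sorted(by_sample):
        row: dict = {"sample": sample}
        for scope, prefix in (("on_target", "on"), ("off_target", "off")):
            st = sample_stats(by_sample[sample], regions, scope,
                              genome_size=genome_size,
                              qual_aggregation=qual_aggregation)
            row[f"{prefix}_avg_len"] = st.avg_len
            row[f"{prefix}_avg_qual"] = st.avg_qual
            row[f"{prefix}_avg_cov"] = st.avg_cov
            row[f"{prefix}_n_reads"] = st.n_reads
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


#: Printed precision per QC column (half-up rounding for display).
DISPLAY_PRECISION = {"avg_len": 0, "avg_qual": 1, "avg_cov": 1, "se": 2}


def format_qc_report(table: pd.DataFrame, cohort: CohortStats) -> str:
    """Render the per-sample QC table plus the cohort SE row as TSV text.

    Display rounding is half-up to the conventional printed precision:
    integer bp for lengths, 1 dp for quality and coverage, 2 dp for SEs.
    """
    cols = [c for c in table.columns if not c.endswith("n_reads")]
    lines = ["sample\t" + "\t".join(cols)]
    for sample, row in table[cols].iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                cells.append("NA")
            elif c.endswith("avg_len"):
                cells.append(str(int(round_half_up(v, 0))))
            else:
                cells.append(f"{round_half_up(v, 1):.1f}")
        lines.append(f"{sample}\t" + "\t".join(cells))
    se_cells = [f"{round_half_up(cohort.se[c], 2):.2f}" if c in cohort.se else "NA"
                for c in cols]
    lines.append("SE\t" + "\t".join(se_cells))
    return "\n".join(lines) + "\n"


def qc_report_json(table: pd.DataFrame, cohort: CohortStats) -> str:
    payload = {
        "per_sample": json.loads(table.to_json(orient="index")),
        "cohort_mean": cohort.mean,
        "cohort_se": cohort.se,
        "n_samples": cohort.n_samples,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
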
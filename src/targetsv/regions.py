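"""Fixed-width target regions centred on GWAS lead SNPs.

Adaptive (Read Until) sequencing enriches a supplied set of genomic windows;
here each window is built by flanking a GWAS lead SNP by a fixed distance on
either side (100 kb by default, giving 200 kb targets). Intervals are stored
0-based half-open throughout; the coordinate pair printed in study-style
tables is simply ``(pos - flank, pos + flank)`` around the SNP's 1-based
position, and interpreting that pair as half-open gives the exact 200 kb
width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._utils import interval_overlap, normalise_chrom

DEFAULT_FLANK = 100_000


@dataclass(frozen=True)
class LeadSNP:
    """A GWAS lead SNP anchoring one target region.

    ``pos`` is the 1-based coordinate as reported by GWAS summary
    statistics / dbSNP.
    """

    rsid: str
    chrom: str
    pos: int
    region_name: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))


@dataclass(frozen=True)
class GenomicRegion:
    """A named 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    flank: int = DEFAULT_FLANK

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def display_coords(self) -> tuple[int, int]:
        """Coordinate pair as printed in study-style tables (pos ± flank)."""
        return (self.start, self.end)

    def contains(self, chrom: str, pos0: int) -> bool:
        return normalise_chrom(chrom) == self.chrom and self.start <= pos0 < self.end

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if normalise_chrom(chrom) != self.chrom:
            return 0
        return interval_overlap(self.start, self.end, start, end)


def build_target_region(snp: LeadSNP, flank: int = DEFAULT_FLANK) -> GenomicRegion:
    """Build the fixed-width target region centred on a lead SNP.

    The region spans ``flank`` bp either side of the SNP: display pair
    ``(pos - flank, pos + flank)``, width exactly ``2 * flank``.

    Raises
    ------
    ValueError
        If ``flank <= 0`` or the region would underflow the chromosome start
        (``pos <= flank``).
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    if snp.pos <= flank:
        raise ValueError(
            f"{snp.rsid}: position {snp.pos} <= flank {flank}; "
            "region would underflow coordinate 0"
        )
    name = snp.region_name or snp.rsid
    return GenomicRegion(
        chrom=snp.chrom, start=snp.pos - flank, end=snp.pos + flank,
        name=name, flank=flank,
    )


def build_target_regions(snps: Iterable[LeadSNP], flank: int = DEFAULT_FLANK) -> list[GenomicRegion]:
    return [build_target_region(s, flank) for s in snps]


def read_lead_snps(path) -> list[LeadSNP]:
    """Read a lead-SNP panel from TSV with columns rsid, chrom, pos, name."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lead-SNP table missing columns: {sorted(missing)}")
    rsids = df["rsid"].tolist()
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsids in lead-SNP panel")
    names = df["name"] if "name" in df.columns else df["rsid"]
    return [
        LeadSNP(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos), region_name=str(n))
        for r, n in zip(df.itertuples(), names)
    ]


def _warn_if_overlapping(regions: Sequence[GenomicRegion]) -> None:
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"target regions overlap on {chrom}: {a.name} and {b.name}",
                    stacklevel=3,
                )


def write_regions_bed(regions: Sequence[GenomicRegion], path) -> None:
    """Write regions as BED3+1 (chrom, 0-based start, exclusive end, name)."""
    _warn_if_overlapping(regions)
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def read_regions_bed(path, flank: int = DEFAULT_FLANK) -> list[GenomicRegion]:
    """Read BED3+1 back into regions (lossless round trip with write)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            regions.append(GenomicRegion(chrom, start, end, name, flank))
    return regions


def extract_region_fasta(reference, regions: Sequence[GenomicRegion], out_path=None):
    """Slice target-region sequences out of a reference FASTA.

    Parameters
    ----------
    reference
        Path to an indexed FASTA (opened with pyfaidx) or an already-open
        ``pyfaidx.Fasta``/mapping of contig name -> sequence string.
    regions
        Regions to extract. Each must lie fully inside its contig.
    out_path
        Optional path; when given the records are also written as FASTA.

    Returns
    -------
    list of (record_id, sequence) with ``record_id`` encoding the region
    name and coordinates.
    """
    import pyfaidx

    if isinstance(reference, (str, Path)):
        ref = pyfaidx.Fasta(str(reference))
    else:
        ref = reference

    records = []
    for r in regions:
        if r.chrom in ref:
            contig = ref[r.chrom]
        else:
            bare = r.chrom.removeprefix("chr")
            if bare not in ref:
                raise KeyError(f"contig {r.chrom} not in reference")
            contig = ref[bare]
        contig_len = len(contig)
        if r.end > contig_len:
            raise ValueError(
                f"region {r.name} ({r.chrom}:{r.start}-{r.end}) extends past "
                f"contig end ({contig_len} bp)"
            )
        seq = str(contig[r.start:r.end])
        rec_id = f"{r.name}::{r.chrom}:{r.start}-{r.end}"
        records.append((rec_id, seq))

    if out_path is not None:
        with open(out_path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    return records
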
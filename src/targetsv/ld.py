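"""Pairwise linkage disequilibrium (r²) and LD blocks around an anchor SNP.

Works on *phased* biallelic haplotypes (alleles coded 0/1). For two sites
with allele frequencies p_A, p_B and joint frequency p_AB of the 1/1
haplotype, D = p_AB − p_A·p_B and

    r² = D² / (p_A (1 − p_A) · p_B (1 − p_B)).

r² is symmetric, invariant to swapping the 0/1 labels at either site, lies
in [0, 1], and for binary vectors equals the squared Pearson correlation —
which tests use as an independent check. A block of high LD around an
anchor site is a maximal run of consecutive sites whose r² with the anchor
reaches a threshold; a below-threshold site always terminates a run, and an
optional ``max_gap`` (bp) additionally breaks runs across large positional
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import normalise_chrom
from .regions import GenomicRegion

DEFAULT_R2_THRESHOLD = 0.8


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: rows = haplotypes, columns = sites (0/1 alleles)."""

    chrom: str
    positions: np.ndarray          # bp, strictly increasing
    alleles: np.ndarray            # (n_haplotypes, n_sites), entries in {0,1}
    haplotype_ids: list[str]

    def __post_init__(self):
        self.chrom = normalise_chrom(self.chrom)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] < 2:
            raise ValueError("need >= 2 haplotypes")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions / matrix column mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def site_index(self, pos: int) -> int:
        idx = int(np.searchsorted(self.positions, pos))
        if idx >= self.n_sites or self.positions[idx] != pos:
            raise KeyError(f"no site at position {pos}")
        return idx


@dataclass(frozen=True)
class LDBlock:
    """A run of sites in high LD with the anchor, as a genomic interval."""

    region: GenomicRegion
    anchor_pos: int
    min_r2: float
    threshold: float
    member_positions: tuple[int, ...]


def r_squared(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """r² between two phased biallelic sites.

    Raises on monomorphic input (r² is undefined there, not zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length allele vectors (>= 2 haplotypes)")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic site: r^2 undefined")
    p_ab = float(np.mean(a * b))
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    # Clamp tiny float overshoot; the quantity is in [0, 1] exactly.
    return min(1.0, max(0.0, float(r2)))


def r2_profile(haps: HaplotypeMatrix, anchor_pos: int) -> np.ndarray:
    """r² of every site against the anchor site (NaN at monomorphic sites)."""
    anchor_idx = haps.site_index(anchor_pos)
    anchor = haps.alleles[:, anchor_idx]
    if anchor.min() == anchor.max():
        raise ValueError("anchor site is monomorphic")
    out = np.full(haps.n_sites, np.nan)
    for j in range(haps.n_sites):
        col = haps.alleles[:, j]
        if col.min() == col.max():
            continue
        out[j] = r_squared(anchor, col)
    return out


def ld_blocks(haps: HaplotypeMatrix, anchor_pos: int,
              r2_threshold: float = DEFAULT_R2_THRESHOLD,
              max_gap: Optional[int] = None) -> list[LDBlock]:
    """LD blocks: maximal runs of sites with r²(site, anchor) >= threshold.

    A below-threshold (or monomorphic) site between two qualifying sites
    breaks the run; a positional gap larger than ``max_gap`` (when given)
    also breaks it. Block intervals span exactly the member sites — padding,
    if wanted, is applied by the caller.
    """
    prof = r2_profile(haps, anchor_pos)
    qualifies = ~np.isnan(prof) & (prof >= r2_threshold)

    blocks: list[LDBlock] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        pos = haps.positions[run_idx]
        blocks.append(LDBlock(
            region=GenomicRegion(haps.chrom, int(pos[0]), int(pos[-1]) + 1,
                                 name=f"ld_block_{len(blocks) + 1}"),
            anchor_pos=anchor_pos,
            min_r2=float(np.min(prof[run_idx])),
            threshold=r2_threshold,
            member_positions=tuple(int(p) for p in pos),
        ))

    for j in range(haps.n_sites):
        if not qualifies[j]:
            flush(run)
            run = []
            continue
        if run and max_gap is not None and (
                haps.positions[j] - haps.positions[run[-1]] > max_gap):
            flush(run)
            run = []
        run.append(j)
    flush(run)
    return blocks


# ---------------------------------------------------------------------------
# I/O


def read_haplotypes_tsv(path) -> HaplotypeMatrix:
    """Read a haplotype matrix from TSV.

    Layout: first column ``haplotype`` (ids), remaining column names are
    ``chrom:pos`` site labels; entries 0/1.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "haplotype":
        raise ValueError("first column must be 'haplotype'")
    ids = df["haplotype"].astype(str).tolist()
    site_cols = list(df.columns[1:])
    chroms = {c.split(":")[0] for c in site_cols}
    if len(chroms) != 1:
        raise ValueError("one haplotype matrix per chromosome")
    positions = np.array([int(c.split(":")[1]) for c in site_cols])
    order = np.argsort(positions)
    return HaplotypeMatrix(
        chrom=chroms.pop(), positions=positions[order],
        alleles=df[site_cols].to_numpy()[:, order], haplotype_ids=ids)


def write_haplotypes_tsv(haps: HaplotypeMatrix, path) -> None:
    cols = {f"{haps.chrom}:{p}": haps.alleles[:, j]
            for j, p in enumerate(haps.positions)}
    df = pd.DataFrame({"haplotype": haps.haplotype_ids, **cols})
    df.to_csv(path, sep="\t", index=False)


def write_blocks_bed(blocks: Sequence[LDBlock], path) -> None:
    """Blocks as BED with the r² threshold in column 5."""
    with open(path, "w") as fh:
        for b in blocks:
            r = b.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{b.threshold}\n")
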
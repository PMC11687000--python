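"""Cross-caller, cross-sample variant harmonisation.

Different callers report the same underlying variant with jittered
breakpoints, different classes (an STR length change may surface as a plain
insertion in an SV caller's VCF) and discordant genotypes. Calls are grouped
into loci by single-linkage clustering under a class-aware match predicate,
and two cohort-level rules are then applied per locus:

* presence — a variant is present for a sample if *any* caller reports a
  non-reference genotype there, or manual alignment inspection (a BAM
  evidence table) flags a clear difference from the reference. Union
  semantics, no majority vote: the aim is presence/absence, not a consensus
  genotype.
* variation — alleles count as distinct when they differ in length or
  structure (motif); sequence-identical alleles of equal length collapse.

The per-caller output cell "N(a)" is: N samples carrying a non-reference
call from that caller at the locus, with `a` distinct alternative alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._utils import interval_overlap, normalise_chrom
from .callset import (
    Caller,
    Genotype,
    NON_REF_GENOTYPES,
    VarClass,
    VariantCall,
)

DEFAULT_MAX_BREAKPOINT_DIST = 500
DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5
DEFAULT_MAX_CLUSTER_SPAN = 100_000

#: Which class pairs may be merged into one locus. Length-change calls from
#: SV/small-variant callers inside an STR locus are STR evidence, and TE
#: insertions surface as plain insertions; SNVs only ever match SNVs.
CLASS_COMPATIBLE: frozenset[tuple[VarClass, VarClass]] = frozenset(
    {(a, a) for a in VarClass}
    | {(VarClass.STR, VarClass.INS), (VarClass.INS, VarClass.STR),
       (VarClass.STR, VarClass.DEL), (VarClass.DEL, VarClass.STR),
       (VarClass.TE, VarClass.INS), (VarClass.INS, VarClass.TE),
       (VarClass.COMPLEX, VarClass.INS), (VarClass.INS, VarClass.COMPLEX),
       (VarClass.COMPLEX, VarClass.DEL), (VarClass.DEL, VarClass.COMPLEX)}
)

#: Locus class priority when members disagree (composite classes win).
_CLASS_PRIORITY = [VarClass.TE, VarClass.STR, VarClass.COMPLEX,
                   VarClass.DEL, VarClass.INS, VarClass.SNV]


@dataclass
class VariantLocus:
    """One underlying variant: the cluster of calls that describe it."""

    chrom: str
    start: int
    end: int
    var_class: VarClass
    member_calls: list[VariantCall] = field(default_factory=list)
    ref_desc: str = ""
    locus_id: str = ""

    def callers(self) -> list[Caller]:
        return sorted({c.caller for c in self.member_calls}, key=lambda c: c.value)

    def samples_nonref(self, caller: Optional[Caller] = None) -> set[str]:
        return {
            c.sample for c in self.member_calls
            if c.is_nonref and (caller is None or c.caller == caller)
        }

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.var_class.value)


@dataclass(frozen=True)
class ConcordanceCell:
    """Per-caller tally at a locus: N samples non-ref, a distinct alt alleles."""

    caller: Caller
    n_samples_nonref: int
    n_distinct_alt: int

    def __str__(self) -> str:
        if self.n_samples_nonref == 0:
            return ""
        return f"{self.n_samples_nonref}({self.n_distinct_alt})"


@dataclass(frozen=True)
class BAMEvidence:
    """Human judgement from alignment inspection at one (sample, locus)."""

    sample: str
    chrom: str
    start: int
    end: int
    differs_from_reference: bool
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))


def read_bam_evidence(path) -> list[BAMEvidence]:
    """Read a BAM-evidence TSV: sample, chrom, start, end, differs (0/1)[, note]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        BAMEvidence(sample=str(r.sample), chrom=r.chrom, start=int(r.start),
                    end=int(r.end), differs_from_reference=bool(int(r.differs)),
                    note=str(getattr(r, "note", "")))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Matching and clustering


def calls_match(a: VariantCall, b: VariantCall,
                max_breakpoint_dist: int = DEFAULT_MAX_BREAKPOINT_DIST,
                min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
                ) -> bool:
    """Pairwise predicate: do two calls describe the same variant?

    * SNV vs SNV: identical position and alt sequences.
    * INS vs INS: insertion points within ``max_breakpoint_dist``.
    * DEL vs DEL: both breakpoints within ``max_breakpoint_dist`` AND
      reciprocal overlap >= ``min_reciprocal_overlap``.
    * STR/TE vs each other or vs INS/DEL (per the compatibility matrix):
      >= 1 bp interval overlap.
    """
    if a.chrom != b.chrom:
        return False
    if (a.var_class, b.var_class) not in CLASS_COMPATIBLE:
        return False
    ca, cb = a.var_class, b.var_class
    if ca is VarClass.SNV:  # implies cb is SNV (matrix)
        if a.start != b.start:
            return False
        alts_a = {al.seq for al in a.alt_alleles}
        alts_b = {al.seq for al in b.alt_alleles}
        # A hom-ref/unresolved record with no alts matches on position alone.
        return not alts_a or not alts_b or bool(alts_a & alts_b)
    if {ca, cb} <= {VarClass.INS}:
        return abs(a.start - b.start) <= max_breakpoint_dist
    if {ca, cb} <= {VarClass.DEL}:
        if abs(a.start - b.start) > max_breakpoint_dist:
            return False
        if abs(a.end - b.end) > max_breakpoint_dist:
            return False
        ov = interval_overlap(a.start, a.end, b.start, b.end)
        shorter = min(a.end - a.start, b.end - b.start)
        longer = max(a.end - a.start, b.end - b.start)
        return longer > 0 and ov / longer >= min_reciprocal_overlap
    # STR/TE/COMPLEX involved: locus-interval overlap.
    return interval_overlap(a.start, a.end, b.start, b.end) >= 1


def _canonical_order(calls: Iterable[VariantCall]) -> list[VariantCall]:
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end,
                                        c.var_class.value, c.caller.value,
                                        c.sample, c.source_record))


def cluster_calls(calls: Sequence[VariantCall],
                  max_breakpoint_dist: int = DEFAULT_MAX_BREAKPOINT_DIST,
                  min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
                  max_cluster_span: int = DEFAULT_MAX_CLUSTER_SPAN,
                  ) -> list[VariantLocus]:
    """Single-linkage clustering of calls into loci.

    Calls are first sorted canonically (chrom, start, end, class, caller,
    sample) so the partition is invariant to input order. Within one
    chromosome, a sorted sweep unions any pair satisfying
    :func:`calls_match`; the pruning window is safe because every predicate
    bounds the start-coordinate distance of matching calls.

    Every call lands in exactly one locus. Clusters spanning more than
    ``max_cluster_span`` are split at their largest internal gap with a
    warning (pathological mega-cluster guard).
    """
    ordered = _canonical_order(calls)
    n = len(ordered)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # Sweep pruning: for b sorted after a, a match needs either
    # |b.start - a.start| <= breakpoint distance or >= 1 bp overlap
    # (b.start < a.end), so b.start is bounded.
    for i in range(n):
        a = ordered[i]
        bound = max(a.start + max_breakpoint_dist, a.end - 1)
        for j in range(i + 1, n):
            b = ordered[j]
            if b.chrom != a.chrom or b.start > bound:
                break
            if calls_match(a, b, max_breakpoint_dist, min_reciprocal_overlap):
                union(i, j)

    groups: dict[int, list[VariantCall]] = {}
    for i, c in enumerate(ordered):
        groups.setdefault(find(i), []).append(c)

    loci: list[VariantLocus] = []
    for members in groups.values():
        loci.extend(_split_mega_cluster(members, max_cluster_span))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.var_class.value))
    for k, locus in enumerate(loci, start=1):
        locus.locus_id = f"locus_{k:04d}"
    return loci


def _make_locus(members: list[VariantCall]) -> VariantLocus:
    var_class = next(c for c in _CLASS_PRIORITY
                     if any(m.var_class is c for m in members))
    ref_descs = [m.ref_seq for m in members if m.ref_seq]
    return VariantLocus(
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        var_class=var_class,
        member_calls=list(members),
        ref_desc=max(ref_descs, key=len) if ref_descs else "",
    )


def _split_mega_cluster(members: list[VariantCall], max_span: int) -> list[VariantLocus]:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    if end - start <= max_span or len(members) < 2:
        return [_make_locus(members)]
    warnings.warn(
        f"splitting pathological cluster spanning {end - start} bp "
        f"at {members[0].chrom}:{start}-{end}", stacklevel=2)
    ms = sorted(members, key=lambda m: (m.start, m.end))
    gaps = [ms[i + 1].start - ms[i].start for i in range(len(ms) - 1)]
    cut = gaps.index(max(gaps)) + 1
    return (_split_mega_cluster(ms[:cut], max_span)
            + _split_mega_cluster(ms[cut:], max_span))


def cluster_calls_bruteforce(calls: Sequence[VariantCall],
                             max_breakpoint_dist: int = DEFAULT_MAX_BREAKPOINT_DIST,
                             min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
                             ) -> list[frozenset[int]]:
    """Transitive closure of the pairwise match predicate, all pairs.

    Reference implementation for small inputs: returns the partition as
    frozensets of indices into the canonically ordered call list. Used as
    the clustering oracle in tests.
    """
    ordered = _canonical_order(calls)
    n = len(ordered)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if calls_match(ordered[i], ordered[j],
                           max_breakpoint_dist, min_reciprocal_overlap):
                adj[i][j] = adj[j][i] = True
    seen = [False] * n
    parts = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if seen[k]:
                continue
            seen[k] = True
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and not seen[j])
        parts.append(frozenset(comp))
    return parts


# ---------------------------------------------------------------------------
# Presence and allele diversity


def _bam_supports(locus: VariantLocus, sample: str,
                  bam_evidence: Sequence[BAMEvidence]) -> bool:
    return any(
        ev.sample == sample and ev.differs_from_reference
        and ev.chrom == locus.chrom
        and interval_overlap(ev.start, ev.end, locus.start, locus.end) > 0
        for ev in bam_evidence
    )


def variant_present(locus: VariantLocus, sample: str,
                    bam_evidence: Sequence[BAMEvidence] = (),
                    count_unresolved: bool = False) -> bool:
    """Presence rule: any caller non-ref call, or BAM inspection evidence.

    ``count_unresolved`` additionally counts calls whose genotype the caller
    could not resolve (some callers coerce these to homozygous reference and
    the record is the only trace of the variant).
    """
    for c in locus.member_calls:
        if c.sample != sample:
            continue
        if c.is_nonref:
            return True
        if count_unresolved and c.genotype is Genotype.UNRESOLVED and c.alt_alleles:
            return True
    return _bam_supports(locus, sample, bam_evidence)


def allele_diversity(locus: VariantLocus) -> dict[Caller, ConcordanceCell]:
    """Per-caller sample and distinct-allele tallies at a locus.

    Distinctness is inequality of the (structural class, length, motif,
    sequence) tuple: a difference in length or structure counts, identical
    alleles of equal length collapse.
    """
    cells: dict[Caller, ConcordanceCell] = {}
    for caller in locus.callers():
        samples = set()
        alleles = set()
        for c in locus.member_calls:
            if c.caller != caller or not c.is_nonref:
                continue
            samples.add(c.sample)
            alleles.update((c.var_class,) + a.distinct_key()
                           for a in c.alt_alleles)
        cells[caller] = ConcordanceCell(caller, len(samples), len(alleles))
    return cells


def concordance_table(loci: Sequence[VariantLocus],
                      bam_evidence: Sequence[BAMEvidence] = (),
                      cohort: Optional[Sequence[str]] = None,
                      callers: Optional[Sequence[Caller]] = None,
                      ) -> pd.DataFrame:
    """Locus × caller concordance matrix with "N(a)" cells and a BAM column.

    The BAM column lists samples whose alignments visibly differ at the
    locus ("All" when the whole cohort does); a caller that never called the
    locus gets an empty cell.
    """
    if callers is None:
        callers = [Caller.SV_CALLER_A, Caller.SV_CALLER_B,
                   Caller.SMALLVAR_CALLER, Caller.STR_CALLER]
    if cohort is None:
        cohort = sorted({c.sample for l in loci for c in l.member_calls})
    rows = []
    for locus in loci:
        cells = allele_diversity(locus)
        row: dict = {
            "id": locus.locus_id, "chrom": locus.chrom,
            "start": locus.start, "end": locus.end,
            "sv_type": locus.var_class.value, "ref_desc": locus.ref_desc,
        }
        for caller in callers:
            cell = cells.get(caller)
            row[caller.value] = str(cell) if cell else ""
        supported = sorted(s for s in cohort if _bam_supports(locus, s, bam_evidence))
        if cohort and len(supported) == len(cohort):
            row["bam"] = "All"
        else:
            row["bam"] = ",".join(supported)
        rows.append(row)
    cols = (["id", "chrom", "start", "end", "sv_type", "ref_desc"]
            + [c.value for c in callers] + ["bam"])
    return pd.DataFrame(rows, columns=cols)
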
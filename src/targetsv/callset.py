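"""Normalised variant model and I/O for heterogeneous caller outputs.

Long-read pipelines commonly combine several callers whose outputs differ in
dialect: SV callers emit VCFs with symbolic alleles and SVTYPE/SVLEN
annotations, small-variant callers emit sequence-explicit VCFs, and STR
genotypers emit BED/TSV locus tables with per-allele motif copy numbers.
Everything is parsed here into one :class:`VariantCall` record so that
downstream harmonisation and prioritisation see a single shape.

Conventions
-----------
* Coordinates are 0-based half-open internally; VCF POS/END are converted on
  the way in and restored on the way out.
* Caller-native quality scales are kept as-is (no rescaling); STR locus
  tables carry no quality and their calls have ``qual=None``.
* Missing genotypes (``./.``) are preserved as ``Genotype.UNRESOLVED`` rather
  than coerced to homozygous reference; a compatibility switch downstream can
  reproduce the coercion some callers apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._utils import normalise_chrom

log = logging.getLogger(__name__)


class Caller(str, Enum):
    """Roles of the four callers plus manual alignment inspection."""

    SV_CALLER_A = "sv_caller_a"      # breakpoint SV caller (Sniffles2-like)
    SV_CALLER_B = "sv_caller_b"      # split-read SV caller (NanoVar-like)
    SMALLVAR_CALLER = "smallvar_caller"  # small-variant caller (Clair3-like)
    STR_CALLER = "str_caller"        # STR genotyper, locus tables (Straglr-like)
    BAM_INSPECTION = "bam_inspection"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: Callers whose native output carries no per-call quality score and which
#: are therefore exempt from quality filtering.
QUAL_EXEMPT_CALLERS = frozenset({Caller.STR_CALLER, Caller.BAM_INSPECTION})


class VarClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    STR = "STR"
    TE = "TE"
    COMPLEX = "COMPLEX"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    UNRESOLVED = "unresolved"


NON_REF_GENOTYPES = frozenset({Genotype.HET, Genotype.HOM_ALT})


@dataclass(frozen=True)
class STRAllele:
    """One short-tandem-repeat allele: motif and (possibly fractional) copies."""

    motif: str
    copy_number: float
    allele_len: int

    def __post_init__(self):
        if len(self.motif) < 1:
            raise ValueError("empty STR motif")
        if self.copy_number <= 0:
            raise ValueError(f"copy_number must be > 0, got {self.copy_number}")


@dataclass(frozen=True)
class AltAllele:
    """One alternative allele: a sequence, a length change, or an STR state.

    ``length`` is the allele's size in bp — inserted bases for an insertion,
    deleted bases for a deletion, total allele length for an STR.
    """

    length: int
    seq: Optional[str] = None
    motif: Optional[str] = None
    copy_number: Optional[float] = None

    def distinct_key(self) -> tuple:
        """Key under which alleles are counted as the same variation.

        A difference in length or structure (motif) makes alleles distinct;
        sequence-identical alleles of equal length collapse.
        """
        return (self.length, self.motif, self.seq)


@dataclass(frozen=True)
class VariantCall:
    """One caller's call for one sample, in the normalised model."""

    sample: str
    caller: Caller
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    var_class: VarClass
    ref_len: int = 0
    ref_seq: Optional[str] = None
    alt_alleles: tuple[AltAllele, ...] = ()
    qual: Optional[float] = None
    genotype: Genotype = Genotype.UNRESOLVED
    source_record: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        object.__setattr__(self, "caller", Caller(self.caller))
        object.__setattr__(self, "var_class", VarClass(self.var_class))
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))
        if self.var_class is VarClass.SNV and self.end != self.start + 1:
            raise ValueError("SNV must have end == start + 1")
        if self.var_class in (VarClass.DEL, VarClass.STR, VarClass.TE) and not (
            self.start < self.end
        ):
            raise ValueError(f"{self.var_class}: need start < end")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be >= 0")
        if not self.alt_alleles and self.genotype in NON_REF_GENOTYPES:
            raise ValueError("non-reference genotype requires alt alleles")

    @property
    def is_nonref(self) -> bool:
        return self.genotype in NON_REF_GENOTYPES

    def max_alt_len(self) -> int:
        return max((a.length for a in self.alt_alleles), default=0)


# ---------------------------------------------------------------------------
# VCF input


def _classify_vcf_alt(ref: str, alt: str, svtype: Optional[str],
                      svlen: Optional[int]) -> tuple[VarClass, AltAllele]:
    """Map a VCF REF/ALT (plus SVTYPE/SVLEN annotations) to class + allele."""
    if alt.startswith("<"):
        tag = alt.strip("<>").split(":")[0].upper()
        svtype = svtype or tag
    if svtype:
        st = svtype.upper()
        length = abs(svlen) if svlen is not None else max(len(ref), 1)
        if st == "INS":
            return VarClass.INS, AltAllele(length=length)
        if st == "DEL":
            return VarClass.DEL, AltAllele(length=length)
        if st in ("STR", "CNV", "DUP", "DUP:TANDEM"):
            return VarClass.STR, AltAllele(length=length)
        if st in ("TE", "INS:ME", "ME"):
            return VarClass.TE, AltAllele(length=length)
        if st == "SNV":
            return VarClass.SNV, AltAllele(length=1, seq=alt if not alt.startswith("<") else None)
        return VarClass.COMPLEX, AltAllele(length=length)
    # Sequence-explicit alleles: class from ref/alt lengths.
    if len(ref) == 1 and len(alt) == 1:
        return VarClass.SNV, AltAllele(length=1, seq=alt)
    if len(alt) > len(ref):
        return VarClass.INS, AltAllele(length=len(alt) - len(ref), seq=alt)
    if len(alt) < len(ref):
        return VarClass.DEL, AltAllele(length=len(ref) - len(alt), seq=alt)
    return VarClass.COMPLEX, AltAllele(length=len(alt), seq=alt)


def _genotype_from_gt(gt: tuple) -> Genotype:
    if gt is None or all(a is None for a in gt):
        return Genotype.UNRESOLVED
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return Genotype.HOM_REF
    if all(a > 0 for a in alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def _scalar(v):
    if isinstance(v, (tuple, list)):
        return v[0] if v else None
    return v


def read_sv_vcf(path, caller_tag: Caller | str, sample: Optional[str] = None,
                with_stats: bool = False):
    """Read a (possibly SV-annotated) VCF into normalised calls.

    Works for both symbolic-allele SV VCFs (SVTYPE/SVLEN/END) and
    sequence-explicit small-variant VCFs. One :class:`VariantCall` is
    produced per record per VCF sample column.

    Parameters
    ----------
    caller_tag
        Which caller produced the file.
    sample
        Override the sample name (useful for single-sample files whose
        header carries a generic name).
    with_stats
        When true, return ``(calls, n_skipped)`` where ``n_skipped`` counts
        records dropped with a warning for missing/inconsistent fields.

    Malformed records are skipped with a logged warning; a truncated file
    raises.
    """
    import pysam

    caller = Caller(caller_tag)
    calls: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            try:
                svtype = rec.info.get("SVTYPE")
                svlen = _scalar(rec.info.get("SVLEN"))
                if svlen is not None:
                    svlen = int(svlen)
                ref = rec.ref or "N"
                alts = rec.alts or ()
                if not alts:
                    raise ValueError("record without ALT allele")
                classified = [_classify_vcf_alt(ref, a, svtype, svlen) for a in alts]
                var_class = classified[0][0]
                alt_alleles = tuple(c[1] for c in classified)
                # VCF anchors indels on the base before the event: the
                # changed bases start at POS+1 (rec.start is 0-based POS).
                if var_class is VarClass.SNV:
                    start = rec.start
                    end = start + 1
                elif var_class is VarClass.INS:
                    start = rec.start + 1  # point of insertion
                    end = start + 1
                else:
                    start = rec.start + 1
                    end = rec.stop
                    if end <= start:
                        end = start + max(len(ref) - 1, 1)
                qual = float(rec.qual) if rec.qual is not None else None
                rec_id = rec.id or f"{rec.chrom}:{rec.pos}"
                if vcf_samples:
                    for vcf_sample in vcf_samples:
                        gt = rec.samples[vcf_sample].get("GT")
                        genotype = _genotype_from_gt(gt)
                        calls.append(VariantCall(
                            sample=sample or vcf_sample, caller=caller,
                            chrom=rec.chrom, start=start, end=end,
                            var_class=var_class, ref_len=len(ref),
                            ref_seq=ref if len(ref) <= 200 else None,
                            alt_alleles=alt_alleles, qual=qual,
                            genotype=genotype, source_record=rec_id,
                        ))
                else:
                    calls.append(VariantCall(
                        sample=sample or "unknown", caller=caller,
                        chrom=rec.chrom, start=start, end=end,
                        var_class=var_class, ref_len=len(ref),
                        ref_seq=ref if len(ref) <= 200 else None,
                        alt_alleles=alt_alleles, qual=qual,
                        genotype=Genotype.UNRESOLVED, source_record=rec_id,
                    ))
            except (ValueError, KeyError, TypeError) as exc:
                n_skipped += 1
                log.warning("skipping malformed record at %s:%s: %s",
                            rec.chrom, rec.pos, exc)
    if with_stats:
        return calls, n_skipped
    return calls


# ---------------------------------------------------------------------------
# STR locus tables

STR_TABLE_COLUMNS = ["chrom", "start", "end", "motif", "ref_copies",
                     "sample", "allele_copies"]


def read_str_table(path, caller_tag: Caller | str = Caller.STR_CALLER,
                   with_stats: bool = False):
    """Read an STR genotyper locus table into normalised calls.

    Expected TSV columns: ``chrom, start, end, motif, ref_copies, sample,
    allele_copies`` with ``allele_copies`` a comma-separated list of copy
    numbers (fractional allowed), one per called allele. Coordinates are
    0-based half-open (BED-like). One call is produced per row; several rows
    at one locus with different motif decompositions stay separate records.

    Rows with a non-positive copy number are rejected with a warning.
    """
    caller = Caller(caller_tag)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(STR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"STR table missing columns: {sorted(missing)}")
    calls: list[VariantCall] = []
    n_skipped = 0
    for row in df.itertuples():
        try:
            motif = str(row.motif)
            ref_copies = float(row.ref_copies)
            copies = [float(c) for c in str(row.allele_copies).split(",")]
            if any(c <= 0 for c in copies) or ref_copies <= 0:
                raise ValueError("copy_number <= 0")
            ref_len = int(round(len(motif) * ref_copies))
            alts = tuple(
                AltAllele(length=int(round(len(motif) * c)), motif=motif,
                          copy_number=c)
                for c in sorted({c for c in copies if c != ref_copies})
            )
            n_ref = sum(1 for c in copies if c == ref_copies)
            if not alts:
                genotype = Genotype.HOM_REF
            elif n_ref > 0:
                genotype = Genotype.HET
            elif len(set(copies)) == 1:
                genotype = Genotype.HOM_ALT
            else:
                genotype = Genotype.HET  # two different non-ref alleles
            calls.append(VariantCall(
                sample=str(row.sample), caller=caller, chrom=row.chrom,
                start=int(row.start), end=int(row.end), var_class=VarClass.STR,
                ref_len=ref_len, alt_alleles=alts, qual=None,
                genotype=genotype,
                source_record=f"{row.chrom}:{row.start}:{motif}",
            ))
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            log.warning("skipping STR table row %s: %s", row.Index, exc)
    if with_stats:
        return calls, n_skipped
    return calls


# ---------------------------------------------------------------------------
# Harmonised VCF output

_SYMBOLIC = {
    VarClass.INS: "<INS>", VarClass.DEL: "<DEL>", VarClass.STR: "<STR>",
    VarClass.TE: "<TE>", VarClass.COMPLEX: "<COMPLEX>",
}


def _record_key(c: VariantCall) -> tuple:
    return (c.caller.value, c.chrom, c.start, c.end, c.var_class.value,
            c.ref_seq or "", tuple(a.distinct_key() for a in c.alt_alleles))


def write_harmonised_vcf(calls: Sequence[VariantCall], path) -> None:
    """Serialise normalised calls back to a multi-sample VCF.

    Calls are grouped by (caller, locus, class, allele set); each group
    becomes one record with per-sample GT and CQ (caller-native quality)
    FORMAT fields, and INFO keys for class, caller provenance and STR
    motif/copy numbers. Two calls from the same group and sample that
    disagree raise with the conflict listed.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=VARCLASS,Number=1,Type=String,Description="Variant class">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">')
    header.add_line('##INFO=<ID=ALTLEN,Number=.,Type=Integer,Description="Alt allele length (bp)">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">')
    header.add_line('##INFO=<ID=MOTIF,Number=.,Type=String,Description="STR motif per alt">')
    header.add_line('##INFO=<ID=CN,Number=.,Type=Float,Description="STR copy number per alt">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=CQ,Number=1,Type=Float,Description="Caller-native quality">')
    # PR distinguishes "caller reported this sample with unresolved GT" (PR=1,
    # GT=./.) from "sample absent from this record group" (PR missing).
    header.add_line('##FORMAT=<ID=PR,Number=1,Type=Integer,Description="Call present for sample">')

    samples = sorted({c.sample for c in calls})
    for s in samples:
        header.add_sample(s)
    chrom_max: dict[str, int] = {}
    for c in calls:
        chrom_max[c.chrom] = max(chrom_max.get(c.chrom, 0), c.end + 1_000_000)
    for chrom in sorted(chrom_max):
        header.contigs.add(chrom, length=chrom_max[chrom])

    groups: dict[tuple, dict[str, VariantCall]] = {}
    for c in calls:
        key = _record_key(c)
        prev = groups.setdefault(key, {}).get(c.sample)
        if prev is not None and prev != c:
            raise ValueError(
                f"conflicting records at identical key {key}: {prev} vs {c}"
            )
        groups[key][c.sample] = c

    gt_map = {Genotype.HOM_REF: (0, 0), Genotype.HET: (0, 1),
              Genotype.HOM_ALT: (1, 1), Genotype.UNRESOLVED: (None, None)}

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(groups, key=lambda k: (k[1], k[2], k[3], k[0])):
            per_sample = groups[key]
            any_call = next(iter(per_sample.values()))
            rec = out.new_record()
            rec.chrom = any_call.chrom
            vc = any_call.var_class
            if vc is VarClass.SNV:
                rec.start = any_call.start
                rec.ref = any_call.ref_seq or "N"
                rec.alts = tuple(a.seq or "N" for a in any_call.alt_alleles)
                rec.stop = any_call.end
            else:
                # anchored convention: POS is the base before the event
                rec.start = max(0, any_call.start - 1)
                rec.ref = "N"
                rec.alts = tuple(_SYMBOLIC[vc] for _ in any_call.alt_alleles) or None
                rec.stop = any_call.end
            rec.info["VARCLASS"] = vc.value
            rec.info["CALLER"] = any_call.caller.value
            if any_call.alt_alleles:
                rec.info["ALTLEN"] = tuple(a.length for a in any_call.alt_alleles)
                if vc is VarClass.STR and all(a.motif for a in any_call.alt_alleles):
                    rec.info["MOTIF"] = tuple(a.motif for a in any_call.alt_alleles)
                    rec.info["CN"] = tuple(float(a.copy_number or 0)
                                           for a in any_call.alt_alleles)
            quals = [c.qual for c in per_sample.values() if c.qual is not None]
            rec.qual = max(quals) if quals else None
            for s in samples:
                call = per_sample.get(s)
                if call is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    gt = gt_map[call.genotype]
                    if call.genotype is Genotype.HET and len(call.alt_alleles) > 1:
                        gt = (1, 2)
                    rec.samples[s]["GT"] = gt
                    rec.samples[s]["PR"] = 1
                    if call.qual is not None:
                        rec.samples[s]["CQ"] = call.qual
            out.write(rec)


def read_harmonised_vcf(path) -> list[VariantCall]:
    """Read back a VCF written by :func:`write_harmonised_vcf`."""
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            vc = VarClass(rec.info["VARCLASS"])
            caller = Caller(rec.info["CALLER"])
            svlens = rec.info.get("ALTLEN", ())
            motifs = rec.info.get("MOTIF", ())
            cns = rec.info.get("CN", ())
            alts = []
            for i, alt in enumerate(rec.alts or ()):
                length = int(svlens[i]) if i < len(svlens) else len(alt)
                motif = motifs[i] if i < len(motifs) else None
                cn = float(cns[i]) if i < len(cns) else None
                seq = alt if not alt.startswith("<") and vc is VarClass.SNV else None
                alts.append(AltAllele(length=length, seq=seq, motif=motif,
                                      copy_number=cn))
            if vc is VarClass.SNV:
                start = rec.start
            else:
                start = rec.start + 1
            end = start + 1 if vc in (VarClass.SNV, VarClass.INS) else rec.stop
            for s in samples:
                if rec.samples[s].get("PR") != 1:
                    continue  # sample absent from this record group
                gt = rec.samples[s].get("GT")
                genotype = _genotype_from_gt(gt)
                cq = rec.samples[s].get("CQ")
                calls.append(VariantCall(
                    sample=s, caller=caller, chrom=rec.chrom, start=start,
                    end=end, var_class=vc,
                    ref_len=len(rec.ref or ""),
                    ref_seq=rec.ref if vc is VarClass.SNV else None,
                    alt_alleles=tuple(alts), qual=float(cq) if cq is not None else None,
                    genotype=genotype, source_record=rec.id or "",
                ))
    return calls
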
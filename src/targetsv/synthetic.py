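"""Hermetic synthetic cohorts with planted truth for every pipeline stage.

The study's raw reads are access-restricted, so all fixtures are simulated:
target regions on small synthetic chromosomes, a truth variant set with
per-sample genotypes, per-caller observed call files in each caller's native
dialect, read summaries with planted on/off-target coverage, functional
annotation tracks, impact tables and phased haplotypes with planted LD
cassettes. Everything is deterministic given the seed.

Study conditions mirrored by the defaults: 10 samples, 8 target regions of
200 kb, 120 truth variants (60 SNVs and 60 non-SNVs — roughly the cohort's
SNV/non-SNV mix) of which 20 are "interesting", i.e. satisfy every
prioritisation criterion: non-SNV, inside a target region, longer than
10 bp if an indel, HIGH predicted impact with no rsID, and inside the LD
cassette around the region's lead SNP. Every non-interesting variant is
planted with a specific failure mode so the cascade's audit trail can be
checked exclusion by exclusion.

Caller emulation: two SV callers and a small-variant caller write VCFs
(symbolic-allele and sequence-explicit dialects); the STR genotyper writes
locus TSVs without quality scores. STR length changes surface in the VCF
callers as plain insertions/deletions, and the composite transposable
element is reported by the VCF callers as insertions inside its VNTR — the
discordance the harmoniser has to undo. Caller noise (per-class
sensitivity, breakpoint jitter, genotype discordance, quality spread) is
configurable per caller; ``CallerProfile.noise_free`` gives the exact-recall
limit in which the pipeline must recover truth perfectly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .callset import (
    AltAllele,
    Caller,
    Genotype,
    VarClass,
    VariantCall,
)
from .enrichment import ReadSummary, error_from_phred
from .harmonize import BAMEvidence
from .ld import HaplotypeMatrix
from .prioritize import Impact, ImpactAnnotation
from .regions import GenomicRegion, LeadSNP, build_target_region

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Specs


@dataclass
class VariantSpec:
    """Composition of the planted truth set."""

    n_snv: int = 60
    n_ins: int = 15
    n_del: int = 15
    n_str: int = 25
    n_te: int = 5
    n_interesting: int = 20
    indel_len_range: tuple[int, int] = (15, 60)
    short_indel_len_range: tuple[int, int] = (3, 10)
    carrier_rate: float = 0.8

    @property
    def n_total(self) -> int:
        return self.n_snv + self.n_ins + self.n_del + self.n_str + self.n_te

    @property
    def n_non_snv(self) -> int:
        return self.n_total - self.n_snv

    @staticmethod
    def small() -> "VariantSpec":
        """Scaled-down composition for quick multi-seed property runs."""
        return VariantSpec(n_snv=20, n_ins=5, n_del=5, n_str=8, n_te=2,
                           n_interesting=8)


@dataclass
class ReadSimSpec:
    """Planted read-summary conditions (per sample)."""

    on_coverage: float = 15.0
    off_coverage: float = 3.0
    on_mean_len: int = 5_000
    off_mean_len: int = 1_500
    mean_qual: float = 22.0
    qual_sd: float = 1.5
    min_len: int = 600
    frac_subthreshold: float = 0.1  # extra reads failing the Q9/500 bp filter


@dataclass
class CallerProfile:
    """Noise model for one emulated caller."""

    caller: Caller
    dialect: str  # "sv" | "smallvar" | "str"
    sensitivity: dict[VarClass, float]
    jitter_sd: float = 0.0
    genotype_discordance: float = 0.0
    unresolved_prob: float = 0.0
    qual_logmean: float = 2.9   # ln-scale; ~10% of draws fall below Q9
    qual_logsd: float = 0.55
    emits_qual: bool = True

    @staticmethod
    def defaults() -> list["CallerProfile"]:
        S = VarClass
        return [
            CallerProfile(Caller.SV_CALLER_A, "sv",
                          {S.INS: 0.9, S.DEL: 0.9, S.STR: 0.85, S.TE: 0.9},
                          jitter_sd=20, genotype_discordance=0.10,
                          unresolved_prob=0.05),
            CallerProfile(Caller.SV_CALLER_B, "sv",
                          {S.INS: 0.7, S.DEL: 0.75, S.STR: 0.5, S.TE: 0.6},
                          jitter_sd=35, genotype_discordance=0.15,
                          unresolved_prob=0.05),
            CallerProfile(Caller.SMALLVAR_CALLER, "smallvar",
                          {S.SNV: 0.98, S.INS: 0.6, S.DEL: 0.6, S.STR: 0.6,
                           S.TE: 0.5},
                          jitter_sd=5, genotype_discordance=0.10),
            CallerProfile(Caller.STR_CALLER, "str",
                          {S.STR: 0.9},
                          jitter_sd=0, genotype_discordance=0.10,
                          emits_qual=False),
        ]

    @staticmethod
    def noise_free() -> list["CallerProfile"]:
        """Sensitivity 1, no jitter, no discordance, fixed high quality."""
        profs = CallerProfile.defaults()
        for p in profs:
            p.sensitivity = {k: 1.0 for k in p.sensitivity}
            p.jitter_sd = 0.0
            p.genotype_discordance = 0.0
            p.unresolved_prob = 0.0
        return profs


@dataclass
class TruthVariant:
    """One planted variant with its cohort-wide allele spectrum and genotypes.

    ``interesting`` variants satisfy every cascade criterion; every other
    variant carries the single ``fail_reason`` it was planted to trip.
    """

    uid: str
    region_name: str
    chrom: str
    start: int
    end: int
    var_class: VarClass
    alt_spectrum: tuple[AltAllele, ...]
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    sample_alts: dict[str, tuple[int, ...]] = field(default_factory=dict)
    motif: Optional[str] = None
    ref_copies: Optional[float] = None
    te_structure: Optional[dict] = None
    impact: Impact = Impact.MODIFIER
    rsid: Optional[str] = None
    in_region: bool = True
    in_ld_block: bool = False
    interesting: bool = False
    fail_reason: Optional[str] = None
    low_qual: bool = False

    def carriers(self) -> list[str]:
        return sorted(s for s, g in self.genotypes.items()
                      if g in (Genotype.HET, Genotype.HOM_ALT))


@dataclass
class CohortBundle:
    """Everything one synthetic run produces, in memory."""

    seed: int
    lead_snps: list[LeadSNP]
    regions: list[GenomicRegion]
    chrom_len: int
    genome_size: float
    samples: list[str]
    truth_variants: list[TruthVariant]
    calls: list[VariantCall]
    bam_evidence: list[BAMEvidence]
    impacts: list[ImpactAnnotation]
    features: list  # AnnotationFeature, late import avoided
    annotation_class_counts: dict[str, int]
    haplotypes: dict[str, HaplotypeMatrix]
    anchors: dict[str, int]
    ld_cassettes: dict[str, GenomicRegion]
    reads: list[ReadSummary]
    removed_read_ids: set[str]
    read_spec: ReadSimSpec
    variant_spec: VariantSpec

    def interesting_truth(self) -> list[TruthVariant]:
        return [t for t in self.truth_variants if t.interesting]


# ---------------------------------------------------------------------------
# Planting primitives


def plant_str_locus(motif: str, ref_copies: float, allele_copy_set,
                    position: int, chrom: str = "chr1",
                    region_name: str = "", uid: str = "str") -> TruthVariant:
    """Plant an STR locus truth variant.

    ``allele_copy_set`` lists cohort allele copy numbers; copies equal to
    ``ref_copies`` describe the reference allele, the others become the
    alternative spectrum (contractions and/or expansions).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if ref_copies <= 0 or any(c <= 0 for c in allele_copy_set):
        raise ValueError("copy numbers must be > 0")
    ref_len = int(round(len(motif) * ref_copies))
    spectrum = tuple(
        AltAllele(length=int(round(len(motif) * c)), motif=motif, copy_number=c)
        for c in sorted(set(allele_copy_set)) if c != ref_copies
    )
    return TruthVariant(
        uid=uid, region_name=region_name, chrom=chrom,
        start=position, end=position + ref_len, var_class=VarClass.STR,
        alt_spectrum=spectrum, motif=motif, ref_copies=float(ref_copies))


def plant_composite_te(position: int, head_motif: str = "CCCTCT",
                       body_len: int = 300, tail_motif: str = "A",
                       vntr_allele_lens=(38, 46, 47), chrom: str = "chr1",
                       head_copies: int = 5, vntr_len: int = 800,
                       sine_len: int = 400, tail_copies: int = 20,
                       region_name: str = "", uid: str = "te") -> TruthVariant:
    """Plant a composite retrotransposon (SVA-like) truth variant.

    Structure: STR head, Alu-like body, VNTR, SINE-R, STR tail. Cohort
    variation is insertions of the given lengths inside the VNTR — which is
    exactly how the VCF callers will observe it (no caller sees the element
    as one unit).
    """
    if body_len <= 0 or vntr_len <= 0 or sine_len <= 0:
        raise ValueError("element part lengths must be positive")
    head_len = len(head_motif) * head_copies
    tail_len = len(tail_motif) * tail_copies
    total = head_len + body_len + vntr_len + sine_len + tail_len
    vntr_offset = head_len + body_len
    spectrum = tuple(AltAllele(length=int(l))
                     for l in sorted(set(vntr_allele_lens)) if l > 0)
    return TruthVariant(
        uid=uid, region_name=region_name, chrom=chrom,
        start=position, end=position + total, var_class=VarClass.TE,
        alt_spectrum=spectrum,
        te_structure={
            "head_motif": head_motif, "head_len": head_len,
            "body_len": body_len, "vntr_offset": vntr_offset,
            "vntr_len": vntr_len, "sine_len": sine_len,
            "tail_motif": tail_motif, "tail_len": tail_len,
        })


# ---------------------------------------------------------------------------
# Haplotypes with planted LD cassettes


def simulate_haplotypes(rng: np.random.Generator, chrom: str, anchor_pos: int,
                        cassettes: Sequence[tuple[int, int]],
                        region: GenomicRegion, n_haplotypes: int = 20,
                        site_spacing: int = 5_000,
                        background_spacing: int = 10_000,
                        background_r2_max: float = 0.5) -> HaplotypeMatrix:
    """Phased haplotypes with perfect-LD cassettes around the anchor.

    Sites inside a cassette copy the anchor's allele column (r² = 1); all
    other sites are resampled until their r² with the anchor falls below
    ``background_r2_max``, so a threshold anywhere in between recovers the
    cassette boundaries exactly.
    """
    # Keep the anchor reasonably balanced (as balanced as n allows) so
    # background sites can fall below the r2 ceiling.
    lo = max(1, n_haplotypes // 4)
    anchor = rng.integers(0, 2, size=n_haplotypes).astype(np.int8)
    while not (lo <= anchor.sum() <= n_haplotypes - lo):
        anchor = rng.integers(0, 2, size=n_haplotypes).astype(np.int8)

    positions: list[int] = [anchor_pos]
    for c_start, c_end in cassettes:
        positions.extend(range(c_start, c_end + 1, site_spacing))
    positions.extend(range(region.start + background_spacing // 2,
                           region.end, background_spacing))
    positions = sorted(set(positions))

    def in_cassette(p: int) -> bool:
        return p == anchor_pos or any(s <= p <= e for s, e in cassettes)

    cols = []
    anchor_f = anchor.astype(float)
    denom_a = anchor_f.var()
    for p in positions:
        if in_cassette(p):
            cols.append(anchor.copy())
            continue
        while True:
            col = rng.integers(0, 2, size=n_haplotypes).astype(np.int8)
            if col.min() == col.max():
                continue
            c = col.astype(float)
            r2 = np.corrcoef(anchor_f, c)[0, 1] ** 2
            if r2 < background_r2_max:
                cols.append(col)
                break
    return HaplotypeMatrix(
        chrom=chrom, positions=np.array(positions),
        alleles=np.column_stack(cols),
        haplotype_ids=[f"hap{i}" for i in range(n_haplotypes)])


# ---------------------------------------------------------------------------
# Read summaries


def simulate_read_summaries(rng: np.random.Generator, sample: str,
                            regions: Sequence[GenomicRegion], chrom_len: int,
                            spec: ReadSimSpec) -> tuple[list[ReadSummary], set[str]]:
    """Per-read summaries with planted on/off-target coverage for one sample.

    On-target reads are drawn fully inside the target regions with total
    bases ≈ on_coverage × target span; off-target reads fall in the
    complement of each region's chromosome. An extra ``frac_subthreshold``
    of reads fails the Q9/500 bp filter; their ids are returned so filter
    tests know the planted removal set exactly.
    """
    reads: list[ReadSummary] = []
    counter = 0

    def q_to_err(qs: np.ndarray) -> np.ndarray:
        return 10.0 ** (-np.clip(qs, 1.0, 40.0) / 10.0)

    def emit(chrom, starts, lens, quals, tag):
        nonlocal counter
        errs = q_to_err(quals)
        for s, l, e in zip(starts, lens, errs):
            reads.append(ReadSummary(
                read_id=f"{sample}_{tag}_{counter}", sample=sample,
                chrom=chrom, mapped_start=int(s), mapped_end=int(s + l),
                read_len=int(l), mean_err=float(e)))
            counter += 1

    def draw_lens(mean_len: int, max_len: int, target_bases: float) -> np.ndarray:
        """Lengths whose total is ~target_bases despite the min-length clip."""
        n_guess = max(1, int(target_bases / mean_len * 1.5) + 8)
        lens = np.clip(rng.normal(mean_len, mean_len / 5, n_guess),
                       spec.min_len, max_len).astype(int)
        n = int(np.searchsorted(np.cumsum(lens), target_bases)) + 1
        return lens[:min(n, n_guess)]

    for r in regions:
        lens = draw_lens(spec.on_mean_len, r.width, spec.on_coverage * r.width)
        starts = np.array([rng.integers(r.start, r.end - l + 1) for l in lens])
        quals = rng.normal(spec.mean_qual, spec.qual_sd, lens.size)
        emit(r.chrom, starts, lens, quals, "on")

        # Off-target: the complement of the region on its chromosome.
        segs = [(0, r.start), (r.end, chrom_len)]
        seg_lens = np.array([e - s for s, e in segs], dtype=float)
        off_span = seg_lens.sum()
        lens = draw_lens(spec.off_mean_len, int(seg_lens.max()),
                         spec.off_coverage * off_span)
        seg_idx = rng.choice(len(segs), size=lens.size, p=seg_lens / off_span)
        starts = np.empty(lens.size, dtype=int)
        for i, (si, l) in enumerate(zip(seg_idx, lens)):
            s0, e0 = segs[si]
            starts[i] = rng.integers(s0, max(s0 + 1, e0 - l))
            if starts[i] + l > e0:  # clip reads to stay inside the segment
                lens[i] = max(1, e0 - starts[i])
        quals = rng.normal(spec.mean_qual, spec.qual_sd, lens.size)
        emit(r.chrom, starts, lens, quals, "off")

    removed: set[str] = set()
    n_bad = int(round(len(reads) * spec.frac_subthreshold))
    for k in range(n_bad):
        r = regions[int(rng.integers(len(regions)))]
        if rng.random() < 0.5:  # too short
            l = int(rng.integers(80, 500))
            q = float(rng.uniform(10, 25))
        else:                   # too low quality
            l = int(rng.integers(600, 3000))
            q = float(rng.uniform(2, 8.9))
        s = int(rng.integers(0, chrom_len - l))
        read = ReadSummary(
            read_id=f"{sample}_bad_{k}", sample=sample, chrom=r.chrom,
            mapped_start=s, mapped_end=s + l, read_len=l,
            mean_err=float(error_from_phred(q)))
        reads.append(read)
        removed.add(read.read_id)
    return reads, removed


# ---------------------------------------------------------------------------
# Caller emission


def _flip_genotype(g: Genotype) -> Genotype:
    return Genotype.HOM_ALT if g is Genotype.HET else Genotype.HET


def _smallvar_seqs(var_class: VarClass, length: int, alt_base: str = "A",
                   ) -> tuple[str, str]:
    """Deterministic sequence-explicit REF/ALT for a given class+length."""
    if var_class is VarClass.SNV:
        return "A", alt_base
    if var_class is VarClass.INS:
        return "N", "N" + "A" * length
    return "N" + "A" * length, "N"  # DEL


def observe_variant(truth: TruthVariant, sample: str, profile: CallerProfile,
                    rng: np.random.Generator) -> Optional[VariantCall]:
    """One caller's (possibly noisy) observation of a truth variant.

    Returns None when the sample is not a carrier or the caller misses the
    variant. Class translation: STR length changes become INS/DEL in the
    VCF dialects; the composite TE becomes an insertion inside its VNTR;
    only the STR dialect reports motif copy numbers.
    """
    gt = truth.genotypes.get(sample, Genotype.HOM_REF)
    if gt not in (Genotype.HET, Genotype.HOM_ALT):
        return None
    sens = profile.sensitivity.get(truth.var_class, 0.0)
    if rng.random() > sens:
        return None

    alt_idx = truth.sample_alts[sample][0]
    alt = truth.alt_spectrum[alt_idx]

    if rng.random() < profile.genotype_discordance:
        gt = _flip_genotype(gt)
    if rng.random() < profile.unresolved_prob:
        gt = Genotype.UNRESOLVED

    if truth.low_qual:
        qual: Optional[float] = float(rng.uniform(1.0, 8.5))
    elif truth.interesting:
        qual = 9.0 + float(rng.lognormal(1.5, 0.5))
    else:
        qual = float(rng.lognormal(profile.qual_logmean, profile.qual_logsd))
    if not profile.emits_qual:
        qual = None

    def jitter(max_abs: int) -> int:
        if profile.jitter_sd <= 0 or max_abs <= 0:
            return 0
        j = int(round(rng.normal(0, profile.jitter_sd)))
        return int(np.clip(j, -max_abs, max_abs))

    vc = truth.var_class
    if profile.dialect == "str":
        if vc is not VarClass.STR:
            return None
        copies = [alt.copy_number]
        if gt is Genotype.HET:
            copies = [truth.ref_copies, alt.copy_number]
        elif gt is Genotype.UNRESOLVED:
            gt = Genotype.HET  # locus tables cannot express missing genotypes
            copies = [truth.ref_copies, alt.copy_number]
        return VariantCall(
            sample=sample, caller=profile.caller, chrom=truth.chrom,
            start=truth.start, end=truth.end, var_class=VarClass.STR,
            ref_len=truth.end - truth.start,
            alt_alleles=(alt,) if gt is not Genotype.HOM_REF else (),
            qual=None, genotype=gt,
            source_record=f"{truth.chrom}:{truth.start}:{truth.motif}")

    # VCF dialects: translate class.
    if vc is VarClass.SNV:
        ref, altseq = _smallvar_seqs(vc, 1, alt.seq or "C")
        return VariantCall(
            sample=sample, caller=profile.caller, chrom=truth.chrom,
            start=truth.start, end=truth.start + 1, var_class=VarClass.SNV,
            ref_len=1, ref_seq=ref,
            alt_alleles=(AltAllele(length=1, seq=altseq),),
            qual=qual, genotype=gt, source_record=truth.uid)

    if vc is VarClass.STR:
        ref_len = int(round(len(truth.motif) * truth.ref_copies))
        delta = alt.length - ref_len
        if delta == 0:
            return None
        obs_class = VarClass.INS if delta > 0 else VarClass.DEL
        length = abs(delta)
        # Callers left-align repeat length changes to the repeat start.
        pos = truth.start
    elif vc is VarClass.TE:
        obs_class = VarClass.INS
        length = alt.length
        v0 = truth.start + truth.te_structure["vntr_offset"]
        v1 = v0 + truth.te_structure["vntr_len"]
        pos = int(np.clip(v0 + jitter(min(200, truth.te_structure["vntr_len"] - 1)),
                          v0, v1 - 1))
    elif vc in (VarClass.INS, VarClass.DEL):
        obs_class = vc
        length = alt.length
        max_shift = 200 if vc is VarClass.INS else max(1, min(200, length // 5))
        pos = max(1, truth.start + jitter(max_shift))
    else:
        return None

    if profile.dialect == "smallvar":
        ref, altseq = _smallvar_seqs(obs_class, length)
        end = pos + length if obs_class is VarClass.DEL else pos + 1
        return VariantCall(
            sample=sample, caller=profile.caller, chrom=truth.chrom,
            start=pos, end=end, var_class=obs_class, ref_len=len(ref),
            ref_seq=ref, alt_alleles=(AltAllele(length=length, seq=altseq),),
            qual=qual, genotype=gt, source_record=truth.uid)

    # symbolic SV dialect
    end = pos + length if obs_class is VarClass.DEL else pos + 1
    return VariantCall(
        sample=sample, caller=profile.caller, chrom=truth.chrom,
        start=pos, end=end, var_class=obs_class, ref_len=1, ref_seq="N",
        alt_alleles=(AltAllele(length=length),),
        qual=qual, genotype=gt, source_record=truth.uid)


# ---------------------------------------------------------------------------
# Cohort generation

#: Planted fractions of interesting-locus windows containing each feature
#: class (distal enhancers and TFBS most common, proximal enhancers rare).
ANNOTATION_CLASS_FRACTIONS = {
    "enhancer_distal": 0.60,
    "TFBS": 0.80,
    "CTCF": 0.45,
    "GWAS_hit": 0.45,
    "eQTL": 0.25,
    "TSS": 0.10,
    "promoter": 0.05,
    "miRNA_site": 0.05,
    "enhancer_proximal": 0.05,
}

_IMPACT_PAD = 500          # impact rows padded so jittered loci still overlap
_CASSETTE_HALF = 30_000    # planted LD cassette half-width around the anchor
_GRID = 4_000              # spacing of non-interesting variant slots
_INTERESTING_GRID = 10_000 # spacing of interesting slots inside the cassette

_FAIL_MODES = ("outside_region", "low_qual", "short_indel",
               "impact", "rsid", "no_ld")


class InfeasibleSpec(ValueError):
    pass


def _assign_genotypes(rng, truth: TruthVariant, samples, carrier_rate):
    carriers = [s for s in samples if rng.random() < carrier_rate]
    if not carriers:
        carriers = [samples[int(rng.integers(len(samples)))]]
    spectrum = truth.alt_spectrum
    if len(spectrum) > len(carriers):
        truth.alt_spectrum = spectrum = spectrum[:len(carriers)]
    for s in samples:
        if s not in carriers or not spectrum:
            truth.genotypes[s] = Genotype.HOM_REF
            continue
        idx = carriers.index(s) % len(spectrum)
        truth.genotypes[s] = (Genotype.HOM_ALT
                              if rng.random() < 0.25 else Genotype.HET)
        truth.sample_alts[s] = (idx,)


def _str_spectrum(rng, motif_len: int, ref_copies: float) -> list[float]:
    """Same-sign copy-number spectrum with bp deltas >= 4 within factor 2."""
    sign = 1 if rng.random() < 0.5 else -1
    base_delta = max(4, int(rng.integers(4, 13)))  # bp
    n_alleles = int(rng.integers(1, 4))
    deltas_bp = sorted({min(2 * base_delta, base_delta + k * max(1, motif_len))
                        for k in range(n_alleles)})
    out = []
    for d in deltas_bp:
        units = max(1, int(round(d / motif_len)))
        cn = ref_copies + sign * units
        if cn > 0:
            out.append(float(cn))
    return out or [float(ref_copies + sign)]


def generate_cohort(seed: int,
                    n_samples: int = 10,
                    n_regions: int = 8,
                    region_width: int = 200_000,
                    chrom_len: int = 1_000_000,
                    variant_spec: Optional[VariantSpec] = None,
                    caller_profiles: Optional[list[CallerProfile]] = None,
                    read_spec: Optional[ReadSimSpec] = None,
                    simulate_reads: bool = True) -> CohortBundle:
    """Generate a full synthetic cohort with planted truth.

    Deterministic given ``seed``. Raises :class:`InfeasibleSpec` when the
    requested variant counts do not fit the region layout (e.g. more
    interesting variants than cassette slots).
    """
    rng = np.random.default_rng(seed)
    spec = variant_spec or VariantSpec()
    profiles = caller_profiles or CallerProfile.defaults()
    rspec = read_spec or ReadSimSpec()
    samples = [f"S{i}" for i in range(1, n_samples + 1)]
    flank = region_width // 2

    if chrom_len < region_width + 40_000:
        raise InfeasibleSpec("chromosomes too short for the region width")
    if spec.n_interesting > spec.n_non_snv:
        raise InfeasibleSpec("more interesting variants than non-SNV truth")

    # --- regions, one per synthetic chromosome -----------------------------
    lead_snps, regions = [], []
    for i in range(n_regions):
        chrom = f"chr{i + 1}"
        pos = chrom_len // 2
        snp = LeadSNP(f"rs_synth_{i + 1}", chrom, pos, f"region_{i + 1}")
        lead_snps.append(snp)
        regions.append(build_target_region(snp, flank))

    # --- position slots -----------------------------------------------------
    cassette_half = min(_CASSETTE_HALF, flank - 20_000)
    interesting_slots: list[tuple[GenomicRegion, int, int]] = []  # (region, pos, anchor)
    other_slots: list[tuple[GenomicRegion, int, bool]] = []       # (region, pos, in_region)
    outside_slots: list[tuple[GenomicRegion, int]] = []
    cassettes: dict[str, GenomicRegion] = {}
    anchors: dict[str, int] = {}
    for snp, r in zip(lead_snps, regions):
        center = snp.pos
        anchors[r.name] = center
        cassettes[r.name] = GenomicRegion(
            r.chrom, center - cassette_half, center + cassette_half + 1,
            name=f"{r.name}_cassette")
        for p in range(center - cassette_half + 2_000,
                       center + cassette_half - 2_000, _INTERESTING_GRID):
            interesting_slots.append((r, p, center))
        lo_zone = range(r.start + 4_000, center - cassette_half - 6_000, _GRID)
        hi_zone = range(center + cassette_half + 6_000, r.end - 4_000, _GRID)
        for p in list(lo_zone) + list(hi_zone):
            other_slots.append((r, p, True))
        for p in range(r.end + 10_000, chrom_len - 6_000, _GRID):
            outside_slots.append((r, p))

    if spec.n_interesting > len(interesting_slots):
        raise InfeasibleSpec(
            f"{spec.n_interesting} interesting variants exceed "
            f"{len(interesting_slots)} cassette slots")

    # Deterministic slot orders interleaving regions.
    def interleave(slots):
        by_region: dict[str, list] = {}
        for s in slots:
            by_region.setdefault(s[0].name, []).append(s)
        out, i = [], 0
        while any(by_region.values()):
            for name in sorted(by_region):
                if by_region[name]:
                    out.append(by_region[name].pop(0))
            i += 1
        return out

    interesting_slots = interleave(interesting_slots)
    other_slots = interleave(other_slots)
    outside_slots = interleave(outside_slots)

    # --- truth variants -----------------------------------------------------
    class_pool = ([VarClass.STR] * spec.n_str + [VarClass.TE] * spec.n_te
                  + [VarClass.INS] * spec.n_ins + [VarClass.DEL] * spec.n_del)
    truth_variants: list[TruthVariant] = []
    uid_counter = 0

    def next_uid(prefix):
        nonlocal uid_counter
        uid_counter += 1
        return f"{prefix}_{uid_counter:04d}"

    def make_variant(vc: VarClass, chrom, pos, region_name, uid,
                     short: bool = False) -> TruthVariant:
        if vc is VarClass.STR:
            motif = "".join(rng.choice(list(_BASES))
                            for _ in range(int(rng.integers(1, 6))))
            ref_copies = float(int(rng.integers(8, 41)))
            copies = _str_spectrum(rng, len(motif), ref_copies)
            return plant_str_locus(motif, ref_copies, copies + [ref_copies],
                                   pos, chrom=chrom, region_name=region_name,
                                   uid=uid)
        if vc is VarClass.TE:
            return plant_composite_te(pos, chrom=chrom, region_name=region_name,
                                      uid=uid,
                                      vntr_allele_lens=tuple(sorted(
                                          rng.choice(range(30, 70), size=3,
                                                     replace=False).tolist())))
        lo, hi = (spec.short_indel_len_range if short else spec.indel_len_range)
        length = int(rng.integers(lo, hi + 1))
        if vc is VarClass.INS:
            n_alts = int(rng.integers(1, 4))
            lens = sorted({length + 2 * k for k in range(n_alts)})
            spectrum = tuple(AltAllele(length=l) for l in lens)
            end = pos + 1
        else:
            spectrum = (AltAllele(length=length),)
            end = pos + length
        return TruthVariant(uid=uid, region_name=region_name, chrom=chrom,
                            start=pos, end=end, var_class=vc,
                            alt_spectrum=spectrum)

    # interesting variants first: non-SNV classes cycled, inside cassettes
    rng.shuffle(class_pool)
    interesting_classes = class_pool[:spec.n_interesting]
    rest_classes = class_pool[spec.n_interesting:]
    for k, vc in enumerate(interesting_classes):
        region, pos, _ = interesting_slots[k]
        t = make_variant(vc, region.chrom, pos, region.name,
                         next_uid("interesting"))
        t.interesting = True
        t.in_ld_block = True
        t.impact = Impact.HIGH
        t.rsid = None
        truth_variants.append(t)

    # non-interesting non-SNVs, each with one planted failure mode
    oi, si = 0, 0  # other/outside slot cursors
    for k, vc in enumerate(rest_classes):
        mode = _FAIL_MODES[k % len(_FAIL_MODES)]
        if mode == "low_qual" and vc in (VarClass.STR, VarClass.TE):
            mode = "impact"   # STR-table calls are quality-exempt
        if mode == "short_indel" and vc not in (VarClass.INS, VarClass.DEL):
            mode = "rsid"
        if mode == "outside_region":
            region, pos = outside_slots[si]; si += 1
            in_region = False
        else:
            region, pos, in_region = other_slots[oi]; oi += 1
        t = make_variant(vc, region.chrom, pos, region.name,
                         next_uid("plain"), short=(mode == "short_indel"))
        t.fail_reason = mode
        t.in_region = in_region
        t.impact = Impact.HIGH
        if mode == "impact":
            t.impact = Impact.MODERATE if rng.random() < 0.7 else Impact.LOW
        if mode == "rsid":
            t.rsid = f"rs{int(rng.integers(10**6, 10**8))}"
        if mode == "low_qual":
            t.low_qual = True
        truth_variants.append(t)

    # SNVs (fail the class stage by definition)
    for k in range(spec.n_snv):
        region, pos, _ = other_slots[oi]; oi += 1
        base_ref, base_alt = rng.choice(list(_BASES), size=2, replace=False)
        t = TruthVariant(uid=next_uid("snv"), region_name=region.name,
                         chrom=region.chrom, start=pos, end=pos + 1,
                         var_class=VarClass.SNV,
                         alt_spectrum=(AltAllele(length=1, seq=str(base_alt)),),
                         impact=Impact.MODIFIER, fail_reason="snv")
        truth_variants.append(t)

    for t in truth_variants:
        _assign_genotypes(rng, t, samples, spec.carrier_rate)

    # --- caller observations ------------------------------------------------
    calls: list[VariantCall] = []
    seen: dict[tuple[str, str], list[VariantCall]] = {}
    for t in truth_variants:
        for s in samples:
            for prof in profiles:
                c = observe_variant(t, s, prof, rng)
                if c is not None:
                    calls.append(c)
                    seen.setdefault((t.uid, s), []).append(c)

    # union-coverage guarantee: every carrier of an interesting variant is
    # called by at least one caller (the presence rule is union-based)
    forced_profiles = {p.caller: p for p in profiles}
    for t in truth_variants:
        if not t.interesting:
            continue
        for s in t.carriers():
            if (t.uid, s) in seen:
                continue
            fallback = (forced_profiles.get(Caller.STR_CALLER)
                        if t.var_class is VarClass.STR else
                        forced_profiles.get(Caller.SV_CALLER_A))
            if fallback is None:
                fallback = profiles[0]
            forced = CallerProfile(fallback.caller, fallback.dialect,
                                   {t.var_class: 1.0}, jitter_sd=0.0)
            c = observe_variant(t, s, forced, rng)
            if c is not None:
                calls.append(c)
                seen[(t.uid, s)] = [c]

    # --- BAM evidence: manual inspection confirms interesting carriers ------
    bam_evidence = [
        BAMEvidence(sample=s, chrom=t.chrom, start=t.start,
                    end=max(t.end, t.start + 1),
                    differs_from_reference=True, note=t.uid)
        for t in truth_variants if t.interesting for s in t.carriers()
    ]

    # --- impact annotations ---------------------------------------------------
    impacts = [
        ImpactAnnotation(chrom=t.chrom, start=max(0, t.start - _IMPACT_PAD),
                         end=t.end + _IMPACT_PAD, impact=t.impact,
                         rsid=t.rsid,
                         consequence="intronic" if t.in_region else "intergenic")
        for t in truth_variants
    ]

    # --- annotation tracks around interesting loci --------------------------
    from .annotate import AnnotationFeature, FeatureClass

    interesting = [t for t in truth_variants if t.interesting]
    features: list = []
    class_counts: dict[str, int] = {}
    order = list(range(len(interesting)))
    for cls_name, frac in ANNOTATION_CLASS_FRACTIONS.items():
        n_with = int(round(frac * len(interesting)))
        class_counts[cls_name] = n_with
        rng.shuffle(order)
        for idx in order[:n_with]:
            t = interesting[idx]
            offset = int(rng.integers(-1_500, 1_501))
            f_start = max(0, t.end + offset) if offset >= 0 else max(0, t.start + offset - 200)
            f_end = f_start + int(rng.integers(50, 400))
            features.append(AnnotationFeature(
                chrom=t.chrom, start=f_start, end=f_end,
                feature_class=FeatureClass(cls_name),
                label=cls_name, track="synthetic"))

    # --- haplotypes with one planted cassette per region ---------------------
    haplotypes: dict[str, HaplotypeMatrix] = {}
    for snp, r in zip(lead_snps, regions):
        cas = cassettes[r.name]
        haplotypes[r.name] = simulate_haplotypes(
            rng, r.chrom, snp.pos, [(cas.start, cas.end - 1)], r,
            n_haplotypes=2 * n_samples)

    # --- reads ----------------------------------------------------------------
    reads: list[ReadSummary] = []
    removed: set[str] = set()
    if simulate_reads:
        for s in samples:
            rd, rm = simulate_read_summaries(rng, s, regions, chrom_len, rspec)
            reads.extend(rd)
            removed.update(rm)

    return CohortBundle(
        seed=seed, lead_snps=lead_snps, regions=regions, chrom_len=chrom_len,
        genome_size=float(chrom_len * n_regions), samples=samples,
        truth_variants=truth_variants, calls=calls, bam_evidence=bam_evidence,
        impacts=impacts, features=features,
        annotation_class_counts=class_counts, haplotypes=haplotypes,
        anchors=anchors, ld_cassettes=cassettes, reads=reads,
        removed_read_ids=removed, read_spec=rspec, variant_spec=spec)


# ---------------------------------------------------------------------------
# Bundle serialisation (caller-native file dialects)


def _write_caller_vcf(calls: Sequence[VariantCall], sample: str, path,
                      dialect: str, chrom_len: int) -> None:
    """Write one sample's calls in a caller-native VCF dialect.

    ``sv``: symbolic alleles with SVTYPE/SVLEN/END. ``smallvar``:
    sequence-explicit REF/ALT. Both parse back through
    :func:`targetsv.callset.read_sv_vcf` to the same normalised records.
    """
    import pysam

    # htslib warns about a transient POS/END state while SVLEN is assigned;
    # the finished records are consistent (checked by the round-trip tests).
    verbosity = pysam.set_verbosity(0)
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = sorted({c.chrom for c in calls}) or ["chr1"]
    for chrom in chroms:
        header.contigs.add(chrom, length=chrom_len)
    header.add_sample(sample)

    gt_map = {Genotype.HOM_REF: (0, 0), Genotype.HET: (0, 1),
              Genotype.HOM_ALT: (1, 1), Genotype.UNRESOLVED: (None, None)}
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end,
                                           c.var_class.value, c.source_record))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record()
            rec.chrom = c.chrom
            alt = c.alt_alleles[0] if c.alt_alleles else None
            # VCF anchors indels on the base before the event, so POS is
            # start-1 for everything except SNVs.
            if dialect == "sv" and c.var_class is not VarClass.SNV:
                rec.start = c.start - 1
                rec.ref = "N"
                rec.alts = (f"<{c.var_class.value}>",)
                rec.info["SVTYPE"] = c.var_class.value
                if alt is not None:
                    svlen = alt.length
                    if c.var_class is VarClass.DEL:
                        svlen = -svlen
                    # htslib derives END from POS and |SVLEN| for symbolic
                    # alleles, which matches the anchored convention.
                    rec.info["SVLEN"] = (svlen,)
            else:
                rec.start = c.start if c.var_class is VarClass.SNV else c.start - 1
                rec.ref = c.ref_seq or "N"
                rec.alts = tuple(a.seq or "N" for a in c.alt_alleles) or None
            rec.qual = c.qual
            rec.samples[sample]["GT"] = gt_map[c.genotype]
            out.write(rec)
    pysam.set_verbosity(verbosity)


def _str_table_rows(calls: Sequence[VariantCall]) -> list[dict]:
    rows = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.source_record)):
        alt = c.alt_alleles[0] if c.alt_alleles else None
        motif = alt.motif if alt else "N"
        ref_copies = round((c.end - c.start) / max(1, len(motif)), 4)
        if c.genotype is Genotype.HOM_REF or alt is None:
            copies = f"{ref_copies:g},{ref_copies:g}"
        elif c.genotype is Genotype.HET:
            copies = f"{ref_copies:g},{alt.copy_number:g}"
        else:
            copies = f"{alt.copy_number:g},{alt.copy_number:g}"
        rows.append({"chrom": c.chrom, "start": c.start, "end": c.end,
                     "motif": motif, "ref_copies": f"{ref_copies:g}",
                     "sample": c.sample, "allele_copies": copies})
    return rows


def _truth_to_json(t: TruthVariant) -> dict:
    return {
        "uid": t.uid, "region": t.region_name, "chrom": t.chrom,
        "start": t.start, "end": t.end, "var_class": t.var_class.value,
        "alt_spectrum": [
            {"length": a.length, "seq": a.seq, "motif": a.motif,
             "copy_number": a.copy_number} for a in t.alt_spectrum],
        "genotypes": {s: g.value for s, g in sorted(t.genotypes.items())},
        "sample_alts": {s: list(v) for s, v in sorted(t.sample_alts.items())},
        "motif": t.motif, "ref_copies": t.ref_copies,
        "te_structure": t.te_structure,
        "impact": t.impact.value, "rsid": t.rsid,
        "in_region": t.in_region, "in_ld_block": t.in_ld_block,
        "interesting": t.interesting, "fail_reason": t.fail_reason,
        "low_qual": t.low_qual,
    }


def write_bundle(bundle: CohortBundle, outdir) -> Path:
    """Write the bundle to disk in the formats the pipeline consumes.

    Layout::

        regions.bed  lead_snps.tsv  reads.tsv  bam_evidence.tsv
        impacts.tsv  annotations.bed  truth.json
        calls/<caller>/<sample>.{vcf,tsv}
        haplotypes/<region>.tsv  anchors.tsv
    """
    import pandas as pd

    from .enrichment import write_reads_tsv
    from .ld import write_haplotypes_tsv
    from .regions import write_regions_bed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_regions_bed(bundle.regions, out / "regions.bed")
    pd.DataFrame([{"rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
                   "name": s.region_name} for s in bundle.lead_snps]
                 ).to_csv(out / "lead_snps.tsv", sep="\t", index=False)
    if bundle.reads:
        write_reads_tsv(bundle.reads, out / "reads.tsv")
    pd.DataFrame([{"sample": e.sample, "chrom": e.chrom, "start": e.start,
                   "end": e.end, "differs": int(e.differs_from_reference),
                   "note": e.note} for e in bundle.bam_evidence]
                 ).to_csv(out / "bam_evidence.tsv", sep="\t", index=False)
    pd.DataFrame([{"chrom": a.chrom, "start": a.start, "end": a.end,
                   "impact": a.impact.value, "rsid": a.rsid or "",
                   "consequence": a.consequence} for a in bundle.impacts]
                 ).to_csv(out / "impacts.tsv", sep="\t", index=False)
    with open(out / "annotations.bed", "w") as fh:
        for f in sorted(bundle.features,
                        key=lambda f: (f.chrom, f.start, f.end,
                                       f.feature_class.value)):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_class.value}\n")

    # caller-native call files
    dialects = {Caller.SV_CALLER_A: "sv", Caller.SV_CALLER_B: "sv",
                Caller.SMALLVAR_CALLER: "smallvar", Caller.STR_CALLER: "str"}
    by_cs: dict[tuple[Caller, str], list[VariantCall]] = {}
    for c in bundle.calls:
        by_cs.setdefault((c.caller, c.sample), []).append(c)
    for caller, dialect in dialects.items():
        cdir = out / "calls" / caller.value
        cdir.mkdir(parents=True, exist_ok=True)
        for sample in bundle.samples:
            calls = by_cs.get((caller, sample), [])
            if dialect == "str":
                rows = _str_table_rows(calls)
                pd.DataFrame(rows, columns=["chrom", "start", "end", "motif",
                                            "ref_copies", "sample",
                                            "allele_copies"]
                             ).to_csv(cdir / f"{sample}.tsv", sep="\t",
                                      index=False)
            else:
                _write_caller_vcf(calls, sample, cdir / f"{sample}.vcf",
                                  dialect, bundle.chrom_len)

    hdir = out / "haplotypes"
    hdir.mkdir(exist_ok=True)
    for name in sorted(bundle.haplotypes):
        write_haplotypes_tsv(bundle.haplotypes[name], hdir / f"{name}.tsv")
    pd.DataFrame([{"region": n, "anchor_pos": p}
                  for n, p in sorted(bundle.anchors.items())]
                 ).to_csv(out / "anchors.tsv", sep="\t", index=False)

    truth = {
        "seed": bundle.seed,
        "n_samples": len(bundle.samples),
        "samples": bundle.samples,
        "genome_size": bundle.genome_size,
        "chrom_len": bundle.chrom_len,
        "read_spec": asdict(bundle.read_spec),
        "variant_spec": asdict(bundle.variant_spec),
        "annotation_class_counts": bundle.annotation_class_counts,
        "ld_cassettes": {n: [c.chrom, c.start, c.end]
                         for n, c in sorted(bundle.ld_cassettes.items())},
        "removed_read_ids": sorted(bundle.removed_read_ids),
        "variants": [_truth_to_json(t) for t in bundle.truth_variants],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out


def load_bundle_calls(bundle_dir) -> list[VariantCall]:
    """Parse every caller file in a written bundle back into calls."""
    from .callset import read_str_table, read_sv_vcf

    root = Path(bundle_dir) / "calls"
    calls: list[VariantCall] = []
    for caller_dir in sorted(root.iterdir()):
        caller = Caller(caller_dir.name)
        for f in sorted(caller_dir.iterdir()):
            if f.suffix == ".vcf":
                calls.extend(read_sv_vcf(f, caller))
            elif f.suffix == ".tsv":
                calls.extend(read_str_table(f, caller))
    return calls
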
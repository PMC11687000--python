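"""Cross-caller clustering, presence rule, allele diversity, concordance."""

import numpy as np
import pytest

from targetsv.callset import (
    AltAllele,
    Caller,
    Genotype,
    VarClass,
    VariantCall,
)
from targetsv.harmonize import (
    BAMEvidence,
    allele_diversity,
    cluster_calls,
    cluster_calls_bruteforce,
    concordance_table,
    variant_present,
)


def _call(chrom="chr1", start=1000, end=None, vc=VarClass.DEL, caller=Caller.SV_CALLER_A,
          sample="S1", alt_len=15, gt=Genotype.HET, seq=None, motif=None, src=""):
    vc = VarClass(vc)
    if end is None:
        end = start + alt_len if vc in (VarClass.DEL, VarClass.STR, VarClass.TE) \
            else start + 1
    alts = (AltAllele(length=alt_len, seq=seq, motif=motif),) \
        if gt is not Genotype.HOM_REF else ()
    return VariantCall(sample=sample, caller=caller, chrom=chrom, start=start,
                       end=end, var_class=vc, ref_len=max(1, end - start),
                       alt_alleles=alts, genotype=gt, qual=20,
                       source_record=src or f"{caller}:{sample}:{start}")


def test_jittered_deletions_cluster_into_one_locus():
    a = _call(start=1000, alt_len=15, caller=Caller.SV_CALLER_A)
    b = _call(start=1003, alt_len=15, caller=Caller.SV_CALLER_B)
    loci = cluster_calls([a, b])
    assert len(loci) == 1
    assert len(loci[0].member_calls) == 2


def test_str_and_distant_snv_stay_separate():
    s = _call(start=1000, vc=VarClass.STR, alt_len=30, motif="AC",
              caller=Caller.STR_CALLER)
    snv = _call(start=50_000, vc=VarClass.SNV, alt_len=1, seq="T",
                caller=Caller.SMALLVAR_CALLER)
    assert len(cluster_calls([s, snv])) == 2


def test_str_locus_absorbs_indel_reports_from_vcf_callers():
    str_call = _call(start=1000, end=1040, vc=VarClass.STR, alt_len=34,
                     motif="T", caller=Caller.STR_CALLER)
    del_call = _call(start=1005, alt_len=6, vc=VarClass.DEL,
                     caller=Caller.SV_CALLER_A)
    (locus,) = cluster_calls([str_call, del_call])
    assert locus.var_class is VarClass.STR
    assert len(locus.member_calls) == 2


def _random_calls(rng, n):
    calls = []
    classes = [VarClass.SNV, VarClass.INS, VarClass.DEL, VarClass.STR, VarClass.TE]
    callers = list(Caller)[:4]
    for i in range(n):
        vc = classes[int(rng.integers(len(classes)))]
        start = int(rng.integers(0, 4000))
        alt_len = int(rng.integers(1, 60))
        calls.append(_call(
            chrom=f"chr{int(rng.integers(1, 3))}", start=start, vc=vc,
            alt_len=alt_len, caller=callers[int(rng.integers(4))],
            sample=f"S{int(rng.integers(1, 4))}",
            seq="ACGT"[int(rng.integers(4))] if vc is VarClass.SNV else None,
            motif="AC" if vc is VarClass.STR else None, src=f"c{i}"))
    return calls


def _partition(loci):
    return {frozenset((c.caller.value, c.sample, c.start, c.source_record)
                      for c in l.member_calls) for l in loci}


@pytest.mark.parametrize("seed", range(20))
def test_clustering_equals_bruteforce_transitive_closure(seed):
    rng = np.random.default_rng(seed)
    calls = _random_calls(rng, int(rng.integers(2, 21)))
    swept = _partition(cluster_calls(calls, max_cluster_span=10**9))
    from targetsv.harmonize import _canonical_order
    ordered = _canonical_order(calls)
    brute = {
        frozenset((ordered[i].caller.value, ordered[i].sample,
                   ordered[i].start, ordered[i].source_record) for i in part)
        for part in cluster_calls_bruteforce(calls)
    }
    assert swept == brute


def test_clustering_is_input_order_invariant():
    rng = np.random.default_rng(3)
    calls = _random_calls(rng, 15)
    p1 = _partition(cluster_calls(calls))
    rng.shuffle(calls)
    p2 = _partition(cluster_calls(calls))
    assert p1 == p2


def test_every_call_lands_in_exactly_one_locus(small_bundle):
    loci = cluster_calls(small_bundle.calls)
    n_members = sum(len(l.member_calls) for l in loci)
    assert n_members == len(small_bundle.calls)


# ---------------------------------------------------------------------------
# Presence rule


def _locus_with(calls):
    (locus,) = cluster_calls(calls)
    return locus


def test_present_when_any_caller_reports_nonref():
    locus = _locus_with([
        _call(sample="S3", caller=Caller.SV_CALLER_A, gt=Genotype.HET),
        _call(sample="S3", caller=Caller.SV_CALLER_B, gt=Genotype.HET, start=1002),
    ])
    assert variant_present(locus, "S3")
    assert not variant_present(locus, "S1")


def test_present_via_bam_evidence_alone():
    locus = _locus_with([_call(sample="S1", gt=Genotype.HET)])
    ev = [BAMEvidence("S2", "chr1", 990, 1020, True)]
    assert variant_present(locus, "S2", ev)
    assert not variant_present(locus, "S2", [])
    no = [BAMEvidence("S2", "chr1", 990, 1020, False)]
    assert not variant_present(locus, "S2", no)


def test_unresolved_genotype_not_present_unless_opted_in():
    call = _call(sample="S1", gt=Genotype.UNRESOLVED)
    locus = _locus_with([call])
    assert not variant_present(locus, "S1")
    assert variant_present(locus, "S1", count_unresolved=True)


def test_presence_is_monotone_in_evidence():
    base = [_call(sample="S1", gt=Genotype.HET)]
    locus = _locus_with(base)
    assert not variant_present(locus, "S2")
    locus2 = _locus_with(base + [_call(sample="S2", caller=Caller.SV_CALLER_B,
                                       gt=Genotype.HET, start=1001)])
    assert variant_present(locus2, "S2")  # adding a call never flips to absent
    assert variant_present(locus2, "S1")


# ---------------------------------------------------------------------------
# Allele diversity and concordance cells


def test_insertion_spectrum_counts_samples_and_distinct_alleles():
    # one caller: 47 bp x5 samples, 46 bp x1, 38 bp x1  ->  "7(3)"
    calls = []
    for i, length in enumerate([47, 47, 47, 47, 47, 46, 38]):
        calls.append(_call(sample=f"S{i}", vc=VarClass.INS, alt_len=length,
                           start=1000 + i, caller=Caller.SV_CALLER_A))
    (locus,) = cluster_calls(calls)
    cell = allele_diversity(locus)[Caller.SV_CALLER_A]
    assert (cell.n_samples_nonref, cell.n_distinct_alt) == (7, 3)
    assert str(cell) == "7(3)"


def test_single_sample_single_allele_cell():
    (locus,) = cluster_calls([_call()])
    assert str(allele_diversity(locus)[Caller.SV_CALLER_A]) == "1(1)"


def test_duplicate_calls_do_not_inflate_tallies():
    a = _call(sample="S1", src="x")
    dup = _call(sample="S1", src="y")
    (locus,) = cluster_calls([a, dup])
    cell = allele_diversity(locus)[Caller.SV_CALLER_A]
    assert (cell.n_samples_nonref, cell.n_distinct_alt) == (1, 1)


def test_diversity_against_bruteforce_enumeration(small_clean_bundle):
    """Tallies at a planted STR locus equal direct truth enumeration."""
    b = small_clean_bundle
    loci = cluster_calls(b.calls)
    truth_strs = [t for t in b.truth_variants
                  if t.var_class is VarClass.STR and t.interesting]
    for t in truth_strs:
        locus = next(l for l in loci
                     if l.chrom == t.chrom and l.start <= t.start < l.end)
        cell = allele_diversity(locus).get(Caller.STR_CALLER)
        carriers = t.carriers()
        expected_alleles = {t.sample_alts[s][0] for s in carriers}
        assert cell is not None
        assert cell.n_samples_nonref == len(carriers)
        assert cell.n_distinct_alt == len(expected_alleles)


def test_concordance_table_cells_and_bam_column():
    calls = []
    for caller in (Caller.SV_CALLER_A, Caller.SV_CALLER_B,
                   Caller.SMALLVAR_CALLER):
        for s in ("S1", "S2"):
            calls.append(_call(sample=s, caller=caller, start=1000,
                               vc=VarClass.DEL, alt_len=20))
    str_call = _call(sample="S1", caller=Caller.STR_CALLER, vc=VarClass.STR,
                     start=1000, end=1020, alt_len=14, motif="T")
    loci = cluster_calls(calls + [str_call])
    ev = [BAMEvidence(s, "chr1", 995, 1025, True) for s in ("S1", "S2")]
    table = concordance_table(loci, bam_evidence=ev, cohort=["S1", "S2"])
    assert len(table) == 1
    row = table.iloc[0]
    assert row["sv_caller_a"] == "2(1)"
    assert row["str_caller"] == "1(1)"
    assert row["bam"] == "All"


def test_caller_that_never_called_gets_empty_cell():
    table = concordance_table(cluster_calls([_call()]), cohort=["S1", "S2"])
    assert table.iloc[0]["sv_caller_b"] == ""
    assert table.iloc[0]["bam"] == ""
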
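"""Parsing caller dialects into the normalised variant model."""

import textwrap

import pytest

from targetsv.callset import (
    AltAllele,
    Caller,
    Genotype,
    VarClass,
    VariantCall,
    read_harmonised_vcf,
    read_str_table,
    read_sv_vcf,
    write_harmonised_vcf,
)

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
    ##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="x">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


def _vcf(tmp_path, body):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + textwrap.dedent(body))
    return path


def test_symbolic_deletion_maps_class_length_genotype(tmp_path):
    path = _vcf(tmp_path,
                "chr1\t1000\t.\tN\t<DEL>\t30\t.\tSVTYPE=DEL;SVLEN=-15\tGT\t0/1\n")
    (call,) = read_sv_vcf(path, Caller.SV_CALLER_A)
    assert call.var_class is VarClass.DEL
    assert call.alt_alleles[0].length == 15
    assert call.genotype is Genotype.HET
    # anchored VCF: POS names the base before the event
    assert (call.start, call.end) == (1000, 1015)
    assert call.qual == 30


def test_missing_genotype_stays_unresolved(tmp_path):
    path = _vcf(tmp_path,
                "chr1\t1000\t.\tN\t<INS>\t12\t.\tSVTYPE=INS;SVLEN=40\tGT\t./.\n")
    (call,) = read_sv_vcf(path, Caller.SV_CALLER_A)
    assert call.genotype is Genotype.UNRESOLVED
    assert call.var_class is VarClass.INS
    assert call.alt_alleles[0].length == 40


def test_sequence_explicit_class_inference(tmp_path):
    body = (
        "chr1\t100\t.\tA\tG\t20\t.\t.\tGT\t1/1\n"            # SNV
        "chr1\t200\t.\tN\tNAAAA\t20\t.\t.\tGT\t0/1\n"        # 4 bp INS
        "chr1\t300\t.\tNAAAAAA\tN\t20\t.\t.\tGT\t0/1\n"      # 6 bp DEL
    )
    calls = read_sv_vcf(_vcf(tmp_path, body), Caller.SMALLVAR_CALLER)
    snv, ins, dele = calls
    assert snv.var_class is VarClass.SNV and snv.end == snv.start + 1
    assert snv.alt_alleles[0].seq == "G"
    assert ins.var_class is VarClass.INS and ins.alt_alleles[0].length == 4
    assert dele.var_class is VarClass.DEL
    assert dele.alt_alleles[0].length == 6
    assert dele.end - dele.start == 6


def test_parser_totality_counts_skipped_records(tmp_path):
    body = (
        "chr1\t100\t.\tA\tG\t20\t.\t.\tGT\t1/1\n"
        "chr1\t200\t.\tA\t.\t20\t.\t.\tGT\t0/0\n"   # no ALT -> skipped
        "chr1\t300\t.\tN\tNAA\t20\t.\t.\tGT\t0/1\n"
    )
    calls, skipped = read_sv_vcf(_vcf(tmp_path, body), Caller.SMALLVAR_CALLER,
                                 with_stats=True)
    assert len(calls) + skipped == 3
    assert skipped == 1


def test_generator_vcf_round_trip_recovers_truth_fields(small_bundle, tmp_path):
    """Writing the bundle's caller files and re-parsing gives the same calls."""
    from targetsv.synthetic import load_bundle_calls, write_bundle

    write_bundle(small_bundle, tmp_path / "bundle")
    back = load_bundle_calls(tmp_path / "bundle")

    def key(c):
        return (c.chrom, c.start, c.end, c.caller.value, c.sample,
                c.var_class.value, tuple(a.length for a in c.alt_alleles))

    orig = sorted(small_bundle.calls, key=key)
    rt = sorted(back, key=key)
    assert len(orig) == len(rt)
    for a, b in zip(orig, rt):
        assert key(a) == key(b)
        assert a.genotype is b.genotype
        assert (a.qual is None) == (b.qual is None)
        if a.qual is not None:
            assert a.qual == pytest.approx(b.qual, abs=1e-3)


# ---------------------------------------------------------------------------
# STR locus tables


def _str_table(tmp_path, rows):
    path = tmp_path / "str.tsv"
    header = "chrom\tstart\tend\tmotif\tref_copies\tsample\tallele_copies\n"
    path.write_text(header + "".join(rows))
    return path


def test_str_contraction_allele_with_reference_partner(tmp_path):
    path = _str_table(tmp_path, ["chr3\t1000\t1040\tT\t40\tS1\t40,35\n"])
    (call,) = read_str_table(path)
    assert call.var_class is VarClass.STR
    assert call.genotype is Genotype.HET     # one reference-length allele
    (alt,) = call.alt_alleles
    assert alt.copy_number == 35 and alt.length == 35
    assert call.qual is None


def test_empty_str_table_gives_no_calls(tmp_path):
    (calls) = read_str_table(_str_table(tmp_path, []))
    assert calls == []


def test_str_cohort_allele_spectrum_enumerates_distinct_lengths(tmp_path):
    rows = [f"chr1\t500\t570\tAAAAT\t14\tS{i}\t14,{c}\n"
            for i, c in enumerate([12, 12, 16, 16, 12, 16, 14, 12, 16, 12], 1)]
    calls = read_str_table(_str_table(tmp_path, rows))
    assert len(calls) == 10
    lens = {a.length for c in calls for a in c.alt_alleles}
    assert lens == {60, 80}  # 12 and 16 copies of a 5-mer
    assert sum(1 for c in calls if c.genotype is Genotype.HOM_REF) == 1


def test_str_table_rejects_nonpositive_copy_numbers(tmp_path):
    path = _str_table(tmp_path, ["chr1\t0\t40\tT\t40\tS1\t-3,35\n",
                                 "chr1\t100\t140\tT\t40\tS2\t40,35\n"])
    calls, skipped = read_str_table(path, with_stats=True)
    assert skipped == 1 and len(calls) == 1


# ---------------------------------------------------------------------------
# Harmonised VCF round trip


def _mixed_calls():
    calls = []
    for i, sample in enumerate(["S1", "S2"]):
        calls.append(VariantCall(
            sample=sample, caller=Caller.SMALLVAR_CALLER, chrom="chr1",
            start=100, end=101, var_class=VarClass.SNV, ref_len=1, ref_seq="A",
            alt_alleles=(AltAllele(length=1, seq="T"),), qual=30 + i,
            genotype=Genotype.HET, source_record="snv1"))
        calls.append(VariantCall(
            sample=sample, caller=Caller.SV_CALLER_A, chrom="chr1",
            start=5_000, end=5_050, var_class=VarClass.DEL, ref_len=1,
            alt_alleles=(AltAllele(length=50),), qual=21,
            genotype=Genotype.HOM_ALT, source_record="del1"))
        calls.append(VariantCall(
            sample=sample, caller=Caller.STR_CALLER, chrom="chr2",
            start=900, end=934, var_class=VarClass.STR, ref_len=34,
            alt_alleles=(AltAllele(length=38, motif="AC", copy_number=19.0),),
            qual=None, genotype=Genotype.HET, source_record="str1"))
    calls.append(VariantCall(
        sample="S1", caller=Caller.SV_CALLER_B, chrom="chr2", start=7_000,
        end=7_001, var_class=VarClass.INS, ref_len=1,
        alt_alleles=(AltAllele(length=47),), qual=15.5,
        genotype=Genotype.UNRESOLVED, source_record="ins1"))
    return calls


def test_harmonised_vcf_round_trip_is_identity(tmp_path):
    calls = _mixed_calls()
    path = tmp_path / "harmonised.vcf"
    write_harmonised_vcf(calls, path)
    back = read_harmonised_vcf(path)

    def key(c):
        return (c.chrom, c.start, c.end, c.caller.value, c.sample,
                c.var_class.value, c.genotype.value,
                tuple((a.length, a.motif, a.copy_number) for a in c.alt_alleles))

    assert sorted(map(key, back)) == sorted(map(key, calls))


def test_harmonised_vcf_encodes_str_motif_and_copies(tmp_path):
    path = tmp_path / "h.vcf"
    write_harmonised_vcf(_mixed_calls(), path)
    text = path.read_text()
    assert "MOTIF=AC" in text and "CN=19" in text


def test_harmonised_vcf_accepted_by_independent_parser(tmp_path):
    import cyvcf2

    path = tmp_path / "h.vcf"
    write_harmonised_vcf(_mixed_calls(), path)
    records = list(cyvcf2.VCF(str(path)))
    assert len(records) == 4  # grouped by (caller, locus, alleles)


def test_conflicting_duplicate_records_raise(tmp_path):
    c = _mixed_calls()[0]
    conflict = VariantCall(
        sample=c.sample, caller=c.caller, chrom=c.chrom, start=c.start,
        end=c.end, var_class=c.var_class, ref_len=1, ref_seq="A",
        alt_alleles=c.alt_alleles, qual=c.qual,
        genotype=Genotype.HOM_ALT, source_record=c.source_record)
    with pytest.raises(ValueError, match="conflict"):
        write_harmonised_vcf([c, conflict], tmp_path / "x.vcf")
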
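"""The five-stage prioritisation cascade and its audit trail."""

import json

import pytest

from targetsv.callset import AltAllele, Caller, Genotype, VarClass, VariantCall
from targetsv.harmonize import cluster_calls
from targetsv.ld import ld_blocks
from targetsv.prioritize import (
    FilterConfig,
    Impact,
    ImpactAnnotation,
    PrioritisationAudit,
    run_cascade,
    stage1_region_filter,
    stage2_quality_filter,
    stage3_class_filter,
    stage4_impact_filter,
    stage5_ld_filter,
)
from targetsv.regions import GenomicRegion


def _call(start, vc=VarClass.DEL, qual=20.0, caller=Caller.SV_CALLER_A,
          alt_len=20, sample="S1", chrom="chr1"):
    vc = VarClass(vc)
    end = start + alt_len if vc in (VarClass.DEL, VarClass.STR, VarClass.TE) \
        else start + 1
    return VariantCall(sample=sample, caller=caller, chrom=chrom, start=start,
                       end=end, var_class=vc, ref_len=max(1, end - start),
                       alt_alleles=(AltAllele(length=alt_len,
                                              seq="T" if vc is VarClass.SNV else None),),
                       qual=qual, genotype=Genotype.HET,
                       source_record=f"v{start}")


REGION = GenomicRegion("chr1", 10_000, 50_000, "r1")


def test_region_filter_keeps_one_bp_overlap_only():
    inside = _call(20_000)
    edge_out = _call(50_000)           # starts exactly at region end
    outside = _call(90_000)
    audit = PrioritisationAudit()
    kept = stage1_region_filter([inside, edge_out, outside], [REGION], audit)
    assert kept == [inside]
    st = audit.stages[0]
    assert st.n_in == 3 and st.n_out == 1 and len(st.exclusions) == 2


def test_quality_filter_inclusive_threshold_and_exemption():
    ok = _call(1000, qual=9.0)
    low = _call(2000, qual=8.9)
    str_call = VariantCall(sample="S1", caller=Caller.STR_CALLER, chrom="chr1",
                           start=3000, end=3030, var_class=VarClass.STR,
                           ref_len=30,
                           alt_alleles=(AltAllele(length=24, motif="AC",
                                                  copy_number=12.0),),
                           qual=None, genotype=Genotype.HET)
    audit = PrioritisationAudit()
    kept = stage2_quality_filter([ok, low, str_call], 9.0, audit)
    assert kept == [ok, str_call]
    st = audit.stages[0]
    assert "qual-exempt" in st.flags[next(iter(st.flags))]


def test_class_filter_strict_indel_length():
    loci_in = cluster_calls([
        _call(1000, VarClass.SNV, alt_len=1),
        _call(5000, VarClass.INS, alt_len=10),   # exactly 10 bp -> dropped
        _call(9000, VarClass.DEL, alt_len=11),   # 11 bp -> kept
        _call(13_000, VarClass.STR, alt_len=4),  # short STR -> kept anyway
        _call(17_000, VarClass.TE, alt_len=2000),
    ])
    audit = PrioritisationAudit()
    kept = stage3_class_filter(loci_in, 10, audit)
    assert {l.var_class for l in kept} == {VarClass.DEL, VarClass.STR, VarClass.TE}
    reasons = list(audit.stages[0].exclusions.values())
    assert any("SNV" in r for r in reasons)
    assert any("<= 10" in r for r in reasons)


def test_impact_filter_requires_high_and_novel():
    loci = cluster_calls([_call(1000), _call(5000), _call(9000), _call(13_000)])
    anns = [
        ImpactAnnotation("chr1", 990, 1030, Impact.HIGH),
        ImpactAnnotation("chr1", 4990, 5030, Impact.HIGH, rsid="rs123"),
        ImpactAnnotation("chr1", 8990, 9030, Impact.MODERATE),
        # locus at 13000 has no annotation row -> quarantined
    ]
    audit = PrioritisationAudit()
    kept = stage4_impact_filter(loci, anns, audit=audit)
    assert [l.start for l in kept] == [1000]
    assert list(audit.quarantined.values()) == ["needs-annotation"]
    reasons = set(audit.stages[0].exclusions.values())
    assert {"existing rsID rs123", "impact MODERATE", "needs-annotation"} == reasons


def test_ld_filter_with_lenient_fallback_for_blockless_regions():
    region_a = GenomicRegion("chr1", 0, 100_000, "A")
    region_b = GenomicRegion("chr2", 0, 100_000, "B")   # no blocks declared
    block = GenomicRegion("chr1", 10_000, 20_000, "blk")
    in_block = cluster_calls([_call(15_000)])
    out_block = cluster_calls([_call(60_000)])
    other_region = cluster_calls([_call(30_000, chrom="chr2")])
    loci = in_block + out_block + other_region
    audit = PrioritisationAudit()
    kept = stage5_ld_filter(loci, [block], [region_a, region_b], audit)
    assert {l.chrom for l in kept} == {"chr1", "chr2"}
    assert len(kept) == 2
    assert "lenient" in audit.stages[0].flags.values()
    assert "outside LD blocks" in audit.stages[0].exclusions.values()


# ---------------------------------------------------------------------------
# Full cascade on planted cohorts


def _cascade(bundle, **cfg_kw):
    blocks = []
    for name, haps in bundle.haplotypes.items():
        blocks.extend(b.region for b in ld_blocks(haps, bundle.anchors[name]))
    return run_cascade(bundle.calls, FilterConfig(**cfg_kw), bundle.impacts,
                       blocks, bundle.regions, bundle.bam_evidence)


def _matches_truth(loci, truth):
    from targetsv._utils import interval_overlap
    hits = 0
    for t in truth:
        if any(l.chrom == t.chrom
               and interval_overlap(l.start, l.end, t.start - 300, t.end + 300) > 0
               for l in loci):
            hits += 1
    return hits


def test_cascade_recovers_exactly_the_planted_interesting_set(small_clean_bundle):
    res = _cascade(small_clean_bundle)
    truth = small_clean_bundle.interesting_truth()
    assert len(res.loci) == len(truth)
    assert _matches_truth(res.loci, truth) == len(truth)


def test_stage1_exclusions_match_planted_outside_fraction(small_clean_bundle):
    b = small_clean_bundle
    audit = PrioritisationAudit()
    kept = stage1_region_filter(b.calls, b.regions, audit)
    outside_uids = {t.uid for t in b.truth_variants if not t.in_region}
    expected_excluded = sum(
        1 for c in b.calls
        if not any(r.overlap(c.chrom, c.start, c.end) > 0 for r in b.regions))
    assert len(audit.stages[0].exclusions) == expected_excluded
    # every excluded call comes from a variant planted outside the regions
    assert all(not any(r.overlap(c.chrom, c.start, c.end) for r in b.regions)
               for c in b.calls if c not in kept)
    assert outside_uids  # the planting actually exercised this stage


def test_audit_conservation_at_every_stage(small_bundle):
    res = _cascade(small_bundle)
    for st in res.audit.stages:
        assert st.n_in == st.n_out + len(st.exclusions)


def test_empty_input_gives_empty_output_and_zero_audit():
    res = run_cascade([], FilterConfig(), [], [], [])
    assert res.loci == [] and len(res.table) == 0
    assert all(s.n_in == 0 and s.n_out == 0 for s in res.audit.stages)


def test_disabling_a_stage_yields_a_superset(small_bundle):
    full = _cascade(small_bundle)
    full_keys = {(l.chrom, l.start, l.end) for l in full.loci}
    for stage in ("class", "impact", "ld"):
        relaxed = _cascade(small_bundle, disabled_stages=frozenset({stage}))
        relaxed_keys = {(l.chrom, l.start, l.end) for l in relaxed.loci}
        assert full_keys <= relaxed_keys
        assert len(relaxed.loci) >= len(full.loci)
    # call-level stages: every surviving locus is still covered
    for stage in ("region", "quality"):
        relaxed = _cascade(small_bundle, disabled_stages=frozenset({stage}))
        from targetsv._utils import interval_overlap
        for l in full.loci:
            assert any(r.chrom == l.chrom
                       and interval_overlap(r.start, r.end, l.start, l.end) > 0
                       for r in relaxed.loci)


def test_cascade_is_deterministic(small_bundle):
    a = _cascade(small_bundle)
    b = _cascade(small_bundle)
    assert a.audit.to_json() == b.audit.to_json()
    assert a.table.equals(b.table)


def test_config_rejects_unknown_stage_and_negative_thresholds():
    with pytest.raises(ValueError, match="unknown stage"):
        FilterConfig(disabled_stages=frozenset({"bogus"}))
    with pytest.raises(ValueError, match="non-negative"):
        FilterConfig(qual_min=-1)
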
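"""The synthetic cohort generator: determinism, planting, noise model."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from targetsv.callset import Genotype, VarClass
from targetsv.synthetic import (
    CallerProfile,
    InfeasibleSpec,
    ReadSimSpec,
    VariantSpec,
    generate_cohort,
    observe_variant,
    plant_composite_te,
    plant_str_locus,
    simulate_read_summaries,
    write_bundle,
)

SMALL = dict(n_samples=3, n_regions=3, variant_spec=VariantSpec.small())


def _dir_digest(d):
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(d)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    write_bundle(generate_cohort(1, **SMALL), tmp_path / "a")
    write_bundle(generate_cohort(1, **SMALL), tmp_path / "b")
    assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")
    write_bundle(generate_cohort(2, **SMALL), tmp_path / "c")
    assert _dir_digest(tmp_path / "a") != _dir_digest(tmp_path / "c")


def test_truth_set_echoes_the_requested_composition(full_noisy_bundle):
    b = full_noisy_bundle
    spec = b.variant_spec
    assert len(b.truth_variants) == spec.n_total == 120
    assert len(b.interesting_truth()) == spec.n_interesting == 20
    by_class = {vc: sum(1 for t in b.truth_variants if t.var_class is vc)
                for vc in VarClass}
    assert by_class[VarClass.SNV] == spec.n_snv
    assert by_class[VarClass.STR] == spec.n_str
    assert by_class[VarClass.TE] == spec.n_te
    for t in b.interesting_truth():
        assert t.var_class is not VarClass.SNV
        assert t.in_region and t.in_ld_block
        assert t.impact.value == "HIGH" and t.rsid is None
        cassette = b.ld_cassettes[t.region_name]
        assert cassette.start <= t.start and t.end <= cassette.end


def test_noise_free_callers_report_every_truth_variant_exactly(full_clean_bundle):
    b = full_clean_bundle
    by_uid_caller = {}
    for c in b.calls:
        by_uid_caller.setdefault((c.source_record, c.caller), []).append(c)
    profiles = {p.caller: p for p in CallerProfile.noise_free()}
    for t in b.truth_variants:
        for caller, prof in profiles.items():
            if prof.sensitivity.get(t.var_class, 0) < 1:
                continue
            if prof.dialect == "str" and t.var_class is not VarClass.STR:
                continue
            calls = [c for c in b.calls
                     if c.caller == caller and c.sample in t.carriers()
                     and c.chrom == t.chrom
                     and t.start - 1 <= c.start <= t.end]
            assert len(calls) >= len(t.carriers()), (t.uid, caller)
            # zero jitter: observed coordinates sit at the planted position
            if t.var_class in (VarClass.INS, VarClass.DEL, VarClass.STR):
                assert all(c.start == t.start for c in calls
                           if c.source_record == t.uid or prof.dialect == "str")


def test_interesting_variants_have_union_caller_coverage(full_noisy_bundle):
    b = full_noisy_bundle
    called = {(c.source_record, c.sample) for c in b.calls}
    str_keys = {(f"{t.chrom}:{t.start}:{t.motif}", s)
                for t in b.truth_variants for s in t.carriers()}
    for t in b.interesting_truth():
        for s in t.carriers():
            ok = (t.uid, s) in called or \
                (f"{t.chrom}:{t.start}:{t.motif}", s) in called
            assert ok, (t.uid, s)


def test_infeasible_specs_are_rejected():
    with pytest.raises(InfeasibleSpec):
        generate_cohort(1, n_samples=2, n_regions=1,
                        variant_spec=VariantSpec(n_interesting=50))
    with pytest.raises(InfeasibleSpec):
        generate_cohort(1, chrom_len=150_000)


# ---------------------------------------------------------------------------
# Planting primitives


def test_plant_str_locus_contraction_only_spectrum():
    t = plant_str_locus("T", 40, {35, 40}, position=1_000)
    assert t.var_class is VarClass.STR
    assert t.end - t.start == 40
    (alt,) = t.alt_spectrum
    assert alt.copy_number == 35 and alt.length == 35  # contraction only


def test_plant_str_locus_monomorphic_and_multiallelic():
    mono = plant_str_locus("AC", 17, {17}, position=0)
    assert mono.alt_spectrum == ()
    tri = plant_str_locus("AAAAT", 14, {12, 14, 16}, position=0)
    assert len(tri.alt_spectrum) == 2  # two non-reference alleles
    assert {a.length for a in tri.alt_spectrum} == {60, 80}


def test_plant_composite_te_structure_and_vntr_observation():
    t = plant_composite_te(10_000, vntr_allele_lens=(38, 46, 47))
    assert t.var_class is VarClass.TE
    s = t.te_structure
    assert t.end - t.start == (s["head_len"] + s["body_len"] + s["vntr_len"]
                               + s["sine_len"] + s["tail_len"])
    assert {a.length for a in t.alt_spectrum} == {38, 46, 47}

    # a noise-free SV caller observes it as an insertion inside the VNTR
    t.genotypes = {"S1": Genotype.HET}
    t.sample_alts = {"S1": (2,)}
    prof = CallerProfile.noise_free()[0]
    rng = np.random.default_rng(0)
    call = observe_variant(t, "S1", prof, rng)
    assert call.var_class is VarClass.INS
    assert call.alt_alleles[0].length == 47
    v0 = t.start + s["vntr_offset"]
    assert v0 <= call.start < v0 + s["vntr_len"]


def test_plant_composite_te_without_variation_yields_no_calls():
    t = plant_composite_te(10_000, vntr_allele_lens=())
    t.genotypes = {"S1": Genotype.HOM_REF}
    prof = CallerProfile.noise_free()[0]
    assert observe_variant(t, "S1", prof, np.random.default_rng(0)) is None


def test_genotype_discordance_flips_about_half_at_half_rate():
    t = plant_str_locus("AC", 20, {15, 20}, position=1_000)
    t.genotypes = {"S1": Genotype.HET}
    t.sample_alts = {"S1": (0,)}
    prof = CallerProfile(
        caller=list(CallerProfile.noise_free())[0].caller, dialect="sv",
        sensitivity={VarClass.STR: 1.0}, genotype_discordance=0.5)
    rng = np.random.default_rng(123)
    flips = 0
    n = 10_000
    for _ in range(n):
        call = observe_variant(t, "S1", prof, rng)
        if call.genotype is not Genotype.HET:
            flips += 1
    assert flips / n == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# Read simulation


def test_planted_coverages_recovered_within_sampling_error():
    from targetsv.enrichment import sample_stats
    from targetsv.regions import GenomicRegion

    rng = np.random.default_rng(17)
    regions = [GenomicRegion("chr1", 400_000, 600_000, "r1")]
    spec = ReadSimSpec(on_coverage=15, off_coverage=3, frac_subthreshold=0.0)
    reads, _ = simulate_read_summaries(rng, "S1", regions,
                                       chrom_len=1_000_000, spec=spec)
    on = sample_stats(reads, regions, "on_target")
    off = sample_stats(reads, regions, "off_target", genome_size=1_000_000)
    assert on.avg_cov == pytest.approx(15, rel=0.05)
    assert off.avg_cov == pytest.approx(3, rel=0.05)
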
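"""Run the five-stage prioritisation cascade with its audit trail.

On a synthetic cohort with 20 planted 'interesting' variants among 120, the
cascade (target region -> caller quality >= 9 -> non-SNV class with indels
> 10 bp -> HIGH impact without rsID -> LD-block overlap) should shortlist
exactly the planted set.
"""

from targetsv import FilterConfig, run_cascade
from targetsv.ld import ld_blocks
from targetsv.synthetic import generate_cohort

bundle = generate_cohort(seed=1, simulate_reads=False)  # 10 samples, 8 regions

blocks = []
for region_name, haps in bundle.haplotypes.items():
    blocks.extend(b.region for b in
                  ld_blocks(haps, bundle.anchors[region_name]))

result = run_cascade(bundle.calls, FilterConfig(), bundle.impacts, blocks,
                     bundle.regions, bundle.bam_evidence)

print(f"{'stage':<10}{'in':>7}{'out':>7}  excluded")
for stage, n_in, n_out in result.audit.counts():
    print(f"{stage:<10}{n_in:>7}{n_out:>7}  {n_in - n_out}")

planted = len(bundle.interesting_truth())
print(f"\nprioritised loci: {len(result.loci)} (planted interesting: {planted})")
print("\nThe audit conserves counts at every stage (in = out + excluded),")
print("and each exclusion carries the reason it was removed, so no variant")
print("is ever dropped silently.")
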
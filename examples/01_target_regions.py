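"""Build the eight 200 kb target regions around the anorexia nervosa GWAS
lead SNPs and write them as a BED file for adaptive sampling.

Each region spans 100 kb either side of the lead SNP; the printed pairs are
the coordinates a targeted-sequencing run would be configured with.
"""

from targetsv import build_target_region, write_regions_bed
from targetsv.datasets import AN_GWAS_LEAD_SNPS, AN_GWAS_NEAREST_GENES

regions = [build_target_region(snp) for snp in AN_GWAS_LEAD_SNPS]
write_regions_bed(regions, "target_regions.bed")

print(f"{'region':<18}{'lead SNP':<14}{'gene(s)':<16}{'coordinates':<28}width")
for snp, region in zip(AN_GWAS_LEAD_SNPS, regions):
    lo, hi = region.display_coords()
    print(f"{region.name:<18}{snp.rsid:<14}"
          f"{AN_GWAS_NEAREST_GENES[snp.rsid]:<16}"
          f"{region.chrom}:{lo:,}-{hi:,}   {region.width:,} bp")

print("\nEvery width is exactly 200,000 bp (lead SNP +/- 100 kb);"
      "\nthe BED file (0-based half-open) is what the sequencer's"
      "\nRead Until interface consumes.")
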
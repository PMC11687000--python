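"""Bundled reference inputs from the anorexia nervosa targeted-sequencing study.

Two small tables ship with the package so the worked examples and the
reproduction script run without external downloads:

* the eight-lead-SNP panel from the anorexia nervosa GWAS (GRCh38
  coordinates) that defines the 200 kb target regions, and
* the ten-sample adaptive-sampling QC table (per-sample average read
  length, read quality and coverage, on and off target) from the same
  study's sequencing runs.

These are published summary numbers, used as inputs; nothing here is
computed by this package.
"""

from __future__ import annotations

import pandas as pd

from .regions import LeadSNP

#: Lead SNPs of the eight genome-wide-significant anorexia nervosa loci
#: (GRCh38). Region names follow the study's "Target Region N" labels.
AN_GWAS_LEAD_SNPS: tuple[LeadSNP, ...] = (
    LeadSNP("rs9821797", "chr3", 48_680_820, "Target Region 1"),
    LeadSNP("rs6589488", "chr11", 115_226_236, "Target Region 2"),
    LeadSNP("rs2287348", "chr2", 53_812_676, "Target Region 3"),
    LeadSNP("rs2008387", "chr10", 129_650_500, "Target Region 4"),
    LeadSNP("rs9874207", "chr3", 70_970_599, "Target Region 5"),
    LeadSNP("rs10747478", "chr1", 96_435_899, "Target Region 6"),
    LeadSNP("rs370838138", "chr5", 25_081_736, "Target Region 7"),
    LeadSNP("rs13100344", "chr3", 94_886_263, "Target Region 8"),
)

#: Nearest coding gene(s) to each lead SNP, keyed by rsid.
AN_GWAS_NEAREST_GENES = {
    "rs9821797": "NCKIPSD",
    "rs6589488": "CADM1",
    "rs2287348": "ASB3, ERLEC1",
    "rs2008387": "MGMT",
    "rs9874207": "FOXP1",
    "rs10747478": "PTBP2",
    "rs370838138": "CDH10",
    "rs13100344": "NSUN3",
}


def an_sequencing_qc_table() -> pd.DataFrame:
    """Per-sample adaptive-sampling QC statistics for the 10-sample cohort.

    Columns: average read length (bp), average read quality (Phred, from
    error probability) and average fold-coverage, separately for on-target
    and off-target reads. These are the published per-sample values; the
    cohort mean/standard-error row is recomputed by
    :func:`targetsv.enrichment.cohort_summary`.
    """
    data = {
        "sample": [f"S{i}" for i in range(1, 11)],
        "on_avg_len": [8216, 8470, 9538, 12148, 12379,
                       14554, 14763, 14774, 15169, 15400],
        "on_avg_qual": [22.5, 22.6, 21.3, 22.6, 22.4,
                        22.2, 22.2, 22.0, 22.5, 22.9],
        "on_avg_cov": [10.4, 13.4, 16.4, 17.7, 10.3,
                       18.6, 13.5, 18.4, 15.8, 11.9],
        "off_avg_len": [3091, 3195, 3192, 2745, 2678,
                        1968, 2407, 4021, 3625, 3609],
        "off_avg_qual": [21.0, 22.2, 22.6, 22.5, 22.6,
                         22.5, 22.5, 23.0, 22.2, 22.1],
        "off_avg_cov": [2.8, 2.9, 3.4, 3.6, 2.2,
                        3.7, 4.0, 4.6, 4.7, 3.5],
    }
    return pd.DataFrame(data).set_index("sample")


#: Combined variant counts reported for the cohort (all callers, all
#: regions, all samples): SNVs, non-SNV structural variants, and their sum.
AN_COHORT_VARIANT_COUNTS = {"snv": 17_328, "non_snv": 5_052, "total": 22_380}
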
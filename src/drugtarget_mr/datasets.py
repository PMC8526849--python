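"""Packaged reference data: LDL-lowering cis variants and hg19 gene regions.

The variant table carries per-effect-allele LDL-cholesterol effects (mmol/L)
for the HMGCR, PCSK9 and NPC1L1 cis scores, with SEs back-derived from the
published 95% confidence intervals. The source table does not publish other
alleles or effect-allele frequencies, so the OA column holds synthetic
non-palindromic placeholders and EAF is missing; neither is needed for
instrument weights or F statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sumstats_io import GeneRegion, VariantAssociation

#: hg19 gene footprints (RefSeq bounds, rounded to the gene body) with the
#: default 100 kb cis flank used for score construction.
GENE_REGIONS = {
    "HMGCR": GeneRegion("HMGCR", "5", 74_632_154, 74_657_929),
    "PCSK9": GeneRegion("PCSK9", "1", 55_505_221, 55_530_525),
    "NPC1L1": GeneRegion("NPC1L1", "7", 44_552_134, 44_580_929),
}


def _table() -> pd.DataFrame:
    path = resources.files("drugtarget_mr").joinpath("data/ldl_lowering_variants.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def ldl_lowering_variants(score: str | None = None) -> list[VariantAssociation]:
    """Exposure-association records for the cis-score variants.

    Parameters
    ----------
    score:
        Optional gene-score filter ("HMGCR", "PCSK9" or "NPC1L1"); default all.
    """
    df = _table()
    if score is not None:
        if score not in set(df["SCORE"]):
            raise KeyError(f"unknown score {score!r}")
        df = df[df["SCORE"] == score]
    return [
        VariantAssociation(
            snp_id=row.SNP,
            chrom=str(row.CHR),
            pos=int(row.BP),
            effect_allele=row.EA,
            other_allele=row.OA,
            eaf=None,
            beta=float(row.BETA),
            se=float(row.SE),
            pval=float(row.P),
            n=int(row.N),
            trait_kind="quantitative",
        )
        for row in df.itertuples(index=False)
    ]
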
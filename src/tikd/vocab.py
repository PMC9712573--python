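"""Closed vocabularies of the screening workflow.

The registry annotates each member with one or two leading-diagnosis
categories drawn from a closed, case-sensitive set of nine labels; the
selection funnel additionally knows six structural/etiologic exclusion
conditions that disqualify a member regardless of category.
"""

from __future__ import annotations

#: The nine leading-diagnosis categories used to pre-select members with a
#: presumed tubulointerstitial or unclear CKD etiology.
CATEGORY_LABELS: tuple[str, ...] = (
    "nephrosclerosis",
    "gout",
    "IgA nephropathy",
    "chronic glomerulonephritis",
    "analgesic nephropathy",
    "interstitial nephritis",
    "hereditary disorders",
    "others",
    "unknown",
)

#: Conditions that exclude a member from selection outright.
EXCLUSION_FLAGS: tuple[str, ...] = (
    "postrenal",
    "primary_glomerular",
    "systemic_disease",
    "post_AKI",
    "polycystic",
    "single_kidney",
)

#: Small-variant and structural variant classes handled by the pipeline.
VARIANT_TYPES: tuple[str, ...] = ("SNV", "indel", "CNV", "mito_SNV")

CHROMOSOME_CLASSES: tuple[str, ...] = ("autosome", "gonosome", "mitochondrial")

ZYGOSITIES: tuple[str, ...] = (
    "heterozygous",
    "hemizygous",
    "homozygous",
    "homoplasmic",
    "unknown",
)

#: Genes of the 29-gene tubulointerstitial panel. The five classic ADTKD
#: genes, three ADTKD differential-diagnosis genes, the three collagen IV
#: a345 genes, and 17 nephronophthisis genes.
ADTKD_GENES: tuple[str, ...] = ("MUC1", "UMOD", "REN", "HNF1B", "SEC61A1")
ADTKD_DIFFERENTIAL_GENES: tuple[str, ...] = ("DNAJB11", "GATM", "PARN")
COL4A_GENES: tuple[str, ...] = ("COL4A3", "COL4A4", "COL4A5")
NPHP_GENES: tuple[str, ...] = (
    "NPHP1", "INVS", "NPHP3", "NPHP4", "IQCB1", "CEP290", "GLIS2",
    "RPGRIP1L", "NEK8", "SDCCAG8", "TMEM67", "TTC21B", "WDR19",
    "ZNF423", "CEP164", "ANKS6", "CEP83",
)

#: The mitochondrial tRNA-Phe gene; homoplasmic variants here cause
#: mitochondrially inherited tubulointerstitial kidney disease.
MITO_GENES: tuple[str, ...] = ("MT-TF",)

DEFAULT_PANEL_GENES: tuple[str, ...] = (
    ADTKD_GENES + ADTKD_DIFFERENTIAL_GENES + COL4A_GENES + NPHP_GENES
)
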
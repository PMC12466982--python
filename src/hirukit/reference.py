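"""Published summary values for the two-species medicinal-leech hirudin study.

These are the printed desk-scale inputs of the comparative study of
*Hirudo nipponia* (genes Hnip1–3) and *Hirudo tianjinensis* (genes Htia1–3):
per-gene diversity counts, per-gene TPM means and SDs across 12 individuals,
recombinant-protein concentrations, and triplicate antithrombin activities.
They parameterise the synthetic study generator and the desk-scale
reproduction checks; no raw sequence or per-sample data are deposited.

``aligned_length`` is the alignment length consistent with the published
per-site diversity values.  For Hnip3 and Htia2 it exceeds the printed CDS
length (207 vs 198 and 252 vs 234), as expected for indel-containing
alignments; the discrepancy is kept visible via ``cds_length_printed``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GeneReference",
    "GENES",
    "SPECIES",
    "EXPRESSION_TPM",
    "CONCENTRATIONS_MG_PER_ML",
    "ACTIVITY_REPLICATES",
    "ACTIVITY_MEANS",
    "N_INDIVIDUALS",
    "TOTAL_VS_DNA",
    "TOTAL_VS_PROTEIN",
]

N_INDIVIDUALS = 12

SPECIES = ("H_nipponia", "H_tianjinensis")


@dataclass(frozen=True)
class GeneReference:
    gene_id: str
    species_id: str
    cds_length_printed: int  # CDS length as tabulated
    aligned_length: int      # alignment length consistent with per-site theta
    S_dna: int               # variable sites, DNA level
    k_dna: int               # haplotypes, DNA level
    theta_dna: float         # per-site Watterson's theta (haplotype-n convention)
    S_prot: int
    k_prot: int
    theta_prot: float

    @property
    def aligned_length_prot(self) -> int:
        return self.aligned_length // 3

    @property
    def self_consistent(self) -> bool:
        """Printed CDS length equals the theta-consistent aligned length."""
        return self.cds_length_printed == self.aligned_length


GENES: dict[str, GeneReference] = {
    g.gene_id: g
    for g in (
        GeneReference("Hnip1", "H_nipponia", 204, 204, 13, 4, 0.03476, 10, 4, 0.08021),
        GeneReference("Hnip2", "H_nipponia", 252, 252, 2, 2, 0.00794, 1, 2, 0.01190),
        GeneReference("Hnip3", "H_nipponia", 198, 207, 4, 4, 0.01054, 4, 4, 0.03162),
        GeneReference("Htia1", "H_tianjinensis", 270, 270, 0, 1, 0.00000, 0, 1, 0.00000),
        GeneReference("Htia2", "H_tianjinensis", 234, 252, 8, 6, 0.01390, 5, 5, 0.02857),
        GeneReference("Htia3", "H_tianjinensis", 207, 207, 15, 7, 0.02958, 7, 7, 0.04141),
    )
}

TOTAL_VS_DNA = 42
TOTAL_VS_PROTEIN = 27

#: Per-gene TPM mean and SD across the 12 individuals of each species.
EXPRESSION_TPM: dict[str, tuple[float, float]] = {
    "Hnip1": (250.4, 333.3),
    "Hnip2": (5365.5, 3829.7),
    "Hnip3": (125.9, 96.3),
    "Htia1": (2362.4, 3331.1),
    "Htia2": (5700.7, 7119.9),
    "Htia3": (166.9, 240.2),
}

#: Raw concentrations of the recombinant proteins, mg/mL.
CONCENTRATIONS_MG_PER_ML: dict[str, float] = {
    "Hnip1": 1.347,
    "Hnip2": 3.191,
    "Hnip3": 1.954,
    "Htia1": 9.235,
    "Htia2": 15.207,
    "Htia3": 17.152,
}

#: Triplicate antithrombin activities, ATU/mg.
ACTIVITY_REPLICATES: dict[str, tuple[float, float, float]] = {
    "Hnip1": (212.766, 222.222, 227.273),
    "Hnip2": (66.225, 66.667, 67.568),
    "Hnip3": (0.000, 0.000, 0.000),
    "Htia1": (16.892, 17.123, 16.667),
    "Htia2": (7.267, 7.184, 7.353),
    "Htia3": (0.000, 0.000, 0.000),
}

#: Tabulated replicate means (mean ± SD column), ATU/mg.
ACTIVITY_MEANS: dict[str, tuple[float, float]] = {
    "Hnip1": (220.754, 7.364),
    "Hnip2": (66.820, 0.684),
    "Hnip3": (0.000, 0.000),
    "Htia1": (16.894, 0.228),
    "Htia2": (7.268, 0.085),
    "Htia3": (0.000, 0.000),
}
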
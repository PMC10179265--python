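"""Bundled worked example: a consanguineous multi-branch kindred with
four segregating candidate variants, a paired tumor/germline call set,
and the candidate-gene interaction neighbourhood.

Phenotype coding: members with benign nodular disease or no evaluation
are phenotype-unknown and contribute no segregation evidence. All
coordinates are GRCh37.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .types import (
    AnnotationBundle,
    AnnotationTable,
    GenotypeCall,
    Individual,
    InteractionGraph,
    Pedigree,
    Phenotype,
    Sex,
    VariantRecord,
)

__all__ = [
    "GENOTYPED_IDS",
    "SEQUENCED_CARRIERS",
    "TUMOR_DONOR",
    "SOMATIC_PANEL",
    "SUSCEPTIBILITY_PANEL",
    "CANDIDATE_GENES",
    "kindred_pedigree",
    "kindred_genotype_matrix",
    "candidate_annotations",
    "internal_frequencies",
    "somatic_fixture",
    "somatic_annotations",
    "interaction_fixture",
    "linkage_inputs",
    "recruitment_linkage_inputs",
]

#: The 11 members with verified genotypes for the candidate variants.
GENOTYPED_IDS: Tuple[str, ...] = (
    "III1", "III2", "III4", "III5", "III6",
    "III8", "III10", "IVA5", "XFIII1", "XFIII4", "XFIII5",
)

#: The exome-sequenced affected members used for the shared-variant intersection.
SEQUENCED_CARRIERS: Tuple[str, ...] = ("III8", "III10", "IVA5", "XFIII4", "XFIII5")

TUMOR_DONOR = "III8"

#: 13-gene somatic alteration panel (as printed, one token per line).
SOMATIC_PANEL: Tuple[str, ...] = (
    "NRAS", "HRAS", "KRAS", "THADA", "PIK3CA", "BRAF", "TERT",
    "PAX/PPARG", "PTEN", "DICER", "E1F1AX", "TSHR", "TP53",
)

#: Germline susceptibility genes assembled from the main-text literature.
SUSCEPTIBILITY_PANEL: Tuple[str, ...] = (
    "NKX2.1", "FOXE1", "HABP2", "RTFC", "MYH9", "CHEK2", "MYO1F",
    "DICER1", "SRRM2", "MAP2K5", "SPRY4", "RASAL1", "SRGAP1",
    "BRCA1", "BRCA2", "ATM", "XRCC1", "PAX8", "HHEX",
)

#: The three surviving germline candidate genes (second-hit scan targets).
CANDIDATE_GENES: Tuple[str, ...] = ("ARHGEF28", "FBXW10", "SLC47A1")

_A = Phenotype.AFFECTED
_H = Phenotype.UNAFFECTED
_U = Phenotype.UNKNOWN
_M = Sex.MALE
_F = Sex.FEMALE


def kindred_pedigree() -> Pedigree:
    """Two-branch reconstruction of the kindred.

    Branch 1: ten generation-III siblings (four affected, three
    unaffected, three unknown) plus one affected generation-IV
    granddaughter. Branch 2: an affected (deceased, unsampled) mother
    with five children, three affected. The branches descend from a
    shared founder couple, making the kindred consanguineous.
    """

    def ind(iid, father, mother, sex, pheno, sequenced=False, sampled=False):
        return Individual(
            id=iid, father_id=father, mother_id=mother, sex=sex,
            phenotype=pheno, sequenced=sequenced, sampled=sampled,
        )

    sequenced = set(SEQUENCED_CARRIERS)
    sampled = set(GENOTYPED_IDS)
    rows = [
        # founders
        ("I1", None, None, _M, _U),
        ("I2", None, None, _F, _U),
        # branch-1 parents: II1 descends from the founders
        ("II1", "I1", "I2", _M, _U),
        ("II1S", None, None, _F, _U),
        # branch-2 mother II2 also descends from the founders; died affected
        ("II2", "I1", "I2", _F, _A),
        ("II2S", None, None, _M, _U),
        # branch 1, generation III
        ("III1", "II1", "II1S", _F, _A),
        ("III2", "II1", "II1S", _M, _H),
        ("III3", "II1", "II1S", _F, _U),   # benign nodular disease
        ("III4", "II1", "II1S", _F, _H),
        ("III5", "II1", "II1S", _M, _A),
        ("III6", "II1", "II1S", _M, _H),
        ("III7", "II1", "II1S", _M, _U),   # benign nodular disease
        ("III8", "II1", "II1S", _M, _A),
        ("III9", "II1", "II1S", _F, _U),   # declined evaluation
        ("III10", "II1", "II1S", _F, _A),
        # generation IV of branch 1
        ("III1S", None, None, _M, _U),
        ("IVA5", "III1S", "III1", _F, _A),
        ("IVA8", "III1S", "III1", _F, _U),  # benign nodular disease
        # branch 2, generation III
        ("XFIII1", "II2S", "II2", _M, _A),
        ("XFIII2", "II2S", "II2", _F, _U),
        ("XFIII3", "II2S", "II2", _M, _U),
        ("XFIII4", "II2S", "II2", _M, _A),
        ("XFIII5", "II2S", "II2", _F, _A),
    ]
    return Pedigree(
        ind(iid, fa, mo, sex, pheno, iid in sequenced, iid in sampled or iid in sequenced)
        for iid, fa, mo, sex, pheno in rows
    )


_R = GenotypeCall.HOM_REF
_E = GenotypeCall.HET
_T = GenotypeCall.HOM_ALT

# Genotype matrix for the four segregating candidates, in the order of
# GENOTYPED_IDS (III1 III2 III4 III5 III6 III8 III10 IVA5 XFIII1 XFIII4 XFIII5).
_MATRIX = [
    ("5", 73048875, "A", "G", "ARHGEF28", "missense_variant",
     (_E, _R, _R, _E, _E, _E, _E, _E, _E, _E, _T)),
    ("17", 18661699, "ACAT", "A", "FBXW10", "inframe_deletion",
     (_E, _E, _R, _E, _R, _E, _E, _E, _E, _E, _E)),
    ("14", 92953131, "A", "G", "SLC24A4", "splice_region_variant",
     (_E, _R, _E, _E, _R, _E, _E, _E, _E, _E, _E)),
    ("17", 19459316, "G", "A", "SLC47A1", "missense_variant",
     (_E, _E, _R, _T, _R, _E, _E, _E, _E, _E, _E)),
]


def kindred_genotype_matrix() -> List[VariantRecord]:
    """The 4-variant x 11-member verified genotype matrix."""
    return [
        VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            consequence=consequence,
            genotypes=dict(zip(GENOTYPED_IDS, calls)),
        )
        for chrom, pos, ref, alt, gene, consequence, calls in _MATRIX
    ]


def candidate_annotations() -> AnnotationTable:
    """Expression, in-silico scores, and origin-population allele
    frequencies for the four candidates.

    Carrier proportions from the source tables are converted to allele
    frequencies as het/2 + hom. Public-database entries are absent (the
    variants were not observed there), which the frequency filter treats
    as zero.
    """
    table = AnnotationTable(
        dbs={"1KG", "EVS", "ExAC", "gnomAD", "Saudi", "Qatari"},
        score_names={"SIFT", "CADD", "PolyPhen", "spliceAI", "dbscSNV_Ada"},
    )
    table.bundles[("5", 73048875, "A", "G")] = AnnotationBundle(
        frequencies={"Saudi": 0.0, "Qatari": 0.0015},
        scores={"SIFT": 0.14, "CADD": 10.71, "PolyPhen": 0.02},
        expression_tpm=19.44,
    )
    table.bundles[("17", 18661699, "ACAT", "A")] = AnnotationBundle(
        frequencies={"Saudi": 0.0, "Qatari": 0.0},
        scores={},
        expression_tpm=1.22,
    )
    table.bundles[("14", 92953131, "A", "G")] = AnnotationBundle(
        frequencies={"Saudi": 0.0, "Qatari": 0.00325},
        scores={"CADD": 4.68, "spliceAI": 0.17, "dbscSNV_Ada": 0.005},
        expression_tpm=0.20,
    )
    table.bundles[("17", 19459316, "G", "A")] = AnnotationBundle(
        frequencies={"Saudi": 0.026, "Qatari": 0.006},
        scores={"SIFT": 0.83, "CADD": 22.0, "PolyPhen": 0.73},
        expression_tpm=7.45,
    )
    return table


def internal_frequencies() -> Dict[tuple, float]:
    """Internal-cohort allele frequencies (het/2 + hom); the splice-region
    candidate was not observed internally and is therefore absent."""
    return {
        ("5", 73048875, "A", "G"): 0.0057 / 2 + 0.0006,
        ("17", 18661699, "ACAT", "A"): 0.0128 / 2,
        ("17", 19459316, "G", "A"): 0.0147 / 2 + 0.0006,
    }


def _single(chrom, pos, ref, alt, gene, call, consequence="missense_variant"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, genotypes={TUMOR_DONOR: call},
    )


def somatic_fixture() -> Tuple[List[VariantRecord], List[VariantRecord]]:
    """(tumor_records, germline_records) for the tumor donor.

    The tumor set holds the two true somatic candidates plus 20 decoys:
    eight shared with the germline, six common in the population, and
    six rare hits in non-panel genes.
    """
    tumor: List[VariantRecord] = [
        _single("19", 44047825, "A", "C", "XRCC1", _E),
        _single("11", 533875, "C", "A", "HRAS", _E),
    ]
    germline: List[VariantRecord] = [
        _single("19", 44047825, "A", "C", "XRCC1", _R),
        _single("11", 533875, "C", "A", "HRAS", _R),
    ]
    # decoys shared with the germline (subtracted away)
    shared_genes = ["APC", "NF1", "RB1", "VHL", "WT1", "MEN1", "RET", "ALK"]
    for i, gene in enumerate(shared_genes):
        site = ("2", 10_000_000 + i * 1000, "G", "T", gene)
        tumor.append(_single(*site, _E))
        germline.append(_single(*site, _E))
    # tumor-only but common decoys (fail the 5% frequency screen);
    # two sit in panel genes to show the frequency filter acts first
    common_genes = ["TP53", "BRAF", "EGFR", "KIT", "MET", "ROS1"]
    for i, gene in enumerate(common_genes):
        site = ("7", 20_000_000 + i * 1000, "C", "T", gene)
        tumor.append(_single(*site, _E))
        germline.append(_single(*site, _R))
    # tumor-only, rare, but in non-panel genes (fail the panel screen)
    nonpanel_genes = ["TTN", "OBSCN", "MUC16", "SYNE1", "NEB", "PCLO"]
    for i, gene in enumerate(nonpanel_genes):
        site = ("12", 30_000_000 + i * 1000, "A", "T", gene)
        tumor.append(_single(*site, _E))
        germline.append(_single(*site, _R))
    return tumor, germline


def somatic_annotations() -> AnnotationTable:
    """Population frequencies for the somatic fixture: common decoys at
    10%, the repair-gene candidate at 4%, everything else absent."""
    table = AnnotationTable(dbs={"1KG", "EVS", "ExAC", "gnomAD"})
    tumor, _ = somatic_fixture()
    common_genes = {"TP53", "BRAF", "EGFR", "KIT", "MET", "ROS1"}
    for rec in tumor:
        if rec.gene in common_genes:
            table.bundles[rec.key] = AnnotationBundle(
                frequencies={"gnomAD": 0.10, "ExAC": 0.10}
            )
        elif rec.gene == "XRCC1":
            table.bundles[rec.key] = AnnotationBundle(
                frequencies={"gnomAD": 0.04}
            )
        else:
            table.bundles[rec.key] = AnnotationBundle()
    return table


def interaction_fixture() -> InteractionGraph:
    """Curated interaction neighbourhood of the candidate genes."""
    graph = InteractionGraph()
    graph.add_edge("ARHGEF28", "SQSTM1", "affinity_chromatography")
    graph.add_edge("SQSTM1", "TP53", "affinity_capture;reconstituted_complex")
    graph.add_edge("ARHGEF28", "MYH9", "crosslinking_ms")
    graph.add_edge("MYH9", "PTCSC2", "binding")
    graph.add_edge("PTCSC2", "FOXE1", "regulation")
    return graph


def linkage_inputs() -> Tuple[Pedigree, Dict[str, GenotypeCall], float]:
    """(pedigree, marker genotypes, marker allele frequency) for the
    two-branch linkage run on the observed genotype matrix, using the
    primary candidate as the marker and its internal-cohort allele
    frequency."""
    pedigree = kindred_pedigree()
    record = kindred_genotype_matrix()[0]
    marker_freq = internal_frequencies()[record.key]
    return pedigree, dict(record.genotypes), marker_freq


def recruitment_linkage_inputs() -> Tuple[Pedigree, Dict[str, GenotypeCall], float]:
    """Inputs for the family-informativeness (recruitment-time) LOD: a
    fully informative marker cosegregating with disease across every
    phenotype-known member — affected members heterozygous (the known
    homozygous carrier kept homozygous), unaffected members homozygous
    reference. This measures the two-point LOD the family can provide
    under the dominant 90%-penetrance model, which is how the published
    figure was quoted; only 11 members were genotyped for the actual
    candidates (see ``linkage_inputs``)."""
    pedigree = kindred_pedigree()
    marker_freq = internal_frequencies()[kindred_genotype_matrix()[0].key]
    genotypes: Dict[str, GenotypeCall] = {}
    for ind in pedigree:
        if ind.phenotype is Phenotype.AFFECTED:
            genotypes[ind.id] = GenotypeCall.HET
        elif ind.phenotype is Phenotype.UNAFFECTED:
            genotypes[ind.id] = GenotypeCall.HOM_REF
    genotypes["XFIII5"] = GenotypeCall.HOM_ALT
    return pedigree, genotypes, marker_freq
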
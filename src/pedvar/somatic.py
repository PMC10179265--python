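"""Tumor-normal subtraction cascade and second-hit scanning.

Calls are genotype-level (no allele fractions). Subtraction keeps tumor
variants whose matched germline call is homozygous reference; a site
with an explicitly missing germline call is dropped by default
(coverage gaps must not masquerade as somatic events), while a site
entirely absent from a variant-only germline call set is treated as
homozygous reference. Both behaviours are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .germline import filter_population_frequency
from .types import (
    AnnotationTable,
    FilterTrace,
    GenotypeCall,
    VariantRecord,
)

__all__ = [
    "SomaticCandidate",
    "SecondHitReport",
    "subtract_germline",
    "filter_somatic_frequency",
    "apply_panel",
    "second_hit_scan",
    "run_somatic_cascade",
    "SomaticCascadeResult",
    "DEFAULT_SUSCEPTIBILITY_PANEL",
]

# Susceptibility genes assembled from the main-text germline literature;
# the published appendix panel is not available.
DEFAULT_SUSCEPTIBILITY_PANEL: Tuple[str, ...] = (
    "NKX2.1",
    "FOXE1",
    "HABP2",
    "RTFC",
    "MYH9",
    "CHEK2",
    "MYO1F",
    "DICER1",
    "SRRM2",
    "MAP2K5",
    "SPRY4",
    "RASAL1",
    "SRGAP1",
    "BRCA1",
    "BRCA2",
    "ATM",
    "XRCC1",
    "PAX8",
    "HHEX",
)


@dataclass
class SomaticCandidate:
    record: VariantRecord
    germline_genotype: GenotypeCall
    panel_hit: str  # "somatic_panel" | "susceptibility_panel" | "none"

    def __post_init__(self) -> None:
        if self.panel_hit not in ("somatic_panel", "susceptibility_panel", "none"):
            raise ValueError(f"unknown panel_hit: {self.panel_hit}")
        if self.germline_genotype is not GenotypeCall.HOM_REF:
            raise ValueError("somatic candidate requires hom-ref germline genotype")


@dataclass
class SecondHitReport:
    gene: str
    homozygous_hits: List[tuple] = field(default_factory=list)
    heterozygous_hits: List[tuple] = field(default_factory=list)
    compound_het_pairs: List[Tuple[tuple, tuple]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (
            self.homozygous_hits or self.heterozygous_hits or self.compound_het_pairs
        )


def _single_sample_id(records: Sequence[VariantRecord]) -> Optional[str]:
    ids: Set[str] = set()
    for rec in records:
        ids.update(rec.genotypes)
    if len(ids) > 1:
        raise ValueError(f"expected single-sample call set, got samples {sorted(ids)}")
    return next(iter(ids)) if ids else None


def subtract_germline(
    tumor_records: Sequence[VariantRecord],
    germline_records: Sequence[VariantRecord],
    exclude_germline_missing: bool = True,
) -> List[VariantRecord]:
    """Keep tumor variants absent from the matched germline calls.

    A tumor record survives when it carries at least one alternate allele
    and the germline genotype at the same (chrom, pos, ref, alt) is
    hom-ref. Sites with an explicit missing germline call are excluded
    when ``exclude_germline_missing`` (the default); sites not present in
    the germline call set at all count as hom-ref.
    """
    tumor_sample = _single_sample_id(tumor_records)
    germline_sample = _single_sample_id(germline_records)
    if (
        tumor_sample is not None
        and germline_sample is not None
        and tumor_sample != germline_sample
    ):
        raise ValueError(
            f"sample-id mismatch: tumor {tumor_sample!r} vs germline {germline_sample!r}"
        )
    germline_by_key = {rec.key: rec for rec in germline_records}
    out = []
    for rec in tumor_records:
        call = rec.genotype(tumor_sample) if tumor_sample else GenotypeCall.MISSING
        if not call.is_carrier:
            continue
        germ = germline_by_key.get(rec.key)
        if germ is None:
            out.append(rec)
            continue
        germ_call = germ.genotype(germline_sample) if germline_sample else GenotypeCall.MISSING
        if germ_call is GenotypeCall.MISSING:
            if not exclude_germline_missing:
                out.append(rec)
            continue
        if germ_call is GenotypeCall.HOM_REF:
            out.append(rec)
    return out


def filter_somatic_frequency(
    records: Sequence[VariantRecord],
    annotations: AnnotationTable,
    dbs: Sequence[str],
    threshold: float = 0.05,
) -> List[VariantRecord]:
    """Population-frequency filter at the somatic (5%) threshold."""
    return filter_population_frequency(records, annotations, dbs, threshold)


def apply_panel(
    records: Sequence[VariantRecord],
    somatic_panel: Iterable[str],
    susceptibility_panel: Iterable[str] = DEFAULT_SUSCEPTIBILITY_PANEL,
) -> List[SomaticCandidate]:
    """Restrict to panel genes; label each survivor with its panel.

    Membership is by gene symbol only. A gene in both panels is labelled
    as a somatic-panel hit.
    """
    somatic_set = set(somatic_panel)
    susceptibility_set = set(susceptibility_panel)
    if not somatic_set and not susceptibility_set:
        raise ValueError("empty panel")
    out = []
    for rec in records:
        if rec.gene in somatic_set:
            hit = "somatic_panel"
        elif rec.gene in susceptibility_set:
            hit = "susceptibility_panel"
        else:
            continue
        out.append(
            SomaticCandidate(
                record=rec, germline_genotype=GenotypeCall.HOM_REF, panel_hit=hit
            )
        )
    return out


def second_hit_scan(
    tumor_only_records: Sequence[VariantRecord],
    candidate_genes: Sequence[str],
) -> List[SecondHitReport]:
    """Per candidate gene, list tumor-only hits by zygosity and enumerate
    distinct het pairs as potential compound heterozygotes."""
    sample = _single_sample_id(tumor_only_records)
    reports = []
    for gene in candidate_genes:
        gene_records = [rec for rec in tumor_only_records if rec.gene == gene]
        homs = []
        hets = []
        for rec in gene_records:
            call = rec.genotype(sample) if sample else GenotypeCall.MISSING
            if call is GenotypeCall.HOM_ALT:
                homs.append(rec.key)
            elif call is GenotypeCall.HET:
                hets.append(rec.key)
        pairs = list(combinations(sorted(hets), 2))
        reports.append(
            SecondHitReport(
                gene=gene,
                homozygous_hits=sorted(homs),
                heterozygous_hits=sorted(hets),
                compound_het_pairs=pairs,
            )
        )
    return reports


@dataclass
class SomaticCascadeResult:
    candidates: List[SomaticCandidate]
    trace: FilterTrace
    second_hits: List[SecondHitReport]


def run_somatic_cascade(
    tumor_records: Sequence[VariantRecord],
    germline_records: Sequence[VariantRecord],
    annotations: AnnotationTable,
    somatic_panel: Iterable[str],
    susceptibility_panel: Iterable[str] = DEFAULT_SUSCEPTIBILITY_PANEL,
    dbs: Sequence[str] = ("1KG", "EVS", "ExAC", "gnomAD"),
    threshold: float = 0.05,
    candidate_genes: Sequence[str] = (),
) -> SomaticCascadeResult:
    """Tumor-minus-germline subtraction, <threshold frequency filter, and
    panel restriction, with an optional second-hit scan over candidate
    genes. Trace mirrors the three cascade stages."""
    trace = FilterTrace()
    n0 = len(tumor_records)

    tumor_only = subtract_germline(tumor_records, germline_records)
    trace.add("tumor_minus_germline", n0, len(tumor_only))

    rare = filter_somatic_frequency(tumor_only, annotations, dbs, threshold)
    trace.add("population_frequency", len(tumor_only), len(rare))

    candidates = apply_panel(rare, somatic_panel, susceptibility_panel)
    trace.add("panel_restriction", len(rare), len(candidates))

    second_hits = second_hit_scan(tumor_only, candidate_genes)
    return SomaticCascadeResult(
        candidates=candidates, trace=trace, second_hits=second_hits
    )
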
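"""Germline candidate filter cascade and annotation-based tiering.

The cascade retains variants that are (1) shared by a designated carrier
set, (2) rare in every public frequency database, (3) rare in the
internal cohort, and (4) compatible with at least one inheritance model
on the family. Survivors are then tiered: splice-region variants that
every splice predictor calls benign are excluded, and the remainder are
split into primary/secondary candidates by tissue expression.

Frequency semantics: a database with no entry for a variant counts as
0.0 at filter time ("not observed"), while storage keeps the entry
absent. Thresholds are exclusive: a variant survives a database when its
frequency is strictly below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .segregation import InheritanceModel, SegregationResult, segregation_filter
from .types import (
    AnnotationTable,
    FilterTrace,
    Pedigree,
    TierLabel,
    VariantRecord,
)

__all__ = [
    "SpliceRules",
    "GermlineConfig",
    "CascadeResult",
    "intersect_shared",
    "filter_population_frequency",
    "filter_internal_cohort",
    "tier_candidates",
    "run_germline_cascade",
    "DEFAULT_DBS",
]

DEFAULT_DBS: Tuple[str, ...] = ("1KG", "EVS", "ExAC", "gnomAD")


@dataclass(frozen=True)
class SpliceRules:
    """Benign-call thresholds for splice predictors (both must agree)."""

    spliceai_benign: float = 0.2
    ada_benign: float = 0.6


@dataclass
class GermlineConfig:
    carriers: Sequence[str]
    dbs: Sequence[str] = DEFAULT_DBS
    pop_threshold: float = 0.01
    internal_threshold: float = 0.01
    splice_rules: SpliceRules = field(default_factory=SpliceRules)
    tpm_threshold: float = 10.0
    models: Sequence[InheritanceModel] = field(
        default_factory=lambda: (
            InheritanceModel("dominant", allow_incomplete_penetrance=True),
        )
    )


@dataclass
class CascadeResult:
    records: List[VariantRecord]
    tiers: Dict[tuple, TierLabel]
    trace: FilterTrace
    segregation: Dict[tuple, List[SegregationResult]]


def intersect_shared(
    records: Sequence[VariantRecord],
    carrier_ids: Sequence[str],
    pedigree: Optional[Pedigree] = None,
) -> List[VariantRecord]:
    """Retain variants carried (het or hom-alt) by every listed individual.

    A missing genotype in any carrier fails the record. When a pedigree
    is supplied, carrier ids must refer to sequenced members.
    """
    if not carrier_ids:
        raise ValueError("carrier_ids must be nonempty")
    if pedigree is not None:
        for cid in carrier_ids:
            ind = pedigree.get(cid)
            if ind is None or not ind.sequenced:
                raise ValueError(f"carrier id not sequenced: {cid}")
    return [
        rec
        for rec in records
        if all(rec.genotype(cid).is_carrier for cid in carrier_ids)
    ]


def _passes_frequency(
    rec: VariantRecord,
    annotations: AnnotationTable,
    dbs: Sequence[str],
    threshold: float,
) -> bool:
    bundle = annotations.get(rec.key)
    return all(bundle.frequencies.get(db, 0.0) < threshold for db in dbs)


def filter_population_frequency(
    records: Sequence[VariantRecord],
    annotations: AnnotationTable,
    dbs: Sequence[str] = DEFAULT_DBS,
    threshold: float = 0.01,
) -> List[VariantRecord]:
    """Retain variants strictly below ``threshold`` in every listed database."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    unknown = set(dbs) - set(annotations.dbs)
    if unknown and annotations.dbs:
        raise ValueError(f"unknown db name(s): {', '.join(sorted(unknown))}")
    return [
        rec
        for rec in records
        if _passes_frequency(rec, annotations, dbs, threshold)
    ]


def filter_internal_cohort(
    records: Sequence[VariantRecord],
    internal_freqs: Dict[tuple, float],
    threshold: float = 0.01,
) -> List[VariantRecord]:
    """Retain variants strictly below ``threshold`` in the internal cohort.

    ``internal_freqs`` maps variant key -> allele frequency; absent keys
    count as unobserved (0.0).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    return [
        rec for rec in records if internal_freqs.get(rec.key, 0.0) < threshold
    ]


def tier_candidates(
    records: Sequence[VariantRecord],
    annotations: AnnotationTable,
    splice_rules: SpliceRules = SpliceRules(),
    tpm_threshold: float = 10.0,
) -> Dict[tuple, TierLabel]:
    """Assign primary/secondary/excluded tiers from annotations.

    A splice-region variant whose spliceAI score is below
    ``splice_rules.spliceai_benign`` AND whose dbscSNV-Ada score is below
    ``splice_rules.ada_benign`` is excluded as splice-benign. Retained
    variants with expression at or above ``tpm_threshold`` TPM are
    primary, the rest secondary. Missing annotation never excludes a
    variant; it is noted in the tier reason.
    """
    tiers: Dict[tuple, TierLabel] = {}
    for rec in records:
        bundle = annotations.get(rec.key)
        notes: List[str] = []
        if "splice" in rec.consequence.lower():
            spliceai = bundle.scores.get("spliceAI")
            ada = bundle.scores.get("dbscSNV_Ada")
            if spliceai is not None and ada is not None:
                if spliceai < splice_rules.spliceai_benign and ada < splice_rules.ada_benign:
                    tiers[rec.key] = TierLabel(
                        "excluded",
                        "splice_benign: spliceAI "
                        f"{spliceai} < {splice_rules.spliceai_benign} and "
                        f"dbscSNV_Ada {ada} < {splice_rules.ada_benign}",
                    )
                    continue
            else:
                notes.append("splice scores missing; splice-benign rule not fired")
        tpm = bundle.expression_tpm
        if tpm is None:
            notes.append("expression TPM missing")
            tiers[rec.key] = TierLabel("secondary", "; ".join(notes))
        elif tpm >= tpm_threshold:
            notes.append(f"expression {tpm} TPM >= {tpm_threshold}")
            tiers[rec.key] = TierLabel("primary", "; ".join(notes))
        else:
            notes.append(f"expression {tpm} TPM < {tpm_threshold}")
            tiers[rec.key] = TierLabel("secondary", "; ".join(notes))
    return tiers


def run_germline_cascade(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    annotations: AnnotationTable,
    internal_freqs: Dict[tuple, float],
    config: GermlineConfig,
) -> CascadeResult:
    """Run the four-stage germline cascade and tier the survivors.

    Stages (in order): shared-carrier intersection, population-frequency
    filter, internal-cohort filter, familial segregation. The returned
    trace chains the four stage counts; tiers cover segregation survivors
    only.
    """
    trace = FilterTrace()
    n0 = len(records)

    shared = intersect_shared(records, config.carriers, pedigree)
    trace.add("shared_carriers", n0, len(shared))

    rare_pop = filter_population_frequency(
        shared, annotations, config.dbs, config.pop_threshold
    )
    trace.add("population_frequency", len(shared), len(rare_pop))

    rare_internal = filter_internal_cohort(
        rare_pop, internal_freqs, config.internal_threshold
    )
    trace.add("internal_cohort_frequency", len(rare_pop), len(rare_internal))

    survivors, seg_results, seg_trace = segregation_filter(
        rare_internal, pedigree, config.models
    )
    stage = seg_trace.stages[0]
    trace.add(stage.name, stage.count_in, stage.count_out)

    tiers = tier_candidates(
        survivors, annotations, config.splice_rules, config.tpm_threshold
    )
    return CascadeResult(
        records=survivors, tiers=tiers, trace=trace, segregation=seg_results
    )
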
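"""Segregation-compatibility classification.

Verdicts are deterministic genotype/phenotype checks, not likelihoods:

* dominant — every genotyped affected member must carry at least one
  alternate allele (homozygous carriers count as carriers); unaffected
  carriers are tolerated as non-penetrant only when incomplete
  penetrance is allowed.
* recessive — every genotyped affected member must be homozygous for
  the alternate allele; unaffected homozygotes violate. A
  pseudo-dominant flag records that affected members may appear in
  successive generations (carrier-by-descent matings); it grants no
  genotype exemption, and a homozygous affected child of a genotyped
  homozygous-reference parent is always a Mendelian violation.

Phenotype-unknown members contribute no evidence in either direction;
missing genotypes likewise contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from .types import (
    FilterTrace,
    GenotypeCall,
    Pedigree,
    Phenotype,
    VariantRecord,
)

__all__ = [
    "InheritanceModel",
    "SegregationResult",
    "SegregationError",
    "classify_dominant",
    "classify_recessive",
    "classify",
    "check_mendelian",
    "segregation_filter",
]


class SegregationError(ValueError):
    """Raised when a classification cannot be performed."""


@dataclass(frozen=True)
class InheritanceModel:
    mode: str  # "dominant" | "recessive"
    allow_incomplete_penetrance: bool = False
    allow_pseudo_dominant: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.allow_pseudo_dominant and self.mode != "recessive":
            raise ValueError("pseudo_dominant requires recessive mode")

    @property
    def label(self) -> str:
        parts = [self.mode]
        if self.allow_incomplete_penetrance:
            parts.append("incomplete_penetrance")
        if self.allow_pseudo_dominant:
            parts.append("pseudo_dominant")
        return "+".join(parts)


@dataclass
class SegregationResult:
    variant: VariantRecord
    model: InheritanceModel
    compatible: bool
    non_penetrant_carriers: List[str] = field(default_factory=list)
    violators: List[str] = field(default_factory=list)
    n_informative: int = 0

    def __post_init__(self) -> None:
        if self.compatible and self.violators:
            raise ValueError("compatible result cannot list violators")


def _genotyped_members(variant: VariantRecord, pedigree: Pedigree):
    for ind in pedigree:
        call = variant.genotype(ind.id)
        if call is not GenotypeCall.MISSING:
            yield ind, call


def _informative_count(variant: VariantRecord, pedigree: Pedigree) -> int:
    return sum(
        1
        for ind, _ in _genotyped_members(variant, pedigree)
        if ind.phenotype is not Phenotype.UNKNOWN
    )


def classify_dominant(
    variant: VariantRecord,
    pedigree: Pedigree,
    allow_incomplete: bool = True,
) -> SegregationResult:
    """Check compatibility with an autosomal dominant model."""
    model = InheritanceModel("dominant", allow_incomplete_penetrance=allow_incomplete)
    violators: List[str] = []
    non_penetrant: List[str] = []
    n_affected_genotyped = 0
    for ind, call in _genotyped_members(variant, pedigree):
        if ind.phenotype is Phenotype.AFFECTED:
            n_affected_genotyped += 1
            if not call.is_carrier:
                violators.append(ind.id)
        elif ind.phenotype is Phenotype.UNAFFECTED and call.is_carrier:
            if allow_incomplete:
                non_penetrant.append(ind.id)
            else:
                violators.append(ind.id)
    if n_affected_genotyped == 0:
        raise SegregationError("no genotyped affected individual")
    return SegregationResult(
        variant=variant,
        model=model,
        compatible=not violators,
        non_penetrant_carriers=non_penetrant,
        violators=violators,
        n_informative=_informative_count(variant, pedigree),
    )


def classify_recessive(
    variant: VariantRecord,
    pedigree: Pedigree,
    allow_pseudo_dominant: bool = False,
) -> SegregationResult:
    """Check compatibility with an autosomal recessive model."""
    model = InheritanceModel(
        "recessive", allow_pseudo_dominant=allow_pseudo_dominant
    )
    violators: List[str] = []
    n_affected_genotyped = 0
    for ind, call in _genotyped_members(variant, pedigree):
        if ind.phenotype is Phenotype.AFFECTED:
            n_affected_genotyped += 1
            if call is not GenotypeCall.HOM_ALT:
                violators.append(ind.id)
        elif ind.phenotype is Phenotype.UNAFFECTED and call is GenotypeCall.HOM_ALT:
            violators.append(ind.id)
    if n_affected_genotyped == 0:
        raise SegregationError("no genotyped affected individual")
    # Transmission sanity: a hom-alt affected child cannot have a
    # genotyped hom-ref parent, pseudo-dominant or not.
    for ind in pedigree:
        if ind.phenotype is not Phenotype.AFFECTED:
            continue
        if variant.genotype(ind.id) is not GenotypeCall.HOM_ALT:
            continue
        for parent_id in (ind.father_id, ind.mother_id):
            if parent_id is None:
                continue
            if variant.genotype(parent_id) is GenotypeCall.HOM_REF:
                if parent_id not in violators:
                    violators.append(parent_id)
    return SegregationResult(
        variant=variant,
        model=model,
        compatible=not violators,
        non_penetrant_carriers=[],
        violators=violators,
        n_informative=_informative_count(variant, pedigree),
    )


def classify(
    variant: VariantRecord, pedigree: Pedigree, model: InheritanceModel
) -> SegregationResult:
    if model.mode == "dominant":
        return classify_dominant(
            variant, pedigree, allow_incomplete=model.allow_incomplete_penetrance
        )
    return classify_recessive(
        variant, pedigree, allow_pseudo_dominant=model.allow_pseudo_dominant
    )


_TRANSMITTED = {
    GenotypeCall.HOM_REF: (0,),
    GenotypeCall.HET: (0, 1),
    GenotypeCall.HOM_ALT: (1,),
}


@dataclass(frozen=True)
class MendelianViolation:
    child_id: str
    father_id: str
    mother_id: str
    child_call: GenotypeCall
    father_call: GenotypeCall
    mother_call: GenotypeCall


def check_mendelian(
    variant: VariantRecord, pedigree: Pedigree
) -> List[MendelianViolation]:
    """Flag fully genotyped trios whose genotype combination is impossible
    under biallelic Mendelian transmission."""
    violations = []
    for child, father, mother in pedigree.trios():
        c = variant.genotype(child.id)
        f = variant.genotype(father.id)
        m = variant.genotype(mother.id)
        if GenotypeCall.MISSING in (c, f, m):
            continue
        possible = {a + b for a, b in product(_TRANSMITTED[f], _TRANSMITTED[m])}
        if c.alt_count not in possible:
            violations.append(
                MendelianViolation(child.id, father.id, mother.id, c, f, m)
            )
    return violations


def segregation_filter(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    models: Sequence[InheritanceModel],
) -> Tuple[List[VariantRecord], Dict[tuple, List[SegregationResult]], "FilterTrace"]:
    """Keep records compatible with at least one supplied model.

    Returns the survivors, the per-record results (all models), and a
    one-stage FilterTrace.
    """
    if not models:
        raise SegregationError("empty model list")
    survivors: List[VariantRecord] = []
    results: Dict[tuple, List[SegregationResult]] = {}
    for rec in records:
        rec_results = [classify(rec, pedigree, model) for model in models]
        results[rec.key] = rec_results
        if any(r.compatible for r in rec_results):
            survivors.append(rec)
    trace = FilterTrace()
    trace.add("familial_segregation", len(records), len(survivors))
    return survivors, results, trace
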
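"""Two-point parametric linkage between a candidate variant (used as a
fully typed marker) and a disease phenotype on an arbitrary pedigree.

The likelihood sums over latent two-locus ordered genotypes — a
(disease allele, marker allele) haplotype of paternal and maternal
origin per individual — with founder haplotypes at Hardy-Weinberg /
linkage-equilibrium proportions, transmissions recombining at rate
theta, penetrance applied to the disease-genotype dose, and observed
marker calls treated as exact. The sum is evaluated exactly by variable
elimination over the pedigree's factor graph (peeling individuals
leaf-first by a min-degree order), which handles consanguineous loops
without explicit loop breakers. Likelihoods are rescaled after every
elimination, so results stay finite in log10 space.

Reported likelihoods are conditioned on the observed marker data:
``pedigree_likelihood`` returns log10 P(phenotypes | marker, model,
theta). The marker-only normalizer is theta-free (the disease locus
marginalizes out of pure marker transmission), so LOD scores are
unaffected by the normalization; it makes a lone phenotype-unknown
individual score exactly 0.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import GenotypeCall, Pedigree, Phenotype, VariantRecord

__all__ = [
    "DiseaseModel",
    "LinkageResult",
    "InconsistentDataError",
    "pedigree_likelihood",
    "two_point_lod",
]

N_HAPS = 4  # (disease allele in {0,1}) x (marker allele in {0,1})
N_STATES = 16  # ordered genotype: paternal haplotype x maternal haplotype


class InconsistentDataError(ValueError):
    """Marker data admit no valid genotype configuration."""


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease model: mode, penetrance by alt-allele dose,
    and population disease-allele frequency."""

    mode: str  # "dominant" | "recessive"
    penetrance: Tuple[float, float, float]
    disease_allele_freq: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown mode: {self.mode}")
        f0, f1, f2 = self.penetrance
        for f in self.penetrance:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"penetrance outside [0,1]: {f}")
        if not (f0 <= f1 <= f2):
            raise ValueError("penetrance must be monotone non-decreasing")
        if not (0.0 < self.disease_allele_freq < 1.0):
            raise ValueError(
                f"disease allele frequency outside (0,1): {self.disease_allele_freq}"
            )

    @classmethod
    def dominant(
        cls, penetrance: float, phenocopy: float = 0.0, disease_allele_freq: float = 0.001
    ) -> "DiseaseModel":
        return cls("dominant", (phenocopy, penetrance, penetrance), disease_allele_freq)

    @classmethod
    def recessive(
        cls, penetrance: float, phenocopy: float = 0.0, disease_allele_freq: float = 0.001
    ) -> "DiseaseModel":
        return cls("recessive", (phenocopy, phenocopy, penetrance), disease_allele_freq)


@dataclass(frozen=True)
class LinkageResult:
    lod: float
    log10_likelihood_linked: float
    log10_likelihood_unlinked: float
    theta: float

    @property
    def incompatible_at_theta(self) -> bool:
        return math.isinf(self.lod) and self.lod < 0


def _d_of(hap: int) -> int:
    return hap >> 1


def _m_of(hap: int) -> int:
    return hap & 1


def transmission_matrix(theta: float) -> np.ndarray:
    """T[parent_state, transmitted_hap]: probability the parent passes a
    given haplotype; intact haplotypes each at (1-theta)/2, recombinants
    each at theta/2."""
    T = np.zeros((N_STATES, N_HAPS))
    for g in range(N_STATES):
        hp, hm = divmod(g, N_HAPS)
        T[g, hp] += (1.0 - theta) / 2.0
        T[g, hm] += (1.0 - theta) / 2.0
        T[g, 2 * _d_of(hp) + _m_of(hm)] += theta / 2.0
        T[g, 2 * _d_of(hm) + _m_of(hp)] += theta / 2.0
    return T


def _founder_prior(q: float, p_marker: float) -> np.ndarray:
    pd = (1.0 - q, q)
    pm = (1.0 - p_marker, p_marker)
    hap = np.array([pd[_d_of(h)] * pm[_m_of(h)] for h in range(N_HAPS)])
    return np.outer(hap, hap).reshape(N_STATES)


def _penetrance_vector(phenotype: Phenotype, f: Tuple[float, float, float]) -> np.ndarray:
    vec = np.ones(N_STATES)
    if phenotype is Phenotype.UNKNOWN:
        return vec
    for g in range(N_STATES):
        hp, hm = divmod(g, N_HAPS)
        dose = _d_of(hp) + _d_of(hm)
        prob = f[dose]
        vec[g] = prob if phenotype is Phenotype.AFFECTED else 1.0 - prob
    return vec


def _marker_vector(call: GenotypeCall) -> np.ndarray:
    vec = np.ones(N_STATES)
    if call is GenotypeCall.MISSING:
        return vec
    want = call.alt_count
    for g in range(N_STATES):
        hp, hm = divmod(g, N_HAPS)
        vec[g] = 1.0 if _m_of(hp) + _m_of(hm) == want else 0.0
    return vec


@dataclass
class _Factor:
    vars: Tuple[str, ...]
    table: np.ndarray


def _eliminate_var(factors: List[_Factor], var: str) -> _Factor:
    """Sum-product elimination of one variable over its factor group."""
    out_vars: List[str] = []
    for f in factors:
        for v in f.vars:
            if v != var and v not in out_vars:
                out_vars.append(v)
    all_vars = out_vars + [var]
    letters = {v: string.ascii_letters[i] for i, v in enumerate(all_vars)}
    subs = ",".join("".join(letters[v] for v in f.vars) for f in factors)
    out_sub = "".join(letters[v] for v in out_vars)
    table = np.einsum(f"{subs}->{out_sub}", *[f.table for f in factors], optimize=True)
    return _Factor(tuple(out_vars), table)


def _elimination_order(factors: Sequence[_Factor], variables: Sequence[str]) -> List[str]:
    """Greedy min-degree order on the factor-scope interaction graph."""
    neighbors: Dict[str, set] = {v: set() for v in variables}
    for f in factors:
        for a in f.vars:
            for b in f.vars:
                if a != b:
                    neighbors[a].add(b)
    remaining = set(variables)
    order = []
    while remaining:
        var = min(remaining, key=lambda v: (len(neighbors[v] & remaining), v))
        order.append(var)
        live = neighbors[var] & remaining
        for a in live:  # connect the fill-in clique
            neighbors[a] |= live - {a}
        remaining.discard(var)
    return order


def _peel(factors: List[_Factor], variables: Sequence[str]) -> Optional[float]:
    """log10 of the total sum-product, or None when it is zero."""
    log10_total = 0.0
    factors = list(factors)
    for var in _elimination_order(factors, variables):
        group = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        merged = _eliminate_var(group, var)
        peak = merged.table.max() if merged.table.size else 0.0
        if peak <= 0.0:
            return None
        log10_total += math.log10(peak)
        merged.table = merged.table / peak
        factors.append(merged)
    for f in factors:  # zero-dimensional leftovers
        value = float(f.table)
        if value <= 0.0:
            return None
        log10_total += math.log10(value)
    return log10_total


def _augmented_families(pedigree: Pedigree):
    """(child, father, mother) with a synthetic untyped founder standing in
    when exactly one parent is recorded."""
    families = []
    synthetic = []
    for ind in pedigree:
        father, mother = ind.father_id, ind.mother_id
        if father is None and mother is None:
            continue
        if father is None:
            father = f"__founder_father_of_{ind.id}"
            synthetic.append(father)
        if mother is None:
            mother = f"__founder_mother_of_{ind.id}"
            synthetic.append(mother)
        families.append((ind.id, father, mother))
    return families, synthetic


def _build_factors(
    pedigree: Pedigree,
    genotypes: Dict[str, GenotypeCall],
    phenotypes: Dict[str, Phenotype],
    model: DiseaseModel,
    theta: float,
    marker_allele_freq: float,
    use_phenotypes: bool,
) -> Tuple[List[_Factor], List[str]]:
    families, synthetic = _augmented_families(pedigree)
    variables = list(pedigree.ids) + synthetic
    if len(variables) > len(string.ascii_letters):
        raise ValueError(
            f"pedigree too large for the elimination engine "
            f"({len(variables)} > {len(string.ascii_letters)} variables)"
        )
    prior = _founder_prior(model.disease_allele_freq, marker_allele_freq)
    T = transmission_matrix(theta)
    child_of = {child: (father, mother) for child, father, mother in families}
    factors: List[_Factor] = []
    for var in variables:
        unary = np.ones(N_STATES)
        if var not in child_of:
            unary = unary * prior
        call = genotypes.get(var, GenotypeCall.MISSING)
        unary = unary * _marker_vector(call)
        if use_phenotypes:
            pheno = phenotypes.get(var, Phenotype.UNKNOWN)
            unary = unary * _penetrance_vector(pheno, model.penetrance)
        factors.append(_Factor((var,), unary))
    for child, father, mother in families:
        # P(child_state | father_state, mother_state)
        trio = np.einsum("fp,mq->fmpq", T, T).reshape(N_STATES, N_STATES, N_STATES)
        factors.append(_Factor((father, mother, child), trio))
    return factors, variables


def pedigree_likelihood(
    pedigree: Pedigree,
    variant_genotypes: Dict[str, GenotypeCall],
    phenotypes: Optional[Dict[str, Phenotype]] = None,
    disease_model: DiseaseModel = DiseaseModel.dominant(0.9),
    theta: float = 0.0,
    marker_allele_freq: float = 0.01,
) -> float:
    """log10 P(phenotypes | marker data, model, theta).

    Returns ``-inf`` when the phenotypes are impossible given the marker
    data at this theta; raises InconsistentDataError when the marker data
    themselves admit no genotype configuration (e.g. a Mendelian
    violation at the marker).
    """
    if not (0.0 <= theta <= 0.5):
        raise ValueError(f"theta outside [0, 0.5]: {theta}")
    if phenotypes is None:
        phenotypes = {ind.id: ind.phenotype for ind in pedigree}
    factors, variables = _build_factors(
        pedigree, variant_genotypes, phenotypes, disease_model, theta,
        marker_allele_freq, use_phenotypes=True,
    )
    marker_factors, _ = _build_factors(
        pedigree, variant_genotypes, phenotypes, disease_model, theta,
        marker_allele_freq, use_phenotypes=False,
    )
    log_marker = _peel(marker_factors, variables)
    if log_marker is None:
        raise InconsistentDataError(
            "inconsistent data: marker genotypes admit no configuration"
        )
    log_joint = _peel(factors, variables)
    if log_joint is None:
        return float("-inf")
    return log_joint - log_marker


def two_point_lod(
    pedigree: Pedigree,
    variant: "VariantRecord | Dict[str, GenotypeCall]",
    disease_model: DiseaseModel = DiseaseModel.dominant(0.9),
    theta: float = 0.0,
    marker_allele_freq: float = 0.01,
    phenotypes: Optional[Dict[str, Phenotype]] = None,
) -> LinkageResult:
    """LOD(theta) = log10 L(theta) - log10 L(0.5).

    A ``-inf`` LOD marks data incompatible with full linkage at the
    requested theta (an obligate recombinant at theta=0).
    """
    genotypes = variant.genotypes if isinstance(variant, VariantRecord) else variant
    log_linked = pedigree_likelihood(
        pedigree, genotypes, phenotypes, disease_model, theta, marker_allele_freq
    )
    log_null = pedigree_likelihood(
        pedigree, genotypes, phenotypes, disease_model, 0.5, marker_allele_freq
    )
    if math.isinf(log_null):
        raise InconsistentDataError(
            "inconsistent data: phenotypes impossible even at theta = 0.5"
        )
    lod = log_linked - log_null
    return LinkageResult(
        lod=lod,
        log10_likelihood_linked=log_linked,
        log10_likelihood_unlinked=log_null,
        theta=theta,
    )
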
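"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (direct
rule statements, exhaustive enumeration) and shares no logic with the
implementation under test.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from pedvar.types import GenotypeCall, Pedigree, Phenotype

HOM_REF = GenotypeCall.HOM_REF
HET = GenotypeCall.HET
HOM_ALT = GenotypeCall.HOM_ALT
MISSING = GenotypeCall.MISSING


# ---------------------------------------------------------------------------
# segregation truth tables

def dominant_compatible(
    calls: Dict[str, GenotypeCall],
    phenotypes: Dict[str, Phenotype],
    allow_incomplete: bool,
) -> Optional[bool]:
    """Direct restatement of the dominant rule. None = undefined (no
    genotyped affected)."""
    affected_seen = False
    ok = True
    for iid, pheno in phenotypes.items():
        call = calls.get(iid, MISSING)
        if call is MISSING:
            continue
        if pheno is Phenotype.AFFECTED:
            affected_seen = True
            if call is HOM_REF:
                ok = False
        elif pheno is Phenotype.UNAFFECTED:
            if call in (HET, HOM_ALT) and not allow_incomplete:
                ok = False
    if not affected_seen:
        return None
    return ok


def recessive_compatible(
    calls: Dict[str, GenotypeCall],
    phenotypes: Dict[str, Phenotype],
    parents: Dict[str, Tuple[Optional[str], Optional[str]]],
) -> Optional[bool]:
    """Direct restatement of the recessive rule."""
    affected_seen = False
    ok = True
    for iid, pheno in phenotypes.items():
        call = calls.get(iid, MISSING)
        if call is MISSING:
            continue
        if pheno is Phenotype.AFFECTED:
            affected_seen = True
            if call is not HOM_ALT:
                ok = False
        elif pheno is Phenotype.UNAFFECTED:
            if call is HOM_ALT:
                ok = False
    if not affected_seen:
        return None
    # hom-alt affected child of a genotyped hom-ref parent is impossible
    for iid, pheno in phenotypes.items():
        if pheno is not Phenotype.AFFECTED:
            continue
        if calls.get(iid, MISSING) is not HOM_ALT:
            continue
        for parent in parents.get(iid, (None, None)):
            if parent is not None and calls.get(parent, MISSING) is HOM_REF:
                ok = False
    return ok


def trio_possible(
    father: GenotypeCall, mother: GenotypeCall, child: GenotypeCall
) -> bool:
    """Enumerate gamete combinations for a fully genotyped trio."""
    alleles = {HOM_REF: [(0, 0)], HET: [(0, 1)], HOM_ALT: [(1, 1)]}
    child_doses = set()
    for fa in alleles[father][0]:
        for mo in alleles[mother][0]:
            child_doses.add(fa + mo)
    return child.alt_count in child_doses


# ---------------------------------------------------------------------------
# somatic subtraction predicate

def somatic_retained(
    tumor: GenotypeCall,
    germline: Optional[GenotypeCall],
    exclude_germline_missing: bool = True,
) -> bool:
    """Per-site subtraction predicate; germline None = site not in the
    germline call set."""
    if tumor not in (HET, HOM_ALT):
        return False
    if germline is None:
        return True
    if germline is MISSING:
        return not exclude_germline_missing
    return germline is HOM_REF


# ---------------------------------------------------------------------------
# path enumeration

def all_simple_paths(
    adjacency: Dict[str, set],
    source: str,
    targets: set,
    max_edges: int,
) -> List[Tuple[str, ...]]:
    """Recursive enumeration of simple paths with <= max_edges edges that
    end on a target."""
    found: List[Tuple[str, ...]] = []
    if source in targets:
        found.append((source,))

    def walk(path: List[str]) -> None:
        if len(path) - 1 >= max_edges:
            return
        for nxt in sorted(adjacency.get(path[-1], ())):
            if nxt in path:
                continue
            if nxt in targets and nxt != source:
                found.append(tuple(path + [nxt]))
            walk(path + [nxt])

    if source in adjacency:
        walk([source])
    return sorted(set(found), key=lambda p: (len(p), p))


# ---------------------------------------------------------------------------
# two-locus pedigree likelihood by full enumeration

def _hap_d(h: int) -> int:
    return h // 2


def _hap_m(h: int) -> int:
    return h % 2


def _transmit_prob(parent_state: int, hap: int, theta: float) -> float:
    """Pick one of the parent's two strands uniformly; recombine between
    the loci with probability theta."""
    pat, mat = divmod(parent_state, 4)
    prob = 0.0
    for strand, other in ((pat, mat), (mat, pat)):
        no_rec = 2 * _hap_d(strand) + _hap_m(strand)
        rec = 2 * _hap_d(strand) + _hap_m(other)
        if hap == no_rec:
            prob += 0.5 * (1.0 - theta)
        if hap == rec:
            prob += 0.5 * theta
    return prob


def _marker_ok(state: int, call: GenotypeCall) -> bool:
    if call is MISSING:
        return True
    pat, mat = divmod(state, 4)
    return _hap_m(pat) + _hap_m(mat) == call.alt_count


def _pheno_prob(state: int, pheno: Phenotype, f: Sequence[float]) -> float:
    if pheno is Phenotype.UNKNOWN:
        return 1.0
    pat, mat = divmod(state, 4)
    p_affected = f[_hap_d(pat) + _hap_d(mat)]
    return p_affected if pheno is Phenotype.AFFECTED else 1.0 - p_affected


def _founder_state_prob(state: int, q: float, p_marker: float) -> float:
    pat, mat = divmod(state, 4)
    prob = 1.0
    for hap in (pat, mat):
        prob *= (q if _hap_d(hap) else 1.0 - q) * (
            p_marker if _hap_m(hap) else 1.0 - p_marker
        )
    return prob


def enumerate_joint(
    pedigree: Pedigree,
    genotypes: Dict[str, GenotypeCall],
    phenotypes: Dict[str, Phenotype],
    penetrance: Sequence[float],
    q: float,
    theta: float,
    p_marker: float,
    use_phenotypes: bool,
    max_cells: int = 20_000_000,
) -> float:
    """Sum the full joint over every marker-consistent ordered two-locus
    genotype assignment. Builds the complete outer-product tensor, so it
    is exponential by construction."""
    ids = [ind.id for ind in pedigree]
    states = [
        [s for s in range(16) if _marker_ok(s, genotypes.get(i, MISSING))]
        for i in ids
    ]
    shape = [len(s) for s in states]
    n_cells = math.prod(shape)
    if n_cells > max_cells:
        raise MemoryError(f"enumeration too large: {n_cells} cells")
    joint = np.ones(shape)
    index_of = {iid: axis for axis, iid in enumerate(ids)}

    for axis, ind in enumerate(pedigree):
        unary = np.ones(len(states[axis]))
        for k, s in enumerate(states[axis]):
            if ind.father_id is None and ind.mother_id is None:
                unary[k] *= _founder_state_prob(s, q, p_marker)
            if use_phenotypes:
                unary[k] *= _pheno_prob(
                    s, phenotypes.get(ind.id, Phenotype.UNKNOWN), penetrance
                )
        expand = [np.newaxis] * len(ids)
        expand[axis] = slice(None)
        joint *= unary[tuple(expand)]

    for ind in pedigree:
        if ind.father_id is None and ind.mother_id is None:
            continue
        if ind.father_id is None or ind.mother_id is None:
            raise ValueError("enumeration oracle needs both parents or none")
        fa, ma, ca = index_of[ind.father_id], index_of[ind.mother_id], index_of[ind.id]
        table = np.zeros((len(states[fa]), len(states[ma]), len(states[ca])))
        for i, fs in enumerate(states[fa]):
            for j, ms in enumerate(states[ma]):
                for k, cs in enumerate(states[ca]):
                    pat, mat = divmod(cs, 4)
                    table[i, j, k] = _transmit_prob(fs, pat, theta) * _transmit_prob(
                        ms, mat, theta
                    )
        axes = sorted([(fa, 0), (ma, 1), (ca, 2)])
        perm = [pair[1] for pair in axes]
        expand = [np.newaxis] * len(ids)
        for target_axis, _src in axes:
            expand[target_axis] = slice(None)
        joint *= table.transpose(*perm)[tuple(expand)]
    return float(joint.sum())


def enumeration_log10_conditional(
    pedigree: Pedigree,
    genotypes: Dict[str, GenotypeCall],
    phenotypes: Dict[str, Phenotype],
    penetrance: Sequence[float],
    q: float,
    theta: float,
    p_marker: float,
) -> Optional[float]:
    """log10 P(phenotypes | marker data) by exhaustive summation, or None
    when the phenotypes are impossible. Raises ZeroDivisionError when the
    marker data themselves are impossible."""
    joint = enumerate_joint(
        pedigree, genotypes, phenotypes, penetrance, q, theta, p_marker, True
    )
    marker = enumerate_joint(
        pedigree, genotypes, phenotypes, penetrance, q, theta, p_marker, False
    )
    if marker <= 0.0:
        raise ZeroDivisionError("marker data impossible")
    if joint <= 0.0:
        return None
    return math.log10(joint) - math.log10(marker)
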
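from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
import pytest

from pedvar import examples
from pedvar.types import (
    GenotypeCall,
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    VariantRecord,
)

HOM_REF = GenotypeCall.HOM_REF
HET = GenotypeCall.HET
HOM_ALT = GenotypeCall.HOM_ALT
MISSING = GenotypeCall.MISSING


@pytest.fixture(scope="session")
def kindred():
    return examples.kindred_pedigree()


@pytest.fixture(scope="session")
def matrix():
    return examples.kindred_genotype_matrix()


def make_pedigree(rows) -> Pedigree:
    """rows: (id, father, mother, phenotype) tuples; phenotype in 'AHU'."""
    pheno = {"A": Phenotype.AFFECTED, "H": Phenotype.UNAFFECTED, "U": Phenotype.UNKNOWN}
    return Pedigree(
        Individual(
            id=iid, father_id=fa, mother_id=mo, phenotype=pheno[p],
            sequenced=True, sampled=True,
        )
        for iid, fa, mo, p in rows
    )


@pytest.fixture(scope="session")
def five_member_pedigree():
    """Founder couple with three children; phenotypes A, A, H, H, U."""
    return make_pedigree(
        [
            ("F", None, None, "A"),
            ("M", None, None, "H"),
            ("C1", "F", "M", "A"),
            ("C2", "F", "M", "H"),
            ("C3", "F", "M", "U"),
        ]
    )


def variant_with(calls: Dict[str, GenotypeCall], **kwargs) -> VariantRecord:
    defaults = dict(chrom="1", pos=100, ref="A", alt="G", gene="GENE1")
    defaults.update(kwargs)
    return VariantRecord(genotypes=calls, **defaults)


def random_lod_case(rng: np.random.Generator):
    """A random 4-8 member pedigree with marker genotypes produced by an
    explicit allele drop (guaranteeing marker consistency) and random
    phenotypes; at most one genotype is masked to keep the enumeration
    oracle tractable."""
    n_children = int(rng.integers(2, 5))
    rows = [("F", None, None), ("M", None, None)]
    for i in range(n_children):
        rows.append((f"C{i}", "F", "M"))
    if rng.random() < 0.5 and len(rows) <= 6:
        rows.append(("S", None, None))
        rows.append(("G0", "C0", "S"))
        if len(rows) < 8 and rng.random() < 0.5:
            rows.append(("G1", "C0", "S"))
    p_marker = float(rng.uniform(0.05, 0.4))
    alleles: Dict[str, Tuple[int, int]] = {}
    for iid, fa, mo in rows:
        if fa is None:
            alleles[iid] = (
                int(rng.random() < p_marker),
                int(rng.random() < p_marker),
            )
        else:
            alleles[iid] = (
                alleles[fa][int(rng.integers(0, 2))],
                alleles[mo][int(rng.integers(0, 2))],
            )
    calls = {
        iid: (HOM_REF, HET, HOM_ALT)[sum(pair)] for iid, pair in alleles.items()
    }
    ids = [r[0] for r in rows]
    if rng.random() < 0.4:
        calls[ids[int(rng.integers(0, len(ids)))]] = MISSING
    phenotypes = {
        iid: (Phenotype.AFFECTED, Phenotype.UNAFFECTED, Phenotype.UNKNOWN)[
            int(rng.integers(0, 3))
        ]
        for iid in ids
    }
    pedigree = Pedigree(
        Individual(id=iid, father_id=fa, mother_id=mo, phenotype=phenotypes[iid])
        for iid, fa, mo in rows
    )
    penetrance = (
        float(rng.uniform(0.0, 0.1)),
        float(rng.uniform(0.5, 1.0)),
        float(rng.uniform(0.5, 1.0)),
    )
    penetrance = tuple(sorted(penetrance))
    q = float(rng.uniform(0.001, 0.1))
    theta = float(rng.choice([0.0, 0.01, 0.1, 0.3, 0.5]))
    return pedigree, calls, phenotypes, penetrance, q, theta, p_marker


def phase_known_dominant_family(n_children: int, child_pattern=None):
    """Grandparent-phased fully penetrant dominant family with
    ``n_children`` informative non-recombinant meioses.

    Grandfather affected marker alt/alt, grandmother unaffected ref/ref,
    their affected het child married to an unaffected ref/ref spouse;
    each child is affected+het or unaffected+hom-ref.
    """
    rows = [
        ("GF", None, None, "A"),
        ("GM", None, None, "H"),
        ("P", "GF", "GM", "A"),
        ("S", None, None, "H"),
    ]
    calls = {"GF": HOM_ALT, "GM": HOM_REF, "P": HET, "S": HOM_REF}
    if child_pattern is None:
        child_pattern = ["carrier" if i % 2 == 0 else "clear" for i in range(n_children)]
    for i, kind in enumerate(child_pattern):
        iid = f"K{i}"
        rows.append((iid, "P", "S", "A" if kind == "carrier" else "H"))
        calls[iid] = HET if kind == "carrier" else HOM_REF
    return make_pedigree(rows), calls
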
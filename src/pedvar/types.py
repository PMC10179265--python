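"""Core in-memory data model: pedigrees, genotype calls, variant records,
annotation bundles, interaction graphs, and filter traces.

Coordinates are 1-based and refer to GRCh37 throughout; no liftover is
performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import networkx as nx

__all__ = [
    "Sex",
    "Phenotype",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "VariantRecord",
    "variant_key",
    "AnnotationBundle",
    "AnnotationTable",
    "InteractionGraph",
    "FilterStage",
    "FilterTrace",
    "TierLabel",
]


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


# Published genotype tables often use U+2212 MINUS SIGN; accept ASCII hyphen too.
_SYMBOL_TO_CALL = {
    "+/+": "hom_ref",
    "-/+": "het",
    "+/-": "het",
    "-/-": "hom_alt",
    "./.": "missing",
}

_GT_TO_CALL = {
    "0/0": "hom_ref",
    "0|0": "hom_ref",
    "0/1": "het",
    "1/0": "het",
    "0|1": "het",
    "1|0": "het",
    "1/1": "hom_alt",
    "1|1": "hom_alt",
    "./.": "missing",
    ".|.": "missing",
    ".": "missing",
}


class GenotypeCall(Enum):
    """Biallelic genotype call for one individual at one site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_count(self) -> Optional[int]:
        """Number of alternate alleles, or ``None`` when missing."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]

    @property
    def is_carrier(self) -> bool:
        """True when the call carries at least one alternate allele."""
        return self in (GenotypeCall.HET, GenotypeCall.HOM_ALT)

    @classmethod
    def from_vcf(cls, gt: str) -> "GenotypeCall":
        try:
            return cls(_GT_TO_CALL[gt.strip()])
        except KeyError:
            raise ValueError(f"malformed GT string: {gt!r}") from None

    def to_vcf(self) -> str:
        return {
            "hom_ref": "0/0",
            "het": "0/1",
            "hom_alt": "1/1",
            "missing": "./.",
        }[self.value]

    @classmethod
    def from_symbol(cls, symbol: str) -> "GenotypeCall":
        """Parse a matrix symbol (``+/+``, ``-/+``, ``-/-``)."""
        normalized = symbol.strip().replace("−", "-")
        try:
            return cls(_SYMBOL_TO_CALL[normalized])
        except KeyError:
            raise ValueError(f"unknown genotype symbol: {symbol!r}") from None

    def to_symbol(self) -> str:
        return {
            "hom_ref": "+/+",
            "het": "-/+",
            "hom_alt": "-/-",
            "missing": "./.",
        }[self.value]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate id, bad parent, cycle)."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN
    sequenced: bool = False
    sampled: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated family graph.

    Parent references must resolve to members (or be ``None``); the graph
    must be acyclic. Consanguineous loops (mating pairs with shared
    ancestors) are explicitly allowed.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: List[Individual] = list(individuals)
        if not self.individuals:
            raise PedigreeError("no individuals")
        self._by_id: Dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate id: {ind.id}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self._by_id:
                    raise PedigreeError(
                        f"unresolvable parent id {parent!r} for {ind.id!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self._by_id)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    graph.add_edge(parent, ind.id)
        if not nx.is_directed_acyclic_graph(graph):
            raise PedigreeError("cycle detected: an individual is its own ancestor")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def get(self, individual_id: str) -> Optional[Individual]:
        return self._by_id.get(individual_id)

    @property
    def ids(self) -> List[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> List[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def members_with_phenotype(self, phenotype: Phenotype) -> List[Individual]:
        return [ind for ind in self.individuals if ind.phenotype is phenotype]

    def affected(self) -> List[Individual]:
        return self.members_with_phenotype(Phenotype.AFFECTED)

    def unaffected(self) -> List[Individual]:
        return self.members_with_phenotype(Phenotype.UNAFFECTED)

    def children_of(self, individual_id: str) -> List[Individual]:
        return [
            ind
            for ind in self.individuals
            if individual_id in (ind.father_id, ind.mother_id)
        ]

    def trios(self) -> List[Tuple[Individual, Individual, Individual]]:
        """(child, father, mother) for every child with both parents present."""
        out = []
        for ind in self.individuals:
            if ind.father_id is not None and ind.mother_id is not None:
                out.append((ind, self[ind.father_id], self[ind.mother_id]))
        return out

    def topological_order(self) -> List[Individual]:
        graph = nx.DiGraph()
        graph.add_nodes_from(self._by_id)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    graph.add_edge(parent, ind.id)
        return [self[i] for i in nx.topological_sort(graph)]

    def with_phenotypes(self, phenotypes: Dict[str, Phenotype]) -> "Pedigree":
        """Return a copy with the given phenotype overrides applied."""
        updated = []
        for ind in self.individuals:
            if ind.id in phenotypes:
                updated.append(
                    Individual(
                        id=ind.id,
                        father_id=ind.father_id,
                        mother_id=ind.mother_id,
                        sex=ind.sex,
                        phenotype=phenotypes[ind.id],
                        sequenced=ind.sequenced,
                        sampled=ind.sampled,
                    )
                )
            else:
                updated.append(ind)
        return Pedigree(updated)


VariantKey = Tuple[str, int, str, str]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    return (str(chrom), int(pos), ref, alt)


@dataclass
class VariantRecord:
    """One biallelic site with per-individual genotype calls.

    ``pos`` is 1-based (GRCh37). Records are normalized (minimal
    representation) and unique by ``(chrom, pos, ref, alt)`` within a cohort.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    genotypes: Dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, individual_id: str) -> GenotypeCall:
        return self.genotypes.get(individual_id, GenotypeCall.MISSING)

    def carriers(self) -> List[str]:
        return [i for i, g in self.genotypes.items() if g.is_carrier]


@dataclass
class AnnotationBundle:
    """Per-variant external annotations.

    Frequencies are allele frequencies in [0, 1]. A database absent from
    ``frequencies`` means "not observed"; it is distinct from an explicit
    0.0 entry and only treated as zero at filter time.
    """

    frequencies: Dict[str, float] = field(default_factory=dict)
    scores: Dict[str, float] = field(default_factory=dict)
    expression_tpm: Optional[float] = None

    def __post_init__(self) -> None:
        for db, freq in self.frequencies.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(f"frequency outside [0,1] for {db}: {freq}")
        if self.expression_tpm is not None and self.expression_tpm < 0:
            raise ValueError(f"negative expression TPM: {self.expression_tpm}")


@dataclass
class AnnotationTable:
    """Keyed collection of AnnotationBundles plus the declared column sets."""

    bundles: Dict[VariantKey, AnnotationBundle] = field(default_factory=dict)
    dbs: set = field(default_factory=set)
    score_names: set = field(default_factory=set)

    def get(self, key: VariantKey) -> AnnotationBundle:
        return self.bundles.get(key, AnnotationBundle())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.bundles


class InteractionGraph:
    """Undirected gene-interaction graph with evidence labels on edges."""

    def __init__(self) -> None:
        self._graph = nx.Graph()

    def add_edge(self, gene_a: str, gene_b: str, evidence: str = "") -> None:
        if gene_a == gene_b:
            raise ValueError(f"self-loop not allowed: {gene_a}")
        self._graph.add_edge(gene_a, gene_b, evidence=evidence)

    def has_edge(self, gene_a: str, gene_b: str) -> bool:
        return self._graph.has_edge(gene_a, gene_b)

    def evidence(self, gene_a: str, gene_b: str) -> str:
        return self._graph.edges[gene_a, gene_b]["evidence"]

    def neighbors(self, gene: str) -> List[str]:
        if gene not in self._graph:
            return []
        return sorted(self._graph.neighbors(gene))

    @property
    def genes(self) -> List[str]:
        return sorted(self._graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str, str]]:
        return sorted(
            (min(a, b), max(a, b), data["evidence"])
            for a, b, data in self._graph.edges(data=True)
        )

    def __len__(self) -> int:
        return self._graph.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        return self._graph


@dataclass(frozen=True)
class FilterStage:
    name: str
    count_in: int
    count_out: int


class FilterTrace:
    """Ordered before/after counts for a filter cascade.

    Invariants: ``count_out <= count_in`` within a stage, and the input
    count of each stage equals the output count of the previous one.
    """

    def __init__(self) -> None:
        self.stages: List[FilterStage] = []

    def add(self, name: str, count_in: int, count_out: int) -> None:
        if count_out > count_in:
            raise ValueError(
                f"stage {name!r}: count_out {count_out} > count_in {count_in}"
            )
        if self.stages and self.stages[-1].count_out != count_in:
            raise ValueError(
                f"stage {name!r}: count_in {count_in} does not chain from "
                f"previous count_out {self.stages[-1].count_out}"
            )
        self.stages.append(FilterStage(name, count_in, count_out))

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterator[FilterStage]:
        return iter(self.stages)

    def as_rows(self) -> List[Tuple[str, int, int]]:
        return [(s.name, s.count_in, s.count_out) for s in self.stages]

    def to_dict(self) -> List[Dict[str, object]]:
        return [
            {"name": s.name, "count_in": s.count_in, "count_out": s.count_out}
            for s in self.stages
        ]


@dataclass(frozen=True)
class TierLabel:
    """Candidate priority tier with the rule that produced it."""

    value: str  # "primary" | "secondary" | "excluded"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.value not in ("primary", "secondary", "excluded"):
            raise ValueError(f"unknown tier: {self.value}")
        if self.value == "excluded" and not self.reason:
            raise ValueError("excluded tier requires a reason")
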
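"""Synthetic cohorts: pedigree construction, gene-dropping, tumor
spiking, and an on-disk fixture suite.

Everything is driven by a single integer seed: sub-generators are
derived with fixed offsets so the full output is reproducible
byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import examples, io
from .linkage import DiseaseModel
from .types import (
    AnnotationBundle,
    AnnotationTable,
    GenotypeCall,
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    VariantRecord,
    variant_key,
)

__all__ = [
    "PedigreeSpec",
    "BackgroundSpec",
    "SomaticSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_pedigree",
    "gene_drop",
    "spike_tumor",
    "cohort_annotations",
    "write_fixture_suite",
]

_CALL_BY_DOSE = (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)


@dataclass(frozen=True)
class PedigreeSpec:
    """Multi-branch three-generation family: one founder couple whose
    children head the branches, each married into the family, with an
    optional first-cousin mating contributing a fourth generation."""

    branch_sizes: Tuple[int, ...] = (5, 4)
    consanguineous: bool = False
    sequence_all: bool = True


@dataclass(frozen=True)
class BackgroundSpec:
    """Background (decoy) site-frequency model."""

    n_variants: int = 100
    beta_a: float = 0.5
    beta_b: float = 5.0
    fixed_freqs: Optional[Tuple[float, ...]] = None  # overrides the Beta draw
    max_freq: float = 0.5


@dataclass(frozen=True)
class SomaticSpec:
    genes: Tuple[str, ...] = ("HRAS", "XRCC1")
    n_spikes: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    pedigree: PedigreeSpec = PedigreeSpec()
    causal_model: DiseaseModel = DiseaseModel.dominant(0.9)
    background: BackgroundSpec = BackgroundSpec()
    missing_rate: float = 0.0
    somatic: SomaticSpec = SomaticSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError(f"missing_rate outside [0,1]: {self.missing_rate}")


def simulate_pedigree(spec: PedigreeSpec = PedigreeSpec(), seed: int = 0) -> Pedigree:
    """Deterministically build the pedigree skeleton for ``spec``.

    Child sexes are drawn from the seeded generator; ids follow a
    generation-Roman-numeral convention (I1, II1A, III2B, ...).
    """
    rng = np.random.default_rng(seed)
    seq = spec.sequence_all
    individuals = [
        Individual("I1", sex=Sex.MALE, sampled=True, sequenced=seq),
        Individual("I2", sex=Sex.FEMALE, sampled=True, sequenced=seq),
    ]
    branch_letters = "ABCDEFGH"
    first_children: List[str] = []
    for b, size in enumerate(spec.branch_sizes):
        letter = branch_letters[b]
        head_sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        head = Individual(
            f"II{letter}1", father_id="I1", mother_id="I2",
            sex=head_sex, sampled=True, sequenced=seq,
        )
        spouse = Individual(
            f"II{letter}2",
            sex=Sex.FEMALE if head_sex is Sex.MALE else Sex.MALE,
            sampled=True, sequenced=seq,
        )
        individuals += [head, spouse]
        father, mother = (
            (head.id, spouse.id) if head_sex is Sex.MALE else (spouse.id, head.id)
        )
        for i in range(size):
            child_id = f"III{letter}{i + 1}"
            individuals.append(
                Individual(
                    child_id, father_id=father, mother_id=mother,
                    sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                    sampled=True, sequenced=seq,
                )
            )
            if i == 0:
                first_children.append(child_id)
    pedigree = Pedigree(individuals)
    if spec.consanguineous:
        if len(first_children) < 2:
            raise ValueError("consanguineous mating needs at least two branches")
        a, b = first_children[0], first_children[1]
        # force opposite sexes on the cousin pair, then add their child
        fixed = []
        for ind in individuals:
            if ind.id == a:
                fixed.append(replace(ind, sex=Sex.MALE))
            elif ind.id == b:
                fixed.append(replace(ind, sex=Sex.FEMALE))
            else:
                fixed.append(ind)
        fixed.append(
            Individual(
                "IV1", father_id=a, mother_id=b,
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                sampled=True, sequenced=seq,
            )
        )
        pedigree = Pedigree(fixed)
    return pedigree


@dataclass
class SimulatedCohort:
    pedigree: Pedigree  # phenotypes filled in
    records: List[VariantRecord]
    site_freqs: Dict[tuple, float]
    causal_key: tuple

    @property
    def causal_record(self) -> VariantRecord:
        return next(r for r in self.records if r.key == self.causal_key)


def _draw_background_freqs(spec: BackgroundSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.fixed_freqs is not None:
        freqs = np.asarray(spec.fixed_freqs, dtype=float)
        if len(freqs) != spec.n_variants:
            raise ValueError("fixed_freqs length must equal n_variants")
        return freqs
    freqs = rng.beta(spec.beta_a, spec.beta_b, size=spec.n_variants)
    freqs = np.clip(freqs, 1e-4, spec.max_freq)
    return freqs


def _site_table(background: BackgroundSpec, rng: np.random.Generator):
    """Background sites on a synthetic GRCh37-like grid plus one causal site."""
    freqs = _draw_background_freqs(background, rng)
    sites = []
    for i, freq in enumerate(freqs):
        chrom = str(1 + (i % 22))
        pos = 1_000_000 + 10_000 * (i // 22 + 1) + (i % 22)
        sites.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "gene": f"BG{i:04d}",
                "consequence": "missense_variant",
                "freq": float(freq),
            }
        )
    return sites


_CAUSAL_SITE = {
    "chrom": "5",
    "pos": 73_048_875,
    "ref": "A",
    "alt": "G",
    "gene": "CAND1",
    "consequence": "missense_variant",
}


def gene_drop(
    pedigree: Pedigree,
    causal_model: DiseaseModel = DiseaseModel.dominant(0.9),
    background: BackgroundSpec = BackgroundSpec(),
    seed: int = 0,
    missing_rate: float = 0.0,
    min_affected: int = 0,
    forced_carrier: Optional[str] = None,
) -> SimulatedCohort:
    """Drop genotypes through the pedigree and assign phenotypes.

    Founders draw site genotypes at Hardy-Weinberg proportions from each
    site's frequency; children inherit one uniformly chosen allele per
    parent. The causal site uses ``causal_model.disease_allele_freq``
    with one designated founder forced heterozygous. Phenotypes are
    affected with probability ``penetrance[dose]``. When
    ``min_affected`` > 0, whole cohorts are redrawn until at least that
    many sequenced members are affected (family ascertainment).
    """
    rng = np.random.default_rng(seed)
    q = causal_model.disease_allele_freq
    if not (0.0 < q < 1.0):
        raise ValueError(f"causal frequency outside (0,1): {q}")
    sites = _site_table(background, rng)
    causal = dict(_CAUSAL_SITE)
    causal["freq"] = q
    all_sites = [causal] + sites
    order = pedigree.topological_order()
    if forced_carrier is None:
        forced_carrier = order[0].id
    if not pedigree[forced_carrier].is_founder:
        raise ValueError(f"forced carrier must be a founder: {forced_carrier}")

    for _attempt in range(1000):
        alleles: Dict[str, np.ndarray] = {}  # id -> (n_sites, 2) 0/1
        n_sites = len(all_sites)
        freqs = np.array([s["freq"] for s in all_sites])
        for ind in order:
            if ind.is_founder:
                alleles[ind.id] = (
                    rng.random((n_sites, 2)) < freqs[:, None]
                ).astype(np.int8)
                if ind.id == forced_carrier:
                    alleles[ind.id][0] = np.array([1, 0], dtype=np.int8)
            else:
                pat = _gamete(alleles, ind.father_id, n_sites, rng)
                mat = _gamete(alleles, ind.mother_id, n_sites, rng)
                alleles[ind.id] = np.stack([pat, mat], axis=1)

        phenotypes: Dict[str, Phenotype] = {}
        for ind in order:
            dose = int(alleles[ind.id][0].sum())
            affected = rng.random() < causal_model.penetrance[dose]
            phenotypes[ind.id] = (
                Phenotype.AFFECTED if affected else Phenotype.UNAFFECTED
            )
        n_affected_sequenced = sum(
            1
            for ind in order
            if ind.sequenced and phenotypes[ind.id] is Phenotype.AFFECTED
        )
        if n_affected_sequenced >= min_affected:
            break
    else:
        raise RuntimeError("could not satisfy min_affected in 1000 redraws")

    records = []
    for s_idx, site in enumerate(all_sites):
        genotypes = {}
        for ind in order:
            if rng.random() < missing_rate:
                genotypes[ind.id] = GenotypeCall.MISSING
            else:
                genotypes[ind.id] = _CALL_BY_DOSE[int(alleles[ind.id][s_idx].sum())]
        records.append(
            VariantRecord(
                chrom=site["chrom"],
                pos=site["pos"],
                ref=site["ref"],
                alt=site["alt"],
                gene=site["gene"],
                consequence=site["consequence"],
                genotypes=genotypes,
            )
        )
    site_freqs = {rec.key: site["freq"] for rec, site in zip(records, all_sites)}
    causal_key = records[0].key
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return SimulatedCohort(
        pedigree=pedigree.with_phenotypes(phenotypes),
        records=records,
        site_freqs=site_freqs,
        causal_key=causal_key,
    )


def _gamete(alleles, parent_id, n_sites, rng) -> np.ndarray:
    picks = rng.integers(0, 2, size=n_sites)
    return alleles[parent_id][np.arange(n_sites), picks]


def spike_tumor(
    germline_records: Sequence[VariantRecord],
    individual_id: str,
    spec: SomaticSpec = SomaticSpec(),
    seed: int = 0,
) -> List[VariantRecord]:
    """Single-sample tumor call set: the individual's germline calls plus
    ``n_spikes`` heterozygous somatic variants in ``spec.genes`` at
    positions absent from the germline set."""
    rng = np.random.default_rng(seed)
    existing = {rec.key for rec in germline_records}
    tumor = [
        VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=rec.alt,
            gene=rec.gene,
            consequence=rec.consequence,
            genotypes={individual_id: rec.genotype(individual_id)},
        )
        for rec in germline_records
    ]
    for i in range(spec.n_spikes):
        gene = spec.genes[i % len(spec.genes)]
        while True:
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(1_000_000, 200_000_000))
            key = variant_key(chrom, pos, "C", "A")
            if key not in existing:
                break
        existing.add(key)
        tumor.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="C",
                alt="A",
                gene=gene,
                consequence="missense_variant",
                genotypes={individual_id: GenotypeCall.HET},
            )
        )
    return sorted(tumor, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


def cohort_annotations(
    cohort: SimulatedCohort,
    dbs: Sequence[str] = ("1KG", "EVS", "ExAC", "gnomAD"),
    causal_tpm: float = 20.0,
    background_tpm: float = 5.0,
) -> Tuple[AnnotationTable, Dict[tuple, float]]:
    """Annotation table + internal-cohort frequency map for a simulated
    cohort: background sites carry their simulated frequency in every
    database; the causal site is absent everywhere."""
    table = AnnotationTable(dbs=set(dbs))
    internal: Dict[tuple, float] = {}
    for rec in cohort.records:
        if rec.key == cohort.causal_key:
            table.bundles[rec.key] = AnnotationBundle(expression_tpm=causal_tpm)
        else:
            freq = cohort.site_freqs[rec.key]
            table.bundles[rec.key] = AnnotationBundle(
                frequencies={db: freq for db in dbs},
                expression_tpm=background_tpm,
            )
            internal[rec.key] = freq
    return table, internal


def write_fixture_suite(outdir: str, seed: int = 0) -> Dict[str, str]:
    """Emit a complete plain-text input suite under ``outdir``.

    Includes a simulated cohort (PED, germline VCF, tumor VCF, annotation
    and frequency TSVs) and the bundled worked-example fixtures (kindred
    genotype matrix, candidate annotations, somatic pair, interaction
    edges, panels). Returns a name -> path map.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    pedigree = simulate_pedigree(PedigreeSpec(consanguineous=True), seed=seed)
    cohort = gene_drop(
        pedigree,
        background=BackgroundSpec(n_variants=50),
        seed=seed + 1,
        min_affected=3,
    )
    table, internal = cohort_annotations(cohort)
    sample_ids = [ind.id for ind in cohort.pedigree if ind.sequenced]
    tumor_donor = next(
        ind.id
        for ind in cohort.pedigree
        if ind.sequenced and ind.phenotype is Phenotype.AFFECTED
    )
    tumor = spike_tumor(
        [
            VariantRecord(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt, gene=r.gene,
                consequence=r.consequence,
                genotypes={tumor_donor: r.genotype(tumor_donor)},
            )
            for r in cohort.records
        ],
        tumor_donor,
        seed=seed + 2,
    )

    paths["ped"] = os.path.join(outdir, "cohort.ped")
    io.write_ped(cohort.pedigree, paths["ped"])
    paths["germline_vcf"] = os.path.join(outdir, "germline.vcf")
    io.write_vcf(cohort.records, sample_ids, paths["germline_vcf"])
    paths["tumor_vcf"] = os.path.join(outdir, "tumor.vcf")
    io.write_vcf(tumor, [tumor_donor], paths["tumor_vcf"])
    paths["annotations"] = os.path.join(outdir, "annotations.tsv")
    io.write_annotation_table(table, paths["annotations"])
    paths["internal_freqs"] = os.path.join(outdir, "internal_freqs.tsv")
    io.write_frequency_table({"internal": internal}, paths["internal_freqs"])

    # Worked-example fixtures
    kindred = examples.kindred_pedigree()
    paths["example_ped"] = os.path.join(outdir, "example.ped")
    io.write_ped(kindred, paths["example_ped"])
    paths["example_vcf"] = os.path.join(outdir, "example_genotypes.vcf")
    io.write_vcf(
        examples.kindred_genotype_matrix(), examples.GENOTYPED_IDS, paths["example_vcf"]
    )
    paths["example_annotations"] = os.path.join(outdir, "example_annotations.tsv")
    io.write_annotation_table(examples.candidate_annotations(), paths["example_annotations"])
    paths["example_internal"] = os.path.join(outdir, "example_internal_freqs.tsv")
    io.write_frequency_table(
        {"internal": examples.internal_frequencies()}, paths["example_internal"]
    )
    somatic_tumor, somatic_germ = examples.somatic_fixture()
    paths["example_tumor_vcf"] = os.path.join(outdir, "example_tumor.vcf")
    io.write_vcf(somatic_tumor, [examples.TUMOR_DONOR], paths["example_tumor_vcf"])
    paths["example_tumor_germline_vcf"] = os.path.join(outdir, "example_tumor_germline.vcf")
    io.write_vcf(somatic_germ, [examples.TUMOR_DONOR], paths["example_tumor_germline_vcf"])
    paths["example_somatic_annotations"] = os.path.join(
        outdir, "example_somatic_annotations.tsv"
    )
    io.write_annotation_table(
        examples.somatic_annotations(), paths["example_somatic_annotations"]
    )
    paths["somatic_panel"] = os.path.join(outdir, "somatic_panel.txt")
    io.write_panel(examples.SOMATIC_PANEL, paths["somatic_panel"])
    paths["susceptibility_panel"] = os.path.join(outdir, "susceptibility_panel.txt")
    io.write_panel(examples.SUSCEPTIBILITY_PANEL, paths["susceptibility_panel"])
    paths["edges"] = os.path.join(outdir, "interactions.tsv")
    io.write_edges(examples.interaction_fixture(), paths["edges"])
    return paths
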
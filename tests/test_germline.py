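import numpy as np
import pytest

from conftest import HET, HOM_ALT, HOM_REF, MISSING, variant_with
from pedvar import examples
from pedvar.germline import (
    DEFAULT_DBS,
    GermlineConfig,
    SpliceRules,
    filter_internal_cohort,
    filter_population_frequency,
    intersect_shared,
    run_germline_cascade,
    tier_candidates,
)
from pedvar.segregation import InheritanceModel
from pedvar.simulate import (
    BackgroundSpec,
    PedigreeSpec,
    cohort_annotations,
    gene_drop,
    simulate_pedigree,
)
from pedvar.types import AnnotationBundle, AnnotationTable, Phenotype, VariantRecord

CARRIERS = list(examples.SEQUENCED_CARRIERS)


def random_records(rng, n, sample_ids):
    recs = []
    for i in range(n):
        genotypes = {
            s: rng.choice([HOM_REF, HET, HOM_ALT, MISSING], p=[0.5, 0.3, 0.1, 0.1])
            for s in sample_ids
        }
        recs.append(
            variant_with(genotypes, chrom=str(1 + i % 22), pos=1000 + i, gene=f"G{i}")
        )
    return recs


class TestIntersectShared:
    def test_all_carriers_retained(self, kindred, matrix):
        assert intersect_shared(matrix, CARRIERS, kindred) == matrix

    def test_hom_ref_in_one_carrier_removed(self, matrix):
        rec = variant_with(
            {**dict.fromkeys(CARRIERS, HET), "III10": HOM_REF},
            pos=999,
        )
        assert intersect_shared([rec], CARRIERS) == []

    def test_missing_fails(self):
        rec = variant_with({**dict.fromkeys(CARRIERS, HET), "III8": MISSING})
        assert intersect_shared([rec], CARRIERS) == []

    def test_empty_carriers_error(self, matrix):
        with pytest.raises(ValueError, match="nonempty"):
            intersect_shared(matrix, [])

    def test_unsequenced_carrier_error(self, kindred, matrix):
        with pytest.raises(ValueError, match="not sequenced"):
            intersect_shared(matrix, ["III1"], kindred)  # sampled, not sequenced

    def test_brute_force_oracle_1000_records(self):
        rng = np.random.default_rng(7)
        samples = [f"P{i}" for i in range(8)]
        carriers = samples[:5]
        recs = random_records(rng, 1000, samples)
        got = intersect_shared(recs, carriers)
        expected = [
            r
            for r in recs
            if all(r.genotypes[c] in (HET, HOM_ALT) for c in carriers)
        ]
        assert got == expected


class TestFrequencyFilters:
    def _table(self, entries):
        table = AnnotationTable(dbs=set(DEFAULT_DBS))
        for rec, freqs in entries:
            table.bundles[rec.key] = AnnotationBundle(frequencies=freqs)
        return table

    def test_common_in_one_db_removed(self):
        rec = variant_with({}, pos=1)
        table = self._table([(rec, {"gnomAD": 0.02})])
        assert filter_population_frequency([rec], table, DEFAULT_DBS, 0.01) == []

    def test_absent_everywhere_retained(self):
        rec = variant_with({}, pos=2)
        table = self._table([(rec, {})])
        assert filter_population_frequency([rec], table, DEFAULT_DBS, 0.01) == [rec]

    def test_unknown_db_errors(self):
        rec = variant_with({}, pos=3)
        table = self._table([(rec, {"gnomAD": 0.001})])
        with pytest.raises(ValueError, match="unknown db"):
            filter_population_frequency([rec], table, ["NotADb"], 0.01)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_population_frequency([], AnnotationTable(), DEFAULT_DBS, 0.0)

    def test_brute_force_oracle_random_frequencies(self):
        rng = np.random.default_rng(11)
        recs = [variant_with({}, pos=10 + i) for i in range(300)]
        table = AnnotationTable(dbs=set(DEFAULT_DBS))
        for rec in recs:
            freqs = {
                db: float(rng.uniform(0, 0.05))
                for db in DEFAULT_DBS
                if rng.random() < 0.7
            }
            table.bundles[rec.key] = AnnotationBundle(frequencies=freqs)
        got = filter_population_frequency(recs, table, DEFAULT_DBS, 0.01)
        expected = [
            r
            for r in recs
            if all(
                table.bundles[r.key].frequencies.get(db, 0.0) < 0.01
                for db in DEFAULT_DBS
            )
        ]
        assert got == expected

    def test_internal_low_frequency_retained(self, matrix):
        internal = examples.internal_frequencies()
        primary = matrix[0]
        assert filter_internal_cohort([primary], internal, 0.01) == [primary]

    def test_internal_four_percent_removed(self):
        rec = variant_with({}, pos=44047825, chrom="19")
        assert filter_internal_cohort([rec], {rec.key: 0.04}, 0.01) == []

    def test_threshold_one_retains_everything(self, matrix):
        internal = {matrix[0].key: 0.99}
        assert filter_internal_cohort(matrix, internal, 1.0) == matrix

    def test_frequency_filter_order_commutes(self):
        rng = np.random.default_rng(3)
        recs = [variant_with({}, pos=500 + i) for i in range(200)]
        table = AnnotationTable(dbs=set(DEFAULT_DBS))
        internal = {}
        for rec in recs:
            table.bundles[rec.key] = AnnotationBundle(
                frequencies={
                    db: float(rng.uniform(0, 0.03))
                    for db in DEFAULT_DBS
                    if rng.random() < 0.5
                }
            )
            if rng.random() < 0.5:
                internal[rec.key] = float(rng.uniform(0, 0.03))
        a = filter_internal_cohort(
            filter_population_frequency(recs, table, DEFAULT_DBS, 0.01), internal, 0.01
        )
        b = filter_population_frequency(
            filter_internal_cohort(recs, internal, 0.01), table, DEFAULT_DBS, 0.01
        )
        assert a == b


class TestTiering:
    def test_worked_example_tiers(self, matrix):
        table = examples.candidate_annotations()
        tiers = tier_candidates(matrix, table)
        by_gene = {rec.gene: tiers[rec.key] for rec in matrix}
        assert by_gene["SLC24A4"].value == "excluded"
        assert "splice_benign" in by_gene["SLC24A4"].reason
        assert by_gene["ARHGEF28"].value == "primary"
        assert by_gene["FBXW10"].value == "secondary"
        assert by_gene["SLC47A1"].value == "secondary"

    def test_boundary_tpm_inclusive(self):
        rec = variant_with({}, pos=77)
        table = AnnotationTable()
        table.bundles[rec.key] = AnnotationBundle(expression_tpm=10.0)
        assert tier_candidates([rec], table, tpm_threshold=10.0)[rec.key].value == "primary"

    def test_missing_splice_scores_noted_not_excluded(self):
        rec = variant_with({}, pos=78, consequence="splice_region_variant")
        table = AnnotationTable()
        table.bundles[rec.key] = AnnotationBundle(expression_tpm=15.0)
        label = tier_candidates([rec], table)[rec.key]
        assert label.value == "primary"
        assert "splice scores missing" in label.reason

    def test_missing_tpm_is_secondary_with_reason(self):
        rec = variant_with({}, pos=79)
        tiers = tier_candidates([rec], AnnotationTable())
        assert tiers[rec.key].value == "secondary"
        assert "TPM missing" in tiers[rec.key].reason

    def test_high_spliceai_not_excluded(self):
        rec = variant_with({}, pos=80, consequence="splice_region_variant")
        table = AnnotationTable()
        table.bundles[rec.key] = AnnotationBundle(
            scores={"spliceAI": 0.9, "dbscSNV_Ada": 0.005}, expression_tpm=20.0
        )
        assert tier_candidates([rec], table)[rec.key].value == "primary"


class TestCascade:
    def _config(self):
        return GermlineConfig(carriers=CARRIERS)

    def test_worked_example_end_to_end(self, kindred, matrix):
        result = run_germline_cascade(
            matrix,
            kindred,
            examples.candidate_annotations(),
            examples.internal_frequencies(),
            self._config(),
        )
        assert [s.name for s in result.trace] == [
            "shared_carriers",
            "population_frequency",
            "internal_cohort_frequency",
            "familial_segregation",
        ]
        assert len(result.records) == 4
        values = sorted(t.value for t in result.tiers.values())
        assert values == ["excluded", "primary", "secondary", "secondary"]

    def test_trace_chains(self, kindred, matrix):
        result = run_germline_cascade(
            matrix, kindred, examples.candidate_annotations(),
            examples.internal_frequencies(), self._config(),
        )
        rows = result.trace.as_rows()
        for (_, _, out_prev), (_, in_next, _) in zip(rows, rows[1:]):
            assert out_prev == in_next

    def test_empty_cohort_four_zero_stages(self, kindred):
        result = run_germline_cascade(
            [], kindred, AnnotationTable(), {}, self._config()
        )
        assert result.trace.as_rows() == [
            ("shared_carriers", 0, 0),
            ("population_frequency", 0, 0),
            ("internal_cohort_frequency", 0, 0),
            ("familial_segregation", 0, 0),
        ]

    def test_planted_variant_survives_common_decoys(self):
        pedigree = simulate_pedigree(PedigreeSpec(), seed=5)
        cohort = gene_drop(
            pedigree,
            background=BackgroundSpec(n_variants=500, beta_a=2.0, beta_b=2.0),
            seed=5,
            min_affected=3,
        )
        table, internal = cohort_annotations(cohort)
        carriers = [
            ind.id
            for ind in cohort.pedigree
            if ind.sequenced and ind.phenotype is Phenotype.AFFECTED
        ]
        result = run_germline_cascade(
            cohort.records, cohort.pedigree, table, internal,
            GermlineConfig(carriers=carriers),
        )
        assert cohort.causal_key in {r.key for r in result.records}
        counts = [s.count_out for s in result.trace]
        assert counts[0] > counts[-1]  # decoys actually get filtered

    def test_conjunction_oracle_equivalence(self):
        """Naive per-record conjunction of all predicates == cascade output."""
        pedigree = simulate_pedigree(PedigreeSpec(), seed=9)
        cohort = gene_drop(
            pedigree,
            background=BackgroundSpec(n_variants=400, beta_a=0.5, beta_b=5.0),
            seed=9,
            min_affected=2,
        )
        table, internal = cohort_annotations(cohort)
        carriers = [
            ind.id
            for ind in cohort.pedigree
            if ind.sequenced and ind.phenotype is Phenotype.AFFECTED
        ]
        config = GermlineConfig(carriers=carriers)
        result = run_germline_cascade(
            cohort.records, cohort.pedigree, table, internal, config
        )
        from _oracles import dominant_compatible

        phenos = {ind.id: ind.phenotype for ind in cohort.pedigree}
        expected = set()
        for rec in cohort.records:
            shared = all(rec.genotypes.get(c) in (HET, HOM_ALT) for c in carriers)
            freqs = table.bundles[rec.key].frequencies
            rare_pop = all(freqs.get(db, 0.0) < 0.01 for db in DEFAULT_DBS)
            rare_internal = internal.get(rec.key, 0.0) < 0.01
            seg = dominant_compatible(rec.genotypes, phenos, allow_incomplete=True)
            if shared and rare_pop and rare_internal and seg:
                expected.add(rec.key)
        assert {r.key for r in result.records} == expected
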
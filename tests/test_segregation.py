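from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    dominant_compatible,
    recessive_compatible,
    trio_possible,
)
from conftest import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    make_pedigree,
    variant_with,
)
from pedvar.segregation import (
    InheritanceModel,
    SegregationError,
    check_mendelian,
    classify,
    classify_dominant,
    classify_recessive,
    segregation_filter,
)
from pedvar.types import GenotypeCall, Individual, Pedigree, Phenotype

ALL_CALLS = list(GenotypeCall)


class TestWorkedExample:
    """The four-variant genotype matrix from the bundled kindred."""

    def test_primary_candidate_row(self, kindred, matrix):
        result = classify_dominant(matrix[0], kindred, allow_incomplete=True)
        assert result.compatible
        assert result.non_penetrant_carriers == ["III6"]
        assert result.violators == []

    def test_strict_penetrance_flips_to_violation(self, kindred, matrix):
        result = classify_dominant(matrix[0], kindred, allow_incomplete=False)
        assert not result.compatible
        assert result.violators == ["III6"]

    def test_hom_alt_affected_is_a_carrier(self, kindred, matrix):
        # the transporter-gene row: one affected member is homozygous
        result = classify_dominant(matrix[3], kindred, allow_incomplete=True)
        assert result.compatible
        assert result.non_penetrant_carriers == ["III2"]

    def test_all_rows_one_nonpenetrant_carrier(self, kindred, matrix):
        expected = {"ARHGEF28": "III6", "FBXW10": "III2", "SLC24A4": "III4", "SLC47A1": "III2"}
        for rec in matrix:
            result = classify_dominant(rec, kindred, allow_incomplete=True)
            assert result.compatible, rec.gene
            assert result.non_penetrant_carriers == [expected[rec.gene]]

    def test_recessive_rejects_het_affecteds(self, kindred, matrix):
        result = classify_recessive(matrix[0], kindred)
        assert not result.compatible
        assert len(result.violators) >= 7  # the het affecteds

    def test_n_informative_counts_known_phenotypes(self, kindred, matrix):
        result = classify_dominant(matrix[0], kindred)
        assert result.n_informative == 11  # 8 affected + 3 unaffected genotyped


class TestClassifierBasics:
    def test_no_genotyped_affected_errors(self, five_member_pedigree):
        rec = variant_with({"F": MISSING, "M": HOM_REF, "C2": HET})
        with pytest.raises(SegregationError, match="no genotyped affected"):
            classify_dominant(rec, five_member_pedigree)

    def test_recessive_all_hom_alt_affected_compatible(self):
        ped = make_pedigree(
            [("F", None, None, "H"), ("M", None, None, "H"),
             ("C1", "F", "M", "A"), ("C2", "F", "M", "H")]
        )
        rec = variant_with({"F": HET, "M": HET, "C1": HOM_ALT, "C2": HET})
        assert classify_recessive(rec, ped).compatible

    def test_recessive_hom_ref_parent_violates(self):
        ped = make_pedigree(
            [("F", None, None, "H"), ("M", None, None, "H"), ("C1", "F", "M", "A")]
        )
        rec = variant_with({"F": HOM_REF, "M": HET, "C1": HOM_ALT})
        result = classify_recessive(rec, ped, allow_pseudo_dominant=True)
        assert not result.compatible
        assert "F" in result.violators

    def test_pseudo_dominant_requires_recessive(self):
        with pytest.raises(ValueError, match="pseudo_dominant"):
            InheritanceModel("dominant", allow_pseudo_dominant=True)


class TestTruthTableOracles:
    """Exhaustive enumeration of all 4^5 genotype vectors on a 5-member
    family, versus the independent truth-table restatement."""

    @pytest.mark.parametrize("allow_incomplete", [True, False])
    def test_dominant_all_genotype_vectors(self, five_member_pedigree, allow_incomplete):
        ids = five_member_pedigree.ids
        phenos = {i: five_member_pedigree[i].phenotype for i in ids}
        for vector in product(ALL_CALLS, repeat=5):
            calls = dict(zip(ids, vector))
            expected = dominant_compatible(calls, phenos, allow_incomplete)
            rec = variant_with(calls)
            if expected is None:
                with pytest.raises(SegregationError):
                    classify_dominant(rec, five_member_pedigree, allow_incomplete)
            else:
                got = classify_dominant(rec, five_member_pedigree, allow_incomplete)
                assert got.compatible == expected, calls

    def test_recessive_all_genotype_vectors(self, five_member_pedigree):
        ids = five_member_pedigree.ids
        phenos = {i: five_member_pedigree[i].phenotype for i in ids}
        parents = {
            i: (five_member_pedigree[i].father_id, five_member_pedigree[i].mother_id)
            for i in ids
        }
        for vector in product(ALL_CALLS, repeat=5):
            calls = dict(zip(ids, vector))
            expected = recessive_compatible(calls, phenos, parents)
            rec = variant_with(calls)
            if expected is None:
                with pytest.raises(SegregationError):
                    classify_recessive(rec, five_member_pedigree)
            else:
                got = classify_recessive(rec, five_member_pedigree)
                assert got.compatible == expected, calls


class TestMendelian:
    def test_hom_ref_parents_het_child(self):
        ped = make_pedigree(
            [("F", None, None, "U"), ("M", None, None, "U"), ("C", "F", "M", "U")]
        )
        rec = variant_with({"F": HOM_REF, "M": HOM_REF, "C": HET})
        assert len(check_mendelian(rec, ped)) == 1

    def test_het_parents_any_child(self):
        ped = make_pedigree(
            [("F", None, None, "U"), ("M", None, None, "U"), ("C", "F", "M", "U")]
        )
        for child_call in (HOM_REF, HET, HOM_ALT):
            rec = variant_with({"F": HET, "M": HET, "C": child_call})
            assert check_mendelian(rec, ped) == []

    def test_all_27_combinations_match_gamete_oracle(self):
        ped = make_pedigree(
            [("F", None, None, "U"), ("M", None, None, "U"), ("C", "F", "M", "U")]
        )
        typed = (HOM_REF, HET, HOM_ALT)
        for f, m, c in product(typed, repeat=3):
            rec = variant_with({"F": f, "M": m, "C": c})
            violations = check_mendelian(rec, ped)
            assert (len(violations) == 0) == trio_possible(f, m, c), (f, m, c)

    def test_missing_genotype_skips_trio(self):
        ped = make_pedigree(
            [("F", None, None, "U"), ("M", None, None, "U"), ("C", "F", "M", "U")]
        )
        rec = variant_with({"F": HOM_REF, "M": MISSING, "C": HOM_ALT})
        assert check_mendelian(rec, ped) == []


class TestSegregationFilter:
    def test_four_rows_survive_with_incomplete_penetrance(self, kindred, matrix):
        models = [InheritanceModel("dominant", allow_incomplete_penetrance=True)]
        survivors, results, trace = segregation_filter(matrix, kindred, models)
        assert len(survivors) == 4
        assert trace.as_rows() == [("familial_segregation", 4, 4)]
        for rec in matrix:
            (result,) = results[rec.key]
            assert len(result.non_penetrant_carriers) == 1

    def test_strict_dominant_rejects_all(self, kindred, matrix):
        models = [InheritanceModel("dominant", allow_incomplete_penetrance=False)]
        survivors, _, trace = segregation_filter(matrix, kindred, models)
        assert survivors == []
        assert trace.as_rows() == [("familial_segregation", 4, 0)]

    def test_empty_model_list_errors(self, kindred, matrix):
        with pytest.raises(SegregationError, match="empty model"):
            segregation_filter(matrix, kindred, [])


# ---------------------------------------------------------------------------
# properties

call_st = st.sampled_from(ALL_CALLS)


@settings(max_examples=100, deadline=None)
@given(
    vector=st.lists(call_st, min_size=5, max_size=5),
    extra_call=call_st,
    allow_incomplete=st.booleans(),
)
def test_unknown_phenotype_member_never_changes_verdict(
    vector, extra_call, allow_incomplete
):
    rows = [
        ("F", None, None, "A"),
        ("M", None, None, "H"),
        ("C1", "F", "M", "A"),
        ("C2", "F", "M", "H"),
        ("C3", "F", "M", "U"),
    ]
    base = make_pedigree(rows)
    augmented = make_pedigree(rows + [("X", "F", "M", "U")])
    ids = ["F", "M", "C1", "C2", "C3"]
    calls = dict(zip(ids, vector))
    calls_aug = dict(calls, X=extra_call)
    for model in (
        InheritanceModel("dominant", allow_incomplete_penetrance=allow_incomplete),
        InheritanceModel("recessive"),
    ):
        try:
            before = classify(variant_with(calls), base, model).compatible
        except SegregationError:
            continue
        after = classify(variant_with(calls_aug), augmented, model).compatible
        assert before == after


@settings(max_examples=100, deadline=None)
@given(
    vector=st.lists(call_st, min_size=5, max_size=5),
    drop_index=st.integers(min_value=0, max_value=4),
    allow_incomplete=st.booleans(),
)
def test_masking_a_genotype_never_breaks_compatibility(
    five_member_pedigree, vector, drop_index, allow_incomplete
):
    ids = five_member_pedigree.ids
    calls = dict(zip(ids, vector))
    masked = dict(calls)
    masked[ids[drop_index]] = MISSING
    for model in (
        InheritanceModel("dominant", allow_incomplete_penetrance=allow_incomplete),
        InheritanceModel("recessive"),
    ):
        try:
            before = classify(variant_with(calls), five_member_pedigree, model)
        except SegregationError:
            continue
        if not before.compatible:
            continue
        try:
            after = classify(variant_with(masked), five_member_pedigree, model)
        except SegregationError:
            continue  # masking removed the last genotyped affected
        assert after.compatible
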
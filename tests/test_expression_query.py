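"""Matrix building, threshold pruning, annotation joins, summaries,
and the scaled-TPM transform."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gexmap import (
    Abundance,
    AnnotationRecord,
    AnnotationStore,
    Category,
    Condition,
    ExpressionDataset,
    ExpressionMatrix,
    FillPolicy,
    GeneCategoryFilter,
    GeneExpressionRecord,
    QuerySpec,
    UNANNOTATED_KEY,
    UnknownReferenceError,
    ValidationError,
    annotate_result,
    apply_threshold,
    build_matrix,
    run_query,
    scaled_tpm_matrix,
    summarize_by_disease,
)


def _dataset(tpm_by_gene: dict[str, list[float]], samples: list[str],
             length: float = 1000.0) -> ExpressionDataset:
    records = {}
    for gid, values in tpm_by_gene.items():
        for sid, tpm in zip(samples, values):
            if tpm is None:  # absent (sample, gene) pair
                continue
            records[(sid, gid)] = GeneExpressionRecord(
                sample_id=sid, gene_id=gid, length=length, effective_length=length - 180,
                expected_count=tpm, tpm=tpm, fpkm=tpm,
            )
    return ExpressionDataset(samples=samples, genes=list(tpm_by_gene), records=records)


G1, G2, G3 = "ENSG00000000001", "ENSG00000000002", "ENSG00000000003"


@pytest.fixture()
def toy_dataset():
    return _dataset({G1: [120.0, 5.0], G2: [50.0, 60.0], G3: [100.0, 0.0]}, ["A", "B"])


@pytest.fixture()
def toy_store():
    return AnnotationStore([
        AnnotationRecord("AAA", G1, Category.PROTEIN_CODING, "asthma"),
        AnnotationRecord("AAA", G1, Category.PROTEIN_CODING, "arthritis"),
        AnnotationRecord("BBB", G2, Category.NON_PROTEIN_CODING, "asthma"),
    ])


class TestBuildMatrix:
    def test_all_category_no_disease_selects_every_gene(self, toy_dataset):
        spec = QuerySpec(samples=["A", "B"])
        matrix = build_matrix(toy_dataset, spec)
        assert matrix.gene_ids == [G1, G2, G3]
        assert matrix.values.shape == (3, 2)
        np.testing.assert_array_equal(matrix.values, [[120, 5], [50, 60], [100, 0]])

    def test_disease_restriction_narrows_to_annotated_genes(self, toy_dataset, toy_store):
        spec = QuerySpec(samples=["A", "B"], diseases=["arthritis"])
        matrix = build_matrix(toy_dataset, spec, toy_store)
        assert matrix.gene_ids == [G1]
        assert matrix.gene_symbols == ["AAA"]

    def test_category_filter_uses_annotation_records(self, toy_dataset, toy_store):
        spec = QuerySpec(samples=["A"], category=GeneCategoryFilter.NON_CODING)
        matrix = build_matrix(toy_dataset, spec, toy_store)
        assert matrix.gene_ids == [G2]

    def test_unknown_sample_is_a_reference_error(self, toy_dataset):
        with pytest.raises(UnknownReferenceError, match="nope"):
            build_matrix(toy_dataset, QuerySpec(samples=["nope"]))

    def test_empty_candidate_set_yields_empty_matrix(self, toy_dataset, toy_store):
        spec = QuerySpec(samples=["A"], diseases=["unknown disease"])
        matrix = build_matrix(toy_dataset, spec, toy_store)
        assert matrix.n_genes == 0

    def test_matches_cell_by_cell_brute_force(self):
        rng = random.Random(5)
        samples = [f"S{j}" for j in range(6)]
        genes = {f"ENSG{i + 1:011d}": [
            rng.uniform(0, 200) if rng.random() < 0.9 else None for _ in samples
        ] for i in range(20)}
        dataset = _dataset(genes, samples)
        matrix = build_matrix(dataset, QuerySpec(samples=samples))
        for i, gid in enumerate(matrix.gene_ids):
            for j, sid in enumerate(matrix.sample_ids):
                rec = dataset.get(sid, gid)
                expected = 0.0 if rec is None else rec.tpm
                assert matrix.values[i, j] == expected

    def test_exclude_missing_drops_incomplete_genes(self):
        dataset = _dataset({G1: [1.0, None], G2: [2.0, 3.0]}, ["A", "B"])
        spec = QuerySpec(samples=["A", "B"], fill_policy=FillPolicy.EXCLUDE_MISSING)
        matrix = build_matrix(dataset, spec)
        assert matrix.gene_ids == [G2]


def _brute_force_threshold(values, lo, hi, condition):
    """Independent per-gene predicate evaluation (pure-python oracle)."""
    kept = []
    for i, row in enumerate(values):
        inside = [lo <= v <= hi for v in row]
        if condition is Condition.ANY_SAMPLE:
            ok = any(inside)
        elif condition is Condition.ALL_SAMPLES:
            ok = all(inside)
        else:
            mean = sum(row) / len(row)
            ok = lo <= mean <= hi
        if ok:
            kept.append(i)
    return kept


class TestApplyThreshold:
    def test_any_sample_keeps_gene_exceeding_cutoff_once(self):
        matrix = ExpressionMatrix([G1, G2], ["g1", "g2"], ["A", "B"],
                                  np.array([[120.0, 5.0], [50.0, 60.0]]))
        out = apply_threshold(matrix, 100, math.inf, Condition.ANY_SAMPLE)
        assert out.gene_ids == [G1]
        assert out.sample_ids == ["A", "B"]  # columns untouched

    def test_vacuous_window_keeps_everything(self, toy_dataset):
        matrix = build_matrix(toy_dataset, QuerySpec(samples=["A", "B"]))
        for condition in Condition:
            out = apply_threshold(matrix, 0, math.inf, condition)
            assert out.gene_ids == matrix.gene_ids

    def test_bounds_are_inclusive(self):
        matrix = ExpressionMatrix([G1], ["g1"], ["A", "B"], np.array([[100.0, 0.0]]))
        out = apply_threshold(matrix, 100, math.inf, Condition.ANY_SAMPLE)
        assert out.gene_ids == [G1]

    def test_min_above_max_rejected(self):
        matrix = ExpressionMatrix([G1], ["g1"], ["A"], np.array([[1.0]]))
        with pytest.raises(ValidationError):
            apply_threshold(matrix, 10, 5, Condition.ANY_SAMPLE)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        values=st.lists(
            st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=10),
            min_size=1, max_size=50,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1),
        bounds=st.tuples(st.floats(0, 500), st.floats(0, 1000)).map(sorted),
        condition=st.sampled_from(list(Condition)),
    )
    def test_agrees_with_brute_force_predicate(self, values, bounds, condition):
        lo, hi = bounds
        n_samples = len(values[0])
        matrix = ExpressionMatrix(
            [f"ENSG{i + 1:011d}" for i in range(len(values))],
            [f"g{i}" for i in range(len(values))],
            [f"S{j}" for j in range(n_samples)],
            np.array(values),
        )
        out = apply_threshold(matrix, lo, hi, condition)
        expected = [matrix.gene_ids[i]
                    for i in _brute_force_threshold(values, lo, hi, condition)]
        assert out.gene_ids == expected

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        lo=st.floats(0, 400, allow_nan=False),
        delta=st.floats(0, 200, allow_nan=False),
    )
    def test_raising_min_never_adds_genes(self, seed, lo, delta):
        rng = np.random.default_rng(seed)
        matrix = ExpressionMatrix(
            [f"ENSG{i + 1:011d}" for i in range(12)],
            [f"g{i}" for i in range(12)],
            ["A", "B", "C"],
            rng.uniform(0, 500, size=(12, 3)),
        )
        for condition in Condition:
            loose = set(apply_threshold(matrix, lo, math.inf, condition).gene_ids)
            tight = set(apply_threshold(matrix, lo + delta, math.inf, condition).gene_ids)
            assert tight <= loose

    def test_all_samples_result_is_subset_of_any_sample(self):
        rng = np.random.default_rng(21)
        matrix = ExpressionMatrix(
            [f"ENSG{i + 1:011d}" for i in range(30)],
            [f"g{i}" for i in range(30)],
            [f"S{j}" for j in range(5)],
            rng.uniform(0, 300, size=(30, 5)),
        )
        strict = set(apply_threshold(matrix, 50, 250, Condition.ALL_SAMPLES).gene_ids)
        loose = set(apply_threshold(matrix, 50, 250, Condition.ANY_SAMPLE).gene_ids)
        assert strict <= loose


class TestAnnotateAndSummarize:
    def test_annotated_gene_carries_sorted_disease_terms(self, toy_dataset, toy_store):
        matrix = build_matrix(toy_dataset, QuerySpec(samples=["A", "B"]))
        table = annotate_result(matrix, toy_store, toy_dataset)
        by_gene = {row.ensembl_id: row for row in table.rows}
        assert by_gene[G1].diseases == ("arthritis", "asthma")
        assert by_gene[G1].mean_transcript_length == 1000.0

    def test_unannotated_gene_is_retained_with_empty_diseases(self, toy_dataset, toy_store):
        matrix = build_matrix(toy_dataset, QuerySpec(samples=["A", "B"]))
        table = annotate_result(matrix, toy_store, toy_dataset)
        by_gene = {row.ensembl_id: row for row in table.rows}
        assert by_gene[G3].diseases == ()

    def test_rows_ordered_by_descending_mean_abundance(self, toy_dataset, toy_store):
        matrix = build_matrix(toy_dataset, QuerySpec(samples=["A", "B"]))
        table = annotate_result(matrix, toy_store, toy_dataset)
        means = [float(np.mean(row.abundances)) for row in table.rows]
        assert means == sorted(means, reverse=True)

    def test_summary_counts_distinct_genes_per_disease(self, toy_dataset, toy_store):
        matrix = build_matrix(toy_dataset, QuerySpec(samples=["A", "B"]))
        table = annotate_result(matrix, toy_store, toy_dataset)
        summary = summarize_by_disease(table)
        assert summary == {"arthritis": 1, "asthma": 2, UNANNOTATED_KEY: 1}

    def test_summary_of_empty_table_is_empty(self, toy_dataset, toy_store):
        spec = QuerySpec(samples=["A"], min_value=1e9)
        table = run_query(toy_dataset, spec, toy_store)
        assert summarize_by_disease(table) == {}

    def test_summary_totals_equal_gene_disease_pairs(self, toy_dataset, toy_store):
        table = run_query(toy_dataset, QuerySpec(samples=["A", "B"]), toy_store)
        summary = summarize_by_disease(table)
        pairs = sum(len(row.diseases) for row in table.rows)
        assert sum(v for k, v in summary.items() if k != UNANNOTATED_KEY) == pairs

    def test_planted_panels_recovered_exactly(self, small_dataset, small_annotations,
                                              small_cohort, cutoff_query):
        _paths, _ann, truth = small_cohort
        table = run_query(small_dataset, cutoff_query, small_annotations)
        for term, expressed in truth.expressed_genes.items():
            recovered = sorted({r.ensembl_id for r in table.rows if term in r.diseases})
            assert recovered == expressed


class TestScaledTpm:
    def test_scales_by_library_size_in_millions(self):
        dataset = _dataset({G1: [50.0]}, ["A"])
        matrix = scaled_tpm_matrix(dataset, {"A": 20_000_000})
        assert matrix.values[0, 0] == 1000.0

    def test_unit_library_is_identity(self, small_dataset):
        sizes = {s: 1_000_000 for s in small_dataset.samples}
        matrix = scaled_tpm_matrix(small_dataset, sizes)
        np.testing.assert_array_equal(matrix.values, small_dataset.matrix("tpm"))

    def test_column_totals_equal_library_sizes_on_complete_fixture(
            self, small_dataset, small_cohort):
        _paths, _ann, truth = small_cohort
        matrix = scaled_tpm_matrix(small_dataset, truth.library_sizes)
        totals = matrix.values.sum(axis=0)
        expected = [truth.library_sizes[s] for s in matrix.sample_ids]
        np.testing.assert_allclose(totals, expected, rtol=1e-9)

    def test_non_positive_library_size_rejected(self, toy_dataset):
        with pytest.raises(ValidationError, match="library size"):
            scaled_tpm_matrix(toy_dataset, {"A": 0, "B": 1e6})


class TestQuerySpec:
    def test_dict_round_trip(self):
        spec = QuerySpec(samples=["A", "B"], abundance=Abundance.FPKM, min_value=10,
                         max_value=90, condition=Condition.MEAN_OF_SAMPLES,
                         cohorts={"control": ["A"], "diseased": ["B"]},
                         category=GeneCategoryFilter.CODING, diseases=["asthma"])
        assert QuerySpec.from_dict(spec.to_dict()) == spec

    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            (dict(samples=[]), "non-empty"),
            (dict(samples=["A"], min_value=-1), "min_value"),
            (dict(samples=["A"], min_value=10, max_value=5), "exceed"),
            (dict(samples=["A", "B"], cohorts={"control": ["A"]}), "partition"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, fragment):
        with pytest.raises(ValidationError, match=fragment):
            QuerySpec(**kwargs)

    def test_from_dict_rejects_unknown_enum_token(self):
        with pytest.raises(ValidationError, match="condition"):
            QuerySpec.from_dict({"samples": ["A"], "condition": "sometimes"})
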
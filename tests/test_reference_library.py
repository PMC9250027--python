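import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cysttea.errors import EmptyLibraryError, RangeError, UsageError
from cysttea.io_formats import AnnotationTable
from cysttea.reference_library import (
    ReferenceLibrary,
    build_ihc_reference,
    build_percentile_reference,
    filter_promiscuous,
    map_identifiers,
)


class TestIHCReference:
    def test_literal_level_and_fraction_reading(self, liver_annotations):
        # g2 fails the level criterion, g3 the fraction criterion
        library = build_ihc_reference(liver_annotations)
        assert library.tissues["liver"] == frozenset({"g1"})
        assert library.tissues["kidney"] == frozenset({"g4"})

    def test_gene_strong_in_two_tissues_is_in_both_sets(self):
        rows = pd.DataFrame(
            [
                ("g1", "liver", "strong", "25-75%"),
                ("g1", "kidney", "strong", "25-75%"),
            ],
            columns=["gene", "tissue", "level", "fraction"],
        )
        library = build_ihc_reference(AnnotationTable(rows))
        assert library.tissues["liver"] == library.tissues["kidney"] == frozenset({"g1"})

    def test_all_weak_raises_empty_library(self):
        rows = pd.DataFrame(
            [("g1", "liver", "weak", "25-75%")],
            columns=["gene", "tissue", "level", "fraction"],
        )
        with pytest.raises(EmptyLibraryError):
            build_ihc_reference(AnnotationTable(rows))

    def test_empty_annotations_is_usage_error(self):
        empty = AnnotationTable(
            pd.DataFrame(columns=["gene", "tissue", "level", "fraction"])
        )
        with pytest.raises(UsageError):
            build_ihc_reference(empty)


def _matrix(values_by_tissue):
    size = max(len(v) for v in values_by_tissue.values())
    index = [f"p{i:03d}" for i in range(size)]
    return pd.DataFrame(values_by_tissue, index=index, dtype=float)


class TestPercentileReference:
    def test_ramp_1_to_100_at_80th_selects_21(self):
        # nearest-rank threshold = value at rank ceil(0.80*100) = 80
        matrix = _matrix({"eye": np.arange(1.0, 101.0)})
        library = build_percentile_reference(matrix, 80.0)
        assert len(library.tissues["eye"]) == 21
        assert library.provenance["parameters"]["thresholds"]["eye"] == 80.0

    def test_all_equal_selects_all(self):
        matrix = _matrix({"eye": np.full(10, 7.0)})
        library = build_percentile_reference(matrix, 80.0)
        assert len(library.tissues["eye"]) == 10

    def test_percentile_100_selects_maxima_with_ties(self):
        matrix = _matrix({"eye": [1.0, 2.0, 5.0, 5.0]})
        library = build_percentile_reference(matrix, 100.0)
        assert library.tissues["eye"] == frozenset({"p002", "p003"})

    @pytest.mark.parametrize("bad", [0.0, -5.0, 101.0])
    def test_percentile_out_of_range(self, bad):
        matrix = _matrix({"eye": np.arange(1.0, 11.0)})
        with pytest.raises(RangeError):
            build_percentile_reference(matrix, bad)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0.0, 1e6), min_size=3, max_size=40),
        q_low=st.floats(5.0, 50.0),
        q_high=st.floats(51.0, 99.0),
    )
    def test_lower_percentile_selects_superset(self, values, q_low, q_high):
        matrix = _matrix({"t": np.asarray(values)})
        low = build_percentile_reference(matrix, q_low).tissues["t"]
        high = build_percentile_reference(matrix, q_high).tissues["t"]
        assert high <= low

    def test_selected_intensities_at_or_above_stored_threshold(self):
        rng = np.random.default_rng(7)
        matrix = _matrix({"a": rng.lognormal(3, 1, 50), "b": rng.lognormal(3, 1, 50)})
        library = build_percentile_reference(matrix, 80.0)
        thresholds = library.provenance["parameters"]["thresholds"]
        for tissue, members in library.tissues.items():
            assert (matrix.loc[sorted(members), tissue] >= thresholds[tissue]).all()


def _library(tissues):
    return ReferenceLibrary(
        name="x",
        tissues={t: frozenset(s) for t, s in tissues.items()},
        provenance={"method": "ihc_annotation", "parameters": {}},
    )


class TestPromiscuityFilter:
    def test_protein_in_three_of_five_sets_removed(self):
        library = _library(
            {
                "t1": {"shared", "a"}, "t2": {"shared", "b"}, "t3": {"shared", "c"},
                "t4": {"d"}, "t5": {"e"},
            }
        )
        filtered = filter_promiscuous(library, max_tissues=2)
        assert all("shared" not in s for s in filtered.tissues.values())

    def test_protein_in_exactly_two_sets_retained(self):
        library = _library({"t1": {"dual", "a"}, "t2": {"dual", "b"}})
        filtered = filter_promiscuous(library, max_tissues=2)
        assert "dual" in filtered.tissues["t1"] and "dual" in filtered.tissues["t2"]

    def test_unique_library_unchanged(self):
        library = _library({"t1": {"a"}, "t2": {"b"}})
        assert dict(filter_promiscuous(library).tissues) == dict(library.tissues)

    def test_idempotent(self):
        library = _library(
            {"t1": {"s", "a"}, "t2": {"s", "b"}, "t3": {"s", "c"}, "t4": {"d"}}
        )
        once = filter_promiscuous(library, 2)
        twice = filter_promiscuous(once, 2)
        assert dict(once.tissues) == dict(twice.tissues)

    def test_max_tissues_below_one_rejected(self):
        with pytest.raises(RangeError):
            filter_promiscuous(_library({"t": {"a"}}), 0)

    def test_strict_literal_reading_available(self):
        # max_tissues=1 discards anything present in two or more tissues
        library = _library({"t1": {"dual", "a"}, "t2": {"dual", "b"}})
        filtered = filter_promiscuous(library, max_tissues=1)
        assert dict(filtered.tissues) == {"t1": frozenset({"a"}), "t2": frozenset({"b"})}


class TestIdentifierMapping:
    def test_identity_mapping_unchanged(self):
        library = _library({"t": {"a", "b"}})
        mapped = map_identifiers(library, {"a": ["a"], "b": ["b"]})
        assert dict(mapped.tissues) == dict(library.tissues)

    def test_many_to_one_collapses_by_set_semantics(self):
        library = _library({"t": {"gA", "gB"}})
        mapped = map_identifiers(library, {"gA": ["P1"], "gB": ["P1"]})
        assert mapped.tissues["t"] == frozenset({"P1"})

    def test_one_to_many_expands(self):
        library = _library({"t": {"gA"}})
        mapped = map_identifiers(library, {"gA": ["P1", "P2"]})
        assert mapped.tissues["t"] == frozenset({"P1", "P2"})

    def test_unmapped_dropped_and_counted(self):
        library = _library({"t": {"gA", "gB"}})
        mapped = map_identifiers(library, {"gA": ["P1"]})
        assert mapped.tissues["t"] == frozenset({"P1"})
        assert mapped.provenance["parameters"]["unmapped_dropped"] == 1
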
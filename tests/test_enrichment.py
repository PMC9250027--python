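import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cysttea.enrichment import (
    QuerySet,
    bonferroni,
    hypergeom_lower,
    hypergeom_upper,
    run_enrichment,
    select_query,
)
from cysttea.errors import (
    ConsistencyError,
    DataSufficiencyError,
    DomainError,
    RangeError,
    SampleLookupError,
    UsageError,
)
from cysttea.io_formats import IntensityTable
from cysttea.reference_library import ReferenceLibrary


def exact_upper_tail(N: int, M: int, n: int, k: int) -> Fraction:
    """Rational-arithmetic enumeration of P(X >= k); the independent oracle."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, M) + 1):
        acc += Fraction(math.comb(M, i) * math.comb(N - M, n - i), total)
    return acc


class TestQuerySelection:
    def test_ramp_q98_threshold_and_members(self, ramp_table):
        query = select_query(ramp_table, "W7", 98.0)
        assert query.threshold == 98.0
        assert query.proteins == frozenset({"p098", "p099", "p100"})

    def test_all_equal_selects_everything(self):
        frame = pd.DataFrame(
            {"W7": np.full(20, 5.0)},
            index=pd.Index([f"p{i}" for i in range(20)], name="protein"),
        )
        query = select_query(IntensityTable(frame), "W7", 98.0)
        assert len(query) == 20

    def test_q50_on_1_to_10_selects_six(self):
        frame = pd.DataFrame(
            {"W7": np.arange(1.0, 11.0)},
            index=pd.Index([f"p{i}" for i in range(10)], name="protein"),
        )
        query = select_query(IntensityTable(frame), "W7", 50.0)
        assert query.threshold == 5.0
        assert len(query) == 6

    def test_unknown_sample(self, ramp_table):
        with pytest.raises(SampleLookupError):
            select_query(ramp_table, "W9")

    def test_too_few_detected(self):
        frame = pd.DataFrame(
            {"W7": [1.0] * 5},
            index=pd.Index([f"p{i}" for i in range(5)], name="protein"),
        )
        with pytest.raises(DataSufficiencyError):
            select_query(IntensityTable(frame), "W7")

    def test_missing_cells_excluded_from_distribution(self, small_table):
        # W4 has 9 detected values (one NaN); rank over those 9 only
        query = select_query(small_table, "W4", 50.0, min_detected=5)
        assert query.threshold == 50.0


class TestHypergeometricTails:
    def test_upper_at_zero_is_one(self):
        assert hypergeom_upper(10, 4, 5, 0) == 1.0

    def test_upper_worked_example(self):
        assert hypergeom_upper(10, 4, 5, 3) == pytest.approx(11 / 42, rel=1e-12)

    def test_upper_k_beyond_support_is_domain_error(self):
        with pytest.raises(DomainError):
            hypergeom_upper(10, 4, 5, 5)

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 1), (10, 4, 11, 1), (10, 4, 5, -1), (-1, 0, 0, 0)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(DomainError):
            hypergeom_upper(*args)

    def test_lower_at_support_max_is_one(self):
        assert hypergeom_lower(10, 4, 5, 4) == 1.0

    def test_lower_complement_of_upper_example(self):
        assert hypergeom_lower(10, 4, 5, 2) == pytest.approx(31 / 42, rel=1e-12)

    def test_lower_negative_k_is_domain_error(self):
        with pytest.raises(DomainError):
            hypergeom_lower(10, 4, 5, -1)

    def test_exact_oracle_small_grid(self):
        # exhaustive to N=12 here; the full N<=25 sweep runs in acceptance
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, M) + 1):
                        expected = float(exact_upper_tail(N, M, n, k))
                        assert hypergeom_upper(N, M, n, k) == pytest.approx(
                            expected, rel=1e-12
                        ), (N, M, n, k)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(data=st.data())
    def test_matches_scipy_sf_at_scale(self, data):
        N = data.draw(st.integers(1, 3000))
        M = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, M)))
        ours = hypergeom_upper(N, M, n, k)
        ref = float(hypergeom.sf(k - 1, N, M, n))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data())
    def test_tail_identities(self, data):
        N = data.draw(st.integers(1, 200))
        M = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        hi = min(n, M)
        assert hypergeom_upper(N, M, n, 0) == 1.0
        values = [hypergeom_upper(N, M, n, k) for k in range(hi + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        for k in range(hi):
            total = hypergeom_lower(N, M, n, k) + hypergeom_upper(N, M, n, k + 1)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestBonferroni:
    def test_single_test_identity(self):
        assert bonferroni([0.01]) == [0.01]

    def test_multiplication_and_clamp(self):
        assert bonferroni([0.01, 0.5]) == pytest.approx([0.02, 1.0])

    def test_family_of_44(self):
        adjusted = bonferroni([0.001] * 44)
        assert adjusted == pytest.approx([0.044] * 44)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(RangeError):
            bonferroni([0.5, bad])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(ps=st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_contract_and_rank_preservation(self, ps):
        adjusted = bonferroni(ps)
        T = len(ps)
        for p, pa in zip(ps, adjusted):
            assert pa == pytest.approx(min(1.0, p * T), rel=1e-12)
            assert pa >= p - 1e-15
        # ranking by adjusted p equals ranking by raw p up to clamp ties
        raw_order = np.argsort(ps, kind="stable")
        adj_sorted = np.asarray(adjusted)[raw_order]
        assert (np.diff(adj_sorted) >= -1e-15).all()


def _query(proteins, sample="W7", q=98.0, threshold=1.0):
    return QuerySet(
        sample_id=sample, percentile_q=q, threshold=threshold,
        proteins=frozenset(proteins),
    )


def _library(tissues):
    return ReferenceLibrary(
        name="x",
        tissues={t: frozenset(s) for t, s in tissues.items()},
        provenance={"method": "ihc_annotation", "parameters": {}},
    )


class TestRunEnrichment:
    universe = frozenset(f"p{i}" for i in range(10))

    def test_single_tissue_composition(self):
        library = _library({"liver": {"p0", "p1", "p2", "p3"}})
        query = _query({"p0", "p1", "p2", "p8", "p9"})
        records = run_enrichment(query, library, self.universe)
        assert len(records) == 1
        rec = records[0]
        assert (rec.universe_N, rec.tissue_M, rec.query_n, rec.overlap_k) == (10, 4, 5, 3)
        assert rec.p_raw == pytest.approx(11 / 42, rel=1e-12)
        assert rec.p_adj == pytest.approx(11 / 42, rel=1e-12)  # T = 1
        assert rec.overlap_proteins == frozenset({"p0", "p1", "p2"})

    def test_disjoint_tissues_give_p_one(self):
        library = _library({"a": {"p0"}, "b": {"p1"}})
        query = _query({"p8", "p9"})
        records = run_enrichment(query, library, self.universe)
        assert all(r.overlap_k == 0 and r.p_raw == 1.0 and r.p_adj == 1.0
                   for r in records)

    def test_tissue_outside_universe_skipped_and_family_reduced(self):
        library = _library({"inside": {"p0", "p1"}, "outside": {"zz1", "zz2"}})
        query = _query({"p0", "p9"})
        records = run_enrichment(query, library, self.universe)
        assert [r.tissue for r in records] == ["inside"]
        # T = 1, so p_adj equals p_raw
        assert records[0].p_adj == pytest.approx(records[0].p_raw)

    def test_query_not_subset_of_universe(self):
        library = _library({"a": {"p0"}})
        query = _query({"p0", "not_detected"})
        with pytest.raises(ConsistencyError):
            run_enrichment(query, library, self.universe)

    def test_records_sorted_by_adjusted_p_then_tissue(self):
        library = _library(
            {"hit": {"p0", "p1", "p2"}, "dud_b": {"p7"}, "dud_a": {"p8"}}
        )
        query = _query({"p0", "p1", "p2"})
        records = run_enrichment(query, library, self.universe)
        assert records[0].tissue == "hit"
        assert [r.tissue for r in records[1:]] == ["dud_a", "dud_b"]
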
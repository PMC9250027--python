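"""Percentile query selection and hypergeometric tissue enrichment.

The central computation of the pipeline: given a proteome sample, select
the highly expressed *query* proteins (those at or above the 98th
percentile of the sample's detected intensity distribution, by default)
and test, for each tissue in a reference library, whether the query
overlaps the tissue's protein set more than chance expects.

With N the number of proteins detected in the sample (the universe), M
the number of tissue-specific proteins inside that universe, n the query
size and k the observed overlap, the enrichment p-value is the upper tail
of the hypergeometric distribution,

    P(X >= k) = sum_{i=k}^{min(n,M)} C(M,i) C(N-M, n-i) / C(N,n),

computed in log-space via log-gamma binomial coefficients for numerical
stability. One test is run per tissue and the raw p-values are
Bonferroni-corrected across the tissues actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConsistencyError,
    DataSufficiencyError,
    DomainError,
    RangeError,
    UsageError,
)
from .io_formats import IntensityTable
from .percentiles import nearest_rank_threshold
from .reference_library import ReferenceLibrary

logger = logging.getLogger(__name__)

#: Smallest positive double; p-values are floored here, never reported as 0.
_P_FLOOR = float(np.nextafter(0.0, 1.0))

DEFAULT_QUERY_PERCENTILE = 98.0


@dataclass(frozen=True)
class QuerySet:
    """The highly expressed proteins of one sample.

    `threshold` is the nearest-rank intensity cutoff at `percentile_q`;
    every member's detected intensity is >= threshold.
    """

    sample_id: str
    percentile_q: float
    threshold: float
    proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise UsageError("a query set cannot be empty")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One tissue's hypergeometric test.

    N = universe (detected proteins), M = tissue-specific proteins within
    the universe, n = query size, k = overlap; p_raw = P(X >= k), p_adj =
    Bonferroni-adjusted p over the tissues tested in the same run.
    """

    tissue: str
    universe_N: int
    tissue_M: int
    query_n: int
    overlap_k: int
    p_raw: float
    p_adj: float
    overlap_proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_k <= min(self.query_n, self.tissue_M):
            raise DomainError(
                f"overlap k={self.overlap_k} outside [0, min(n, M)] for "
                f"n={self.query_n}, M={self.tissue_M}"
            )
        if self.tissue_M > self.universe_N or self.query_n > self.universe_N:
            raise DomainError("M and n must not exceed N")
        if not 0.0 < self.p_raw <= 1.0 or not self.p_raw <= self.p_adj <= 1.0:
            raise DomainError(
                f"p values out of order: p_raw={self.p_raw}, p_adj={self.p_adj}"
            )
        if self.overlap_k != len(self.overlap_proteins):
            raise ConsistencyError("overlap_k does not match |overlap_proteins|")


def select_query(
    table: IntensityTable,
    sample_id: str,
    percentile_q: float = DEFAULT_QUERY_PERCENTILE,
    min_detected: int = 10,
) -> QuerySet:
    """Select the sample's proteins at or above the percentile cutoff.

    The distribution is over the sample's *detected* intensities (zeros
    included, missing excluded); the nearest-rank threshold is inclusive,
    so ties at the cutoff all enter the query.
    """
    detected = table.detected(sample_id)
    if len(detected) < min_detected:
        raise DataSufficiencyError(
            f"sample {sample_id!r} has only {len(detected)} detected proteins "
            f"(>= {min_detected} required)"
        )
    threshold = nearest_rank_threshold(detected.to_numpy(), percentile_q)
    members = frozenset(detected.index[detected >= threshold].astype(str))
    return QuerySet(
        sample_id=sample_id,
        percentile_q=percentile_q,
        threshold=threshold,
        proteins=members,
    )


# ---------------------------------------------------------------------------
# Hypergeometric tails
# ---------------------------------------------------------------------------

def _check_domain(N: int, M: int, n: int, k: int) -> None:
    for name, v in (("N", N), ("M", M), ("n", n), ("k", k)):
        if v != int(v):
            raise DomainError(f"{name} must be an integer, got {v}")
    if N < 0 or M < 0 or n < 0:
        raise DomainError(f"N, M, n must be non-negative (N={N}, M={M}, n={n})")
    if M > N or n > N:
        raise DomainError(f"M={M} and n={n} must not exceed N={N}")
    if k < 0 or k > min(n, M):
        raise DomainError(
            f"k={k} outside [0, min(n, M)] = [0, {min(n, M)}] for n={n}, M={M}"
        )


def _log_binom(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf_sum(N: int, M: int, n: int, lo: int, hi: int) -> float:
    """log of sum_{i=lo}^{hi} C(M,i) C(N-M,n-i) / C(N,n); -inf if empty."""
    if hi < lo:
        return float("-inf")
    i = np.arange(lo, hi + 1, dtype=float)
    log_terms = (
        _log_binom(float(M), i)
        + _log_binom(float(N - M), float(n) - i)
        - _log_binom(float(N), float(n))
    )
    return float(logsumexp(log_terms))


def hypergeom_upper(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) of Hypergeometric(N, M, n), exact to ~1e-12.

    The tail is summed directly in log-space (all terms positive, so no
    cancellation). Results are floored at the smallest positive double so
    a p-value is never reported as exactly 0.
    """
    _check_domain(N, M, n, k)
    support_lo = max(0, n - (N - M))
    support_hi = min(n, M)
    if k <= support_lo:
        return 1.0
    # Direct log-space summation of the requested tail: all terms are
    # positive, so there is no cancellation whether the tail is tiny or
    # close to 1; a complement shortcut would destroy tiny tails.
    p = float(np.exp(_log_pmf_sum(N, M, n, k, support_hi)))
    if p <= 0.0:
        logger.warning(
            "hypergeometric tail underflowed for (N=%d, M=%d, n=%d, k=%d); "
            "flooring at %.3e", N, M, n, k, _P_FLOOR,
        )
        p = _P_FLOOR
    return min(p, 1.0)


def hypergeom_lower(N: int, M: int, n: int, k: int) -> float:
    """Lower-tail P(X <= k), the depletion counterpart of `hypergeom_upper`.

    Provided for reporting under-represented tissues; satisfies
    P(X <= k) + P(X >= k+1) = 1. Not part of the canonical enrichment
    test, which is upper-tail only.
    """
    _check_domain(N, M, n, k)
    support_lo = max(0, n - (N - M))
    support_hi = min(n, M)
    if k >= support_hi:
        return 1.0
    p = float(np.exp(_log_pmf_sum(N, M, n, support_lo, k)))
    if p <= 0.0:
        logger.warning(
            "hypergeometric tail underflowed for (N=%d, M=%d, n=%d, k=%d); "
            "flooring at %.3e", N, M, n, k, _P_FLOOR,
        )
        p = _P_FLOOR
    return min(p, 1.0)


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * T), order preserved."""
    if len(p_values) == 0:
        raise UsageError("no p-values to adjust")
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise RangeError(f"p-value {p} outside (0, 1]")
    _, p_adj, _, _ = multipletests(p_values, method="bonferroni")
    return [float(p) for p in p_adj]


def run_enrichment(
    query: QuerySet,
    library: ReferenceLibrary,
    universe: frozenset[str] | set[str],
) -> list[EnrichmentRecord]:
    """One hypergeometric test per tissue, Bonferroni-corrected.

    Tissue sets are intersected with the universe before M is counted (the
    formula needs M <= N, and N is defined as the proteins detected by
    MS). Tissues with no protein in the universe are skipped with a
    warning and do not count toward the correction family size T. Records
    are sorted ascending by p_adj, ties broken by tissue name.
    """
    universe = frozenset(universe)
    if not query.proteins <= universe:
        extra = sorted(query.proteins - universe)[:5]
        raise ConsistencyError(
            f"query proteins not in universe (e.g. {extra}); the universe must "
            "be the detected proteins of the queried sample"
        )
    if len(library) == 0:
        raise UsageError("reference library is empty")

    N = len(universe)
    n = len(query.proteins)
    tested: list[tuple[str, int, int, frozenset[str], float]] = []
    for tissue in sorted(library.tissues):
        tissue_in_universe = library.tissues[tissue] & universe
        M = len(tissue_in_universe)
        if M == 0:
            logger.warning(
                "tissue %r has no protein in the detected universe; skipped "
                "(not counted in the correction family)", tissue,
            )
            continue
        overlap = frozenset(tissue_in_universe & query.proteins)
        p_raw = hypergeom_upper(N, M, n, len(overlap))
        tested.append((tissue, M, len(overlap), overlap, p_raw))
    if not tested:
        raise UsageError("every tissue was skipped; nothing to test")

    p_adj = bonferroni([t[4] for t in tested])
    records = [
        EnrichmentRecord(
            tissue=tissue,
            universe_N=N,
            tissue_M=M,
            query_n=n,
            overlap_k=k,
            p_raw=p_raw,
            p_adj=pa,
            overlap_proteins=overlap,
        )
        for (tissue, M, k, overlap, p_raw), pa in zip(tested, p_adj)
    ]
    records.sort(key=lambda r: (r.p_adj, r.tissue))
    return records
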
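"""Percentile-cutoff sensitivity of the enrichment ranking.

Enrichment p-values move with the query percentile cutoff, but the
*qualitative* result — which tissues lead the ranking — should not. This
module operationalizes that claim: re-run the query selection and
enrichment at several cutoffs and score how much the top of the ranking
is conserved between cutoffs, as the pairwise top-k overlap fraction
(k = 3 by default). Spearman rank correlation over the full ranking is
available as an alternative metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .errors import DataSufficiencyError, RangeError, UsageError
from .enrichment import EnrichmentRecord, run_enrichment, select_query
from .io_formats import IntensityTable
from .reference_library import ReferenceLibrary

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class SweepResult:
    """Per-cutoff enrichment rankings plus a pairwise stability matrix.

    `cutoffs` holds the non-degenerate cutoffs in the order supplied;
    `records` the corresponding enrichment runs; `stability[i, j]` the
    top-k overlap fraction between rankings i and j (symmetric, unit
    diagonal); `degenerate` the cutoffs that produced no usable query.
    """

    cutoffs: tuple[float, ...]
    records: tuple[tuple[EnrichmentRecord, ...], ...]
    stability: np.ndarray
    top_k: int
    degenerate: tuple[float, ...] = ()

    @property
    def rankings(self) -> list[list[str]]:
        """Tissue labels ordered by ascending adjusted p, one list per cutoff."""
        return [[r.tissue for r in recs] for recs in self.records]

    def mean_stability(self) -> float:
        """Mean off-diagonal stability; NaN with fewer than two rankings."""
        m = self.stability.shape[0]
        if m < 2:
            return float("nan")
        mask = ~np.eye(m, dtype=bool)
        return float(self.stability[mask].mean())


def rank_stability(rankings: list[list[str]], k: int = DEFAULT_TOP_K) -> np.ndarray:
    """Pairwise top-k overlap matrix: score(a, b) = |top_k(a) & top_k(b)| / k."""
    if len(rankings) < 2:
        raise UsageError("need at least two rankings to score stability")
    if k < 1:
        raise RangeError(f"top size k must be >= 1, got {k}")
    shortest = min(len(r) for r in rankings)
    if k > shortest:
        raise RangeError(f"k={k} exceeds the shortest ranking length {shortest}")
    tops = [set(r[:k]) for r in rankings]
    m = len(tops)
    scores = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            scores[i, j] = scores[j, i] = len(tops[i] & tops[j]) / k
    return scores


def rank_correlation(rankings: list[list[str]]) -> np.ndarray:
    """Pairwise Spearman correlation of tissue ranks (common tissues only)."""
    if len(rankings) < 2:
        raise UsageError("need at least two rankings to correlate")
    m = len(rankings)
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            common = sorted(set(rankings[i]) & set(rankings[j]))
            if len(common) < 2:
                out[i, j] = out[j, i] = np.nan
                continue
            ri = [rankings[i].index(t) for t in common]
            rj = [rankings[j].index(t) for t in common]
            out[i, j] = out[j, i] = spearmanr(ri, rj).statistic
    return out


def sweep_percentiles(
    table: IntensityTable,
    sample_id: str,
    library: ReferenceLibrary,
    cutoffs: list[float],
    top_k: int = DEFAULT_TOP_K,
) -> SweepResult:
    """Run query selection + enrichment at each percentile cutoff.

    Cutoffs that yield no usable query (too few detected proteins at the
    cutoff) are recorded as degenerate and excluded from the stability
    matrix with a warning.
    """
    if len(cutoffs) < 2:
        raise UsageError("a sweep needs at least two cutoffs")
    for q in cutoffs:
        if not 0.0 < q <= 100.0:
            raise RangeError(f"cutoff {q} outside (0, 100]")

    kept: list[float] = []
    runs: list[tuple[EnrichmentRecord, ...]] = []
    degenerate: list[float] = []
    universe = frozenset(table.detected(sample_id).index.astype(str))
    for q in cutoffs:
        try:
            query = select_query(table, sample_id, percentile_q=q)
        except DataSufficiencyError as exc:
            logger.warning("cutoff %s degenerate: %s", q, exc)
            degenerate.append(q)
            continue
        records = run_enrichment(query, library, universe)
        kept.append(q)
        runs.append(tuple(records))

    if len(kept) >= 2:
        stability = rank_stability([[r.tissue for r in run] for run in runs], k=top_k)
    else:
        stability = np.ones((len(kept), len(kept)))
    return SweepResult(
        cutoffs=tuple(kept),
        records=tuple(runs),
        stability=stability,
        top_k=top_k,
        degenerate=tuple(degenerate),
    )
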
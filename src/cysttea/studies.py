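"""End-to-end study runners over the synthetic presets.

Each runner simulates one seeded experiment under the documented study
conditions and measures the quantity the pipeline is supposed to
deliver: signal recovery (does the planted tissue rank first and reach
significance?), null calibration (how often does any tissue reach
family-wise significance when nothing is planted?), and ranking
stability across percentile cutoffs. They exist so the same computation
backs the test suite, the acceptance report, and the analysis scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrichment import EnrichmentRecord, run_enrichment, select_query
from .io_formats import IntensityTable
from .reference_library import ReferenceLibrary
from .sensitivity import sweep_percentiles
from .synthetic import PRESETS, simulate_experiment

DEFAULT_CUTOFFS = (95.0, 97.0, 98.0, 99.0)


def enrich_sample(
    table: IntensityTable,
    library: ReferenceLibrary,
    sample_id: str = "W7",
    percentile_q: float = 98.0,
) -> list[EnrichmentRecord]:
    """Query selection + enrichment with the universe taken from the sample."""
    universe = frozenset(table.detected(sample_id).index.astype(str))
    query = select_query(table, sample_id, percentile_q=percentile_q)
    return run_enrichment(query, library, universe)


@dataclass(frozen=True)
class RecoveryOutcome:
    planted_tissue: str
    top_tissue: str
    p_adj_planted: float
    recovered: bool  # planted ranked first at family-wise significance


def recovery_trial(seed: int, alpha: float = 0.05, **overrides) -> RecoveryOutcome:
    """One seeded run of the planted-signal (recovery) condition."""
    params = {**PRESETS["recovery"], **overrides}
    table, library, _, truth = simulate_experiment(seed, **params)
    records = enrich_sample(table, library, percentile_q=truth.percentile_q)
    by_tissue = {r.tissue: r for r in records}
    planted = truth.planted_tissue
    return RecoveryOutcome(
        planted_tissue=planted,
        top_tissue=records[0].tissue,
        p_adj_planted=by_tissue[planted].p_adj,
        recovered=records[0].tissue == planted and records[0].p_adj < alpha,
    )


def null_trial(seed: int, alpha: float = 0.05, **overrides) -> bool:
    """One seeded no-signal run; True if any tissue reaches p_adj < alpha."""
    params = {**PRESETS["null"], **overrides}
    table, library, _, truth = simulate_experiment(seed, **params)
    records = enrich_sample(table, library, percentile_q=truth.percentile_q)
    return any(r.p_adj < alpha for r in records)


@dataclass(frozen=True)
class StabilityOutcome:
    planted_tissue: str
    planted_top3_everywhere: bool
    mean_stability: float

    @property
    def qualitative_result_stable(self) -> bool:
        """The tracked tissue leads every cutoff and the top-3 is conserved."""
        return self.planted_top3_everywhere and self.mean_stability > 0.66


def stability_trial(
    seed: int,
    effect_fraction: float,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    top_k: int = 3,
    **overrides,
) -> StabilityOutcome:
    """One seeded percentile sweep; scores conservation of the top ranking."""
    params = {**PRESETS["recovery"], **overrides, "effect_fraction": effect_fraction}
    table, library, _, truth = simulate_experiment(seed, **params)
    result = sweep_percentiles(table, "W7", library, list(cutoffs), top_k=top_k)
    planted = truth.planted_tissue
    in_top3 = all(planted in ranking[:top_k] for ranking in result.rankings)
    return StabilityOutcome(
        planted_tissue=planted,
        planted_top3_everywhere=in_top3,
        mean_stability=result.mean_stability(),
    )
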
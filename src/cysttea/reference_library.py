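"""Tissue -> protein-set reference libraries.

Two construction routes mirror the two kinds of tissue resources the
enrichment stage consumes:

* the *annotation* route (``build_ihc_reference``) takes IHC-style
  annotation rows and calls a protein tissue-specific when it shows a
  chosen staining level in a chosen fraction of cells — by default a
  strong staining intensity in 25-75% of cells, the Human Protein Atlas
  style criterion;
* the *expression* route (``build_percentile_reference``) takes a
  protein x tissue intensity matrix and keeps, per tissue, the proteins
  at or above a nearest-rank percentile cutoff of that tissue's detected
  expression distribution (80th percentile by convention for published
  tissue proteomes).

``filter_promiscuous`` then removes proteins that appear in many tissue
sets: a protein found in more than `max_tissues` tissues (default 2) is
considered non-specifically expressed and dropped from every set. The
threshold is configurable, so the stricter reading — discarding anything
found in two or more tissues — can be run as well (``max_tissues=1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyLibraryError,
    IntegrityError,
    RangeError,
    UsageError,
)
from .io_formats import AnnotationTable
from .percentiles import nearest_rank_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceLibrary:
    """Named mapping tissue -> protein-id set, with construction provenance.

    `provenance["method"]` is ``ihc_annotation`` or ``percentile_expression``;
    `provenance["parameters"]` records the level/fraction or percentile (and,
    for the expression route, the per-tissue thresholds) plus any filters
    applied afterwards.
    """

    name: str
    tissues: Mapping[str, frozenset[str]]
    provenance: Mapping[str, object]

    def __post_init__(self) -> None:
        if "method" not in self.provenance:
            raise IntegrityError("reference library provenance lacks 'method'")
        empty = sorted(t for t, s in self.tissues.items() if not s)
        if empty:
            raise IntegrityError(f"empty tissue set(s) in library: {empty}")

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.tissues.values():
            out |= s
        return frozenset(out)

    def tissue_counts(self) -> dict[str, int]:
        """Number of tissue sets each protein occurs in."""
        counts: dict[str, int] = {}
        for s in self.tissues.values():
            for p in s:
                counts[p] = counts.get(p, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.tissues)


def build_ihc_reference(
    annotations: AnnotationTable,
    level: str = "strong",
    fraction: str = "25-75%",
    name: str = "ihc_reference",
) -> ReferenceLibrary:
    """Tissue sets from annotation rows matching one (level, fraction) pair.

    A gene belongs to a tissue's set when at least one of its annotation
    rows in that tissue has exactly the requested staining level and
    stained-cell fraction; a gene may belong to several tissues (no
    exclusivity at this stage — see ``filter_promiscuous``).
    """
    if len(annotations) == 0:
        raise UsageError("annotation table is empty")
    rows = annotations.rows
    hits = rows[(rows["level"] == level) & (rows["fraction"] == fraction)]
    tissues = {
        tissue: frozenset(group["gene"])
        for tissue, group in hits.groupby("tissue", sort=True)
    }
    if not tissues:
        raise EmptyLibraryError(
            f"no annotation row matches level={level!r}, fraction={fraction!r} "
            "in any tissue"
        )
    return ReferenceLibrary(
        name=name,
        tissues=tissues,
        provenance={
            "method": "ihc_annotation",
            "parameters": {"level": level, "fraction": fraction},
        },
    )


def build_percentile_reference(
    matrix: pd.DataFrame,
    percentile: float = 80.0,
    name: str = "percentile_reference",
) -> ReferenceLibrary:
    """Tissue sets from an expression matrix via a nearest-rank cutoff.

    Per tissue column, proteins with detected (non-missing) intensity at
    or above the percentile threshold of that tissue's detected
    distribution are selected; ties at the threshold are included. Zero
    intensities count as detected. Per-tissue thresholds are recorded in
    the provenance parameters.
    """
    if not 0.0 < percentile <= 100.0:
        raise RangeError(f"percentile must be in (0, 100], got {percentile}")
    if matrix.shape[1] < 1:
        raise UsageError("expression matrix needs at least one tissue column")
    tissues: dict[str, frozenset[str]] = {}
    thresholds: dict[str, float] = {}
    for tissue in matrix.columns:
        detected = matrix[tissue].dropna()
        if detected.empty:
            logger.warning("tissue %r has no detected intensities; dropped", tissue)
            continue
        threshold = nearest_rank_threshold(detected.to_numpy(), percentile)
        members = frozenset(detected.index[detected >= threshold].astype(str))
        thresholds[str(tissue)] = threshold
        if members:
            tissues[str(tissue)] = members
    if not tissues:
        raise EmptyLibraryError("no tissue yielded a non-empty percentile set")
    return ReferenceLibrary(
        name=name,
        tissues=tissues,
        provenance={
            "method": "percentile_expression",
            "parameters": {"percentile": percentile, "thresholds": thresholds},
        },
    )


def filter_promiscuous(
    library: ReferenceLibrary, max_tissues: int = 2
) -> ReferenceLibrary:
    """Drop proteins occurring in more than `max_tissues` tissue sets.

    Tissues whose sets become empty are dropped with a warning. The
    operation is idempotent and records itself in the provenance.
    """
    if max_tissues < 1:
        raise RangeError(f"max_tissues must be >= 1, got {max_tissues}")
    counts = library.tissue_counts()
    promiscuous = {p for p, c in counts.items() if c > max_tissues}
    tissues: dict[str, frozenset[str]] = {}
    for tissue, members in library.tissues.items():
        kept = frozenset(members - promiscuous)
        if kept:
            tissues[tissue] = kept
        else:
            logger.warning(
                "tissue %r lost all proteins to the promiscuity filter; dropped",
                tissue,
            )
    if not tissues:
        raise EmptyLibraryError(
            f"promiscuity filter (max_tissues={max_tissues}) emptied the library"
        )
    parameters = dict(library.provenance.get("parameters", {}))
    parameters["max_tissues"] = max_tissues
    parameters["promiscuous_removed"] = len(promiscuous)
    return ReferenceLibrary(
        name=library.name,
        tissues=tissues,
        provenance={"method": library.provenance["method"], "parameters": parameters},
    )


def map_identifiers(
    library: ReferenceLibrary, mapping: Mapping[str, list[str]]
) -> ReferenceLibrary:
    """Translate every protein id through a (possibly one-to-many) mapping.

    Unmapped ids are dropped; the total number dropped is logged and
    recorded in provenance. Tissues emptied by the translation are dropped
    with a warning.
    """
    dropped = 0
    tissues: dict[str, frozenset[str]] = {}
    for tissue, members in library.tissues.items():
        translated: set[str] = set()
        for p in members:
            targets = mapping.get(p)
            if targets is None:
                dropped += 1
            else:
                translated.update(targets)
        if translated:
            tissues[tissue] = frozenset(translated)
        else:
            logger.warning("tissue %r empty after identifier mapping; dropped", tissue)
    if dropped:
        logger.warning("identifier mapping dropped %d unmapped protein id(s)", dropped)
    if not tissues:
        raise EmptyLibraryError("identifier mapping emptied the library")
    parameters = dict(library.provenance.get("parameters", {}))
    parameters["unmapped_dropped"] = dropped
    return ReferenceLibrary(
        name=library.name,
        tissues=tissues,
        provenance={"method": library.provenance["method"], "parameters": parameters},
    )
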
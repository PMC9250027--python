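"""Epithelial/mesenchymal marker fold-change profiling.

Classifies each marker protein of a panel by its intensity change between
an early and a late collection (week 4 vs week 7 of differentiation,
equivalently day 28 vs day 45 — both label conventions are accepted):

* fold change = late / early, defined when both intensities are > 0;
* fold change >= 2.0 -> ``upregulated``; <= 0.5 -> ``downregulated``
  (both boundaries inclusive); otherwise ``unchanged``;
* early = 0, late > 0 -> ``gained``; early > 0, late = 0 -> ``lost``;
  both zero or missing -> ``absent``. A panel member entirely absent from
  the table is reported ``absent`` (logged), not an error.

``marker_matrix`` lays the calls out as a log10-intensity matrix (rows
grouped by panel class) for heatmap rendering; zero intensities are
floored one decade below the smallest positive intensity and flagged in
companion mask columns so rendering never has to invent a detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError
from .io_formats import IntensityTable, MarkerPanel

logger = logging.getLogger(__name__)

UPREGULATED_FC = 2.0
DOWNREGULATED_FC = 0.5

#: The two collections appear under week-based and day-based labels.
SAMPLE_ALIASES = {"W4": "D28", "D28": "W4", "W7": "D45", "D45": "W7"}


@dataclass(frozen=True)
class MarkerCall:
    """One marker's two-timepoint intensities, fold change and call."""

    protein_id: str
    panel_class: str
    intensity_early: float
    intensity_late: float
    fold_change: float | None
    call: str  # upregulated | downregulated | unchanged | gained | lost | absent


def _resolve_sample(table: IntensityTable, label: str) -> str:
    if label in table.samples:
        return label
    alias = SAMPLE_ALIASES.get(label)
    if alias is not None and alias in table.samples:
        return alias
    from .errors import SampleLookupError

    raise SampleLookupError(
        f"sample {label!r} (or alias) not in table; have {table.samples}"
    )


def _classify(early: float, late: float) -> tuple[float | None, str]:
    if early == 0.0 and late == 0.0:
        return None, "absent"
    if early == 0.0:
        return None, "gained"
    if late == 0.0:
        return None, "lost"
    fc = late / early
    if fc >= UPREGULATED_FC:
        return fc, "upregulated"
    if fc <= DOWNREGULATED_FC:
        return fc, "downregulated"
    return fc, "unchanged"


def call_markers(
    table: IntensityTable,
    panel: MarkerPanel,
    sample_early: str = "W4",
    sample_late: str = "W7",
) -> list[MarkerCall]:
    """One :class:`MarkerCall` per panel member.

    Missing intensities (not measured) are treated as not detected, i.e.
    0, for calling purposes; markers absent from the table altogether are
    called ``absent`` and logged.
    """
    early_col = _resolve_sample(table, sample_early)
    late_col = _resolve_sample(table, sample_late)
    known = set(table.proteins)
    calls = []
    for protein_id, panel_class in panel.members:
        if protein_id not in known:
            logger.warning("panel marker %r not in intensity table; absent", protein_id)
            early = late = 0.0
        else:
            row = table.data.loc[protein_id]
            early = 0.0 if pd.isna(row[early_col]) else float(row[early_col])
            late = 0.0 if pd.isna(row[late_col]) else float(row[late_col])
        fc, call = _classify(early, late)
        calls.append(
            MarkerCall(
                protein_id=protein_id,
                panel_class=panel_class,
                intensity_early=early,
                intensity_late=late,
                fold_change=fc,
                call=call,
            )
        )
    return calls


def marker_matrix(
    calls: list[MarkerCall],
    label_early: str = "W4",
    label_late: str = "W7",
) -> pd.DataFrame:
    """Heatmap-ready log10 matrix, rows grouped by panel class.

    Columns: ``panel_class``, ``log10_<early>``, ``log10_<late>``,
    ``floored_<early>``, ``floored_<late>``, ``fold_change``, ``call``.
    The floor for zero intensities sits one decade below the smallest
    positive intensity among the calls; the mask columns flag floored
    cells.
    """
    if not calls:
        raise UsageError("no marker calls to lay out")
    positives = [
        v
        for c in calls
        for v in (c.intensity_early, c.intensity_late)
        if v > 0
    ]
    floor = math.log10(min(positives)) - 1.0 if positives else 0.0

    def _log10(v: float) -> tuple[float, bool]:
        if v > 0:
            return math.log10(v), False
        return floor, True

    rows = []
    for c in sorted(calls, key=lambda c: (c.panel_class, c.protein_id)):
        le, fe = _log10(c.intensity_early)
        ll, fl = _log10(c.intensity_late)
        rows.append(
            {
                "protein_id": c.protein_id,
                "panel_class": c.panel_class,
                f"log10_{label_early}": le,
                f"log10_{label_late}": ll,
                f"floored_{label_early}": fe,
                f"floored_{label_late}": fl,
                "fold_change": np.nan if c.fold_change is None else c.fold_change,
                "call": c.call,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def write_marker_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", float_format="%.6g")
    return path


def write_marker_calls(calls: list[MarkerCall], path: str | Path) -> Path:
    """Flat TSV of the calls (protein, class, intensities, FC, call)."""
    path = Path(path)
    rows = [
        {
            "protein_id": c.protein_id,
            "panel_class": c.panel_class,
            "intensity_early": c.intensity_early,
            "intensity_late": c.intensity_late,
            "fold_change": "" if c.fold_change is None else f"{c.fold_change:.6g}",
            "call": c.call,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
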
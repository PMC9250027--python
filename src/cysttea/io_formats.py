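"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are tab-separated UTF-8 text with a header row;
reference libraries are JSON. Readers validate strictly and report the
offending row and column rather than silently coercing; writers use a
fixed, documented column order so outputs are diff-stable.

Domain types
------------
:class:`IntensityTable`
    Per-protein, per-sample label-free MS intensities. An intensity of 0
    means *detected-absent* and is distinct from a missing cell (empty or
    ``NA``), which means *not measured*; the percentile machinery includes
    zeros in the expression distribution but never missing cells.
:class:`AnnotationTable`
    Immunohistochemistry-style tissue annotations (gene, tissue, staining
    level, stained-cell fraction), emulating Human Protein Atlas
    normal-tissue annotation rows.
:class:`MarkerPanel`
    A curated marker list with a class per protein (mesenchymal /
    epithelial by default; extensible).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    RangeError,
    UsageError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

STAINING_LEVELS = ("not_detected", "weak", "moderate", "strong")
CELL_FRACTIONS = ("<25%", "25-75%", ">75%")
DEFAULT_PANEL_CLASSES = ("mesenchymal", "epithelial")

#: Fixed column order of the enrichment-results TSV.
ENRICHMENT_COLUMNS = (
    "tissue", "N", "M", "n", "k", "p_raw", "p_adj", "overlap_proteins",
)


# ---------------------------------------------------------------------------
# IntensityTable
# ---------------------------------------------------------------------------

class IntensityTable:
    """Protein x sample intensity matrix with explicit missingness.

    Wraps a float DataFrame indexed by protein accession with one column
    per sample; ``NaN`` encodes a missing (unmeasured) cell. Invariants:
    unique protein ids, all stored intensities >= 0, at least one sample.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] < 1:
            raise UsageError("an intensity table needs at least one sample column")
        if data.index.duplicated().any():
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise IntegrityError(f"duplicate protein ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise RangeError("negative intensity in table")
        self._data = data.astype(float)
        self._data.index = self._data.index.astype(str)
        self._data.index.name = "protein"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def samples(self) -> list[str]:
        return [str(c) for c in self._data.columns]

    @property
    def proteins(self) -> list[str]:
        return [str(p) for p in self._data.index]

    def detected(self, sample_id: str) -> pd.Series:
        """Non-missing intensities of one sample (zeros included)."""
        if sample_id not in self._data.columns:
            from .errors import SampleLookupError

            raise SampleLookupError(
                f"sample {sample_id!r} not in table (have {self.samples})"
            )
        return self._data[sample_id].dropna()

    def __len__(self) -> int:
        return int(self._data.notna().sum().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self._data, other._data)
        except AssertionError:
            return False
        return True

    def __repr__(self) -> str:
        return (
            f"IntensityTable({self._data.shape[0]} proteins x "
            f"{self._data.shape[1]} samples, {len(self)} entries)"
        )


def read_intensity_table(
    path: str | Path,
    sample_columns: Sequence[str],
    protein_column: str = "protein",
) -> IntensityTable:
    """Read a MaxQuant-proteinGroups-like TSV into an :class:`IntensityTable`.

    `sample_columns` selects the intensity columns to keep; the identifier
    column is configurable because MaxQuant exports several candidate
    columns ("Protein IDs", "Majority protein IDs", ...). Empty cells and
    the literal strings ``NA``/``NaN`` become missing entries.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in [protein_column, *sample_columns] if c not in raw.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: missing required column(s) {missing_cols}; "
            f"found {list(raw.columns)}"
        )
    if raw[protein_column].duplicated().any():
        dupes = sorted(raw[protein_column][raw[protein_column].duplicated()].unique())
        raise IntegrityError(f"{path}: duplicate protein id(s) {dupes}")

    parsed = pd.DataFrame(index=pd.Index(raw[protein_column], name="protein"))
    for col in sample_columns:
        out = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                continue
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric intensity {cell!r} at row {i + 2}, "
                    f"column {col!r}"
                ) from None
            if value < 0:
                raise RangeError(
                    f"{path}: negative intensity {value} at row {i + 2}, "
                    f"column {col!r}"
                )
            out[i] = value
        parsed[col] = out
    return IntensityTable(parsed)


def write_intensity_table(table: IntensityTable, path: str | Path) -> Path:
    """Write an intensity table as TSV; missing cells become empty strings."""
    path = Path(path)
    frame = table.data.copy()
    frame.to_csv(path, sep="\t", float_format="%.12g", na_rep="")
    return path


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationTable:
    """Validated IHC-style annotation rows (gene, tissue, level, fraction)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "tissue", "level", "fraction"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"annotation table missing column(s) {missing}")
        bad_level = set(self.rows["level"]) - set(STAINING_LEVELS)
        if bad_level:
            raise VocabularyError(
                f"unknown staining level(s) {sorted(bad_level)}; "
                f"allowed: {list(STAINING_LEVELS)}"
            )
        bad_frac = set(self.rows["fraction"]) - set(CELL_FRACTIONS)
        if bad_frac:
            raise VocabularyError(
                f"unknown cell fraction(s) {sorted(bad_frac)}; "
                f"allowed: {list(CELL_FRACTIONS)}"
            )
        if self.rows.duplicated().any():
            dupes = self.rows[self.rows.duplicated()]
            raise IntegrityError(
                f"fully identical duplicate annotation rows: "
                f"{dupes.to_dict(orient='records')[:5]}"
            )

    def __len__(self) -> int:
        return len(self.rows)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a (gene, tissue, level, fraction) TSV with vocabulary checks."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene", "tissue", "level", "fraction"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("level", "fraction"):
        allowed = STAINING_LEVELS if col == "level" else CELL_FRACTIONS
        for i, cell in enumerate(raw[col]):
            if cell not in allowed:
                raise VocabularyError(
                    f"{path}: unknown {col} {cell!r} at row {i + 2}; "
                    f"allowed: {list(allowed)}"
                )
    return AnnotationTable(raw[required].reset_index(drop=True))


def write_annotation_table(table: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    table.rows.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# MarkerPanel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Curated marker list: protein accession -> panel class."""

    members: tuple[tuple[str, str], ...]
    classes: tuple[str, ...] = DEFAULT_PANEL_CLASSES

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.members]
        if len(ids) != len(set(ids)):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise IntegrityError(f"duplicate protein id(s) in panel: {dupes}")
        bad = sorted({c for _, c in self.members} - set(self.classes))
        if bad:
            raise VocabularyError(
                f"unknown panel class(es) {bad}; allowed: {list(self.classes)}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return [p for p, _ in self.members]

    def class_of(self, protein_id: str) -> str:
        return dict(self.members)[protein_id]

    def __len__(self) -> int:
        return len(self.members)


def read_marker_panel(
    path: str | Path, classes: Sequence[str] = DEFAULT_PANEL_CLASSES
) -> MarkerPanel:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein_id", "panel_class"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    members = tuple(zip(raw["protein_id"], raw["panel_class"]))
    return MarkerPanel(members, tuple(classes))


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(panel.members, columns=["protein_id", "panel_class"]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Enrichment results
# ---------------------------------------------------------------------------

def write_enrichment_results(records: Sequence, path: str | Path) -> Path:
    """Serialize enrichment records as a sorted TSV.

    Columns: tissue, N, M, n, k, p_raw, p_adj, overlap_proteins
    (semicolon-joined, sorted). Rows sorted ascending by p_adj, ties
    broken alphabetically by tissue. Probabilities are written at 12
    significant digits, which round-trips within 1e-12 relative error.
    """
    if len(records) == 0:
        raise UsageError("no enrichment records to write")
    path = Path(path)
    rows = []
    for rec in records:
        rows.append(
            {
                "tissue": rec.tissue,
                "N": rec.universe_N,
                "M": rec.tissue_M,
                "n": rec.query_n,
                "k": rec.overlap_k,
                "p_raw": f"{rec.p_raw:.12g}",
                "p_adj": f"{rec.p_adj:.12g}",
                "overlap_proteins": ";".join(sorted(rec.overlap_proteins)),
            }
        )
    frame = pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))
    frame = frame.sort_values(
        ["p_adj", "tissue"], key=lambda s: s.astype(float) if s.name == "p_adj" else s
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_enrichment_results(path: str | Path) -> list:
    """Read an enrichment TSV back into EnrichmentRecord objects."""
    from .enrichment import EnrichmentRecord  # local import to avoid a cycle

    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ENRICHMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in raw.iterrows():
        overlap = frozenset(p for p in row["overlap_proteins"].split(";") if p)
        records.append(
            EnrichmentRecord(
                tissue=row["tissue"],
                universe_N=int(row["N"]),
                tissue_M=int(row["M"]),
                query_n=int(row["n"]),
                overlap_k=int(row["k"]),
                p_raw=float(row["p_raw"]),
                p_adj=float(row["p_adj"]),
                overlap_proteins=overlap,
            )
        )
    return records


# ---------------------------------------------------------------------------
# ReferenceLibrary JSON
# ---------------------------------------------------------------------------

def write_reference(library, path: str | Path) -> Path:
    """Serialize a ReferenceLibrary to JSON with its provenance block."""
    path = Path(path)
    doc = {
        "name": library.name,
        "provenance": {
            "method": library.provenance["method"],
            "parameters": library.provenance.get("parameters", {}),
        },
        "tissues": {t: sorted(s) for t, s in sorted(library.tissues.items())},
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_reference(path: str | Path):
    """Read a ReferenceLibrary JSON; a missing provenance block is an error."""
    from .reference_library import ReferenceLibrary  # avoid import cycle

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("name", "provenance", "tissues"):
        if key not in doc:
            raise FormatError(f"{path}: missing top-level {key!r} block")
    if "method" not in doc["provenance"]:
        raise FormatError(f"{path}: provenance block lacks 'method'")
    tissues = {t: frozenset(ids) for t, ids in doc["tissues"].items()}
    return ReferenceLibrary(
        name=doc["name"],
        tissues=tissues,
        provenance={
            "method": doc["provenance"]["method"],
            "parameters": doc["provenance"].get("parameters", {}),
        },
    )


# ---------------------------------------------------------------------------
# Expression matrices & id mappings
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein x tissue expression TSV (first column = protein id)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "NaN"])
    if frame.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix needs >= 1 tissue column")
    if frame.index.duplicated().any():
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise IntegrityError(f"{path}: duplicate protein id(s) {dupes}")
    values = frame.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise RangeError(f"{path}: negative intensity in expression matrix")
    frame.index = frame.index.astype(str)
    frame.index.name = "protein"
    return frame


def read_mapping(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (id_from, id_to) TSV; one-to-many targets allowed."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: mapping needs two columns (from, to)")
    if raw.duplicated().any():
        dupes = raw[raw.duplicated()]
        raise IntegrityError(
            f"{path}: duplicate mapping row(s) {dupes.to_dict(orient='records')[:5]}"
        )
    mapping: dict[str, list[str]] = {}
    for _, row in raw.iterrows():
        mapping.setdefault(row.iloc[0], []).append(row.iloc[1])
    return mapping
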
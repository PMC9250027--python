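"""Seeded synthetic datasets for every stage of the pipeline.

Real runs of this pipeline consume deposited MS intensity tables and
external tissue resources; these generators emulate all of them with
planted, machine-readable ground truth so recovery, calibration and
stability are testable offline:

* ``gen_reference`` builds an IHC-style annotation table whose
  default-filter reconstruction equals a known tissue->protein library,
  with a controlled fraction of proteins shared across 2 or 3 tissues to
  exercise the promiscuity filter;
* ``gen_ms_table`` draws log-normal background intensities for two
  collections (W4/W7) and, for the query collection, plants a chosen
  fraction of the top-percentile band inside one tissue's protein set by
  rank surgery — direct placement into the top band — so the realized
  overlap k* is exact;
* ``gen_marker_panel`` plants markers at every fold-change regime
  (boundary 2.0 and 0.5 included) with their expected calls;
* ``gen_timeline`` draws count-versus-age scatter data with a known
  generating correlation.

All generators are pure functions of their parameters including the
seed; every dataset can be written alongside a ``truth.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    AnnotationTable,
    CELL_FRACTIONS,
    IntensityTable,
    MarkerPanel,
    STAINING_LEVELS,
    write_annotation_table,
    write_intensity_table,
    write_marker_panel,
    write_reference,
)
from .reference_library import ReferenceLibrary
from .timeline import TimelineDataset

#: Log-normal background on the natural-log scale of arbitrary intensity
#: units; location 20, scale 1.5 spans the ~5 decades of dynamic range
#: typical of label-free MS protein intensities.
LOGNORMAL_MU = 20.0
LOGNORMAL_SIGMA = 1.5


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated experiment."""

    planted_tissue: str | None
    effect_fraction: float
    n_proteins: int
    n_tissues: int
    set_size: int
    overlap_rate: float
    percentile_q: float
    seed: int
    lognormal_mu: float = LOGNORMAL_MU
    lognormal_sigma: float = LOGNORMAL_SIGMA
    realized_overlap: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Reference / annotation generator
# ---------------------------------------------------------------------------

def _tissue_label(j: int) -> str:
    return f"tissue_{j:02d}"


def gen_reference(
    n_tissues: int,
    n_proteins: int,
    set_size: int,
    overlap_rate: float,
    seed: int,
    level: str = "strong",
    fraction: str = "25-75%",
) -> tuple[AnnotationTable, ReferenceLibrary]:
    """Annotation rows whose default IHC reconstruction equals a known library.

    Each of the `n_tissues` tissue sets holds exactly `set_size` proteins.
    A fraction `overlap_rate` of the membership slots is covered by
    proteins deliberately shared across 2 or 3 tissues (to exercise the
    promiscuity filter); the rest are tissue-unique. Decoy rows at other
    staining levels / fractions are added so the builder's filtering is
    actually exercised.
    """
    T, G, M = n_tissues, n_proteins, set_size
    if T < 1 or G < 1 or M < 1 or not 0.0 <= overlap_rate <= 1.0:
        raise ConfigurationError(
            f"invalid generator parameters T={T}, G={G}, M={M}, "
            f"overlap_rate={overlap_rate}"
        )
    slots = T * M
    if slots > G * (1 + overlap_rate):
        raise ConfigurationError(
            f"T*M={slots} membership slots infeasible for G={G} proteins at "
            f"overlap_rate={overlap_rate}"
        )
    shared_slots = int(round(overlap_rate * slots))
    n_triple = shared_slots // 9
    n_double = (shared_slots - 3 * n_triple) // 2
    n_unique = slots - 2 * n_double - 3 * n_triple
    needed = n_unique + n_double + n_triple
    if needed > G:
        raise ConfigurationError(
            f"need {needed} distinct proteins but only G={G} available"
        )

    rng = np.random.default_rng([int(seed), 11])
    pool = [f"P{i:05d}" for i in range(G)]
    chosen = list(rng.permutation(pool)[:needed])
    membership: dict[str, set[str]] = {_tissue_label(j): set() for j in range(T)}
    labels = [_tissue_label(j) for j in range(T)]

    cursor = 0
    for t in range(n_triple):
        protein = chosen[cursor]; cursor += 1
        for offset in range(3):
            membership[labels[(t + offset) % T]].add(protein)
    for d in range(n_double):
        protein = chosen[cursor]; cursor += 1
        for offset in range(2):
            membership[labels[(d + offset) % T]].add(protein)
    overfull = [t for t, s in membership.items() if len(s) > M]
    if overfull:
        raise ConfigurationError(
            f"shared-protein assignment overfills tissue set(s) {overfull}; "
            "increase set_size or reduce overlap_rate"
        )
    for label in labels:
        while len(membership[label]) < M:
            membership[label].add(chosen[cursor])
            cursor += 1

    # Member rows reconstruct the library; decoys must not match the filter.
    decoy_combos = [
        (lv, fr)
        for lv in STAINING_LEVELS
        for fr in CELL_FRACTIONS
        if not (lv == level and fr == fraction)
    ]
    rows: list[tuple[str, str, str, str]] = []
    for label in labels:
        for protein in sorted(membership[label]):
            rows.append((protein, label, level, fraction))
        n_decoys = max(1, M // 2)
        decoy_proteins = rng.choice(pool, size=n_decoys, replace=False)
        combo_idx = rng.integers(0, len(decoy_combos), size=n_decoys)
        for protein, ci in zip(decoy_proteins, combo_idx):
            rows.append((str(protein), label, *decoy_combos[ci]))

    frame = pd.DataFrame(rows, columns=["gene", "tissue", "level", "fraction"])
    frame = frame.drop_duplicates().reset_index(drop=True)
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    annotations = AnnotationTable(frame)

    library = ReferenceLibrary(
        name="synthetic_ihc",
        tissues={t: frozenset(s) for t, s in membership.items()},
        provenance={
            "method": "ihc_annotation",
            "parameters": {
                "level": level,
                "fraction": fraction,
                "synthetic": True,
                "n_tissues": T,
                "n_proteins": G,
                "set_size": M,
                "overlap_rate": overlap_rate,
                "seed": int(seed),
            },
        },
    )
    return annotations, library


# ---------------------------------------------------------------------------
# MS intensity table generator
# ---------------------------------------------------------------------------

def gen_ms_table(
    truth: SyntheticTruth,
    reference: ReferenceLibrary,
    samples: tuple[str, str] = ("W4", "W7"),
    dropout: float = 0.0,
) -> tuple[IntensityTable, int | None]:
    """Two-collection intensity table with planted top-percentile structure.

    The second sample is the query collection: its top band (the proteins
    at or above the `truth.percentile_q` nearest-rank cutoff) is
    constructed so that a fraction `truth.effect_fraction` of it belongs
    to the planted tissue's set. The first sample is pure background.
    Returns the table and the realized overlap k* (exact under planting;
    measured post hoc when effect_fraction is 0; None when no tissue is
    tracked). `dropout` randomly blanks that fraction of cells to missing.
    """
    G = truth.n_proteins
    q = truth.percentile_q
    rng = np.random.default_rng([int(truth.seed), 23])
    proteins = [f"P{i:05d}" for i in range(G)]

    if truth.planted_tissue is not None and truth.planted_tissue not in reference.tissues:
        raise ConfigurationError(
            f"planted tissue {truth.planted_tissue!r} absent from the reference"
        )

    early = rng.lognormal(truth.lognormal_mu, truth.lognormal_sigma, G)
    values = np.sort(rng.lognormal(truth.lognormal_mu, truth.lognormal_sigma, G))[::-1]
    n_query = G - math.ceil(q / 100.0 * G) + 1  # size of the top band

    late = np.empty(G)
    if truth.effect_fraction > 0.0:
        if truth.planted_tissue is None:
            raise ConfigurationError("effect_fraction > 0 requires a planted tissue")
        planted_set = sorted(reference.tissues[truth.planted_tissue])
        m = int(round(truth.effect_fraction * n_query))
        if m > len(planted_set):
            raise ConfigurationError(
                f"cannot plant {m} of {n_query} query slots: planted tissue has "
                f"only {len(planted_set)} proteins"
            )
        non_planted = [p for p in proteins if p not in set(planted_set)]
        if n_query - m > len(non_planted):
            raise ConfigurationError("not enough non-planted proteins for the top band")
        top_planted = list(rng.choice(planted_set, size=m, replace=False))
        top_other = list(rng.choice(non_planted, size=n_query - m, replace=False))
        top = top_planted + top_other
        rng.shuffle(top)
        top_set = set(top)
        rest = [p for p in proteins if p not in top_set]
        rng.shuffle(rest)
        order = top + rest  # protein receiving the i-th largest value
        position = {p: i for i, p in enumerate(proteins)}
        for rank, p in enumerate(order):
            late[position[p]] = values[rank]
        k_star: int | None = m
    else:
        assignment = rng.permutation(G)
        for i, p in enumerate(proteins):
            late[i] = values[assignment[i]]
        if truth.planted_tissue is not None:
            from .percentiles import nearest_rank_threshold

            threshold = nearest_rank_threshold(late, q)
            top_set = {p for p, v in zip(proteins, late) if v >= threshold}
            k_star = len(top_set & set(reference.tissues[truth.planted_tissue]))
        else:
            k_star = None

    frame = pd.DataFrame(
        {samples[0]: early, samples[1]: late},
        index=pd.Index(proteins, name="protein"),
    )
    if dropout > 0.0:
        mask = rng.random(frame.shape) < dropout
        frame = frame.mask(mask)
    truth.realized_overlap = k_star
    return IntensityTable(frame), k_star


# ---------------------------------------------------------------------------
# Marker panel generator
# ---------------------------------------------------------------------------

#: (protein id, panel class, early multiplier, late multiplier or regime).
_MARKER_PLAN: tuple[tuple[str, str, float, float], ...] = (
    # mesenchymal arm: expected to rise in a mesenchymal-like compartment
    ("P08670", "mesenchymal", 1.0, 2.0),   # boundary FC = 2.0 -> upregulated
    ("P02751", "mesenchymal", 1.0, 3.2),   # clear upregulation
    ("P16070", "mesenchymal", 0.0, 1.0),   # gained (absent early)
    ("P04216", "mesenchymal", 1.0, 1.0),   # unchanged
    # epithelial arm: expected to fall
    ("P12830", "epithelial", 1.0, 0.5),    # boundary FC = 0.5 -> downregulated
    ("P16422", "epithelial", 1.0, 0.3),    # clear downregulation
    ("Q16625", "epithelial", 1.0, 0.0),    # lost (absent late)
    ("P05783", "epithelial", 1.0, 1.4),    # unchanged
    ("P15924", "epithelial", 0.0, 0.0),    # absent at both collections
)

#: A panel member deliberately missing from the generated intensity table.
_MARKER_NOT_IN_TABLE = ("P35580", "mesenchymal")


def gen_marker_panel(
    seed: int,
) -> tuple[MarkerPanel, IntensityTable, dict[str, str]]:
    """Marker panel + intensity slice with planted expected calls.

    Plants one marker per fold-change regime, including the inclusive
    boundaries at 2.0 and 0.5, plus gained/lost/absent cases and one
    panel member missing from the table entirely. The seed jitters the
    base intensities; calls are scale-invariant, so the expectation is
    identical for every seed.
    """
    rng = np.random.default_rng([int(seed), 31])
    rows = {}
    expected: dict[str, str] = {}
    for protein, _cls, early_mult, late_mult in _MARKER_PLAN:
        base = float(rng.lognormal(LOGNORMAL_MU, 1.0))
        early = base * early_mult
        late = base * late_mult
        rows[protein] = (early, late)
        if early == 0.0 and late == 0.0:
            expected[protein] = "absent"
        elif early == 0.0:
            expected[protein] = "gained"
        elif late == 0.0:
            expected[protein] = "lost"
        else:
            fc = late / early
            expected[protein] = (
                "upregulated" if fc >= 2.0
                else "downregulated" if fc <= 0.5
                else "unchanged"
            )
    expected[_MARKER_NOT_IN_TABLE[0]] = "absent"

    members = tuple(
        [(p, c) for p, c, _, _ in _MARKER_PLAN] + [_MARKER_NOT_IN_TABLE]
    )
    panel = MarkerPanel(members)
    frame = pd.DataFrame(
        {
            "W4": {p: e for p, (e, _) in rows.items()},
            "W7": {p: l for p, (_, l) in rows.items()},
        }
    )
    frame.index.name = "protein"
    return panel, IntensityTable(frame), expected


# ---------------------------------------------------------------------------
# Timeline generator
# ---------------------------------------------------------------------------

def gen_timeline(
    n: int,
    slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
    week_range: tuple[float, float] = (3.0, 9.0),
) -> tuple[TimelineDataset, float]:
    """Count-versus-age scatter with a known generating correlation.

    x lies on a half-week grid across `week_range`; y = intercept +
    slope*x + Gaussian noise, truncated at 0 (counts cannot be negative).
    Returns the dataset and the generating correlation
    slope*sd(x) / sqrt(slope^2 sd(x)^2 + noise_sd^2) — exact for the
    untruncated model, hence approximate when truncation bites.
    """
    if n < 3:
        raise ConfigurationError("need n >= 3 timeline points")
    rng = np.random.default_rng([int(seed), 41])
    grid = np.arange(week_range[0], week_range[1] + 0.25, 0.5)
    x = np.sort(rng.choice(grid, size=n, replace=True))
    y = intercept + slope * x + rng.normal(0.0, noise_sd, n)
    y = np.maximum(y, 0.0)
    sd_x = float(np.std(x))
    denom = math.hypot(slope * sd_x, noise_sd)
    truth_r = (slope * sd_x / denom) if denom > 0 else 0.0
    return TimelineDataset(x=x, y=y), float(truth_r)


# ---------------------------------------------------------------------------
# Presets and the end-to-end convenience wrapper
# ---------------------------------------------------------------------------

#: Study-scale defaults: a 2000-protein detected proteome, a 20-tissue
#: reference with 100-protein sets, the 98th-percentile query band, and a
#: planted signal covering half the query for the recovery condition.
PRESETS: dict[str, dict] = {
    "recovery": dict(
        n_proteins=2000, n_tissues=20, set_size=100, overlap_rate=0.2,
        percentile_q=98.0, effect_fraction=0.5, planted_tissue="random",
    ),
    "null": dict(
        n_proteins=2000, n_tissues=20, set_size=100, overlap_rate=0.2,
        percentile_q=98.0, effect_fraction=0.0, planted_tissue="random",
    ),
    "markers": dict(),
    "timeline": dict(n=14, slope=3.0, noise_sd=5.0),
}


def simulate_experiment(
    seed: int,
    n_proteins: int = 2000,
    n_tissues: int = 20,
    set_size: int = 100,
    overlap_rate: float = 0.2,
    percentile_q: float = 98.0,
    effect_fraction: float = 0.5,
    planted_tissue: str | None = "random",
    dropout: float = 0.0,
) -> tuple[IntensityTable, ReferenceLibrary, AnnotationTable, SyntheticTruth]:
    """Generate a full synthetic enrichment experiment (one seed).

    ``planted_tissue="random"`` (the default) draws the planted/tracked
    tissue uniformly per seed; a fixed label would interact with the
    alphabetical tie-break of the result ordering and bias null studies.
    """
    annotations, library = gen_reference(
        n_tissues, n_proteins, set_size, overlap_rate, seed
    )
    if planted_tissue == "random":
        pick = np.random.default_rng([int(seed), 7])
        planted_tissue = _tissue_label(int(pick.integers(0, n_tissues)))
    truth = SyntheticTruth(
        planted_tissue=planted_tissue,
        effect_fraction=effect_fraction,
        n_proteins=n_proteins,
        n_tissues=n_tissues,
        set_size=set_size,
        overlap_rate=overlap_rate,
        percentile_q=percentile_q,
        seed=int(seed),
    )
    table, _ = gen_ms_table(truth, library, dropout=dropout)
    return table, library, annotations, truth


def generate_preset(name: str, seed: int, out_dir: str | Path | None = None) -> dict:
    """Generate one named preset; optionally write its files + truth.json."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    params = PRESETS[name]
    out: dict = {"preset": name, "seed": int(seed)}
    if name in ("recovery", "null"):
        table, library, annotations, truth = simulate_experiment(seed, **params)
        out.update(
            table=table, library=library, annotations=annotations, truth=truth
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_intensity_table(table, out_dir / "intensities.tsv")
            write_annotation_table(annotations, out_dir / "annotations.tsv")
            write_reference(library, out_dir / "reference.json")
            truth.to_json(out_dir / "truth.json")
    elif name == "markers":
        panel, table, expected = gen_marker_panel(seed)
        out.update(panel=panel, table=table, expected_calls=expected)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_marker_panel(panel, out_dir / "panel.tsv")
            write_intensity_table(table, out_dir / "marker_intensities.tsv")
            (out_dir / "truth.json").write_text(
                json.dumps({"expected_calls": expected, "seed": int(seed)}, indent=2)
                + "\n"
            )
    elif name == "timeline":
        data, truth_r = gen_timeline(seed=seed, **params)
        out.update(data=data, truth_r=truth_r)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame({"x": data.x, "y": data.y}).to_csv(
                out_dir / "timeline.tsv", sep="\t", index=False
            )
            (out_dir / "truth.json").write_text(
                json.dumps({"truth_r": truth_r, "seed": int(seed), **params}, indent=2)
                + "\n"
            )
    return out
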
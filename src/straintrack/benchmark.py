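"""Scoring species detection against culture, and ranking parameter grids.

Bacterial culture is the gold standard: a detection method (marker-based
filtering, taxonomic profiler, ...) is scored per species by its confusion
counts over the samples that have both a detection call and a culture result.
Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN);
all retained at full precision internally and rounded only when a report is
formatted (integer percents, F1 to two decimals).

A parameter grid is ranked by overall F1 with confusion counts pooled across
species and datasets (micro-average; a macro option averages per-species F1
instead), ties broken by closeness to the default parameters under a
range-normalized L1 distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .markerfilter import ConsensusMarker, ParameterSet, DEFAULT_PARAMETERS, detection_calls

logger = logging.getLogger(__name__)

#: grid bounds used for distance normalization and the shipped default grid
#: (a reconstruction spanning the stated parameter ranges, not the study's
#: exact enumerated sets)
GRID_BOUNDS = {
    "breadth_threshold": (20.0, 80.0),
    "trim_sequences": (50, 50),
    "marker_in_n_samples": (10.0, 80.0),
    "sample_with_n_markers": (10, 20),
}


@dataclass(frozen=True)
class BenchmarkResult:
    species: str
    method: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        """Percent; NaN when there are no culture positives."""
        if self.tp + self.fn == 0:
            return float("nan")
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """Percent; NaN when there are no culture negatives."""
        if self.tn + self.fp == 0:
            return float("nan")
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            return float("nan")
        return 2 * self.tp / denom

    def formatted(self) -> dict:
        """Report-layer rounding: integer percents, F1 to 2 decimals."""
        fmt_pct = lambda v: "na" if math.isnan(v) else f"{round(v):d}%"
        return {
            "species": self.species,
            "method": self.method,
            "TP": self.tp,
            "TN": self.tn,
            "specificity": fmt_pct(self.specificity),
            "sensitivity": fmt_pct(self.sensitivity),
            "F1": "na" if math.isnan(self.f1) else f"{self.f1:.2f}",
        }


def confusion(detection: pd.Series, culture: pd.Series) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over samples having both a detection and a culture call.

    Both inputs are 0/1 Series indexed by sample_id; samples with a missing
    culture result (NaN) are excluded, mirroring per-species denominators
    that vary with culture availability.
    """
    culture = culture.dropna()
    common = detection.dropna().index.intersection(culture.index)
    if len(common) == 0:
        raise ValueError("no samples with both a detection call and a culture result")
    det = detection.loc[common].astype(int)
    cul = culture.loc[common].astype(int)
    tp = int(((det == 1) & (cul == 1)).sum())
    fp = int(((det == 1) & (cul == 0)).sum())
    fn = int(((det == 0) & (cul == 1)).sum())
    tn = int(((det == 0) & (cul == 0)).sum())
    return tp, fp, fn, tn


def metrics(
    tp: int, fp: int, fn: int, tn: int, species: str = "", method: str = ""
) -> BenchmarkResult:
    """Wrap confusion counts; derived metrics are lazy properties."""
    for name, v in (("TP", tp), ("FP", fp), ("FN", fn), ("TN", tn)):
        if v < 0:
            raise ValueError(f"negative {name} count")
    return BenchmarkResult(species, method, tp, fp, fn, tn)


def from_margins(
    tp: int, tn: int, n_positive: int, n_negative: int, species: str = "", method: str = ""
) -> BenchmarkResult:
    """Build a result from printed TP/TN plus culture margins (P and N totals)."""
    fn = n_positive - tp
    fp = n_negative - tn
    if fn < 0 or fp < 0:
        raise ValueError("TP/TN exceed the stated culture margins")
    return metrics(tp, fp, fn, tn, species, method)


def distance_to_default(
    pset: ParameterSet,
    default: ParameterSet = DEFAULT_PARAMETERS,
    bounds: dict = GRID_BOUNDS,
) -> float:
    """Range-normalized L1 distance between parameter sets.

    Each of the four dimensions contributes |x - d| / range with the range
    taken from the grid bounds; a zero-range dimension contributes 0.
    """
    total = 0.0
    for name, (lo, hi) in bounds.items():
        rng = hi - lo
        if rng == 0:
            continue
        total += abs(getattr(pset, name) - getattr(default, name)) / rng
    return total


def default_grid() -> list[ParameterSet]:
    """Reconstruction grid spanning the stated ranges (trim fixed at 50)."""
    breadths = [20, 30, 40, 50, 60, 70, 80]
    marker_pcts = [10, 20, 30, 40, 50, 60, 70, 80]
    sample_counts = [10, 15, 20]
    return [
        ParameterSet(b, 50, m, s)
        for b, m, s in itertools.product(breadths, marker_pcts, sample_counts)
    ]


@dataclass
class GridRanking:
    """Parameter sets ordered by pooled F1 (desc), then distance-to-default (asc)."""

    table: pd.DataFrame  # rank, parameters..., f1, distance_to_default

    @property
    def best(self) -> ParameterSet:
        row = self.table.iloc[0]
        return ParameterSet(
            row["breadth_threshold"], int(row["trim_sequences"]),
            row["marker_in_n_samples"], int(row["sample_with_n_markers"]),
        )


def evaluate_grid(
    parameter_sets: list[ParameterSet],
    markers_by_species: dict[str, list[ConsensusMarker]],
    culture: pd.DataFrame,
    default: ParameterSet = DEFAULT_PARAMETERS,
    average: str = "micro",
) -> GridRanking:
    """Score every parameter set against culture and rank them.

    ``culture`` has columns sample_id, species, culture (0/1, NaN allowed).
    For each set, per-species detection calls come from the marker filter;
    confusion counts are pooled over species into one overall F1 ("micro"),
    or per-species F1 values are averaged ("macro").
    """
    if not parameter_sets:
        raise ValueError("empty parameter grid")
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    unique: list[ParameterSet] = []
    for ps in parameter_sets:
        if ps in unique:
            logger.warning("duplicate parameter set %s dropped", ps)
            continue
        unique.append(ps)

    cul = culture.set_index(["species", "sample_id"])["culture"]
    rows = []
    for ps in unique:
        pooled = [0, 0, 0, 0]
        per_species_f1 = []
        for species, markers in markers_by_species.items():
            det = detection_calls(markers, ps)
            try:
                c = confusion(det, cul.loc[species])
            except (KeyError, ValueError):
                continue
            pooled = [a + b for a, b in zip(pooled, c)]
            per_species_f1.append(metrics(*c).f1)
        if average == "micro":
            f1 = metrics(*pooled).f1
        else:
            defined = [v for v in per_species_f1 if not math.isnan(v)]
            f1 = sum(defined) / len(defined) if defined else float("nan")
        rows.append({**ps.as_dict(), "f1": f1,
                     "distance_to_default": distance_to_default(ps, default)})
    table = pd.DataFrame(rows)
    table.sort_values(
        ["f1", "distance_to_default"], ascending=[False, True],
        inplace=True, kind="mergesort",
    )
    table.insert(0, "rank", range(1, len(table) + 1))
    return GridRanking(table.reset_index(drop=True))
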
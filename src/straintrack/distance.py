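"""Pairwise SNV rates from a species alignment, and median normalization.

The SNV rate between two samples is the number of mismatching bases divided
by the number of positions both samples actually cover (no N, no gap).
Rates are raw proportions -- no model correction -- and are made comparable
across species by dividing by the per-species median rate over all sample
pairs, so a normalized distance of 1 is "typical between-sample divergence
for this species".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: symbols that count as covered; everything else (N, -, ambiguity codes) is missing
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """Symmetric raw SNV-rate matrix; NaN where a pair shares no position."""

    species: str
    sample_ids: list[str]
    rates: np.ndarray   # (n, n) float, zero diagonal, NaN = undefined
    shared: np.ndarray  # (n, n) int, mutually covered positions

    def to_long(self) -> pd.DataFrame:
        """Long format, one row per unordered pair, lexicographic order."""
        rows = []
        for i, a in enumerate(self.sample_ids):
            for j in range(i + 1, len(self.sample_ids)):
                rows.append(
                    (a, self.sample_ids[j], self.species,
                     self.rates[i, j], int(self.shared[i, j]))
                )
        return pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "species", "raw_snv_rate", "shared_positions"]
        )


@dataclass
class NormalizedDistanceMatrix(DistanceMatrix):
    """Same shape as the raw matrix, divided by the median raw rate."""

    median_rate: float = float("nan")


def _encode(seq: str) -> np.ndarray:
    """Uppercase bytes; anything outside A/C/G/T flagged as uncovered."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    covered = np.isin(arr, _ACGT)
    return np.where(covered, arr, 0).astype(np.uint8)  # 0 = missing sentinel


def pairwise_snv_rate(seq_a: str, seq_b: str) -> tuple[float, int]:
    """(SNV rate, shared positions) for one aligned pair.

    Columns where either sequence is uncovered are excluded; with zero shared
    positions the rate is undefined and returned as NaN.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}")
    a, b = _encode(seq_a), _encode(seq_b)
    both = (a != 0) & (b != 0)
    shared = int(both.sum())
    if shared == 0:
        return float("nan"), 0
    mismatches = int((a[both] != b[both]).sum())
    return mismatches / shared, shared


def all_vs_all(alignment) -> DistanceMatrix:
    """Raw SNV-rate matrix over all sample pairs of a species alignment.

    Accepts a :class:`~straintrack.markerfilter.SpeciesAlignment` or any
    mapping sample_id -> aligned sequence; needs at least two samples.
    """
    if hasattr(alignment, "rows"):
        rows, species = alignment.rows, alignment.species
    else:
        rows, species = dict(alignment), ""
    sample_ids = sorted(rows)
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    encoded = np.vstack([_encode(rows[s]) for s in sample_ids])
    covered = encoded != 0
    rates = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = covered[i] & covered[i + 1 :]
        sh = both.sum(axis=1)
        mm = ((encoded[i] != encoded[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            r = np.where(sh > 0, mm / np.maximum(sh, 1), np.nan)
        rates[i, i + 1 :] = r
        rates[i + 1 :, i] = r
        shared[i, i + 1 :] = sh
        shared[i + 1 :, i] = sh
        shared[i, i] = int(covered[i].sum())
    return DistanceMatrix(species, sample_ids, rates, shared)


def median_offdiagonal(matrix: DistanceMatrix) -> float:
    """Median of defined off-diagonal rates, each unordered pair counted once."""
    iu = np.triu_indices(len(matrix.sample_ids), k=1)
    vals = matrix.rates[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal distances")
    return float(np.median(vals))


def normalize_by_median(matrix: DistanceMatrix) -> NormalizedDistanceMatrix:
    """Divide every rate by the median off-diagonal rate.

    Raises on an all-identical cohort (median 0), where normalized distances
    are meaningless.
    """
    med = median_offdiagonal(matrix)
    if med == 0.0:
        raise ValueError("degenerate cohort: all pairs identical (median SNV rate is 0)")
    return NormalizedDistanceMatrix(
        matrix.species, list(matrix.sample_ids), matrix.rates / med,
        matrix.shared.copy(), median_rate=med,
    )


def to_long_with_normalized(
    raw: DistanceMatrix, normalized: NormalizedDistanceMatrix
) -> pd.DataFrame:
    """Combined long table: raw rate, shared positions, normalized distance."""
    out = raw.to_long()
    out["normalized_distance"] = normalized.to_long()["raw_snv_rate"]
    return out
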
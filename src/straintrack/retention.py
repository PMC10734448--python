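"""Pair categorization, distance binning, and strain-retention calling.

A longitudinal cohort yields three kinds of sample pairs per species: the
same subject at different timepoints (intra), different subjects at the same
timepoint (inter, same timepoint), and different subjects at different
timepoints (inter, different timepoints).  Normalized distances are binned at
width 0.1; an intra pair whose normalized distance falls strictly below a
species-specific threshold (a bin boundary, typically 0.1 or 0.2) is called a
retained strain, and the retained fraction over intra pairs is the per-species
strain-retention estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import NormalizedDistanceMatrix

logger = logging.getLogger(__name__)

INTRA = "intra"
INTER_SAME_TP = "inter_same_timepoint"
INTER_DIFF_TP = "inter_diff_timepoint"
CATEGORIES = (INTRA, INTER_SAME_TP, INTER_DIFF_TP)

#: species-group retention thresholds on the normalized distance scale
DEFAULT_THRESHOLDS = {
    "S_pneumoniae": 0.2,
    "M_catarrhalis": 0.2,
    "H_influenzae": 0.1,
    "S_aureus": 0.1,
}

BIN_WIDTH = 0.1


@dataclass(frozen=True)
class RetentionResult:
    species: str
    threshold: float
    n_intra: int
    n_retained: int

    @property
    def fraction(self) -> float:
        if self.n_intra == 0:
            return float("nan")
        return self.n_retained / self.n_intra


def categorize_pairs(
    matrix: NormalizedDistanceMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """One row per defined unordered pair with its category and bin.

    ``metadata`` needs sample_id, subject_id and timepoint columns covering
    every sample in the matrix.  Bin index is floor(d / 0.1), half-open bins
    with the boundary rounding up.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    rows = []
    ids = matrix.sample_ids
    for i, a in enumerate(ids):
        sub_a, tp_a = meta.loc[a, "subject_id"], meta.loc[a, "timepoint"]
        for j in range(i + 1, len(ids)):
            b = ids[j]
            d = matrix.rates[i, j]
            if np.isnan(d):
                continue
            sub_b, tp_b = meta.loc[b, "subject_id"], meta.loc[b, "timepoint"]
            if sub_a == sub_b:
                cat = INTRA
            elif tp_a == tp_b:
                cat = INTER_SAME_TP
            else:
                cat = INTER_DIFF_TP
            rows.append((a, b, matrix.species, cat, d, int(math.floor(d / BIN_WIDTH))))
    return pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "species", "category", "normalized_distance", "bin"],
    )


def bin_distances(pairs: pd.DataFrame, width: float = BIN_WIDTH) -> pd.DataFrame:
    """Histogram of normalized distances per category.

    Bin k covers [k*width, (k+1)*width); counts per category sum to the
    number of defined pairs in that category.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if pairs.empty:
        return pd.DataFrame(columns=["category", "bin", "count"])
    if (pairs["normalized_distance"] < 0).any():
        raise ValueError("negative distances cannot be binned")
    out = pairs.assign(bin=np.floor(pairs["normalized_distance"] / width).astype(int))
    hist = (
        out.groupby(["category", "bin"], observed=True).size().rename("count").reset_index()
    )
    return hist.sort_values(["category", "bin"]).reset_index(drop=True)


def call_retention(
    pairs: pd.DataFrame, threshold_map: dict[str, float]
) -> list[RetentionResult]:
    """Retained fraction of intra pairs per species, strictly below threshold.

    The denominator counts intra pairs with a defined distance only; pairs
    sharing no alignment positions never reach this table.
    """
    results = []
    for species, grp in pairs.groupby("species"):
        if species not in threshold_map:
            raise KeyError(f"no retention threshold configured for species {species}")
        thr = threshold_map[species]
        intra = grp[grp["category"] == INTRA]
        retained = int((intra["normalized_distance"] < thr).sum())
        results.append(RetentionResult(species, thr, len(intra), retained))
    return results


def retention_table(results: list[RetentionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.species, r.threshold, r.n_intra, r.n_retained, r.fraction) for r in results],
        columns=["species", "threshold", "n_intra", "n_retained", "fraction"],
    )


def suggest_thresholds(
    pairs: pd.DataFrame, inter_cap: float = 0.05, width: float = BIN_WIDTH
) -> pd.DataFrame:
    """Data-driven per-species retention threshold.

    Starting from one bin, the threshold grows bin-by-bin while (a) the next
    bin holds a larger fraction of intra pairs than of inter pairs (the bin is
    intra-dominated) and (b) the inter-pair fraction below the grown threshold
    stays at most ``inter_cap``.  When even the first bin violates the cap --
    intra and inter distributions overlap -- the single-bin threshold is
    returned flagged, with a warning.

    Returns a table (species, threshold, inter_fraction_below, flagged).
    """
    rows = []
    for species, grp in pairs.groupby("species"):
        intra = grp.loc[grp["category"] == INTRA, "normalized_distance"].to_numpy()
        inter = grp.loc[grp["category"] != INTRA, "normalized_distance"].to_numpy()
        if inter.size == 0:
            raise ValueError(f"{species}: no inter-subject pairs to set a threshold against")
        if intra.size == 0:
            raise ValueError(f"{species}: no intra-subject pairs")
        k = 1
        flagged = False
        if np.mean(inter < width) > inter_cap:
            flagged = True
            logger.warning(
                "%s: inter pairs below the first bin exceed the %.0f%% cap; "
                "threshold %.1f is unreliable", species, 100 * inter_cap, width,
            )
        else:
            while True:
                lo, hi = k * width, (k + 1) * width
                intra_bin = np.mean((intra >= lo) & (intra < hi))
                inter_bin = np.mean((inter >= lo) & (inter < hi))
                if intra_bin <= inter_bin:
                    break
                if np.mean(inter < hi) > inter_cap:
                    break
                k += 1
        t = k * width
        rows.append((species, t, float(np.mean(inter < t)), flagged))
    return pd.DataFrame(
        rows, columns=["species", "threshold", "inter_fraction_below", "flagged"]
    )


def plot_histograms(pairs: pd.DataFrame, path, width: float = BIN_WIDTH) -> None:
    """Linear-scale distance histograms per category, one panel each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    top = max(1.0, pairs["normalized_distance"].max() if len(pairs) else 1.0)
    edges = np.arange(0, top + 2 * width, width)
    for ax, cat in zip(axes, CATEGORIES):
        vals = pairs.loc[pairs["category"] == cat, "normalized_distance"]
        ax.hist(vals, bins=edges, color="#4878a8", edgecolor="white")
        ax.set_title(cat.replace("_", " "))
        ax.set_xlabel("normalized distance")
    axes[0].set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
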
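"""Canned experiments on synthetic cohorts.

These drive the validation studies: recovering a known retention probability
from simulated cohorts, recovering planted strain clusters through the
neighbor-joining / single-linkage route, and benchmarking the marker filter
against simulated culture.  Both the analysis drivers and the acceptance
checks run these, so the numbers they report are always recomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import assign_clusters, cluster_mlst_concordance, neighbor_joining
from .distance import all_vs_all, normalize_by_median
from .markerfilter import ParameterSet, build_species_alignment
from .retention import call_retention, categorize_pairs
from .synth import SpeciesSpec, SynthConfig, simulate_cohort, simulate_marker_db

#: keeps every marker and sample of a well-covered synthetic cohort
RELAXED_PARAMETERS = ParameterSet(breadth_threshold=20, trim_sequences=10,
                                  marker_in_n_samples=50, sample_with_n_markers=5)

SPECIES = "S_pneumoniae"


def _simulate(seed: int, n_markers: int = 10, marker_length: int = 300, **config_kwargs):
    rng = np.random.default_rng(seed)
    db = simulate_marker_db([SpeciesSpec(SPECIES, n_markers, marker_length)], rng)
    cfg = SynthConfig(species=(SPECIES,), **config_kwargs)
    return simulate_cohort(cfg, db, rng), cfg


def retention_recovery_trial(
    retention_prob: float,
    seed: int,
    n_subjects: int = 50,
    drift: float = 0.001,
    replacement_divergence: float = 0.05,
    threshold: float = 0.1,
    n_markers: int = 10,
    marker_length: int = 300,
) -> tuple[int, int]:
    """One replicate: simulate, filter, normalize, call retention.

    Returns (n intra pairs, n called retained).
    """
    cohort, _ = _simulate(
        seed, n_markers=n_markers, marker_length=marker_length,
        n_subjects=n_subjects, retention_prob=retention_prob,
        drift=drift, replacement_divergence=replacement_divergence,
    )
    aln = build_species_alignment(cohort.markers[SPECIES], RELAXED_PARAMETERS)
    norm = normalize_by_median(all_vs_all(aln))
    pairs = categorize_pairs(norm, cohort.metadata)
    (result,) = call_retention(pairs, {SPECIES: threshold})
    return result.n_intra, result.n_retained


def retention_recovery_study(
    retention_probs=(0.2, 0.4, 0.6),
    n_seeds: int = 20,
    n_subjects: int = 50,
    seed0: int = 0,
) -> pd.DataFrame:
    """Parameter recovery over replicate cohorts.

    One row per (retention_prob, seed) with the recovered fraction and whether
    the recovered count lies inside the central 95% binomial interval of the
    true probability at the realized number of intra pairs.
    """
    rows = []
    for p in retention_probs:
        for k in range(n_seeds):
            seed = seed0 + 1000 * int(round(100 * p)) + k
            n_intra, n_ret = retention_recovery_trial(p, seed, n_subjects=n_subjects)
            lo, hi = stats.binom.interval(0.95, n_intra, p)
            rows.append({
                "retention_prob": p, "seed": seed, "n_intra": n_intra,
                "n_retained": n_ret, "recovered_fraction": n_ret / n_intra,
                "ci_low": int(lo), "ci_high": int(hi),
                "within_ci": bool(lo <= n_ret <= hi),
            })
    return pd.DataFrame(rows)


def planted_cluster_trial(seed: int, n_subjects: int = 12):
    """Plant one lineage per subject, rebuild clusters via NJ + single linkage.

    With full retention each subject keeps a single lineage across visits;
    lineages are far apart (inter-subject divergence) while within-lineage
    drift is tiny, so clusters at the branch-length threshold should equal
    lineages.  Returns (n lineages planted, cluster assignment, ARI vs truth).
    """
    cohort, _ = _simulate(
        seed, n_subjects=n_subjects, retention_prob=1.0, drift=0.0005,
        inter_subject_divergence=0.05, coverage_mean=60.0, coverage_sigma=0.0,
    )
    aln = build_species_alignment(cohort.markers[SPECIES], RELAXED_PARAMETERS)
    raw = all_vs_all(aln)
    tree = neighbor_joining(raw)
    assignment = assign_clusters(tree, threshold=0.01)
    lin = cohort.lineages[cohort.lineages["species"] == SPECIES]
    mlst = pd.DataFrame({"sample_id": lin["sample_id"].to_numpy(),
                         "sequence_type": lin["lineage_id"].to_numpy()})
    ari = cluster_mlst_concordance(assignment, mlst)
    return lin["lineage_id"].nunique(), assignment, ari


def dropout_benchmark_cohort(seed: int = 0, n_subjects: int = 15):
    """Cohort with low coverage so stringent breadth thresholds lose carriers.

    Returns (markers_by_species, culture table) ready for grid evaluation.
    """
    cohort, _ = _simulate(
        seed, n_subjects=n_subjects, retention_prob=0.5,
        coverage_mean=1.2, coverage_sigma=0.4,
        culture_prob_by_grade=(0.0, 0.9, 0.95, 0.99, 1.0),
    )
    det = cohort.detection
    culture = pd.DataFrame({
        "sample_id": det["sample_id"].to_numpy(),
        "species": det["species"].to_numpy(),
        "culture": (det["culture_grade"] > 0).astype(int).to_numpy(),
    })
    return cohort.markers, culture
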
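"""Pair categories, binning, retention calls and threshold suggestion."""

import numpy as np
import pandas as pd
import pytest

from straintrack.distance import NormalizedDistanceMatrix
from straintrack.retention import (INTER_DIFF_TP, INTER_SAME_TP, INTRA,
                                   bin_distances, call_retention, categorize_pairs,
                                   suggest_thresholds)


def _norm_matrix(ids, values):
    n = len(ids)
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mat[iu] = values
    mat.T[iu] = values
    return NormalizedDistanceMatrix("sp", list(ids), mat,
                                    np.ones((n, n), dtype=np.int64), median_rate=0.1)


def _pairs(categories, values, species="sp"):
    return pd.DataFrame({
        "sample_a": [f"a{i}" for i in range(len(values))],
        "sample_b": [f"b{i}" for i in range(len(values))],
        "species": species,
        "category": categories,
        "normalized_distance": values,
        "bin": [int(v // 0.1) for v in values],
    })


class TestCategorize:
    def test_three_categories(self, metadata_two_tp):
        ids = ["SUB0.t1", "SUB0.t2", "SUB1.t1"]
        norm = _norm_matrix(ids, [0.1, 0.2, 0.3])
        pairs = categorize_pairs(norm, metadata_two_tp)
        cat = pairs.set_index(["sample_a", "sample_b"])["category"]
        assert cat[("SUB0.t1", "SUB0.t2")] == INTRA          # same subject, 2 visits
        assert cat[("SUB0.t1", "SUB1.t1")] == INTER_SAME_TP  # different subjects, same visit
        assert cat[("SUB0.t2", "SUB1.t1")] == INTER_DIFF_TP

    def test_undefined_pairs_skipped(self, metadata_two_tp):
        norm = _norm_matrix(["SUB0.t1", "SUB0.t2"], [np.nan])
        assert categorize_pairs(norm, metadata_two_tp).empty

    def test_missing_metadata_rejected(self, metadata_two_tp):
        norm = _norm_matrix(["SUB0.t1", "GHOST"], [0.1])
        with pytest.raises(KeyError, match="GHOST"):
            categorize_pairs(norm, metadata_two_tp)


class TestBinning:
    def test_forced_counts(self):
        hist = bin_distances(_pairs([INTRA] * 3, [0.05, 0.15, 0.15]))
        assert dict(zip(hist["bin"], hist["count"])) == {0: 1, 1: 2}

    def test_boundary_goes_up(self):
        hist = bin_distances(_pairs([INTRA], [0.1]))
        assert hist["bin"].tolist() == [1]

    def test_empty_input(self):
        assert bin_distances(_pairs([], [])).empty

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bin_distances(_pairs([INTRA], [-0.1]))

    def test_counts_conserved_per_category(self):
        rng = np.random.default_rng(41)
        cats = rng.choice([INTRA, INTER_SAME_TP, INTER_DIFF_TP], 200)
        pairs = _pairs(cats, rng.uniform(0, 3, 200))
        hist = bin_distances(pairs)
        totals = hist.groupby("category")["count"].sum()
        for cat in set(cats):
            assert totals[cat] == (cats == cat).sum()


class TestRetentionCall:
    def test_strictly_below_threshold(self):
        pairs = _pairs([INTRA, INTRA, INTRA], [0.05, 0.1, 0.15])
        (r,) = call_retention(pairs, {"sp": 0.1})
        assert (r.n_intra, r.n_retained) == (3, 1)  # 0.1 itself not retained

    def test_inter_pairs_ignored(self):
        pairs = _pairs([INTRA, INTER_SAME_TP], [0.05, 0.05])
        (r,) = call_retention(pairs, {"sp": 0.1})
        assert r.n_intra == 1 and r.fraction == 1.0

    def test_missing_species_threshold_rejected(self):
        with pytest.raises(KeyError, match="sp"):
            call_retention(_pairs([INTRA], [0.05]), {"other": 0.1})

    def test_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        pairs = _pairs([INTRA] * 100, rng.uniform(0, 2, 100))
        fracs = [call_retention(pairs, {"sp": t})[0].fraction
                 for t in (0.1, 0.2, 0.5, 1.0, 2.5)]
        assert fracs == sorted(fracs)


class TestSuggestThresholds:
    def test_bimodal_separation(self):
        rng = np.random.default_rng(43)
        intra = rng.uniform(0.0, 0.08, 40)       # retained mode, well below first bin
        inter = rng.uniform(0.8, 1.4, 200)       # replacement/between mode
        pairs = _pairs([INTRA] * 40 + [INTER_SAME_TP] * 200,
                       np.concatenate([intra, inter]))
        out = suggest_thresholds(pairs)
        t = out.loc[0, "threshold"]
        assert intra.max() < t <= inter.min()
        assert not out.loc[0, "flagged"]

    def test_two_bin_intra_mode_widens_threshold(self):
        rng = np.random.default_rng(44)
        intra = rng.uniform(0.0, 0.18, 60)       # spills into the second bin
        inter = rng.uniform(0.9, 1.5, 300)
        pairs = _pairs([INTRA] * 60 + [INTER_DIFF_TP] * 300,
                       np.concatenate([intra, inter]))
        assert suggest_thresholds(pairs).loc[0, "threshold"] == pytest.approx(0.2)

    def test_identical_distributions_flagged(self):
        rng = np.random.default_rng(45)
        vals = rng.uniform(0, 1, 200)
        pairs = _pairs([INTRA] * 100 + [INTER_SAME_TP] * 100,
                       np.concatenate([vals[:100], vals[100:]]))
        out = suggest_thresholds(pairs)
        assert out.loc[0, "flagged"]
        assert out.loc[0, "threshold"] == pytest.approx(0.1)

    def test_clean_zero_intra(self):
        pairs = _pairs([INTRA] * 5 + [INTER_SAME_TP] * 20,
                       [0.0] * 5 + list(np.linspace(0.5, 2.0, 20)))
        assert suggest_thresholds(pairs).loc[0, "threshold"] == pytest.approx(0.1)

    def test_no_inter_pairs_rejected(self):
        with pytest.raises(ValueError, match="no inter"):
            suggest_thresholds(_pairs([INTRA], [0.05]))


class TestParameterRecovery:
    def test_recovered_fraction_tracks_truth(self, small_cohort):
        """End-to-end on one synthetic cohort: calls agree with the truth table."""
        from conftest import RELAXED
        from straintrack.distance import all_vs_all, normalize_by_median
        from straintrack.markerfilter import build_species_alignment

        cohort, cfg = small_cohort
        aln = build_species_alignment(cohort.markers["S_pneumoniae"], RELAXED)
        norm = normalize_by_median(all_vs_all(aln))
        pairs = categorize_pairs(norm, cohort.metadata)
        (r,) = call_retention(pairs, {"S_pneumoniae": 0.1})
        truth_retained = int((cohort.truth["status"] == "retained").sum())
        assert r.n_intra == len(cohort.truth)
        assert r.n_retained == truth_retained

    def test_mean_absolute_error_small_at_large_cohorts(self):
        """Over 20 replicate cohorts of 200 subjects, the recovered retention
        fraction sits within 0.05 of truth on average; at this cohort size the
        binomial sampling floor (~0.028 at p=0.4) leaves room under the bound."""
        from straintrack.experiments import retention_recovery_trial

        errors = []
        for k in range(20):
            n_intra, n_ret = retention_recovery_trial(
                0.4, seed=7000 + k, n_subjects=200, n_markers=5, marker_length=200)
            errors.append(abs(n_ret / n_intra - 0.4))
        assert np.mean(errors) <= 0.05
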
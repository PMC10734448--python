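import numpy as np
import pandas as pd
import pytest

from straintrack.markerfilter import ConsensusMarker, ParameterSet
from straintrack.synth import SpeciesSpec, SynthConfig, simulate_cohort, simulate_marker_db

#: relaxed parameters that keep every marker/sample of a well-covered cohort
RELAXED = ParameterSet(breadth_threshold=20, trim_sequences=10,
                       marker_in_n_samples=50, sample_with_n_markers=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_cohort(rng):
    """10 subjects x 2 timepoints, one species, half-retained strains."""
    db = simulate_marker_db([SpeciesSpec("S_pneumoniae", 10, 300)], rng)
    cfg = SynthConfig(species=("S_pneumoniae",), n_subjects=10, retention_prob=0.5)
    return simulate_cohort(cfg, db, rng), cfg


def toy_markers(n_samples=4, n_markers=6, length=40, species="sp",
                breadths=None, rng=None):
    """Fully aligned toy marker set; per-sample breadth overridable."""
    if rng is None:
        rng = np.random.default_rng(0)
    base = rng.integers(0, 4, size=(n_markers, length))
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    markers = []
    for s in range(n_samples):
        b = 1.0 if breadths is None else breadths[s]
        for m in range(n_markers):
            seq = letters[base[m]].tobytes().decode()
            n_mask = int(round((1 - b) * length))
            if n_mask:
                seq = "N" * n_mask + seq[n_mask:]
            markers.append(ConsensusMarker(f"S{s}", species, f"M{m:02d}", seq))
    return markers


@pytest.fixture
def metadata_two_tp():
    rows = []
    for s in range(4):
        for t in ("t1", "t2"):
            rows.append((f"SUB{s}.{t}", f"SUB{s}", t, "toy"))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "timepoint", "dataset"])
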
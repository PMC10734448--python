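"""Synthetic longitudinal cohorts with known strain genealogies.

Emulates the statistical structure that the strain-retention analysis
assumes: each subject carries, per species, a strain lineage per timepoint;
between consecutive timepoints the lineage is either retained (same lineage,
small substitution drift) or replaced (an independent lineage re-drawn from
the species pool at a much larger divergence).  Sequencing dropout is modelled
by masking contiguous blocks of marker positions to N according to a
per-sample coverage draw, and culture positivity is drawn with probability
monotone in a semi-quantitative abundance grade.

All lineages are generated by an independent-site substitution process from a
species reference: each hit site moves to one of the other three bases
uniformly (Jukes-Cantor-like forward simulation).  Two lineages drawn
independently at per-site divergence ``d`` therefore sit at an expected raw
mismatch rate ``2 d (1 - 2 d / 3)``; a retained pair sits at the drift rate.

Every draw flows through one :class:`numpy.random.Generator` handle passed
explicitly; a fixed seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markerfilter import ConsensusMarker

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MarkerDefinition:
    species: str
    marker_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"marker {self.marker_id}: non-positive length {self.length}")


@dataclass(frozen=True)
class SpeciesSpec:
    """How many markers a species has in the database, and how long they are."""

    name: str
    n_markers: int = 20
    marker_length: int = 400


@dataclass
class MarkerDB:
    """Marker definitions plus the ancestral (reference) sequences.

    Ancestral sequences are stored as uint8 index arrays over {0..3}
    ("ACGT") keyed by (species, marker_id).
    """

    definitions: list[MarkerDefinition]
    ancestral: dict[tuple[str, str], np.ndarray]

    def markers_for(self, species: str) -> list[MarkerDefinition]:
        return [d for d in self.definitions if d.species == species]


@dataclass(frozen=True)
class StrainLineage:
    """Ground-truth lineage carried by a subject at one timepoint."""

    subject_id: str
    species: str
    lineage_id: str
    status: str  # "founding" | "retained" | "replaced"


def expected_pairwise_divergence(d: float) -> float:
    """Expected raw mismatch rate between two independent lineages at divergence d."""
    p_same = (1.0 - d) ** 2 + d * d / 3.0
    return 1.0 - p_same


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror a two-visit infant cohort.

    Rates are substitutions per site.  ``retention_prob`` may be one float for
    all species or a per-species mapping.  The coverage model draws a
    per-sample mean marker depth from a log-normal and converts per-marker
    depth to breadth as 1 - exp(-depth) (Poisson coverage); the culture model
    maps depth to an abundance grade 0-4 and draws culture positivity with a
    per-grade probability.
    """

    species: tuple[str, ...] = ("S_pneumoniae",)
    n_subjects: int = 50
    timepoints: tuple = ("t1", "t2")
    retention_prob: float | dict[str, float] = 0.5
    drift: float = 0.001
    replacement_divergence: float = 0.05
    inter_subject_divergence: float = 0.05
    carriage_prob: float = 1.0
    coverage_mean: float = 8.0
    coverage_sigma: float = 0.6
    grade_depth_cutoffs: tuple[float, ...] = (0.5, 2.0, 5.0, 12.0)
    culture_prob_by_grade: tuple[float, ...] = (0.02, 0.45, 0.75, 0.92, 0.99)
    tool_detection_depth: float = 0.25
    tool_false_positive_prob: float = 0.02
    dataset: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be non-empty")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for sp in self.species:
            p = self.retention_for(sp)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"retention_prob for {sp} outside [0, 1]: {p}")
        for name in ("drift", "replacement_divergence", "inter_subject_divergence",
                     "carriage_prob", "tool_false_positive_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")

    def retention_for(self, species: str) -> float:
        if isinstance(self.retention_prob, dict):
            return self.retention_prob[species]
        return float(self.retention_prob)


@dataclass
class SyntheticCohort:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    markers: dict[str, list[ConsensusMarker]]
    metadata: pd.DataFrame   # sample_id, subject_id, timepoint, dataset
    detection: pd.DataFrame  # sample_id, species, tool_call, culture_grade
    truth: pd.DataFrame      # subject_id, species, timepoint_pair, status
    lineages: pd.DataFrame   # sample_id, species, lineage_id (synthetic MLST truth)
    marker_db: MarkerDB = field(repr=False, default=None)


def simulate_marker_db(
    species_specs: list[SpeciesSpec], rng: np.random.Generator
) -> MarkerDB:
    """IID-uniform A/C/G/T ancestral sequences for every marker of every species."""
    definitions: list[MarkerDefinition] = []
    ancestral: dict[tuple[str, str], np.ndarray] = {}
    for spec in species_specs:
        if spec.n_markers <= 0:
            raise ValueError(f"species {spec.name}: needs at least one marker")
        width = max(2, len(str(spec.n_markers)))
        for i in range(spec.n_markers):
            marker_id = f"M{i + 1:0{width}d}"
            definitions.append(MarkerDefinition(spec.name, marker_id, spec.marker_length))
            ancestral[(spec.name, marker_id)] = rng.integers(
                0, 4, size=spec.marker_length, dtype=np.uint8
            )
    return MarkerDB(definitions, ancestral)


def mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent-site substitution: each hit site moves to another base uniformly."""
    if rate < 0 or rate > 1:
        raise ValueError(f"substitution rate outside [0, 1]: {rate}")
    out = seq.copy()
    if rate == 0:
        return out
    hits = rng.random(seq.size) < rate
    n = int(hits.sum())
    if n:
        out[hits] = (out[hits] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _mask_to_string(seq: np.ndarray, breadth: float, rng: np.random.Generator) -> str:
    """Render an index array as A/C/G/T, N-masking contiguous blocks.

    Exactly ``round((1 - breadth) * L)`` positions are masked, laid out as a
    small number of non-overlapping contiguous blocks (read dropout is bursty,
    not IID per site).
    """
    length = seq.size
    n_mask = int(round((1.0 - breadth) * length))
    letters = _BASES[seq].tobytes().decode()
    if n_mask <= 0:
        return letters
    if n_mask >= length:
        return "N" * length
    n_blocks = min(n_mask, 1 + int(rng.poisson(1.0)))
    block_sizes = np.full(n_blocks, n_mask // n_blocks)
    block_sizes[: n_mask % n_blocks] += 1
    # stars-and-bars gaps: kept positions split into n_blocks+1 runs
    gaps = rng.multinomial(length - n_mask, np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
    out = np.frombuffer(letters.encode(), dtype=np.uint8).copy()
    pos = 0
    for g, b in zip(gaps[:-1], block_sizes):
        pos += int(g)
        out[pos : pos + int(b)] = ord("N")
        pos += int(b)
    return out.tobytes().decode()


def _grade(depth: float, cutoffs: tuple[float, ...]) -> int:
    g = 0
    for c in cutoffs:
        if depth >= c:
            g += 1
    return g


def simulate_cohort(
    config: SynthConfig, marker_db: MarkerDB, rng: np.random.Generator
) -> SyntheticCohort:
    """Draw a full cohort: sequences, metadata, detection table, truth tables."""
    meta_rows, det_rows, truth_rows, lin_rows = [], [], [], []
    markers: dict[str, list[ConsensusMarker]] = {sp: [] for sp in config.species}

    sample_ids = {}
    for si in range(config.n_subjects):
        subject = f"SUB{si + 1:03d}"
        for ti, tp in enumerate(config.timepoints):
            sample = f"{subject}.T{ti + 1}"
            sample_ids[(subject, tp)] = sample
            meta_rows.append((sample, subject, tp, config.dataset))

    for species in config.species:
        defs = marker_db.markers_for(species)
        if not defs:
            raise ValueError(f"species {species} absent from marker DB")
        p_ret = config.retention_for(species)
        lineage_counter = 0
        for si in range(config.n_subjects):
            subject = f"SUB{si + 1:03d}"
            carrier = rng.random() < config.carriage_prob
            current: dict[str, np.ndarray] | None = None
            lineage_id = None
            for ti, tp in enumerate(config.timepoints):
                sample = sample_ids[(subject, tp)]
                if not carrier:
                    tool_call = int(rng.random() < config.tool_false_positive_prob)
                    det_rows.append((sample, species, tool_call, 0))
                    continue
                if current is None:
                    lineage_counter += 1
                    lineage_id = f"{species}.L{lineage_counter:04d}"
                    current = {
                        d.marker_id: mutate(
                            marker_db.ancestral[(species, d.marker_id)],
                            config.inter_subject_divergence, rng,
                        )
                        for d in defs
                    }
                else:
                    retained = rng.random() < p_ret
                    prev_tp = config.timepoints[ti - 1]
                    if retained:
                        current = {
                            mid: mutate(seq, config.drift, rng)
                            for mid, seq in current.items()
                        }
                        status = "retained"
                    else:
                        lineage_counter += 1
                        lineage_id = f"{species}.L{lineage_counter:04d}"
                        current = {
                            d.marker_id: mutate(
                                marker_db.ancestral[(species, d.marker_id)],
                                config.replacement_divergence, rng,
                            )
                            for d in defs
                        }
                        status = "replaced"
                    truth_rows.append((subject, species, f"{prev_tp}-{tp}", status))
                lin_rows.append((sample, species, lineage_id))

                coverage = rng.lognormal(np.log(config.coverage_mean), config.coverage_sigma)
                for d in defs:
                    depth = coverage * rng.gamma(4.0, 0.25)
                    breadth = 1.0 - np.exp(-depth)
                    markers[species].append(
                        ConsensusMarker(
                            sample, species, d.marker_id,
                            _mask_to_string(current[d.marker_id], breadth, rng),
                        )
                    )
                grade = _grade(coverage, config.grade_depth_cutoffs)
                culture_pos = rng.random() < config.culture_prob_by_grade[grade]
                culture_grade = max(grade, 1) if culture_pos else 0
                tool_call = int(coverage >= config.tool_detection_depth)
                det_rows.append((sample, species, tool_call, culture_grade))

    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "subject_id", "timepoint", "dataset"])
    detection = pd.DataFrame(det_rows, columns=["sample_id", "species", "tool_call", "culture_grade"])
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "species", "timepoint_pair", "status"])
    lineages = pd.DataFrame(lin_rows, columns=["sample_id", "species", "lineage_id"])
    for df in (metadata, detection, truth, lineages):
        df.sort_values(list(df.columns[:2]), inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)
    return SyntheticCohort(markers, metadata, detection, truth, lineages, marker_db)
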
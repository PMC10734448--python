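"""Four-parameter filtering of per-sample consensus marker genes.

Strain-level phylogenies from shotgun metagenomes are built from per-sample
consensus sequences of species-specific marker genes, with uncovered positions
masked as ``N``.  Before concatenating markers into a per-species alignment,
four knobs control which markers and samples survive:

``breadth_threshold``
    minimum percent of non-``N`` positions for a marker to count as observed
    in a sample (breadth of coverage of the consensus marker);
``trim_sequences``
    bases removed from both ends of every marker (alignment-edge noise);
``marker_in_n_samples``
    percent of samples that must carry a marker for the marker to be kept;
``sample_with_n_markers``
    minimum number of kept markers for a sample to be kept.

A sample that survives the last filter counts as "detected" for the species,
which is what the culture benchmarking scores.  Defaults (80 / 50 / 80 / 20)
are the stringent values appropriate for high-biomass gut metagenomes; for
low-biomass airway samples they are typically relaxed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID = frozenset(b"ACGTN")


@dataclass(frozen=True)
class ConsensusMarker:
    """One sample's consensus sequence for one species-specific marker.

    ``sequence`` is over {A,C,G,T,N}; breadth is always recomputed from the
    sequence, never trusted from a file.
    """

    sample_id: str
    species: str
    marker_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        bad = set(seq.encode()) - _VALID
        if bad:
            raise ValueError(
                f"marker {self.marker_id} in sample {self.sample_id}: "
                f"invalid symbols {sorted(chr(b) for b in bad)}"
            )
        if not seq:
            raise ValueError(f"marker {self.marker_id} in sample {self.sample_id}: empty sequence")

    @property
    def breadth(self) -> float:
        """Fraction of non-N positions, in [0, 1]."""
        n = self.sequence.count("N")
        return (len(self.sequence) - n) / len(self.sequence)


@dataclass(frozen=True)
class ParameterSet:
    """The four filtering knobs, in the tool's native units."""

    breadth_threshold: float = 80.0   # percent
    trim_sequences: int = 50          # bases off each end
    marker_in_n_samples: float = 80.0  # percent of samples
    sample_with_n_markers: int = 20   # count of kept markers

    def __post_init__(self) -> None:
        if not 0 <= self.breadth_threshold <= 100:
            raise ValueError("breadth_threshold must be in [0, 100]")
        if self.trim_sequences < 0:
            raise ValueError("trim_sequences must be >= 0")
        if not 0 <= self.marker_in_n_samples <= 100:
            raise ValueError("marker_in_n_samples must be in [0, 100]")
        if self.sample_with_n_markers < 1:
            raise ValueError("sample_with_n_markers must be >= 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "breadth_threshold": self.breadth_threshold,
            "trim_sequences": self.trim_sequences,
            "marker_in_n_samples": self.marker_in_n_samples,
            "sample_with_n_markers": self.sample_with_n_markers,
        }


DEFAULT_PARAMETERS = ParameterSet()


@dataclass
class SpeciesAlignment:
    """Concatenation of kept, trimmed markers for the samples that passed.

    ``marker_spans`` maps each kept marker_id to its half-open column range in
    the concatenated rows, so any column can be traced back to its source
    marker.  ``rows`` is empty (with ``is_empty`` True) when no sample passed.
    """

    species: str
    kept_markers: list[str]
    rows: dict[str, str]
    marker_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    parameters: ParameterSet = DEFAULT_PARAMETERS

    @property
    def is_empty(self) -> bool:
        return not self.rows

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.rows)

    @property
    def length(self) -> int:
        if self.is_empty:
            return 0
        return len(next(iter(self.rows.values())))


def _marker_table(markers: list[ConsensusMarker]) -> tuple[list[str], list[str], dict]:
    """Sorted sample/marker index plus {(sample, marker): ConsensusMarker}."""
    if not markers:
        raise ValueError("empty marker set")
    index: dict[tuple[str, str], ConsensusMarker] = {}
    lengths: dict[str, int] = {}
    for m in markers:
        key = (m.sample_id, m.marker_id)
        if key in index:
            raise ValueError(f"duplicate marker {m.marker_id} for sample {m.sample_id}")
        if m.marker_id in lengths and lengths[m.marker_id] != len(m.sequence):
            raise ValueError(
                f"marker {m.marker_id}: inconsistent lengths "
                f"({lengths[m.marker_id]} vs {len(m.sequence)})"
            )
        lengths[m.marker_id] = len(m.sequence)
        index[key] = m
    samples = sorted({s for s, _ in index})
    marker_ids = sorted({mk for _, mk in index})
    return samples, marker_ids, index


def apply_breadth_threshold(
    markers: list[ConsensusMarker], breadth_threshold: float
) -> pd.DataFrame:
    """Boolean presence matrix (samples x markers) from the breadth filter.

    A marker counts as present for a sample iff ``100 * breadth >=
    breadth_threshold`` (inclusive); a marker missing for a sample, or below
    threshold, is absent.
    """
    samples, marker_ids, index = _marker_table(markers)
    presence = pd.DataFrame(False, index=samples, columns=marker_ids)
    for (sample, marker_id), m in index.items():
        presence.loc[sample, marker_id] = 100.0 * m.breadth >= breadth_threshold
    return presence


def trim_marker(sequence: str, trim_sequences: int) -> str:
    """Remove ``trim_sequences`` bases from both ends (0-based half-open)."""
    if trim_sequences < 0:
        raise ValueError("trim_sequences must be >= 0")
    if len(sequence) <= 2 * trim_sequences:
        raise ValueError(
            f"sequence of length {len(sequence)} cannot be trimmed by {trim_sequences} per end"
        )
    if trim_sequences == 0:
        return sequence
    return sequence[trim_sequences : len(sequence) - trim_sequences]


def filter_markers(presence: pd.DataFrame, marker_in_n_samples: float) -> list[str]:
    """Marker ids present in >= ``marker_in_n_samples`` percent of samples."""
    if presence.empty:
        raise ValueError("empty presence matrix")
    frac = presence.mean(axis=0)
    return sorted(frac.index[100.0 * frac >= marker_in_n_samples])


def filter_samples(
    presence: pd.DataFrame, sample_with_n_markers: int
) -> tuple[list[str], pd.Series]:
    """Kept sample ids and the per-sample detection call.

    ``presence`` must already be restricted to the kept markers.  A sample is
    kept -- the species is "detected" in it -- iff it carries at least
    ``sample_with_n_markers`` kept markers (inclusive).
    """
    counts = presence.sum(axis=1)
    detected = (counts >= sample_with_n_markers).astype(int)
    detected.name = "detected"
    return sorted(detected.index[detected == 1]), detected


def build_species_alignment(
    markers: list[ConsensusMarker], parameters: ParameterSet
) -> SpeciesAlignment:
    """Run the full filter pipeline and concatenate surviving markers.

    Order: breadth filter (on untrimmed sequences) -> trim -> marker filter ->
    sample filter -> concatenation in lexicographic marker_id order.  Markers
    too short to trim are dropped globally with a warning so rows stay aligned;
    a kept sample's absent markers are filled with N so downstream SNV counting
    skips those columns.
    """
    species = markers[0].species if markers else ""
    samples, marker_ids, index = _marker_table(markers)

    lengths = {mk: len(index[(s, mk)].sequence) for (s, mk) in index}
    too_short = sorted(
        mk for mk in marker_ids if lengths[mk] <= 2 * parameters.trim_sequences
    )
    if too_short:
        logger.warning(
            "%s: dropping %d marker(s) shorter than 2*trim_sequences+1: %s",
            species, len(too_short), ", ".join(too_short),
        )
    usable = [mk for mk in marker_ids if mk not in set(too_short)]
    if not usable:
        return SpeciesAlignment(species, [], {}, {}, parameters)

    presence = apply_breadth_threshold(markers, parameters.breadth_threshold)
    presence = presence[usable]
    kept_markers = filter_markers(presence, parameters.marker_in_n_samples)
    kept_samples, _ = filter_samples(presence[kept_markers], parameters.sample_with_n_markers)
    logger.info(
        "%s: %d/%d markers and %d/%d samples kept",
        species, len(kept_markers), len(marker_ids), len(kept_samples), len(samples),
    )
    if not kept_samples or not kept_markers:
        return SpeciesAlignment(species, kept_markers, {}, {}, parameters)

    trimmed_len = {mk: lengths[mk] - 2 * parameters.trim_sequences for mk in kept_markers}
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for mk in kept_markers:
        spans[mk] = (offset, offset + trimmed_len[mk])
        offset += trimmed_len[mk]

    rows: dict[str, str] = {}
    for sample in kept_samples:
        parts = []
        for mk in kept_markers:
            if presence.loc[sample, mk]:
                parts.append(trim_marker(index[(sample, mk)].sequence, parameters.trim_sequences))
            else:
                parts.append("N" * trimmed_len[mk])
        rows[sample] = "".join(parts)
    return SpeciesAlignment(species, kept_markers, rows, spans, parameters)


def detection_calls(
    markers: list[ConsensusMarker], parameters: ParameterSet
) -> pd.Series:
    """Per-sample 0/1 species detection under ``parameters``.

    Equals membership in :func:`build_species_alignment`'s rows; samples with
    no marker at all report 0.
    """
    alignment = build_species_alignment(markers, parameters)
    samples = sorted({m.sample_id for m in markers})
    calls = pd.Series(0, index=samples, name="detected", dtype=int)
    calls[ [s for s in alignment.rows] ] = 1
    return calls


def presence_counts(presence: pd.DataFrame) -> np.ndarray:
    """Per-sample counts of present markers (convenience for reports)."""
    return presence.sum(axis=1).to_numpy()
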
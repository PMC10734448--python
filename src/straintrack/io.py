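"""Readers and writers for the pipeline's file dialects, plus configuration.

Sequence data travels as per-species FASTA with ``>{sample_id}|{marker_id}``
headers (uppercase A/C/G/T/N); tables are UTF-8 TSV with ``NA`` for missing.
All writers emit deterministic row order so a fixed seed reproduces output
files byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .markerfilter import ConsensusMarker, ParameterSet
from .retention import DEFAULT_THRESHOLDS

logger = logging.getLogger(__name__)


def read_marker_fasta(path, species: str | None = None) -> list[ConsensusMarker]:
    """Load consensus markers from a per-species FASTA.

    Headers must be ``sample|marker``; lowercase bases are upper-cased with a
    warning, and inconsistent lengths within a marker_id raise an error that
    names the marker.
    """
    if species is None:
        species = Path(path).stem
    markers: list[ConsensusMarker] = []
    lengths: dict[str, tuple[str, int]] = {}
    lowercased = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"malformed header {rec.id!r}: expected 'sample|marker'")
        sample_id, marker_id = rec.id.split("|", 1)
        seq = str(rec.seq)
        if seq != seq.upper():
            lowercased += 1
            seq = seq.upper()
        if marker_id in lengths and lengths[marker_id][1] != len(seq):
            first_sample, first_len = lengths[marker_id]
            raise ValueError(
                f"marker {marker_id}: length {len(seq)} in sample {sample_id} "
                f"differs from {first_len} in sample {first_sample}"
            )
        lengths.setdefault(marker_id, (sample_id, len(seq)))
        markers.append(ConsensusMarker(sample_id, species, marker_id, seq))
    if lowercased:
        logger.warning("%s: %d record(s) had lowercase bases; upper-cased", path, lowercased)
    return markers


def write_marker_fasta(markers: list[ConsensusMarker], path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=f"{m.sample_id}|{m.marker_id}", description="")
        for m in sorted(markers, key=lambda m: (m.sample_id, m.marker_id))
    ]
    SeqIO.write(records, str(path), "fasta")


def write_alignment_fasta(alignment, path) -> None:
    """Concatenated per-species alignment, one record per kept sample."""
    records = [
        SeqRecord(Seq(alignment.rows[s]), id=s, description="")
        for s in alignment.sample_ids
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class PipelineConfig:
    """End-to-end run settings; defaults are the study defaults.

    Either ``synth`` holds generator settings (synthetic mode) or
    ``input_fasta`` maps species to consensus-marker FASTA paths with
    ``metadata``/``detection`` tables alongside.
    """

    seed: int = 0
    outdir: str = "results"
    synth: dict | None = None
    input_fasta: dict[str, str] | None = None
    metadata: str | None = None
    detection: str | None = None
    mlst: str | None = None
    tree: str | None = None
    parameters: ParameterSet = field(default_factory=ParameterSet)
    retention_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    default_retention_threshold: float = 0.1
    cluster_threshold: float = 0.01
    suggest_cap: float = 0.05

    def __post_init__(self) -> None:
        if self.synth is None and self.input_fasta is None:
            raise ValueError("config needs either a 'synth' section or 'input_fasta' paths")
        if self.cluster_threshold < 0:
            raise ValueError("cluster_threshold must be >= 0")

    def threshold_for(self, species: str) -> float:
        return self.retention_thresholds.get(species, self.default_retention_threshold)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "parameters" in raw and isinstance(raw["parameters"], dict):
        raw["parameters"] = ParameterSet(**raw["parameters"])
    return PipelineConfig(**raw)
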
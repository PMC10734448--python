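"""End-to-end run: simulate (optional) -> filter -> distances -> retention
-> clustering -> benchmark, with a JSON manifest for bit-identical re-runs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import confusion, metrics
from .clustering import (assign_clusters, build_tracks, cluster_mlst_concordance,
                         neighbor_joining, read_tree)
from .distance import all_vs_all, normalize_by_median, to_long_with_normalized
from .io import (PipelineConfig, read_marker_fasta, read_tsv, write_alignment_fasta,
                 write_marker_fasta, write_tsv)
from .markerfilter import build_species_alignment, detection_calls
from .retention import bin_distances, call_retention, categorize_pairs, retention_table
from .synth import MarkerDB, SpeciesSpec, SynthConfig, simulate_cohort, simulate_marker_db

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged failure; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("synth")
def _run_synth(config: PipelineConfig, outdir: Path):
    opts = dict(config.synth or {})
    species_specs = [
        SpeciesSpec(**sp) if isinstance(sp, dict) else SpeciesSpec(sp)
        for sp in opts.pop("species_specs", [{"name": "S_pneumoniae"}])
    ]
    rng = np.random.default_rng(config.seed)
    db = simulate_marker_db(species_specs, rng)
    synth_cfg = SynthConfig(species=tuple(s.name for s in species_specs), **opts)
    cohort = simulate_cohort(synth_cfg, db, rng)
    for species, markers in cohort.markers.items():
        write_marker_fasta(markers, outdir / f"{species}.markers.fasta")
    write_tsv(cohort.metadata, outdir / "metadata.tsv")
    write_tsv(cohort.detection, outdir / "detection_raw.tsv")
    write_tsv(cohort.truth, outdir / "truth.tsv")
    write_tsv(cohort.lineages, outdir / "lineages.tsv")
    return cohort.markers, cohort.metadata, cohort.detection, cohort.lineages


@_stage("input")
def _load_inputs(config: PipelineConfig):
    markers = {
        sp: read_marker_fasta(path, sp) for sp, path in config.input_fasta.items()
    }
    metadata = read_tsv(config.metadata) if config.metadata else None
    detection = read_tsv(config.detection) if config.detection else None
    return markers, metadata, detection, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synth is not None:
        markers, metadata, detection, lineages = _run_synth(config, outdir)
    else:
        markers, metadata, detection, lineages = _load_inputs(config)

    # -- marker filtering & detection ------------------------------------
    alignments = {}
    det_rows = []
    for species in sorted(markers):
        try:
            aln = build_species_alignment(markers[species], config.parameters)
        except Exception as exc:
            raise PipelineError(f"[markerfilter] {species}: {exc}") from exc
        alignments[species] = aln
        calls = detection_calls(markers[species], config.parameters)
        det_rows.append(
            pd.DataFrame({"sample_id": calls.index, "species": species,
                          "detected": calls.to_numpy()})
        )
        if not aln.is_empty:
            write_alignment_fasta(aln, outdir / f"{species}.alignment.fasta")
    detected = pd.concat(det_rows, ignore_index=True)
    write_tsv(detected, outdir / "detection.tsv")
    report = pd.DataFrame(
        [
            {"species": sp, "kept_markers": len(a.kept_markers),
             "kept_samples": len(a.rows), "alignment_length": a.length}
            for sp, a in sorted(alignments.items())
        ]
    )
    write_tsv(report, outdir / "filter_report.tsv")

    # -- distances & retention -------------------------------------------
    pair_tables, retention_results, norm_by_species = [], [], {}
    for species, aln in alignments.items():
        if aln.is_empty or len(aln.rows) < 2:
            logger.info("%s: fewer than 2 kept samples, skipping distances", species)
            continue
        try:
            raw = all_vs_all(aln)
            norm = normalize_by_median(raw)
        except Exception as exc:
            raise PipelineError(f"[distance] {species}: {exc}") from exc
        norm_by_species[species] = (raw, norm)
        write_tsv(to_long_with_normalized(raw, norm), outdir / f"{species}.distances.tsv")
        if metadata is not None:
            try:
                pairs = categorize_pairs(norm, metadata)
            except Exception as exc:
                raise PipelineError(f"[retention] {species}: {exc}") from exc
            pair_tables.append(pairs)
            retention_results.extend(
                call_retention(pairs, {species: config.threshold_for(species)})
            )
    if pair_tables:
        all_pairs = pd.concat(pair_tables, ignore_index=True)
        write_tsv(bin_distances(all_pairs), outdir / "histograms.tsv")
        write_tsv(retention_table(retention_results), outdir / "retention.tsv")

    # -- clustering & longitudinal tracks --------------------------------
    cluster_frames, track_frames, concordance = [], [], {}
    for species, (raw, _norm) in sorted(norm_by_species.items()):
        if config.tree is not None:
            tree = read_tree(config.tree)
        elif len(raw.sample_ids) >= 3 and not np.isnan(raw.rates).any():
            tree = neighbor_joining(raw)
        else:
            continue
        try:
            assignment = assign_clusters(tree, config.cluster_threshold)
        except Exception as exc:
            raise PipelineError(f"[clustering] {species}: {exc}") from exc
        cf = assignment.to_frame()
        cf.insert(1, "species", species)
        cluster_frames.append(cf)
        if metadata is not None and detection is not None:
            det_sp = _detection_states(detection, detected, species)
            mlst = _mlst_from_lineages(lineages, species)
            tracks = build_tracks(assignment, metadata, det_sp, mlst)
            tracks.insert(1, "species", species)
            track_frames.append(tracks)
            if mlst is not None:
                try:
                    concordance[species] = cluster_mlst_concordance(assignment, mlst)
                except ValueError:
                    pass
    if cluster_frames:
        write_tsv(pd.concat(cluster_frames, ignore_index=True), outdir / "clusters.tsv")
    if track_frames:
        write_tsv(pd.concat(track_frames, ignore_index=True), outdir / "tracks.tsv")

    # -- benchmarking vs culture -----------------------------------------
    bench_rows = []
    if detection is not None and "culture_grade" in detection.columns:
        for species in sorted(markers):
            sub = detection[detection["species"] == species]
            culture = pd.Series(
                (sub["culture_grade"].fillna(-1).astype(float) > 0).astype(float).to_numpy(),
                index=sub["sample_id"],
            )
            culture[sub["culture_grade"].isna().to_numpy()] = np.nan
            calls = detected[detected["species"] == species].set_index("sample_id")["detected"]
            try:
                counts = confusion(calls, culture)
            except ValueError:
                continue
            bench_rows.append(metrics(*counts, species=species, method="markerfilter").formatted())
    if bench_rows:
        write_tsv(pd.DataFrame(bench_rows), outdir / "benchmark.tsv")

    manifest = {
        "straintrack_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": config.parameters.as_dict(),
        "retention_thresholds": {
            sp: config.threshold_for(sp) for sp in sorted(markers)
        },
        "cluster_threshold": config.cluster_threshold,
        "species": sorted(markers),
        "n_samples": int(metadata.shape[0]) if metadata is not None else None,
        "cluster_mlst_ari": concordance or None,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _detection_states(detection: pd.DataFrame, detected: pd.DataFrame, species: str):
    sub = detection[detection["species"] == species]
    culture = (sub["culture_grade"].fillna(0).astype(float) > 0).astype(int)
    det_sp = detected[detected["species"] == species].set_index("sample_id")["detected"]
    return pd.DataFrame({
        "sample_id": sub["sample_id"].to_numpy(),
        "culture_positive": culture.to_numpy(),
        "metagenome_positive": [
            int(det_sp.get(s, 0)) for s in sub["sample_id"]
        ],
    })


def _mlst_from_lineages(lineages: pd.DataFrame | None, species: str):
    """Synthetic sequence types: the true lineage id doubles as the ST label."""
    if lineages is None:
        return None
    sub = lineages[lineages["species"] == species]
    if sub.empty:
        return None
    return pd.DataFrame({
        "sample_id": sub["sample_id"].to_numpy(),
        "sequence_type": sub["lineage_id"].to_numpy(),
    })
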
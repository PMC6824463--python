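"""End-to-end driver: simulation or files in, profiled/damage tables out.

``run_pipeline`` ties the stages together: (simulate or read) G1/S coverage
and annotations -> copy-number profile -> peaks and fired origins ->
interorigin distances -> damage normalization -> orientation contexts ->
T_rep-binned enrichment.  Every run writes a manifest capturing the config,
seeds and input digests; identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__, damage as damage_mod, io as oio, profiling
from .config import AnalysisConfig, RunManifest
from .core import GenomicTrack, ValidationError
from .synthetic import (
    DamageGroundTruth,
    GenomeConfig,
    SimulationCondition,
    build_genome,
    sample_reads,
    simulate_cell_population,
    simulate_damage_tracks,
)

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineInputs:
    """File-based inputs for a profiling + damage run."""

    g1_track: Union[str, Path]
    s_track: Union[str, Path]
    origins: Union[str, Path]
    genes: Optional[Union[str, Path]] = None
    ip_track: Optional[Union[str, Path]] = None
    control_track: Optional[Union[str, Path]] = None


@dataclass
class PipelineResult:
    outdir: Path
    profile: profiling.ReplicationProfile
    peaks: list
    calls: list
    distances: list
    contexts: Optional[list]
    damage_table: Optional[pd.DataFrame]
    manifest_path: Path


def _float_fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6g}"


def run_pipeline(
    config: AnalysisConfig,
    outdir: Union[str, Path],
    inputs: Optional[PipelineInputs] = None,
    simulate_seed: Optional[int] = None,
    genome_config: Optional[GenomeConfig] = None,
    condition: Optional[SimulationCondition] = None,
    damage_truth: Optional[DamageGroundTruth] = None,
    n_cells: int = 500,
    depth: float = 30.0,
) -> PipelineResult:
    """Run profiling (and, when damage inputs exist, damage mapping).

    Exactly one of ``inputs`` (file mode) or ``simulate_seed`` (simulate
    mode) must be given.  File mode validates that every named input exists
    before any computation.
    """
    if (inputs is None) == (simulate_seed is None):
        raise ValidationError("give exactly one of inputs= or simulate_seed=")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    digests: dict[str, str] = {}
    if inputs is not None:
        named = {
            "g1_track": inputs.g1_track,
            "s_track": inputs.s_track,
            "origins": inputs.origins,
            "genes": inputs.genes,
            "ip_track": inputs.ip_track,
            "control_track": inputs.control_track,
        }
        for name, path in named.items():
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input {name} not found: {path}")
        digests = {
            name: RunManifest.digest(path) for name, path in named.items() if path is not None
        }
        g1 = oio.read_track(inputs.g1_track, config.bin_size, label="G1")
        s = oio.read_track(inputs.s_track, config.bin_size, label="S")
        origins = oio.read_origins(inputs.origins)
        genes = oio.read_genes(inputs.genes) if inputs.genes else None
        ip = (
            oio.read_track(inputs.ip_track, config.bin_size, label="IP")
            if inputs.ip_track
            else None
        )
        control = (
            oio.read_track(inputs.control_track, config.bin_size, label="control")
            if inputs.control_track
            else None
        )
    else:
        gcfg = genome_config or GenomeConfig(seed=simulate_seed)
        genome = build_genome(gcfg)
        cond = condition or SimulationCondition()
        state = simulate_cell_population(genome, cond, n_cells, seed=simulate_seed + 1)
        g1, s = sample_reads(state, depth, seed=simulate_seed + 2)
        truth = damage_truth or DamageGroundTruth()
        ip, control = simulate_damage_tracks(state, genome, truth, seed=simulate_seed + 3)
        origins, genes = genome.origins, genome.genes
        oio.write_origins(origins, outdir / "origins.tsv")
        oio.write_genes(genes, outdir / "genes.gff3")
        oio.write_track(g1, outdir / "g1.bedgraph")
        oio.write_track(s, outdir / "s.bedgraph")
        oio.write_track(ip, outdir / "damage_ip.bedgraph")
        oio.write_track(control, outdir / "histone_control.bedgraph")

    # --- replication profile -------------------------------------------------
    ratio = profiling.compute_copy_number(
        s, g1, min_g1=config.min_g1, anchor=config.anchor, g1_reference=config.g1_reference
    )
    smoothed = profiling.fourier_smooth(ratio, config.fourier_cutoff_kb * 1000.0)
    profile = profiling.ReplicationProfile(ratio, smoothed, config.fourier_cutoff_kb * 1000.0)
    peaks = profiling.call_peaks(smoothed, config.persistence_bp)
    peaks = profiling.peak_widths(profile, peaks)
    calls = profiling.call_fired_origins(
        profile,
        origins,
        fired_threshold=config.fired_threshold,
        match_tol=config.match_tol_bp,
        peaks=peaks,
        window_bp=config.fired_window_bp,
        source=config.fired_source,
    )
    distances = profiling.interorigin_distances(calls)

    oio.write_track(ratio, outdir / "copy_number.bedgraph")
    oio.write_track(smoothed, outdir / "copy_number_smoothed.bedgraph")
    pd.DataFrame(
        [
            {
                "chrom": p.chrom, "apex_pos": p.apex_pos, "apex_value": p.apex_value,
                "left_extent": p.left_extent, "right_extent": p.right_extent,
                "fwhm": p.fwhm, "truncated": p.truncated,
            }
            for p in peaks
        ]
    ).to_csv(outdir / "peaks.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "peaks.bed", "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.apex_pos - 1}\t{p.apex_pos}\tpeak\t0\t.\n")
    pd.DataFrame(
        [
            {
                "origin": c.origin.id, "chrom": c.origin.chrom, "pos": c.origin.pos,
                "t_rep": c.origin.t_rep, "copy_number": c.copy_number,
                "fired_fraction": c.fired_fraction, "fired": c.fired,
                "matched_peak_pos": c.matched_peak.apex_pos if c.matched_peak else "",
            }
            for c in calls
        ]
    ).to_csv(outdir / "fired_origins.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [{"origin": o.id, "chrom": o.chrom, "pos": o.pos, "nearest_fired_bp": d}
         for o, d in distances]
    ).to_csv(outdir / "interorigin_distances.tsv", sep="\t", index=False, float_format="%.6g")

    # --- damage mapping ------------------------------------------------------
    contexts = None
    table = None
    if ip is not None and control is not None:
        chip = damage_mod.normalize_chip(ip, control)
        norm = damage_mod.normalize_by_replication(chip, profile, config.min_replication)
        meta = damage_mod.meta_origin_profile(
            chip, origins, config.meta_half_window_bp, config.trep_cutoff_min
        )
        rows = []
        for subset, d in meta.items():
            for off, m in zip(d["offsets"], d["mean"]):
                rows.append({"subset": subset, "offset_bp": int(off),
                             "mean_signal": m, "n_origins": d["n"]})
        pd.DataFrame(rows).to_csv(
            outdir / "meta_origin_profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if genes:
            contexts = damage_mod.classify_origin_gene_context(origins, genes)
            pd.DataFrame(
                [
                    {
                        "origin": c.origin.id, "t_rep": c.origin.t_rep,
                        "pair_class": c.pair_class, "subclass": c.subclass,
                        "left_gene": c.left_gene.id if c.left_gene else "",
                        "right_gene": c.right_gene.id if c.right_gene else "",
                    }
                    for c in contexts
                ]
            ).to_csv(outdir / "origin_contexts.tsv", sep="\t", index=False)
            table = damage_mod.binned_damage_by_trep(
                norm, contexts, config.trep_bin_edges, config.damage_window_bp
            )
            table.to_csv(
                outdir / "damage_by_trep.tsv", sep="\t", index=False, float_format="%.6g"
            )
        oio.write_track(chip, outdir / "chip_ratio.bedgraph")
        oio.write_track(norm, outdir / "damage_per_replication.bedgraph")

    manifest = RunManifest(
        config=config.to_dict(),
        seed=simulate_seed,
        input_digests=digests,
        package_version=__version__,
        mode="simulate" if simulate_seed is not None else "files",
    )
    manifest_path = manifest.write(outdir)
    return PipelineResult(outdir, profile, peaks, calls, distances, contexts, table, manifest_path)
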
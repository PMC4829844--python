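"""End-to-end orchestration: simulate (or ingest) -> normalize ->
segment -> score -> call -> report, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .calling import (CallThresholds, CNAProfile, call_segments, chromosome_calls)
from .config import PipelineConfig
from .errors import ConfigError
from .genome import GenomeModel, build_genome
from .normalize import (CorrectedCounts, build_reference, correct_panel,
                        correct_sample, log2_ratio_profile)
from .segment import cbs_segment, prune_segments, segment_zscores
from .simulate import (BinnedCounts, CNASpec, ControlPanel, GCBias,
                       balanced_spec, mug_cc1_spec, primary_tumor_spec,
                       simulate_control_panel, simulate_sample)

log = logging.getLogger("chordcna")


def preset_spec(name: str, sex: str = "XY") -> tuple[CNASpec, float]:
    """(CNASpec, default purity) for a named karyotype preset."""
    if name == "mug-cc1":
        return mug_cc1_spec(), 1.0
    if name == "primary-tumor":
        return primary_tumor_spec()
    if name in ("lcl", "balanced"):
        return balanced_spec(sex), 1.0
    raise ConfigError(f"unknown preset {name!r}")


@dataclasses.dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    outputs: dict[str, str]  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def counts_to_csv(genome: GenomeModel, samples: list[BinnedCounts], path) -> None:
    """Bins plus one count column per sample."""
    df = genome.bins[["chrom", "start", "end"]].copy()
    for s in samples:
        df[s.sample_id] = s.counts
    df.to_csv(path, index=False)


def counts_from_csv(path, genome: GenomeModel) -> list[BinnedCounts]:
    df = pd.read_csv(path, dtype={"chrom": str})
    samples = []
    for col in df.columns:
        if col in ("chrom", "start", "end"):
            continue
        counts = df[col].to_numpy(dtype=np.int64)
        if len(counts) != genome.n_bins:
            from .errors import DataError
            raise DataError(f"counts column {col!r} does not match the genome")
        samples.append(BinnedCounts(sample_id=col, counts=counts,
                                    total_reads=int(counts.sum())))
    return samples


def analyze_sample(
    counts: BinnedCounts,
    genome: GenomeModel,
    panel: ControlPanel,
    config: PipelineConfig | None = None,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    panel_corrected: list[CorrectedCounts] | None = None,
) -> CNAProfile:
    """Normalize, segment, score and call one sample against a panel."""
    config = config or PipelineConfig()
    ncfg, scfg, ccfg = config.normalization, config.segmentation, config.calling
    if panel_corrected is None:
        panel_corrected = correct_panel(panel, genome, ncfg.lowess_fraction)
    if reference is None:
        reference = build_reference(panel, genome, ncfg.lowess_fraction,
                                    ncfg.max_zero_fraction, corrected=panel_corrected)
    ref, ref_mask = reference
    corrected = correct_sample(counts, genome, ncfg.lowess_fraction)
    profile = log2_ratio_profile(corrected, ref, ref_mask, genome, center=ncfg.center)
    log.info("normalized %s: %d usable bins", counts.sample_id, int(profile.mask.sum()))
    segset = cbs_segment(profile, scfg.alpha, scfg.nperm, scfg.min_width, scfg.seed)
    segset = prune_segments(segset, profile, scfg.sd_undo)
    segset = segment_zscores(segset, corrected, panel_corrected)
    log.info("segmented %s: %d segments", counts.sample_id, len(segset.segments))
    thresholds = CallThresholds(ccfg.gain, ccfg.loss, ccfg.high_level_gain,
                                ccfg.chromosome_fraction)
    called = call_segments(segset, thresholds)
    chromosome_calls(called, genome, thresholds)
    return called


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Simulate inputs per config, analyze, and write all artifacts.

    Writes genome CSV, counts CSV, profile CSV, SEG, segment CSV with
    z-scores, a JSON summary and a manifest with output checksums.  Any
    stage failure removes partial outputs.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    try:
        gcfg, simcfg = config.genome, config.simulation
        genome = build_genome(gcfg.scale, gcfg.bin_size, gcfg.seed)
        log.info("genome: %s scale, %d bins", gcfg.scale, genome.n_bins)
        spec, purity = preset_spec(simcfg.preset, simcfg.sex)
        if simcfg.events is not None:
            spec = CNASpec(events=tuple((str(r), int(c)) for r, c in simcfg.events),
                           sex=simcfg.sex)
        if simcfg.purity is not None:
            purity = simcfg.purity
        gc_bias = GCBias(peak=simcfg.gc_bias_peak, amplitude=simcfg.gc_bias_amplitude)
        ss = np.random.SeedSequence(simcfg.seed)
        panel_seed, sample_seed = ss.spawn(2)
        panel = simulate_control_panel(
            genome, simcfg.n_controls, simcfg.total_reads, simcfg.dispersion,
            gc_bias, seed=panel_seed)
        sample = simulate_sample(
            genome, spec, purity, simcfg.total_reads, simcfg.dispersion,
            gc_bias, seed=sample_seed, sample_id=simcfg.preset)
        log.info("simulated %s (purity %.2f) + %d controls",
                 simcfg.preset, purity, panel.size)

        profile_called = analyze_sample(sample, genome, panel, config)

        genome_csv = outdir / "genome.csv"
        genome.to_csv(genome_csv); written.append(genome_csv)
        counts_csv = outdir / "counts.csv"
        counts_to_csv(genome, [sample], counts_csv); written.append(counts_csv)

        # re-derive the per-bin profile for the CSV artifact
        ncfg = config.normalization
        panel_corr = correct_panel(panel, genome, ncfg.lowess_fraction)
        ref = build_reference(panel, genome, ncfg.lowess_fraction,
                              ncfg.max_zero_fraction, corrected=panel_corr)
        corrected = correct_sample(sample, genome, ncfg.lowess_fraction)
        profile = log2_ratio_profile(corrected, ref[0], ref[1], genome,
                                     center=ncfg.center)
        profile_csv = outdir / "profile.csv"
        profile.to_csv(profile_csv); written.append(profile_csv)

        seg_path = outdir / "segments.seg"
        profile_called.segments.to_seg(seg_path); written.append(seg_path)
        segcsv_path = outdir / "segments.csv"
        profile_called.segments.to_csv(segcsv_path); written.append(segcsv_path)

        summary = {
            "sample_id": profile_called.sample_id,
            "karyotype": profile_called.karyotype_summary(),
            "whole_gains": profile_called.whole_gains(),
            "whole_losses": profile_called.whole_losses(),
            "arm_events": profile_called.arm_events(),
            "n_segments": len(profile_called.segments.segments),
            "n_focal_high_level": len(profile_called.focal_high_level),
            "chromosome_calls": {c: s.call for c, s in
                                 profile_called.chromosome_summary.items()},
        }
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(summary_path)

        manifest = RunManifest(
            config=config.to_dict(),
            seeds={"genome": gcfg.seed, "simulation": simcfg.seed,
                   "segmentation": config.segmentation.seed},
            version=__version__,
            outputs={p.name: _sha256(p) for p in written},
        )
        (outdir / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
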
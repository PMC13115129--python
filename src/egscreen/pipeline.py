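"""Seed-reproducible orchestration: simulate -> concord -> depth/CNV -> screen.

Every stage communicates through the declared file formats (genotype TSV,
depth TSV, TSV/JSON reports); a run emits a JSON manifest listing every
output with its SHA-256 content hash, so an identical config and seed can be
verified to reproduce identical bytes. A single global seed fans out to
deterministic per-stage child seeds, keeping each stage reproducible when
others are toggled off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ampbias, concordance, screening, simulate
from .io import (
    GenotypeMatrix,
    write_depth_track,
    write_genotypes,
    write_report,
)

log = logging.getLogger("egscreen")

#: analysis thresholds; defaults are the screening workflow's printed values
DEFAULT_THRESHOLDS = {
    "callrate_min": 0.9,
    "maf_min": 0.01,
    "hwe_p_min": 1e-5,
    "x_maf_min": 0.015,
    "x_male_het_max": 0.01,
    "sex_het_threshold": 0.02,
    "trisomy_threshold": 2.6,
    "monosomy_threshold": 1.4,
}

DEFAULT_ERROR_SETTINGS = {
    # points in WGA-error space bracketing a clean amplification, an
    # MDA-like low-error regime and a MALBAC-like high-error regime
    "clean": {"ado": 0.0, "het_gain": 0.0, "hom_reversal": 0.0, "missing": 0.0},
    "low_error": {"ado": 0.05, "het_gain": 0.01, "hom_reversal": 0.002,
                  "missing": 0.05},
    "high_error": {"ado": 0.25, "het_gain": 0.05, "hom_reversal": 0.01,
                   "missing": 0.25},
}


@dataclass
class PipelineConfig:
    """Everything a full demo run needs; round-trips losslessly through YAML."""

    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "concord", "depth", "screen"]
    )
    # genotype simulation
    n_truth_samples: int = 3
    n_loci: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_settings: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ERROR_SETTINGS.items()}
    )
    n_replicates: int = 3
    # depth simulation: a bovine-scale genome, 25 autosomes of 100 Mb
    # (about 2.5 Gb, so 2500 bins at the default 1 Mb bin size)
    genome_def: dict[str, int] = field(
        default_factory=lambda: {str(c): 100_000_000 for c in range(1, 26)}
    )
    bin_size: int = 1_000_000
    depth_mean: float = 10.0
    depth_dispersion: float = 1.5
    # cohort / screening
    n_ref: int = 500
    n_embryo: int = 10
    n_cohort_loci: int = 2_000
    h2: dict[str, float] = field(
        default_factory=lambda: {
            "milk_yield": 0.3, "fat_pct": 0.35, "protein_pct": 0.35,
        }
    )
    n_x_loci: int = 3_000
    par_fraction: float = 0.05
    embryo_error_setting: str = "low_error"
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self):
        self.maf_range = tuple(self.maf_range)  # YAML gives a list

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["maf_range"] = list(self.maf_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs carry a .partial suffix."""


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages and return the output manifest.

    The manifest maps every emitted file (relative to ``outdir``) to its
    SHA-256 hash and is also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(["simulate", "depth", "cohort", "x", "embryo_err"],
                     _stage_seeds(config.seed, 5)))
    manifest: dict[str, str] = {}
    state: dict = {}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest[name] = _sha256(path)
        return path

    stage_fns = {
        "simulate": _stage_simulate,
        "concord": _stage_concord,
        "depth": _stage_depth,
        "screen": _stage_screen,
    }
    for stage in config.stages:
        if stage not in stage_fns:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        before = set(manifest)
        try:
            stage_fns[stage](config, seeds, emit, state)
        except Exception as exc:
            for name in set(manifest) - before:
                p = outdir / name
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
                del manifest[name]
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done in %.2fs (%d files)", stage,
                 time.perf_counter() - t0, len(manifest) - len(before))
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, seeds, emit, state) -> None:
    truth, freqs = simulate.simulate_reference_genotypes(
        config.n_truth_samples, config.n_loci, config.maf_range,
        seed=seeds["simulate"],
    )
    amp_rows, amp_names, pairs = [], [], {}
    child = _stage_seeds(seeds["simulate"] + 1,
                         len(config.error_settings) * config.n_replicates)
    k = 0
    for setting, rates_dict in config.error_settings.items():
        rates = simulate.WGAErrorRates(**rates_dict)
        for rep in range(config.n_replicates):
            src = truth.samples[rep % truth.n_samples]
            one = GenotypeMatrix(
                samples=[src], loci=truth.loci,
                calls=truth.row(src)[None, :],
            )
            corrupted = simulate.corrupt_with_wga_errors(one, rates, seed=child[k])
            k += 1
            name = f"{setting}_rep{rep}"
            amp_rows.append(corrupted.calls[0])
            amp_names.append(name)
            pairs[name] = src
    amp = GenotypeMatrix(samples=amp_names, loci=truth.loci,
                         calls=np.vstack(amp_rows))
    state["truth"], state["amp"], state["pairs"] = truth, amp, pairs
    emit("truth_genotypes.tsv", lambda p: write_genotypes(truth, p, "table"))
    emit("amplified_genotypes.tsv", lambda p: write_genotypes(amp, p, "table"))
    emit("pairs.tsv", lambda p: pd.DataFrame(
        {"amp_id": list(pairs), "ref_id": list(pairs.values())}
    ).to_csv(p, sep="\t", index=False))
    emit("truth.json", lambda p: write_report(
        {"seed": config.seed,
         "error_settings": config.error_settings,
         "mean_maf": float(np.mean(np.minimum(freqs, 1 - freqs)))},
        p, "json"))


def _stage_concord(config: PipelineConfig, seeds, emit, state) -> None:
    profiles = concordance.profile_samples(
        state["amp"], state["truth"], state["pairs"]
    )
    emit("error_profiles.tsv", lambda p: write_report(profiles, p, "tsv"))
    summary = concordance.summarize_profiles(profiles)
    emit("error_profile_summary.tsv",
         lambda p: summary.to_csv(p, sep="\t", na_rep="NA"))


def _stage_depth(config: PipelineConfig, seeds, emit, state) -> None:
    chroms = list(config.genome_def)
    tri_chrom = chroms[min(2, len(chroms) - 1)]
    scenarios = {
        "euploid": [],
        "trisomy": [simulate.CNEvent(chrom=tri_chrom, copy_number=3,
                                     whole_chromosome=True)],
    }
    child = _stage_seeds(seeds["depth"], len(scenarios))
    cn_reports = {}
    for (name, events), sd in zip(scenarios.items(), child):
        track = simulate.simulate_depth_track(
            config.genome_def, config.bin_size, config.depth_mean,
            config.depth_dispersion, cn_events=events, seed=sd,
        )
        emit(f"depth_{name}.tsv", lambda p, t=track: write_depth_track(t, p))
        profile = ampbias.call_aneuploidy(
            ampbias.estimate_copy_number(track),
            trisomy_threshold=config.thresholds["trisomy_threshold"],
            monosomy_threshold=config.thresholds["monosomy_threshold"],
        )
        cn_reports[name] = [c.__dict__ for c in profile.per_chromosome]
        sizes = tuple(
            s for s in ampbias.DEFAULT_WINDOW_SIZES
            if s >= config.bin_size and s <= max(config.genome_def.values())
        )
        curve = ampbias.depth_cv(track, sizes)
        emit(f"bias_curve_{name}.tsv", lambda p, c=curve: pd.DataFrame(
            {"window_size": c.window_sizes,
             "cv": [c.cv_per_window[w] for w in c.window_sizes]}
        ).to_csv(p, sep="\t", index=False))
    emit("cnv_calls.json", lambda p: write_report(cn_reports, p, "json"))


def _stage_screen(config: PipelineConfig, seeds, emit, state) -> None:
    cohort = simulate.simulate_breeding_cohort(
        config.n_ref, config.n_embryo, config.n_cohort_loci,
        h2=config.h2, maf_range=config.maf_range, seed=seeds["cohort"],
    )
    geno = cohort.genotypes
    ref_geno = geno.subset_samples(cohort.reference_ids)
    embryo_geno = geno.subset_samples(cohort.embryo_ids)
    rates = simulate.WGAErrorRates(
        **config.error_settings[config.embryo_error_setting]
    )
    embryo_geno = simulate.corrupt_with_wga_errors(
        embryo_geno, rates, seed=seeds["embryo_err"]
    )
    n_male = config.n_embryo // 2
    x_geno, sexes = simulate.simulate_x_genotypes(
        n_male, config.n_embryo - n_male, config.n_x_loci,
        maf_range=config.maf_range, par_fraction=config.par_fraction,
        error_rates=rates, seed=seeds["x"],
    )
    x_geno.samples = list(cohort.embryo_ids)  # align ids with the embryos
    true_sex = dict(zip(cohort.embryo_ids, sexes))
    known_males = [e for e, s in true_sex.items() if s == "male"]

    tri_chrom = list(config.genome_def)[min(2, len(config.genome_def) - 1)]
    child = _stage_seeds(seeds["depth"] + 1, config.n_embryo)
    tracks = {}
    cn_truth = {}
    for i, (e, sd) in enumerate(zip(cohort.embryo_ids, child)):
        events = []
        if i == 1:
            events = [simulate.CNEvent(chrom=tri_chrom, copy_number=3,
                                       whole_chromosome=True)]
        elif i == 2:
            events = [simulate.CNEvent(chrom=tri_chrom, copy_number=1,
                                       whole_chromosome=True)]
        cn_truth[e] = [dataclasses.asdict(ev) for ev in events]
        tracks[e] = simulate.simulate_depth_track(
            config.genome_def, config.bin_size, config.depth_mean,
            config.depth_dispersion, cn_events=events, seed=sd,
        )
    thr = config.thresholds
    report, detail = screening.screen_embryos(
        ref_geno, embryo_geno, cohort.drp, h2=config.h2,
        x_geno=x_geno, known_males=known_males, depth_tracks=tracks,
        callrate_min=thr["callrate_min"], maf_min=thr["maf_min"],
        hwe_p_min=thr["hwe_p_min"],
        trisomy_threshold=thr["trisomy_threshold"],
        monosomy_threshold=thr["monosomy_threshold"],
        sex_het_threshold=thr["sex_het_threshold"],
    )
    emit("cohort_drp.tsv", lambda p: cohort.drp.to_csv(p, sep="\t"))
    emit("screening_report.tsv",
         lambda p: report.to_csv(p, sep="\t", index=False, na_rep="NA"))
    emit("screening_detail.json", lambda p: write_report(detail, p, "json"))
    emit("screen_truth.json", lambda p: write_report(
        {"true_sex": true_sex, "cn_events": cn_truth,
         "true_g_embryos": {
             t: {e: float(cohort.true_g.loc[e, t]) for e in cohort.embryo_ids}
             for t in cohort.h2
         }},
        p, "json"))
    state["screen_report"] = report
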
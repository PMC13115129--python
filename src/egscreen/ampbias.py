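"""Binned-depth analyses: copy-number estimation, bias curves, aneuploidy calls.

The copy number of a bin is estimated as twice the ratio of its mean read
depth to the genome-wide median bin depth (median over autosomal bins when a
sex chromosome is present, so a male X does not bias the normalizer). A
chromosome is called trisomic when its summary CN exceeds 2.6 and monosomic
when it falls below 1.4, both strictly; ties are euploid. The chromosome
summary is the median of its bin CNs — robust to segmental noise — with the
fraction of individually abnormal bins reported alongside so segmental
events stay visible.

Coverage uniformity is summarized as the coefficient of variation (CV) of
binned depth — SD (n-1 denominator) divided by the mean — across a ladder of
window sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_depth_track

TRISOMY_THRESHOLD = 2.6
MONOSOMY_THRESHOLD = 1.4

DEFAULT_WINDOW_SIZES = (1_000, 10_000, 100_000, 1_000_000, 10_000_000, 100_000_000)

_SEX_CHROMS = {"X", "Y", "W", "Z", "M", "MT"}


def is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() not in _SEX_CHROMS


@dataclass
class ChromosomeCall:
    chrom: str
    n_bins: int
    summary_cn: float
    call: str  # euploid | trisomy | monosomy
    fraction_bins_abnormal: float


@dataclass
class CopyNumberProfile:
    """Per-bin CN estimates plus per-chromosome aneuploidy calls."""

    bins: pd.DataFrame  # chrom, start, end, depth, cn [, bin_call]
    genome_median_depth: float
    per_chromosome: list[ChromosomeCall] = field(default_factory=list)

    def calls(self) -> dict[str, str]:
        return {c.chrom: c.call for c in self.per_chromosome}


def rebin_depth(bins: pd.DataFrame, target_size: int) -> pd.DataFrame:
    """Aggregate a uniform-bin track into larger windows.

    ``target_size`` must be an integer multiple of the source bin size.
    Window depth is the unweighted mean of the covered source bins; a
    trailing partial window keeps whatever bins it covers.
    """
    bins = validate_depth_track(bins)
    widths = (bins["end"] - bins["start"]).to_numpy()
    source_size = int(widths.max())  # trailing bins may be shorter
    if target_size % source_size != 0:
        raise ValueError(
            f"target size {target_size} is not a multiple of the "
            f"source bin size {source_size}"
        )
    if target_size == source_size:
        return bins
    win = bins["start"].to_numpy() // target_size
    grouped = (
        bins.assign(_win=win)
        .groupby(["chrom", "_win"], sort=False, observed=True)
        .agg(depth=("depth", "mean"), end=("end", "max"))
        .reset_index()
    )
    grouped["start"] = grouped["_win"] * target_size
    return validate_depth_track(grouped[["chrom", "start", "end", "depth"]])


def estimate_copy_number(bins: pd.DataFrame) -> CopyNumberProfile:
    """Per-bin CN = 2 x depth / median bin depth.

    The median is taken over autosomal bins when any autosome is present;
    on an all-sex-chromosome track it falls back to all bins.
    """
    bins = validate_depth_track(bins)
    autosomal = bins["chrom"].map(is_autosome).to_numpy()
    norm_depths = bins.loc[autosomal, "depth"] if autosomal.any() else bins["depth"]
    median = float(np.median(norm_depths))
    if median <= 0:
        raise ValueError("genome median depth is zero; copy number undefined")
    out = bins.copy()
    out["cn"] = 2.0 * out["depth"] / median
    return CopyNumberProfile(bins=out, genome_median_depth=median)


def call_aneuploidy(
    profile: CopyNumberProfile,
    trisomy_threshold: float = TRISOMY_THRESHOLD,
    monosomy_threshold: float = MONOSOMY_THRESHOLD,
) -> CopyNumberProfile:
    """Per-chromosome aneuploidy calls from the bin-level CN profile.

    The chromosome summary CN is the median of its bin CNs; trisomy iff
    summary > ``trisomy_threshold`` strictly, monosomy iff summary <
    ``monosomy_threshold`` strictly, otherwise euploid. Per-bin calls with
    the same thresholds are added as a ``bin_call`` column for the segmental
    view.
    """

    def classify(cn: float) -> str:
        if cn > trisomy_threshold:
            return "trisomy"
        if cn < monosomy_threshold:
            return "monosomy"
        return "euploid"

    bins = profile.bins.copy()
    bins["bin_call"] = [classify(c) for c in bins["cn"]]
    calls = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        summary = float(np.median(sub["cn"]))
        calls.append(
            ChromosomeCall(
                chrom=str(chrom),
                n_bins=len(sub),
                summary_cn=summary,
                call=classify(summary),
                fraction_bins_abnormal=float((sub["bin_call"] != "euploid").mean()),
            )
        )
    return CopyNumberProfile(
        bins=bins,
        genome_median_depth=profile.genome_median_depth,
        per_chromosome=calls,
    )


@dataclass
class BiasCurve:
    """Coefficient of variation of binned depth per window size."""

    window_sizes: list[int]
    cv_per_window: dict[int, float]


def depth_cv(
    bins: pd.DataFrame, window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
) -> BiasCurve:
    """CV of window depth (SD/mean, n-1 denominator) across window sizes.

    Each requested size must be a multiple of the source bin size and must
    yield at least two windows.
    """
    bins = validate_depth_track(bins)
    curve: dict[int, float] = {}
    for size in sorted(window_sizes):
        windows = rebin_depth(bins, int(size))
        if len(windows) < 2:
            raise ValueError(f"fewer than 2 windows at size {size}")
        depths = windows["depth"].to_numpy(dtype=float)
        mean = depths.mean()
        if mean == 0:
            raise ValueError(f"mean depth is zero at window size {size}")
        curve[int(size)] = float(depths.std(ddof=1) / mean)
    return BiasCurve(window_sizes=sorted(int(s) for s in window_sizes),
                     cv_per_window=curve)
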
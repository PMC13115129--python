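"""Synthetic inputs for the screening pipeline.

Emulates the data-generating processes the analysis assumes: Hardy-Weinberg
genotypes at specified allele frequencies, whole-genome-amplification (WGA)
corruption (allele dropout, heterozygosity gain, homozygosity reversal,
missingness), platform panels, overdispersed binned read depth with copy-
number events and a smooth coverage bias, a breeding cohort with polygenic
trait architecture for GBLUP, and X-chromosome genotypes with male
hemizygosity and a pseudoautosomal region (PAR).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, LocusMeta


@dataclass(frozen=True)
class WGAErrorRates:
    """Per-locus WGA genotyping-error probabilities.

    ado: a true heterozygote is emitted as a random homozygote (50/50
        hom_ref / hom_alt — allele dropout is symmetric in which allele drops).
    het_gain: a true homozygote is emitted as a heterozygote.
    hom_reversal: a true homozygote is emitted as the opposite homozygote.
    missing: any locus is emitted as missing (applied independently, before
        error substitution).
    """

    ado: float = 0.0
    het_gain: float = 0.0
    hom_reversal: float = 0.0
    missing: float = 0.0

    def __post_init__(self):
        for name in ("ado", "het_gain", "hom_reversal", "missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.het_gain + self.hom_reversal > 1.0:
            raise ValueError("het_gain + hom_reversal must be <= 1")


@dataclass(frozen=True)
class CNEvent:
    """A whole-chromosome or segmental copy-number event (ground truth)."""

    chrom: str
    copy_number: int
    start: int | None = None  # 0-based inclusive; None with whole_chromosome
    end: int | None = None  # exclusive
    whole_chromosome: bool = False

    def __post_init__(self):
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError("copy_number must be a non-negative integer != 2")
        if not self.whole_chromosome and (self.start is None or self.end is None):
            raise ValueError("segmental event needs start and end")
        if not self.whole_chromosome and self.start >= self.end:
            raise ValueError("event start must be < end")


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic generator."""

    n_samples: int = 3
    n_loci: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_rates: WGAErrorRates = field(default_factory=WGAErrorRates)
    depth_mean: float = 10.0
    depth_dispersion: float = 1.5  # variance/mean of per-bin depth
    bin_size: int = 1_000_000
    cn_events: list[CNEvent] = field(default_factory=list)
    genome_def: dict[str, int] = field(
        default_factory=lambda: {str(c): 100_000_000 for c in range(1, 6)}
    )
    seed: int = 0

    def __post_init__(self):
        _check_maf_range(self.maf_range)
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion < 1:
            raise ValueError("depth_dispersion must be >= 1")


@dataclass
class BreedingCohort:
    """Reference animals (genotyped + phenotyped) and embryos (genotyped only).

    ``true_g`` holds the simulated additive genetic value of every individual
    per trait; ``drp`` holds the de-regressed-proof-like phenotype (true_g
    plus environmental noise) for reference individuals only.
    """

    genotypes: GenotypeMatrix
    reference_ids: list[str]
    embryo_ids: list[str]
    true_g: pd.DataFrame  # individuals x traits
    drp: pd.DataFrame  # reference individuals x traits
    h2: dict[str, float]


def _check_maf_range(maf_range) -> None:
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")


def _make_loci(n_loci: int, chrom: str = "1", prefix: str = "snp") -> list[LocusMeta]:
    return [
        LocusMeta(chrom=chrom, pos=1000 * (j + 1), id=f"{prefix}{j}")
        for j in range(n_loci)
    ]


def _hwe_draw(rng: np.random.Generator, p: np.ndarray, n_samples: int) -> np.ndarray:
    """Draw genotypes under HWE: two independent Bernoulli(p) alleles."""
    a1 = rng.random((n_samples, p.size)) < p
    a2 = rng.random((n_samples, p.size)) < p
    return (a1.astype(np.int8) + a2.astype(np.int8))


def simulate_reference_genotypes(
    n_samples: int,
    n_loci: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """HWE genotypes at per-locus allele frequencies uniform on ``maf_range``.

    Returns the (fully called) matrix and the per-locus alt-allele frequency.
    """
    _check_maf_range(maf_range)
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_range[0], maf_range[1], size=n_loci)
    calls = _hwe_draw(rng, p, n_samples)
    gm = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        loci=_make_loci(n_loci, chrom=chrom),
        calls=calls,
    )
    return gm, p


def corrupt_with_wga_errors(
    truth: GenotypeMatrix, rates: WGAErrorRates, seed: int = 0
) -> GenotypeMatrix:
    """Apply the WGA error model independently at every call.

    Per locus: with probability ``missing`` the call is dropped; otherwise a
    true het becomes a random hom with probability ``ado`` and a true hom
    becomes het with probability ``het_gain`` or flips to the opposite hom
    with probability ``hom_reversal``. Missing truth stays missing; no error
    channel ever converts missing to called.
    """
    rng = np.random.default_rng(seed)
    calls = truth.calls.copy()
    called = calls != MISSING
    u = rng.random(calls.shape)
    drop = called & (u < rates.missing)

    het = called & (calls == HET)
    do_ado = het & (rng.random(calls.shape) < rates.ado)
    ado_target = np.where(rng.random(calls.shape) < 0.5, HOM_REF, HOM_ALT)

    hom = called & ((calls == HOM_REF) | (calls == HOM_ALT))
    v = rng.random(calls.shape)
    do_gain = hom & (v < rates.het_gain)
    do_rev = hom & (v >= rates.het_gain) & (v < rates.het_gain + rates.hom_reversal)

    out = calls.copy()
    out[do_ado] = ado_target[do_ado].astype(np.int8)
    out[do_gain] = HET
    out[do_rev] = (2 - calls[do_rev]).astype(np.int8)
    out[drop] = MISSING
    return GenotypeMatrix(
        samples=list(truth.samples), loci=list(truth.loci), calls=out
    )


def apply_platform(
    truth: GenotypeMatrix,
    panel: Sequence[str],
    platform_missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Restrict to a platform panel, then add independent platform missingness."""
    if not 0.0 <= platform_missing_rate <= 1.0:
        raise ValueError("platform_missing_rate must be in [0,1]")
    gm = truth.subset_loci(list(panel))
    rng = np.random.default_rng(seed)
    drop = rng.random(gm.calls.shape) < platform_missing_rate
    calls = gm.calls.copy()
    calls[drop] = MISSING
    return GenotypeMatrix(samples=gm.samples, loci=gm.loci, calls=calls)


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------


def _bin_copy_numbers(
    chrom: str, starts: np.ndarray, ends: np.ndarray, cn_events: Sequence[CNEvent],
    chrom_len: int,
) -> np.ndarray:
    cn = np.full(starts.size, 2, dtype=float)
    for ev in cn_events:
        if ev.chrom != chrom:
            continue
        if ev.whole_chromosome:
            cn[:] = ev.copy_number
        else:
            if ev.start < 0 or ev.end > chrom_len:
                raise ValueError(
                    f"CN event {ev.chrom}:{ev.start}-{ev.end} outside chromosome"
                )
            hit = (starts < ev.end) & (ends > ev.start)
            cn[hit] = ev.copy_number
    return cn


def simulate_depth_track(
    genome_def: dict[str, int],
    bin_size: int = 1_000_000,
    depth_mean: float = 10.0,
    depth_dispersion: float = 1.0,
    cn_events: Sequence[CNEvent] = (),
    gc_bias_amplitude: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Overdispersed binned depth with CN events and a smooth coverage bias.

    Per-bin depth follows a gamma-Poisson mixture with mean
    ``depth_mean * (CN/2) * bias`` and variance/mean = ``depth_dispersion``
    (dispersion 1 is pure Poisson). The bias factor is a unit-mean sinusoid
    along each chromosome (random phase) scaled by ``gc_bias_amplitude`` — a
    stand-in for smooth GC/mappability waves, not tied to real sequence.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if depth_dispersion < 1:
        raise ValueError("depth_dispersion must be >= 1")
    known = set(genome_def)
    for ev in cn_events:
        if ev.chrom not in known:
            raise ValueError(f"CN event on unknown chromosome {ev.chrom!r}")
    rng = np.random.default_rng(seed)
    period = 20_000_000.0  # bias wavelength (bp)
    frames = []
    for chrom, length in genome_def.items():
        n_bins = int(np.ceil(length / bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        cn = _bin_copy_numbers(chrom, starts, ends, cn_events, length)
        mid = (starts + ends) / 2.0
        phase = rng.uniform(0, 2 * np.pi)
        bias = 1.0 + gc_bias_amplitude * np.sin(2 * np.pi * mid / period + phase)
        mu = depth_mean * (cn / 2.0) * np.clip(bias, 0.0, None)
        if depth_dispersion == 1.0:
            depth = rng.poisson(mu).astype(float)
        else:
            shape = mu / (depth_dispersion - 1.0)
            lam = rng.gamma(shape, depth_dispersion - 1.0)
            depth = rng.poisson(lam).astype(float)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": depth}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# breeding cohort
# ---------------------------------------------------------------------------


def _mendelian_offspring(
    rng: np.random.Generator, sires: np.ndarray, dams: np.ndarray
) -> np.ndarray:
    """Per-locus Mendelian sampling from parental dosage codes (no linkage)."""
    def gamete(parent: np.ndarray) -> np.ndarray:
        # hom parents transmit their allele; het transmits a coin flip
        g = (parent == HOM_ALT).astype(np.int8)
        het = parent == HET
        g[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
        return g

    return gamete(sires) + gamete(dams)


def simulate_breeding_cohort(
    n_ref: int,
    n_embryo: int,
    n_loci: int,
    h2: float | dict[str, float] = 0.3,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    family_size: int = 25,
    embryos_per_mating: int = 5,
) -> BreedingCohort:
    """A genotyped reference population plus embryos bred from it.

    The cohort mirrors a dairy genomic-selection design: the reference
    population consists of paternal half-sib families (about ``family_size``
    offspring per sire, dams unrelated), and embryos arrive in full-sib
    groups of ``embryos_per_mating`` from matings of reference dams to the
    sire pool — embryos in such a program are progeny of the evaluated
    population, not unrelated strangers. Offspring genotypes are per-locus
    Mendelian samples from the parents (loci independent; no linkage).

    Trait architecture is polygenic: per-locus effects are iid normal,
    scaled so var(true_g) = h2 when the phenotype is true_g plus
    N(0, 1 - h2) noise; the reference phenotype (a stand-in for a
    de-regressed proof) is emitted on that unit-variance scale.
    """
    if n_ref < 2:
        raise ValueError("need at least 2 reference individuals")
    h2_map = {"trait": float(h2)} if not isinstance(h2, dict) else dict(h2)
    for t, v in h2_map.items():
        if not 0.0 < v < 1.0:
            raise ValueError(f"h2 for {t} must be in (0,1), got {v}")
    _check_maf_range(maf_range)
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_range[0], maf_range[1], size=n_loci)
    n_sires = max(2, round(n_ref / family_size))
    sire_calls = _hwe_draw(rng, p, n_sires)
    ref_sire = rng.integers(0, n_sires, size=n_ref)
    ref_dams = _hwe_draw(rng, p, n_ref)  # unrelated, ungenotyped dams
    ref_calls = _mendelian_offspring(rng, sire_calls[ref_sire], ref_dams)
    if n_embryo > 0:
        n_matings = max(1, int(np.ceil(n_embryo / embryos_per_mating)))
        mating_sire = rng.integers(0, n_sires, size=n_matings)
        mating_dam = rng.integers(0, n_ref, size=n_matings)
        mating_of = np.arange(n_embryo) % n_matings
        emb_calls = _mendelian_offspring(
            rng,
            sire_calls[mating_sire[mating_of]],
            ref_calls[mating_dam[mating_of]],
        )
        calls = np.vstack([ref_calls, emb_calls])
    else:
        calls = ref_calls
    ref_ids = [f"ref{i}" for i in range(n_ref)]
    emb_ids = [f"embryo{i}" for i in range(n_embryo)]
    gm = GenotypeMatrix(
        samples=ref_ids + emb_ids, loci=_make_loci(n_loci), calls=calls
    )

    centered = calls.astype(float) - 2.0 * p
    scale = n_loci * 2.0 * np.mean(p * (1.0 - p))
    true_g = {}
    drp = {}
    for trait, h in h2_map.items():
        beta = rng.normal(0.0, np.sqrt(h / scale), size=n_loci)
        g = centered @ beta
        true_g[trait] = g
        noise = rng.normal(0.0, np.sqrt(1.0 - h), size=n_ref)
        drp[trait] = g[:n_ref] + noise
    return BreedingCohort(
        genotypes=gm,
        reference_ids=ref_ids,
        embryo_ids=emb_ids,
        true_g=pd.DataFrame(true_g, index=ref_ids + emb_ids),
        drp=pd.DataFrame(drp, index=ref_ids),
        h2=h2_map,
    )


# ---------------------------------------------------------------------------
# X chromosome
# ---------------------------------------------------------------------------


def simulate_x_genotypes(
    n_male: int,
    n_female: int,
    n_loci: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    par_fraction: float = 0.0,
    error_rates: WGAErrorRates | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[str]]:
    """X-chromosome genotypes with male hemizygosity and an optional PAR.

    Outside the pseudoautosomal region males carry one X allele, which the
    genotyper emits as a homozygous diploid call (never het before error
    injection); females are diploid HWE. The first ``par_fraction`` of loci
    form a terminal PAR where both sexes are diploid HWE. WGA errors are then
    injected with :func:`corrupt_with_wga_errors`.

    Returns the matrix (males first) and the true sex label per sample.
    """
    if not 0.0 <= par_fraction < 1.0:
        raise ValueError("par_fraction must be in [0,1)")
    _check_maf_range(maf_range)
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_range[0], maf_range[1], size=n_loci)
    n_par = int(round(par_fraction * n_loci))
    n = n_male + n_female
    calls = np.empty((n, n_loci), dtype=np.int8)
    calls[n_male:] = _hwe_draw(rng, p, n_female)
    # males: hemizygous X allele emitted as hom; PAR loci diploid HWE
    allele = (rng.random((n_male, n_loci)) < p).astype(np.int8)
    calls[:n_male] = 2 * allele
    if n_par:
        calls[:n_male, :n_par] = _hwe_draw(rng, p[:n_par], n_male)
    sexes = ["male"] * n_male + ["female"] * n_female
    gm = GenotypeMatrix(
        samples=[f"m{i}" for i in range(n_male)] + [f"f{i}" for i in range(n_female)],
        loci=_make_loci(n_loci, chrom="X", prefix="xsnp"),
        calls=calls,
    )
    if error_rates is not None:
        gm = corrupt_with_wga_errors(gm, error_rates, seed=seed + 1)
    return gm, sexes
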
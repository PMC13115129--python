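"""Genotyping-quality metrics for amplified samples versus matched references.

Compares each whole-genome-amplified (WGA) sample against its bulk gDNA
reference over a shared locus set and reports:

* original call rate — called loci / all panel loci;
* relative call rate — loci called in the amplified sample among loci called
  in the reference;
* genotyping concordance — identical calls among loci called in both;
* allele dropout (ADO) — reference het emitted as either hom;
* heterozygosity gain — reference hom emitted as het;
* homozygosity reversal — reference hom emitted as the opposite hom.

All error rates and concordance are computed over *comparable* loci, i.e.
loci called in both samples: a genotype "appearing as" another requires both
calls to exist, and missingness is already captured by the call-rate
metrics. A rate whose denominator is zero is reported as None, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import HET, MISSING, GenotypeMatrix


class UndefinedDenominatorError(ZeroDivisionError):
    """A rate's denominator is zero (e.g. reference sample all-missing)."""


@dataclass
class ErrorProfile:
    """Per-sample call-rate, concordance and WGA error-rate summary."""

    sample_id: str
    ref_id: str
    n_total_loci: int
    n_ref_called: int
    n_amp_called: int
    n_comparable: int
    n_ref_het_comparable: int  # denominator of ado_rate
    n_ref_hom_comparable: int  # denominator of het_gain / hom_reversal
    original_call_rate: float
    relative_call_rate: float | None
    concordance: float | None
    ado_rate: float | None
    het_gain_rate: float | None
    hom_reversal_rate: float | None


def _check_rows(amp: np.ndarray, ref: np.ndarray) -> None:
    if amp.shape != ref.shape:
        raise ValueError(f"locus sets differ: {amp.shape} vs {ref.shape}")


def original_call_rate(row: np.ndarray) -> float:
    """Fraction of all panel loci with a call."""
    row = np.asarray(row)
    if row.size == 0:
        raise UndefinedDenominatorError("empty locus set")
    return float(np.count_nonzero(row != MISSING) / row.size)


def relative_call_rate(amp: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of reference-called loci also called in the amplified sample."""
    amp, ref = np.asarray(amp), np.asarray(ref)
    _check_rows(amp, ref)
    ref_called = ref != MISSING
    n_ref = int(ref_called.sum())
    if n_ref == 0:
        raise UndefinedDenominatorError("reference sample has no called loci")
    return float(np.count_nonzero(ref_called & (amp != MISSING)) / n_ref)


def genotyping_concordance(amp: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of comparable loci (called in both) with identical genotype."""
    amp, ref = np.asarray(amp), np.asarray(ref)
    _check_rows(amp, ref)
    comparable = (amp != MISSING) & (ref != MISSING)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDenominatorError("no comparable loci")
    return float(np.count_nonzero(comparable & (amp == ref)) / n)


def error_rates(
    amp: np.ndarray, ref: np.ndarray
) -> tuple[float | None, float | None, float | None]:
    """(ado, het_gain, hom_reversal) rates over comparable loci.

    ado is computed over comparable reference-het loci; het_gain and
    hom_reversal over comparable reference-hom loci. A rate with a zero
    denominator is returned as None.
    """
    amp, ref = np.asarray(amp), np.asarray(ref)
    _check_rows(amp, ref)
    comparable = (amp != MISSING) & (ref != MISSING)
    ref_het = comparable & (ref == HET)
    ref_hom = comparable & (ref != HET)
    n_het = int(ref_het.sum())
    n_hom = int(ref_hom.sum())
    ado = float(np.count_nonzero(ref_het & (amp != HET)) / n_het) if n_het else None
    if n_hom:
        het_gain = float(np.count_nonzero(ref_hom & (amp == HET)) / n_hom)
        hom_rev = float(
            np.count_nonzero(ref_hom & (amp != HET) & (amp != ref)) / n_hom
        )
    else:
        het_gain = hom_rev = None
    return ado, het_gain, hom_rev


def profile_pair(
    amp: np.ndarray, ref: np.ndarray, sample_id: str = "amp", ref_id: str = "ref"
) -> ErrorProfile:
    """Full metric profile for one amplified/reference sample pair."""
    amp, ref = np.asarray(amp), np.asarray(ref)
    _check_rows(amp, ref)
    amp_called = amp != MISSING
    ref_called = ref != MISSING
    comparable = amp_called & ref_called
    n_comp = int(comparable.sum())
    ado, het_gain, hom_rev = error_rates(amp, ref)
    try:
        rel = relative_call_rate(amp, ref)
    except UndefinedDenominatorError:
        rel = None
    return ErrorProfile(
        sample_id=sample_id,
        ref_id=ref_id,
        n_total_loci=int(amp.size),
        n_ref_called=int(ref_called.sum()),
        n_amp_called=int(amp_called.sum()),
        n_comparable=n_comp,
        n_ref_het_comparable=int((comparable & (ref == HET)).sum()),
        n_ref_hom_comparable=int((comparable & (ref != HET)).sum()),
        original_call_rate=original_call_rate(amp),
        relative_call_rate=rel,
        concordance=(
            float(np.count_nonzero(comparable & (amp == ref)) / n_comp)
            if n_comp else None
        ),
        ado_rate=ado,
        het_gain_rate=het_gain,
        hom_reversal_rate=hom_rev,
    )


def profile_samples(
    amp: GenotypeMatrix, ref: GenotypeMatrix, pairing: Mapping[str, str]
) -> list[ErrorProfile]:
    """One :class:`ErrorProfile` per amplified sample.

    ``pairing`` maps each amplified sample id to its reference sample id; the
    two matrices must share the locus set (matched by locus ids).
    """
    if amp.locus_ids != ref.locus_ids:
        ref = ref.subset_loci(amp.locus_ids)
    profiles = []
    for amp_id in amp.samples:
        if amp_id not in pairing:
            raise KeyError(f"amplified sample {amp_id!r} has no reference pairing")
        ref_id = pairing[amp_id]
        if ref_id not in ref.samples:
            raise KeyError(f"reference sample {ref_id!r} not found")
        profiles.append(
            profile_pair(amp.row(amp_id), ref.row(ref_id), amp_id, ref_id)
        )
    return profiles


def summarize_profiles(profiles: list[ErrorProfile]) -> pd.DataFrame:
    """Group mean and SD (over replicate samples) of every metric."""
    df = pd.DataFrame([p.__dict__ for p in profiles])
    metrics = [
        "original_call_rate", "relative_call_rate", "concordance",
        "ado_rate", "het_gain_rate", "hom_reversal_rate",
    ]
    return df[metrics].agg(["mean", "std"])
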
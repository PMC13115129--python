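"""Embryo screening: SNP QC, genomic relationship matrix, GBLUP, X-het sexing.

Genomic values follow the standard animal model

    y = 1 mu + Z g + e,      g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

where y holds de-regressed-proof (DRP) phenotypes of the reference animals
and G is the VanRaden genomic relationship matrix built from centered marker
dosages, G = Z Z' / (2 sum p_i (1 - p_i)) with genotype codes 0, 1, 2 centered
by 2 p_i. Embryos carry no phenotype and receive predictions through their
genomic covariances with the reference set; the solution is the BLUP

    g_hat = G W' (W G W' + lambda I)^(-1) (y - 1 mu_hat),   lambda = sigma_e^2/sigma_g^2

with mu_hat the GLS mean, algebraically identical to the joint mixed-model
equations but with no inverse of G. Sex is determined from the heterozygosity
rate over a filtered X-chromosome SNP panel: male iff het rate <= 0.02.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import HET, MISSING, GenotypeMatrix

DEFAULT_CALLRATE_MIN = 0.9
DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_P_MIN = 1e-5
X_PANEL_MAF_MIN = 0.015
X_PANEL_MALE_HET_MAX = 0.01
MALE_HET_THRESHOLD = 0.02


# ---------------------------------------------------------------------------
# locus statistics and QC
# ---------------------------------------------------------------------------


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, alt-allele frequency, MAF and HWE chi-square p.

    The HWE test is the 1-df chi-square goodness of fit of observed genotype
    counts against p^2 / 2pq / q^2 expectations among called genotypes.
    """
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n0 = ((calls == 0) & called).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (2 * n2 + n1) / (2 * n_called)
        maf = np.minimum(p_alt, 1 - p_alt)
        q = 1 - p_alt
        e0 = n_called * q**2
        e1 = n_called * 2 * p_alt * q
        e2 = n_called * p_alt**2
        chi2 = np.zeros(gm.n_loci)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
            chi2 += term
    hwe_p = stats.chi2.sf(chi2, df=1)
    # monomorphic loci fit HWE trivially
    hwe_p = np.where((p_alt == 0) | (p_alt == 1), 1.0, hwe_p)
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "call_rate": n_called / max(gm.n_samples, 1),
            "p_alt": p_alt,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )


@dataclass
class QCReport:
    n_input_loci: int
    n_fail_callrate: int
    n_fail_maf: int
    n_fail_hwe: int
    n_retained: int
    fail_callrate: list[str] = field(default_factory=list)
    fail_maf: list[str] = field(default_factory=list)
    fail_hwe: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def qc_filter(
    gm: GenotypeMatrix,
    callrate_min: float = DEFAULT_CALLRATE_MIN,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    apply_hwe: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain loci with call rate >= ``callrate_min``, MAF > ``maf_min`` and,
    when ``apply_hwe`` is set, HWE p > ``hwe_p_min``.

    Filters are evaluated jointly on the input, so the retained set does not
    depend on any filter ordering. An empty retained set is allowed and
    reported, not an error.
    """
    if gm.n_samples < 1:
        raise ValueError("QC needs at least one sample")
    st = locus_stats(gm)
    ok_cr = st["call_rate"].to_numpy() >= callrate_min
    with np.errstate(invalid="ignore"):
        maf = st["maf"].to_numpy()
    ok_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    ok_hwe = (st["hwe_p"].to_numpy() > hwe_p_min) if apply_hwe else np.ones(
        gm.n_loci, dtype=bool
    )
    keep = ok_cr & ok_maf & ok_hwe
    ids = np.asarray(gm.locus_ids)
    report = QCReport(
        n_input_loci=gm.n_loci,
        n_fail_callrate=int((~ok_cr).sum()),
        n_fail_maf=int((~ok_maf).sum()),
        n_fail_hwe=int((~ok_hwe).sum()),
        n_retained=int(keep.sum()),
        fail_callrate=list(ids[~ok_cr]),
        fail_maf=list(ids[~ok_maf]),
        fail_hwe=list(ids[~ok_hwe]),
        retained=list(ids[keep]),
    )
    return gm.subset_loci(report.retained), report


def impute_naive(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-dosage imputation: a float dosage matrix with no missing values.

    Missing calls are replaced by the per-locus mean dosage of the called
    genotypes — a deliberately simple fill used only for building G, not a
    haplotype-based imputation, and not claimed to be equivalent to one.
    """
    d = gm.dosages()
    col_mean = np.nanmean(d, axis=0)
    if np.isnan(col_mean).any():
        j = int(np.flatnonzero(np.isnan(col_mean))[0])
        raise ValueError(f"locus {gm.loci[j].id!r} has no called genotypes")
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


# ---------------------------------------------------------------------------
# G matrix and GBLUP
# ---------------------------------------------------------------------------


def compute_g_matrix(
    dosages: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden genomic relationship matrix from dosages in [0, 2].

    Columns are centered by twice the allele frequency (estimated from the
    supplied individuals unless ``freqs`` is given) and G = ZZ' scaled by
    2 * sum p_i (1 - p_i). Fixed loci (p = 0 or 1) carry no information and
    are dropped with a warning.

    Returns (G, p) with p the frequencies actually used.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 individuals")
    p = dosages.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    if p.shape != (dosages.shape[1],):
        raise ValueError("freqs length does not match the number of loci")
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} fixed loci from G", stacklevel=2
        )
        dosages, p = dosages[:, poly], p[poly]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all loci fixed: G denominator is zero")
    z = dosages - 2.0 * p
    return (z @ z.T) / denom, p


@dataclass
class GBLUPFit:
    """Solved animal model: overall mean, variance ratio and genomic values."""

    mu: float
    lambda_: float
    g_hat: pd.Series  # DGV per individual (reference + embryos)
    ids: list[str]
    reference_ids: list[str]
    h2: float | None = None


def fit_gblup(
    G: np.ndarray,
    y: Sequence[float] | pd.Series,
    ids: Sequence[str],
    reference_ids: Sequence[str] | None = None,
    lambda_: float | None = None,
    h2: float | None = None,
) -> GBLUPFit:
    """Solve the animal model for genomic values of all individuals in G.

    ``ids`` names the rows of G; ``y`` holds the phenotype (DRP) of the
    reference individuals, given either as a pandas Series indexed by id or
    as an array aligned with ``reference_ids``. Individuals without a
    phenotype (embryos) are predicted through their G-covariances with the
    reference set. Exactly one of ``lambda_`` and ``h2`` must be supplied;
    lambda = (1 - h2) / h2.
    """
    if (lambda_ is None) == (h2 is None):
        raise ValueError("supply exactly one of lambda_ or h2")
    if lambda_ is None:
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0,1)")
        lambda_ = (1.0 - h2) / h2
    if lambda_ <= 0:
        raise ValueError("lambda must be > 0")
    ids = list(ids)
    G = np.asarray(G, dtype=float)
    if G.shape != (len(ids), len(ids)):
        raise ValueError("G shape does not match ids")
    if isinstance(y, pd.Series):
        reference_ids = list(y.index)
        y_vec = y.to_numpy(dtype=float)
    else:
        if reference_ids is None:
            raise ValueError("reference_ids required when y is not a Series")
        reference_ids = list(reference_ids)
        y_vec = np.asarray(y, dtype=float)
    pos = {s: i for i, s in enumerate(ids)}
    try:
        ref_idx = np.array([pos[s] for s in reference_ids])
    except KeyError as exc:
        raise KeyError(f"phenotyped individual {exc} not present in G") from exc

    G_rr = G[np.ix_(ref_idx, ref_idx)]
    C = G_rr + lambda_ * np.eye(len(ref_idx))
    try:
        Cinv_y = np.linalg.solve(C, y_vec)
        Cinv_1 = np.linalg.solve(C, np.ones_like(y_vec))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model system: check for duplicated individuals "
            "or a vanishing variance ratio"
        ) from exc
    mu = float(np.ones_like(y_vec) @ Cinv_y / (np.ones_like(y_vec) @ Cinv_1))
    alpha = np.linalg.solve(C, y_vec - mu)
    g_hat = G[:, ref_idx] @ alpha
    return GBLUPFit(
        mu=mu,
        lambda_=float(lambda_),
        g_hat=pd.Series(g_hat, index=ids, name="dgv"),
        ids=ids,
        reference_ids=reference_ids,
        h2=1.0 / (1.0 + lambda_),
    )


def estimate_variance_ratio(
    G: np.ndarray,
    y: Sequence[float],
    jitter: float = 1e-8,
) -> tuple[float, float]:
    """REML estimate of lambda = sigma_e^2 / sigma_g^2 (and h2) from G and y.

    Uses the eigendecomposition of the phenotyped submatrix of G to profile
    the restricted likelihood over h2 in (0, 1) as a 1-D bounded
    optimization. Returns (lambda, h2).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("REML needs at least 10 phenotyped individuals")
    G = np.asarray(G, dtype=float)
    if G.shape != (n, n):
        raise ValueError("G must cover exactly the phenotyped individuals")
    d, U = np.linalg.eigh(G + jitter * np.eye(n))
    if d.min() < -1e-6:
        raise ValueError("G submatrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    ystar = U.T @ y
    xstar = U.T @ np.ones(n)

    def neg_reml(h2: float) -> float:
        w = h2 * d + (1.0 - h2)
        xwx = np.sum(xstar**2 / w)
        mu = np.sum(xstar * ystar / w) / xwx
        r = ystar - mu * xstar
        rss = np.sum(r**2 / w)
        sigma2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(sigma2) + np.sum(np.log(w)) + np.log(xwx))

    res = optimize.minimize_scalar(
        neg_reml, bounds=(1e-4, 1 - 1e-4), method="bounded",
        options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    return (1.0 - h2) / h2, h2


# ---------------------------------------------------------------------------
# sex determination
# ---------------------------------------------------------------------------


@dataclass
class SexCall:
    embryo_id: str
    n_panel_loci: int
    n_called: int
    het_rate: float | None
    call: str  # male | female | no_call


def build_sex_panel(
    x_geno: GenotypeMatrix,
    known_males: Sequence[str],
    callrate_min: float = DEFAULT_CALLRATE_MIN,
    maf_min: float = X_PANEL_MAF_MIN,
    male_het_max: float = X_PANEL_MALE_HET_MAX,
) -> list[str]:
    """Select X loci usable for heterozygosity-based sexing.

    Keeps loci with call rate >= ``callrate_min``, MAF > ``maf_min`` and a
    heterozygous fraction among the known-male samples <= ``male_het_max``;
    the male-het filter removes pseudoautosomal-region loci, which are
    legitimately heterozygous in males.
    """
    if not known_males:
        raise ValueError("PAR filtering requires at least one known-male sample")
    st = locus_stats(x_geno)
    males = x_geno.subset_samples(list(known_males))
    called = males.calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (males.calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        male_het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    keep = (
        (st["call_rate"].to_numpy() >= callrate_min)
        & (np.nan_to_num(st["maf"].to_numpy(), nan=0.0) > maf_min)
        & (male_het <= male_het_max)
    )
    panel = [lid for lid, k in zip(x_geno.locus_ids, keep) if k]
    if not panel:
        raise ValueError(
            "sex panel is empty after filtering; consider relaxing the "
            "call-rate/MAF/male-het thresholds"
        )
    return panel


def determine_sex(
    row: np.ndarray,
    embryo_id: str = "embryo",
    het_threshold: float = MALE_HET_THRESHOLD,
    min_called: int = 50,
) -> SexCall:
    """Classify one embryo from its X-panel heterozygosity rate.

    Male iff the heterozygous fraction over called panel loci is <= the
    threshold (inclusive), female otherwise; no_call when fewer than
    ``min_called`` panel loci are called.
    """
    row = np.asarray(row)
    called = row != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"{embryo_id}: no called panel loci")
    het_rate = float(np.count_nonzero(row == HET) / n_called)
    if n_called < min_called:
        call = "no_call"
    else:
        call = "male" if het_rate <= het_threshold else "female"
    return SexCall(
        embryo_id=embryo_id,
        n_panel_loci=int(row.size),
        n_called=n_called,
        het_rate=het_rate,
        call=call,
    )


def stack_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two sample sets over their shared loci (matched by locus id)."""
    shared = [lid for lid in a.locus_ids if lid in set(b.locus_ids)]
    if not shared:
        raise ValueError("no shared loci between the two genotype sets")
    a2, b2 = a.subset_loci(shared), b.subset_loci(shared)
    return GenotypeMatrix(
        samples=a2.samples + b2.samples,
        loci=a2.loci,
        calls=np.vstack([a2.calls, b2.calls]),
    )


def screen_embryos(
    ref_geno: GenotypeMatrix,
    embryo_geno: GenotypeMatrix,
    drp: pd.DataFrame,
    h2: Mapping[str, float] | float = 0.3,
    x_geno: GenotypeMatrix | None = None,
    known_males: Sequence[str] | None = None,
    depth_tracks: Mapping[str, pd.DataFrame] | None = None,
    callrate_min: float = DEFAULT_CALLRATE_MIN,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    trisomy_threshold: float = 2.6,
    monosomy_threshold: float = 1.4,
    sex_het_threshold: float = MALE_HET_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Consolidated per-embryo screening report.

    Runs SNP QC over the combined reference+embryo genotypes, builds G from
    mean-imputed dosages (allele frequencies from the combined set), solves
    GBLUP per trait against the reference DRP, sexes embryos from the
    X-chromosome matrix when provided, and calls per-chromosome aneuploidy
    from each embryo's binned depth track when provided.

    Returns a per-embryo DataFrame plus a JSON-serializable detail dict.
    """
    from . import ampbias  # local import to avoid a cycle at module load

    combined = stack_samples(ref_geno, embryo_geno)
    qc_geno, qc_report = qc_filter(
        combined, callrate_min=callrate_min, maf_min=maf_min,
        hwe_p_min=hwe_p_min, apply_hwe=True,
    )
    if qc_geno.n_loci == 0:
        raise ValueError("no loci survive QC; cannot build G")
    dosages = impute_naive(qc_geno)
    G, _ = compute_g_matrix(dosages)
    h2_map = {"trait": float(h2)} if not isinstance(h2, Mapping) else dict(h2)
    missing_traits = [t for t in h2_map if t not in drp.columns]
    if missing_traits:
        raise KeyError(f"traits {missing_traits} absent from the DRP table")
    embryo_ids = list(embryo_geno.samples)
    dgv: dict[str, pd.Series] = {}
    fits: dict[str, GBLUPFit] = {}
    for trait, h in h2_map.items():
        fit = fit_gblup(G, drp[trait], ids=qc_geno.samples, h2=h)
        fits[trait] = fit
        dgv[trait] = fit.g_hat

    report = pd.DataFrame({"embryo_id": embryo_ids}).set_index(
        "embryo_id", drop=False
    )
    emb_calls = qc_geno.subset_samples(embryo_ids).calls
    report["call_rate"] = (emb_calls != MISSING).mean(axis=1)
    for trait in h2_map:
        report[f"dgv_{trait}"] = dgv[trait].reindex(embryo_ids).to_numpy()

    sex_calls: list[SexCall] = []
    if x_geno is not None:
        sex_calls, _panel = classify_sex(
            x_geno, embryo_ids, known_males=known_males,
            het_threshold=sex_het_threshold,
        )
        by_id = {c.embryo_id: c for c in sex_calls}
        report["sex"] = [by_id[e].call for e in embryo_ids]
        report["x_het_rate"] = [by_id[e].het_rate for e in embryo_ids]
    cn_detail: dict[str, list] = {}
    if depth_tracks is not None:
        calls_col, abn_col = [], []
        for e in embryo_ids:
            if e not in depth_tracks:
                calls_col.append(None)
                abn_col.append(None)
                continue
            profile = ampbias.call_aneuploidy(
                ampbias.estimate_copy_number(depth_tracks[e]),
                trisomy_threshold=trisomy_threshold,
                monosomy_threshold=monosomy_threshold,
            )
            abnormal = [
                f"{c.call[:3]}{c.chrom}" for c in profile.per_chromosome
                if c.call != "euploid"
            ]
            calls_col.append(";".join(abnormal) if abnormal else "euploid")
            abn_col.append(len(abnormal))
            cn_detail[e] = [c.__dict__ for c in profile.per_chromosome]
        report["aneuploidy"] = calls_col
        report["n_abnormal_chromosomes"] = abn_col
    detail = {
        "qc": {
            "n_input_loci": qc_report.n_input_loci,
            "n_retained": qc_report.n_retained,
            "n_fail_callrate": qc_report.n_fail_callrate,
            "n_fail_maf": qc_report.n_fail_maf,
            "n_fail_hwe": qc_report.n_fail_hwe,
        },
        "gblup": {
            t: {"mu": fits[t].mu, "lambda": fits[t].lambda_} for t in h2_map
        },
        "sex_calls": [c.__dict__ for c in sex_calls],
        "copy_number": cn_detail,
    }
    return report.reset_index(drop=True), detail


def classify_sex(
    x_geno: GenotypeMatrix,
    embryo_ids: Sequence[str],
    known_males: Sequence[str] | None = None,
    het_threshold: float = MALE_HET_THRESHOLD,
    min_called: int = 50,
    panel: Sequence[str] | None = None,
    **panel_kwargs,
) -> tuple[list[SexCall], list[str]]:
    """Panel construction plus per-embryo sexing.

    When neither ``panel`` nor ``known_males`` is given, a two-pass bootstrap
    is used: pass 1 classifies every embryo on the unfiltered X loci (no
    PAR filter), and pass 2 rebuilds the panel using the pass-1 males before
    the final classification.
    """
    if panel is None:
        if known_males is None:
            prelim_panel = [
                lid for lid, k in zip(
                    x_geno.locus_ids,
                    (locus_stats(x_geno)["call_rate"] >= DEFAULT_CALLRATE_MIN),
                ) if k
            ]
            sub = x_geno.subset_loci(prelim_panel)
            prelim = [
                determine_sex(sub.row(e), e, het_threshold, min_called)
                for e in embryo_ids
            ]
            known_males = [c.embryo_id for c in prelim if c.call == "male"]
            if not known_males:
                raise ValueError(
                    "two-pass sexing found no provisional males to anchor the "
                    "PAR filter; supply known_males or an explicit panel"
                )
        panel = build_sex_panel(x_geno, known_males, **panel_kwargs)
    sub = x_geno.subset_loci(list(panel))
    calls = [
        determine_sex(sub.row(e), e, het_threshold, min_called) for e in embryo_ids
    ]
    return calls, list(panel)
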
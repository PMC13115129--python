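import numpy as np
import pandas as pd
import pytest
from scipy import stats

from egscreen.io import MISSING, GenotypeMatrix
from egscreen.screening import (
    build_sex_panel,
    classify_sex,
    compute_g_matrix,
    determine_sex,
    estimate_variance_ratio,
    fit_gblup,
    impute_naive,
    locus_stats,
    qc_filter,
    screen_embryos,
    stack_samples,
)
from egscreen.simulate import (
    CNEvent,
    WGAErrorRates,
    corrupt_with_wga_errors,
    simulate_breeding_cohort,
    simulate_depth_track,
    simulate_reference_genotypes,
    simulate_x_genotypes,
)

from conftest import make_matrix

M = -1


# -- QC ---------------------------------------------------------------------------


def brute_force_qc(gm, callrate_min=0.9, maf_min=0.01, hwe_p_min=1e-5,
                   apply_hwe=False):
    """Per-locus re-evaluation of every filter with plain python loops."""
    retained = []
    for j, locus in enumerate(gm.loci):
        col = [int(c) for c in gm.calls[:, j]]
        called = [c for c in col if c != M]
        call_rate = len(called) / len(col)
        if call_rate < callrate_min:
            continue
        if not called:
            continue
        p = sum(called) / (2 * len(called))
        maf = min(p, 1 - p)
        if maf <= maf_min:
            continue
        if apply_hwe:
            n = len(called)
            exp = [n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2]
            obs = [called.count(0), called.count(1), called.count(2)]
            chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp) if e > 0)
            if p in (0, 1):
                pval = 1.0
            else:
                pval = float(stats.chi2.sf(chi2, 1))
            if pval <= hwe_p_min:
                continue
        retained.append(locus.id)
    return retained


def test_low_call_rate_locus_excluded():
    calls = np.ones((10, 1), dtype=np.int8)
    calls[5:, 0] = 0  # keep it polymorphic
    calls[:2, 0] = M  # call rate 0.8 < 0.9
    gm = make_matrix(calls)
    _, report = qc_filter(gm)
    assert report.retained == []
    assert report.n_fail_callrate == 1


def test_monomorphic_locus_excluded():
    gm = make_matrix(np.zeros((10, 1), dtype=np.int8))
    _, report = qc_filter(gm)
    assert report.n_fail_maf == 1 and report.n_retained == 0


def test_qc_matches_brute_force_with_planted_violations(rng):
    truth, _ = simulate_reference_genotypes(20, 500, maf_range=(0.05, 0.5),
                                            seed=50)
    calls = truth.calls.copy()
    # plant violations: missingness block, monomorphic loci, HWE-violating loci
    calls[:, :40][rng.random((20, 40)) < 0.3] = M
    calls[:, 40:60] = 2
    calls[:, 60:80] = np.where(rng.random((20, 20)) < 0.5, 0, 2)  # no hets
    gm = make_matrix(calls)
    kept, report = qc_filter(gm, apply_hwe=True)
    assert report.retained == brute_force_qc(gm, apply_hwe=True)
    assert kept.locus_ids == report.retained
    assert report.n_retained == report.n_input_loci - len(
        set(report.fail_callrate) | set(report.fail_maf) | set(report.fail_hwe)
    )


def test_qc_is_order_independent(rng):
    """Sequential filtering in either order equals the joint evaluation."""
    truth, _ = simulate_reference_genotypes(30, 300, seed=51)
    calls = truth.calls.copy()
    calls[rng.random(calls.shape) < 0.08] = M
    gm = make_matrix(calls)
    joint, _ = qc_filter(gm, apply_hwe=True)

    def only(callrate_min=0.0, maf_min=-1.0, apply_hwe=False):
        def f(g):
            out, _ = qc_filter(g, callrate_min=callrate_min, maf_min=maf_min,
                               hwe_p_min=1e-5, apply_hwe=apply_hwe)
            return out
        return f

    cr, maf, hwe = only(callrate_min=0.9), only(maf_min=0.01), only(apply_hwe=True)
    assert cr(maf(hwe(gm))).locus_ids == joint.locus_ids
    assert hwe(cr(maf(gm))).locus_ids == joint.locus_ids


# -- imputation ---------------------------------------------------------------------


def test_impute_identity_without_missing():
    gm = make_matrix([[0, 1, 2], [2, 1, 0]])
    np.testing.assert_array_equal(impute_naive(gm), gm.calls.astype(float))


def test_impute_fills_locus_mean():
    gm = make_matrix([[0], [2], [M]])
    assert impute_naive(gm)[2, 0] == 1.0


def test_impute_all_missing_locus_is_an_error():
    with pytest.raises(ValueError, match="no called genotypes"):
        impute_naive(make_matrix([[M], [M]]))


def test_g_after_light_imputation_close_to_complete(rng):
    truth, _ = simulate_reference_genotypes(100, 2000, seed=52)
    G_full, _ = compute_g_matrix(truth.calls.astype(float))
    calls = truth.calls.copy()
    calls[rng.random(calls.shape) < 0.01] = M
    G_imp, _ = compute_g_matrix(impute_naive(make_matrix(calls)))
    assert np.abs(G_full - G_imp).max() < 0.05


# -- G matrix -----------------------------------------------------------------------


def test_g_matrix_hand_example():
    dosages = np.array([[0.0], [2.0]])
    G, p = compute_g_matrix(dosages)
    assert p[0] == 0.5
    np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])


def test_g_matrix_matches_double_loop(rng):
    dosages = rng.integers(0, 3, size=(10, 50)).astype(float)
    G, p = compute_g_matrix(dosages)
    denom = 2 * sum(pi * (1 - pi) for pi in p)
    for i in range(10):
        for k in range(10):
            zi = dosages[i] - 2 * p
            zk = dosages[k] - 2 * p
            assert abs(G[i, k] - float(zi @ zk) / denom) < 1e-10


def test_g_matrix_symmetry_psd_and_diagonal():
    truth, _ = simulate_reference_genotypes(200, 2000, seed=53)
    G, _ = compute_g_matrix(truth.calls.astype(float))
    np.testing.assert_array_equal(G, G.T)
    assert np.linalg.eigvalsh(G).min() >= -1e-8
    assert abs(np.diag(G).mean() - 1.0) < 0.05  # unrelated HWE individuals


def test_g_matrix_drops_fixed_loci():
    dosages = np.array([[0.0, 2.0], [2.0, 2.0]])
    with pytest.warns(UserWarning, match="fixed"):
        G, p = compute_g_matrix(dosages)
    assert p.tolist() == [0.5]


# -- GBLUP --------------------------------------------------------------------------


def test_infinite_shrinkage_limit():
    co = simulate_breeding_cohort(40, 0, 300, h2=0.5, seed=54)
    G, _ = compute_g_matrix(co.genotypes.calls.astype(float))
    y = co.drp["trait"]
    fit = fit_gblup(G, y, ids=co.genotypes.samples, lambda_=1e8)
    assert np.linalg.norm(fit.g_hat) < 1e-4
    assert fit.mu == pytest.approx(y.mean(), abs=1e-6)


def test_identity_g_closed_form():
    n = 12
    rng = np.random.default_rng(55)
    y = rng.normal(size=n)
    y -= y.mean()
    ids = [f"i{k}" for k in range(n)]
    lam = 2.5
    fit = fit_gblup(np.eye(n), pd.Series(y, index=ids), ids=ids, lambda_=lam)
    np.testing.assert_allclose(fit.g_hat.to_numpy(), y / (1 + lam), atol=1e-10)


def test_gblup_equals_ridge_snp_blup():
    """GBLUP through G reproduces ridge SNP effect predictions (duality)."""
    co = simulate_breeding_cohort(50, 10, 200, h2=0.3, seed=56)
    dosages = co.genotypes.calls.astype(float)
    G, p = compute_g_matrix(dosages)
    y = co.drp["trait"]
    lam = (1 - 0.3) / 0.3
    fit = fit_gblup(G, y, ids=co.genotypes.samples, h2=0.3)

    # independent ridge route: marker effects via the reference rows of Z
    Z = dosages - 2 * p
    c = 2 * np.sum(p * (1 - p))
    Zr = Z[:50]
    ones = np.ones(50)
    C = Zr @ Zr.T / c + lam * np.eye(50)
    mu = ones @ np.linalg.solve(C, y) / (ones @ np.linalg.solve(C, ones))
    a = Zr.T @ np.linalg.solve(Zr @ Zr.T + c * lam * np.eye(50), y - mu)
    np.testing.assert_allclose(fit.g_hat.to_numpy(), Z @ a, atol=1e-6)


def test_shrinkage_monotonic_in_lambda():
    co = simulate_breeding_cohort(30, 0, 100, h2=0.5, seed=57)
    G, _ = compute_g_matrix(co.genotypes.calls.astype(float))
    norms = [
        np.linalg.norm(fit_gblup(G, co.drp["trait"],
                                 ids=co.genotypes.samples, lambda_=lam).g_hat)
        for lam in (0.1, 1.0, 10.0, 100.0)
    ]
    assert all(a >= b for a, b in zip(norms, norms[1:]))


def test_gblup_argument_validation():
    with pytest.raises(ValueError, match="exactly one"):
        fit_gblup(np.eye(2), [1.0, 2.0], ids=["a", "b"],
                  reference_ids=["a", "b"])
    with pytest.raises(KeyError, match="not present"):
        fit_gblup(np.eye(2), [1.0], ids=["a", "b"], reference_ids=["zz"],
                  lambda_=1.0)


# -- REML ---------------------------------------------------------------------------


def test_reml_recovers_h2():
    co = simulate_breeding_cohort(500, 0, 2000, h2=0.5, seed=58)
    G, _ = compute_g_matrix(co.genotypes.calls.astype(float))
    _, h2 = estimate_variance_ratio(G, co.drp["trait"].to_numpy())
    assert abs(h2 - 0.5) < 0.1


def test_reml_null_heritability_near_zero():
    rng = np.random.default_rng(59)
    truth, _ = simulate_reference_genotypes(500, 500, seed=60)
    G, _ = compute_g_matrix(truth.calls.astype(float))
    hits = 0
    for _ in range(10):
        y = rng.normal(size=500)  # pure noise, unrelated individuals
        _, h2 = estimate_variance_ratio(G, y)
        hits += h2 < 0.15
    assert hits >= 9


def test_variance_ratio_scale_invariant():
    co = simulate_breeding_cohort(200, 0, 500, h2=0.4, seed=61)
    G, _ = compute_g_matrix(co.genotypes.calls.astype(float))
    y = co.drp["trait"].to_numpy()
    lam1, _ = estimate_variance_ratio(G, y)
    lam2, _ = estimate_variance_ratio(G, y * 10)
    assert lam1 == pytest.approx(lam2, rel=1e-3)


def test_reml_needs_enough_individuals():
    with pytest.raises(ValueError, match="at least 10"):
        estimate_variance_ratio(np.eye(5), np.zeros(5))


# -- sex determination ---------------------------------------------------------------


def brute_force_panel(gm, males, callrate_min=0.9, maf_min=0.015,
                      male_het_max=0.01):
    kept = []
    male_rows = [gm.samples.index(s) for s in males]
    for j, locus in enumerate(gm.loci):
        col = [int(c) for c in gm.calls[:, j]]
        called = [c for c in col if c != M]
        if len(called) / len(col) < callrate_min:
            continue
        p = sum(called) / (2 * len(called)) if called else 0
        if min(p, 1 - p) <= maf_min:
            continue
        mcalls = [col[i] for i in male_rows if col[i] != M]
        mhet = (sum(c == 1 for c in mcalls) / len(mcalls)) if mcalls else 0.0
        if mhet > male_het_max:
            continue
        kept.append(locus.id)
    return kept


def test_par_locus_excluded_and_clean_locus_retained():
    # locus 0: PAR-like, het in males; locus 1: clean non-PAR
    calls = np.array([[1, 0], [1, 2], [1, 0], [0, 2]], dtype=np.int8)
    gm = make_matrix(calls, samples=["m1", "m2", "m3", "f1"])
    panel = build_sex_panel(gm, known_males=["m1", "m2", "m3"])
    assert panel == ["L1"]


def test_panel_matches_brute_force_on_simulated_x():
    rates = WGAErrorRates(ado=0.05, het_gain=0.005, missing=0.03)
    gm, sexes = simulate_x_genotypes(25, 25, 800, par_fraction=0.05,
                                     error_rates=rates, seed=62)
    males = [s for s, sex in zip(gm.samples, sexes) if sex == "male"]
    panel = build_sex_panel(gm, known_males=males)
    assert panel == brute_force_panel(gm, males)
    # the PAR block (first 5% of loci) is mostly removed; only low-MAF PAR
    # loci where no male happened to show a het can survive
    par_kept = sum(lid in set(panel) for lid in gm.locus_ids[:40])
    assert par_kept / 40 < 0.25
    assert len(panel) / 760 > 0.5


def test_sex_threshold_tie_is_male():
    row = np.zeros(100, dtype=np.int8)
    row[:2] = 1  # het rate exactly 0.02
    call = determine_sex(row, "e1")
    assert call.call == "male" and call.het_rate == 0.02
    row[:30] = 1
    assert determine_sex(row, "e2").call == "female"


def test_no_call_below_min_loci():
    row = np.full(100, M, dtype=np.int8)
    row[:10] = 0
    assert determine_sex(row, "e").call == "no_call"
    with pytest.raises(ValueError, match="no called"):
        determine_sex(np.full(3, M, dtype=np.int8))


def test_sexing_simulation_is_accurate():
    rates = WGAErrorRates(ado=0.1, het_gain=0.005)
    gm, sexes = simulate_x_genotypes(20, 20, 1500, par_fraction=0.05,
                                     error_rates=rates, seed=63)
    males = [s for s, sex in zip(gm.samples, sexes) if sex == "male"]
    calls, panel = classify_sex(gm, gm.samples, known_males=males)
    assert [c.call for c in calls] == sexes


def test_two_pass_bootstrap_without_known_males():
    rates = WGAErrorRates(ado=0.1, het_gain=0.005)
    gm, sexes = simulate_x_genotypes(15, 15, 1500, par_fraction=0.05,
                                     error_rates=rates, seed=64)
    calls, _ = classify_sex(gm, gm.samples)  # no males given
    assert [c.call for c in calls] == sexes


# -- consolidated screening -----------------------------------------------------------


@pytest.fixture(scope="module")
def screened():
    co = simulate_breeding_cohort(150, 6, 800, h2={"milk": 0.3}, seed=65)
    ref = co.genotypes.subset_samples(co.reference_ids)
    emb = co.genotypes.subset_samples(co.embryo_ids)
    emb = corrupt_with_wga_errors(emb, WGAErrorRates(ado=0.05, missing=0.05),
                                  seed=66)
    x, sexes = simulate_x_genotypes(3, 3, 1500, par_fraction=0.05,
                                    error_rates=WGAErrorRates(ado=0.1),
                                    seed=67)
    x.samples = list(co.embryo_ids)
    genome = {str(c): 100_000_000 for c in range(1, 6)}
    tracks = {}
    for i, e in enumerate(co.embryo_ids):
        events = ([CNEvent(chrom="3", copy_number=3, whole_chromosome=True)]
                  if i == 1 else [])
        tracks[e] = simulate_depth_track(genome, depth_mean=10,
                                         depth_dispersion=1.5,
                                         cn_events=events, seed=700 + i)
    report, detail = screen_embryos(
        ref, emb, co.drp, h2={"milk": 0.3}, x_geno=x,
        known_males=co.embryo_ids[:3], depth_tracks=tracks,
    )
    return co, ref, emb, report, detail


def test_screen_report_composition(screened):
    co, ref, emb, report, detail = screened
    assert list(report["embryo_id"]) == co.embryo_ids
    assert report.loc[0, "sex"] == "male"
    assert report.loc[3, "sex"] == "female"
    assert report.loc[0, "aneuploidy"] == "euploid"
    assert report.loc[1, "aneuploidy"] == "tri3"
    assert detail["qc"]["n_retained"] > 0


def test_screen_dgv_equals_direct_gblup(screened):
    co, ref, emb, report, detail = screened
    combined = stack_samples(ref, emb)
    qc_geno, _ = qc_filter(combined, apply_hwe=True)
    G, _ = compute_g_matrix(impute_naive(qc_geno))
    fit = fit_gblup(G, co.drp["milk"], ids=qc_geno.samples, h2=0.3)
    np.testing.assert_allclose(
        report["dgv_milk"].to_numpy(),
        fit.g_hat[co.embryo_ids].to_numpy(),
        rtol=1e-12,
    )


def test_prediction_accuracy_on_embryos():
    rs = []
    for seed in (1, 2, 3):
        co = simulate_breeding_cohort(500, 100, 2000, h2=0.3, seed=seed)
        G, _ = compute_g_matrix(impute_naive(co.genotypes))
        fit = fit_gblup(G, co.drp["trait"], ids=co.genotypes.samples, h2=0.3)
        rs.append(np.corrcoef(fit.g_hat[co.embryo_ids],
                              co.true_g.loc[co.embryo_ids, "trait"])[0, 1])
    assert np.median(rs) > 0.4
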
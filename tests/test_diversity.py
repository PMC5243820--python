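import numpy as np
import pandas as pd
import pytest

from canopyefd.diversity import (
    broad_sense_heritability,
    build_coefficient_matrix,
    convex_hull_spread,
    flag_outliers,
    group_cv,
    heritability_report,
    pca_on_efd,
    rcbd_anova,
)
from canopyefd.efd import chain_code, elliptic_fourier_coefficients, standardize
from canopyefd.synthetic import RCBDSimParams, simulate_rcbd_traits

from conftest import analytic_star


# ------------------------------------------------------------------------ PCA

def _random_matrix(n=15, p=8, seed=0):
    return np.random.default_rng(seed).normal(size=(n, p))


def test_pca_variance_fractions_sum_to_one():
    res = pca_on_efd(_random_matrix())
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
    assert (res.explained_variance_ratio >= 0).all()


def test_pca_components_orthonormal():
    res = pca_on_efd(_random_matrix())
    gram = res.loadings @ res.loadings.T
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)


def test_pca_full_rank_reconstruction():
    x = _random_matrix()
    res = pca_on_efd(x)
    reconstructed = res.scores @ res.loadings + res.mean
    assert np.abs(reconstructed - x).max() < 1e-8


def test_pca_rank_one_family():
    """Shapes morphed along a single coefficient direction load on PC1.

    The morph leaves harmonic 1 untouched, so the standardization frame
    (L, psi, theta) is shared and the family stays rank-1 after
    standardization.
    """
    base = elliptic_fourier_coefficients(
        chain_code(analytic_star(10.0, 5, 0.2, 256)), 12)
    records = []
    for t in np.linspace(0.0, 1.5, 12):
        coeffs = base.coeffs.copy()
        coeffs[2] += t * np.array([0.3, -0.1, 0.2, 0.05])
        from canopyefd.efd import EFDSet

        records.append(standardize(EFDSet(A0=0.0, C0=0.0, coeffs=coeffs, T=base.T)))
    res = pca_on_efd(build_coefficient_matrix(records))
    assert res.explained_variance_ratio[0] > 0.99


def test_pca_row_permutation_invariance():
    x = _random_matrix()
    perm = np.random.default_rng(2).permutation(len(x))
    r0, r1 = pca_on_efd(x), pca_on_efd(x[perm])
    # scores invariant up to component sign
    for k in range(min(3, r0.scores.shape[1])):
        s0, s1 = r0.scores[perm, k], r1.scores[:, k]
        assert min(np.abs(s1 - s0).max(), np.abs(s1 + s0).max()) < 1e-8


def test_pca_input_validation():
    with pytest.raises(ValueError):
        pca_on_efd(np.ones((1, 4)))
    bad = np.ones((4, 3))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        pca_on_efd(bad)


def test_build_coefficient_matrix_drops_constants():
    c = analytic_star(10.0, 5, 0.2, 128)
    std = standardize(elliptic_fourier_coefficients(chain_code(c), 6))
    mat = build_coefficient_matrix([std, std])
    assert mat.shape == (2, 6 * 4 - 3)


# ----------------------------------------------------------------- hull spread

def test_hull_area_unit_square():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    out = convex_hull_spread(pts, ["g"] * 4)
    assert out.hull_area.iloc[0] == pytest.approx(1.0)
    assert not out.degenerate.iloc[0]


def test_hull_area_collinear_flagged():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
    out = convex_hull_spread(pts, ["g"] * 5)
    assert out.hull_area.iloc[0] == 0.0
    assert out.degenerate.iloc[0]


def test_hull_area_small_group_flagged():
    pts = np.array([[0, 0], [1, 1]], dtype=float)
    out = convex_hull_spread(pts, ["g", "g"])
    assert out.hull_area.iloc[0] == 0.0 and out.degenerate.iloc[0]


def test_hull_nested_groups_monotone():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(30, 2))
    sub = convex_hull_spread(pts[:10], ["s"] * 10).hull_area.iloc[0]
    sup = convex_hull_spread(pts, ["s"] * 30).hull_area.iloc[0]
    assert sub <= sup


# -------------------------------------------------------------------------- CV

def test_group_cv_known_value():
    df = pd.DataFrame({"trait": [1.0, 2.0, 3.0]})
    out = group_cv(df, ["a"] * 3)
    assert out.cv.iloc[0] == pytest.approx(0.5)


def test_group_cv_constant_group_zero():
    df = pd.DataFrame({"trait": [2.0, 2.0, 2.0]})
    assert group_cv(df, ["a"] * 3).cv.iloc[0] == 0.0


def test_group_cv_singleton_flagged():
    df = pd.DataFrame({"trait": [1.0, 5.0]})
    out = group_cv(df, ["a", "b"])
    assert out.undefined.all()


def test_group_cv_zero_mean_flagged():
    df = pd.DataFrame({"trait": [-1.0, 1.0]})
    out = group_cv(df, ["a", "a"])
    assert out.undefined.iloc[0]


# --------------------------------------------------------------------- outliers

def test_flag_outliers_planted_extreme():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.0, 1.0, 200)  # fences at -0.5/1.5: no natural flags
    q1, q3 = np.percentile(vals, [25, 75])
    planted = np.median(vals) + 10 * (q3 - q1)
    df = pd.DataFrame({
        "id": [f"p{i}" for i in range(201)],
        "trait": np.append(vals, planted),
    })
    flags = flag_outliers(df.assign(group="g"), "group", ["trait"])
    flagged_ids = flags.loc[flags.flagged, "id"].tolist()
    assert flagged_ids == ["p200"]


def test_flag_outliers_constant_group_none():
    df = pd.DataFrame({"id": list("abcdef"), "trait": [3.0] * 6, "group": "g"})
    flags = flag_outliers(df, "group", ["trait"])
    assert not flags.flagged.any()


def test_flag_outliers_small_group_skipped():
    df = pd.DataFrame({"id": list("abc"), "trait": [1.0, 2.0, 99.0], "group": "g"})
    flags = flag_outliers(df, "group", ["trait"])
    assert flags.empty


def test_flag_outliers_replicate_consistency():
    rng = np.random.default_rng(6)
    rows = []
    for g in range(10):
        for rep in range(4):
            rows.append({"id": f"g{g}_r{rep}", "genotype": f"g{g}",
                         "trait": rng.uniform(0, 1), "group": "all"})
    rows[3]["trait"] = 50.0  # genotype g0, one of four reps
    df = pd.DataFrame(rows)
    flags = flag_outliers(df, "group", ["trait"], genotype_col="genotype")
    g0 = flags[(flags.genotype == "g0") & flags.flagged]
    assert len(g0) == 1
    assert g0.consistency.iloc[0] == 1


# ----------------------------------------------------------------------- ANOVA

def test_rcbd_anova_hand_checked_toy():
    df = pd.DataFrame({
        "genotype": ["g1", "g1", "g2", "g2"],
        "block": ["b1", "b2", "b1", "b2"],
        "value": [10.0, 12.0, 14.0, 16.0],
    })
    res = rcbd_anova(df)
    assert res.ms_genotype == pytest.approx(16.0)   # SS_g = 16, df = 1
    assert res.ms_block == pytest.approx(4.0)       # SS_b = 4, df = 1
    assert res.ms_error == pytest.approx(0.0, abs=1e-12)
    assert res.sigma2_g == pytest.approx(8.0)       # (MSG - MSE) / k


def test_rcbd_anova_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = simulate_rcbd_traits(RCBDSimParams(n_genotypes=12, k=4, sigma2_g=1.5,
                                            sigma2_b=0.7, sigma2_e=1.0, seed=8))
    res = rcbd_anova(df)
    fit = ols("value ~ C(genotype) + C(block)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    assert res.f_genotype == pytest.approx(table.loc["C(genotype)", "F"], rel=1e-9)
    assert res.p_genotype == pytest.approx(table.loc["C(genotype)", "PR(>F)"], abs=1e-12)
    assert res.ms_error == pytest.approx(
        table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"], rel=1e-9)


def test_rcbd_anova_ss_identity():
    df = simulate_rcbd_traits(RCBDSimParams(n_genotypes=20, k=3, seed=3))
    res = rcbd_anova(df)
    y = df.pivot(index="genotype", columns="block", values="value").to_numpy()
    ss_tot = ((y - y.mean()) ** 2).sum()
    recomposed = (res.ms_genotype * res.df_genotype
                  + res.ms_block * (res.n_blocks - 1)
                  + res.ms_error * res.df_error)
    assert recomposed == pytest.approx(ss_tot, abs=1e-8)


def test_rcbd_anova_truncates_negative_sigma_g():
    # strong block effect, genotype effect absent -> MSG can fall below MSE
    found = False
    for seed in range(20):
        df = simulate_rcbd_traits(RCBDSimParams(n_genotypes=5, k=3, sigma2_g=0.0,
                                                sigma2_e=1.0, seed=seed))
        res = rcbd_anova(df)
        if res.ms_genotype < res.ms_error:
            assert res.sigma2_g == 0.0
            found = True
    assert found


def test_rcbd_anova_restricts_to_modal_block_set():
    df = simulate_rcbd_traits(RCBDSimParams(n_genotypes=10, k=3, seed=2))
    # genotype g0000 loses one block -> dropped from the balanced core
    df = df[~((df.genotype == "g0000") & (df.block == "b0"))]
    res = rcbd_anova(df)
    assert res.n_genotypes == 9
    assert res.n_blocks == 3


def test_rcbd_anova_too_small():
    df = pd.DataFrame({"genotype": ["g1", "g1"], "block": ["b1", "b2"],
                       "value": [1.0, 2.0]})
    with pytest.raises(ValueError):
        rcbd_anova(df)


def test_null_simulation_mean_f_near_one():
    f = []
    for seed in range(500):
        df = simulate_rcbd_traits(RCBDSimParams(n_genotypes=50, k=3, sigma2_g=0.0,
                                                sigma2_e=1.0, seed=seed))
        f.append(rcbd_anova(df).f_genotype)
    assert np.mean(f) == pytest.approx(1.0, abs=0.1)


# ----------------------------------------------------------------- heritability

def test_heritability_direct_formula():
    from canopyefd.diversity import AnovaResult

    a = AnovaResult(ms_genotype=5.0, ms_block=1.0, ms_error=1.0, f_genotype=5.0,
                    p_genotype=0.01, sigma2_g=1.0, sigma2_e=1.0, n_genotypes=10,
                    n_blocks=4, df_genotype=9, df_error=27)
    assert broad_sense_heritability(a) == pytest.approx(0.8)


def test_heritability_zero_genotypic_variance():
    from canopyefd.diversity import AnovaResult

    a = AnovaResult(1.0, 1.0, 1.0, 1.0, 0.5, 0.0, 1.0, 10, 4, 9, 27)
    assert broad_sense_heritability(a) == 0.0
    undef = AnovaResult(0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 10, 4, 9, 27)
    assert np.isnan(broad_sense_heritability(undef))


def test_heritability_monotone_in_k_and_sigma_g():
    from canopyefd.diversity import AnovaResult

    def h2(sg, k):
        a = AnovaResult(1, 1, 1, 1, 0.5, sg, 1.0, 10, k, 9, 9 * (k - 1))
        return broad_sense_heritability(a)

    assert h2(1.0, 2) < h2(1.0, 3) < h2(1.0, 4)
    assert h2(0.5, 3) < h2(1.0, 3) < h2(2.0, 3)


def test_parameter_recovery_grid():
    """Median bias of H2-hat under the expected-mean-squares estimator."""
    for ratio in (0.25, 1.0, 4.0):
        for k in (2, 3, 4):
            h2_true = ratio / (ratio + 1.0 / k)
            est = []
            for rep in range(20):
                df = simulate_rcbd_traits(RCBDSimParams(
                    n_genotypes=300, k=k, sigma2_g=ratio, sigma2_e=1.0,
                    seed=1000 * k + rep))
                est.append(broad_sense_heritability(rcbd_anova(df)))
            assert abs(np.median(est) - h2_true) < 0.05


def test_heritability_report_shape():
    frames = []
    for i, trait in enumerate(["roundness", "solidity"]):
        frames.append(simulate_rcbd_traits(RCBDSimParams(
            n_genotypes=30, k=3, sigma2_g=2.0, sigma2_e=1.0, seed=i, trait=trait)))
    report = heritability_report(pd.concat(frames))
    assert list(report.columns) == ["trait", "F_G", "significance", "sigma2_g",
                                    "sigma2_e", "k", "H2"]
    assert len(report) == 2
    assert (report.k == 3).all()
    assert report.H2.between(0, 1).all()
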
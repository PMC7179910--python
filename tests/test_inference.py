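"""AR1 mixed-model likelihood, AIC ranking, marginal means, Tukey contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate
from scipy.stats import chi2, multivariate_normal, norm, studentized_range

from dielmove import inference as inf
from dielmove.inference import _block_flags, _profiled_pieces


def _ar1_noise(rng, n, phi, sd):
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov = sd * np.sqrt(1 - phi ** 2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0, innov)
    return x


def _simulate_lmm(rng, n_ind=4, n_per=50, phi=0.5, sd_id=0.5, sd_type=0.2,
                  sigma=1.0, beta=(0.5, 0.8), x_col="SunAlt"):
    rows = []
    b_type = {"True": rng.normal(0, sd_type), "Predicted": rng.normal(0, sd_type)}
    for i in range(n_ind):
        b_i = rng.normal(0, sd_id)
        x = rng.normal(0, 1, n_per)
        e = _ar1_noise(rng, n_per, phi, sigma)
        types = np.where(np.arange(n_per) % 2, "True", "Predicted")
        y = beta[0] + beta[1] * x + b_i + np.array([b_type[t] for t in types]) + e
        for k in range(n_per):
            rows.append({"individual_id": f"A{i}", "type": types[k],
                         "timestamp": pd.Timestamp("2020-01-01")
                         + pd.Timedelta(minutes=5 * k),
                         x_col: x[k], "log_velocity": y[k]})
    return pd.DataFrame(rows)


# --- candidate set ------------------------------------------------------------

def test_candidate_set_is_the_nine_structures():
    specs = inf.build_candidate_models()
    assert len(specs) == 9
    assert [s.label for s in specs] == [str(i) for i in range(1, 10)]
    # 3 single, 3 additive, 3 interactive (term counts incl. intercept)
    assert [len(s.fixed_terms) for s in specs] == [2, 2, 2, 3, 3, 4, 4, 4, 8]
    # the global model expands to 8 fixed terms incl. 3-way interaction
    m9 = specs[-1]
    assert "SunAlt:MoonIlluminatedFrac:TMAX" in m9.fixed_terms
    assert "Intercept" in m9.fixed_terms


def test_every_fit_carries_both_random_factors_and_ar1():
    rng = np.random.default_rng(0)
    df = _simulate_lmm(rng, n_ind=3, n_per=30)
    fit = inf.fit_lme(inf.build_candidate_models()[0], df)
    assert set(fit.re_variances) == {"individual_id", "type"}
    assert -1.0 < fit.phi < 1.0
    assert fit.df_model == 2 + 4  # 2 fixed + 2 variance ratios + phi + sigma2


# --- likelihood oracles -------------------------------------------------------

def _dense_loglik(fit, df, formula, response="log_velocity"):
    """Dense multivariate-normal log-density with the same parameters."""
    from patsy import dmatrices
    d = df.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)
    y_dm, X_dm = dmatrices(f"{response} ~ {formula}", d,
                           return_type="dataframe")
    y, X = y_dm.to_numpy()[:, 0], X_dm.to_numpy()
    n = len(d)
    groups = d["individual_id"].to_numpy()
    C = np.zeros((n, n))
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        k = np.arange(len(idx))
        C[np.ix_(idx, idx)] = fit.phi ** np.abs(k[:, None] - k[None, :])
    V = fit.sigma2 * C
    for fac, var in fit.re_variances.items():
        Z = pd.get_dummies(d[fac].astype(str)).to_numpy(float)
        V += var * Z @ Z.T
    return float(multivariate_normal.logpdf(y, X @ fit.params.to_numpy(), V))


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_structured_loglik_equals_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    df = _simulate_lmm(rng, n_ind=2, n_per=5 * seed + 5)
    assert len(df) <= 50
    fit = inf.fit_lme(inf.ModelSpec("1", "SunAlt"), df)
    dense = _dense_loglik(fit, df, "SunAlt")
    assert abs(dense - fit.loglik) < 1e-8


def test_gls_at_independence_reduces_to_ols():
    # phi = 0 and vanishing variance ratios: the profiled GLS equals OLS
    rng = np.random.default_rng(7)
    n = 300
    x = rng.normal(size=n)
    y = 1.5 + 2.0 * x + rng.normal(size=n)
    df = pd.DataFrame({"individual_id": "A", "type": "True",
                       "timestamp": pd.date_range("2020-01-01", periods=n,
                                                  freq="5min"),
                       "SunAlt": x, "log_velocity": y})
    X = np.column_stack([np.ones(n), x])
    first, last = _block_flags(df["individual_id"].to_numpy())
    Z = np.ones((n, 2))  # constant indicators (single individual, one type)
    theta = np.array([-15.0, -15.0, 0.0])
    _, beta, _, _, _ = _profiled_pieces(theta, y, X, Z, first, last, (1, 1))
    ols = sm.OLS(y, X).fit()
    assert np.abs(beta - ols.params).max() < 1e-6
    # and the free fit estimates phi near zero on iid data
    fit = inf.fit_lme(inf.ModelSpec("1", "SunAlt"), df)
    assert abs(fit.phi) < 0.1


# --- AIC ranking ---------------------------------------------------------------

def test_rank_aic_basics():
    rng = np.random.default_rng(3)
    df = _simulate_lmm(rng, n_ind=3, n_per=40)
    f1 = inf.fit_lme(inf.ModelSpec("1", "SunAlt"), df)
    tab = inf.rank_aic([f1, f1])
    assert np.allclose(tab["dAIC"], 0.0)
    with pytest.raises(ValueError, match="comparable"):
        inf.rank_aic([f1, inf.fit_lme(inf.ModelSpec("1", "SunAlt"),
                                      df.iloc[:-10])])


def test_nested_ml_loglik_monotone_and_permutation_invariant():
    rng = np.random.default_rng(4)
    df = _simulate_lmm(rng, n_ind=3, n_per=60)
    df["TMAX"] = rng.normal(30, 4, len(df))
    small = inf.fit_lme(inf.ModelSpec("1", "SunAlt"), df)
    big = inf.fit_lme(inf.ModelSpec("5", "SunAlt + TMAX"), df)
    assert big.loglik >= small.loglik - 1e-6
    shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
    again = inf.fit_lme(inf.ModelSpec("1", "SunAlt"), shuffled)
    assert again.aic == pytest.approx(small.aic, abs=1e-6)


def test_interaction_structure_recovered_by_aic():
    # data generated with a SunAlt x TMAX interaction only: the interactive
    # models 8 or 9 should win the AIC ranking in most replicates
    wins = 0
    n_rep = 6
    for rep in range(n_rep):
        rng = np.random.default_rng(100 + rep)
        df = _simulate_lmm(rng, n_ind=4, n_per=150, phi=0.3,
                           sd_id=0.3, sd_type=0.1, sigma=1.0)
        df["TMAX"] = rng.normal(30, 4, len(df))
        df["MoonIlluminatedFrac"] = rng.uniform(0, 1, len(df))
        df["log_velocity"] += 0.08 * df["SunAlt"] * (df["TMAX"] - 30)
        fits = [inf.fit_lme(s, df) for s in inf.build_candidate_models()]
        best = inf.rank_aic(fits).iloc[0]["model"]
        wins += best in ("8", "9")
    assert wins >= n_rep - 1


def test_wald_ci_coverage_under_model9_structure():
    # 95% Wald CIs should cover the generating coefficients ~95% of the time
    beta_true = {"Intercept": 0.2, "SunAlt": 0.5, "MoonIlluminatedFrac": -0.4,
                 "TMAX": 0.1, "SunAlt:MoonIlluminatedFrac": 0.3,
                 "SunAlt:TMAX": -0.2, "MoonIlluminatedFrac:TMAX": 0.15,
                 "SunAlt:MoonIlluminatedFrac:TMAX": 0.1}
    covered = total = 0
    for rep in range(8):
        rng = np.random.default_rng(200 + rep)
        df = _simulate_lmm(rng, n_ind=4, n_per=150, phi=0.4, sd_id=0.3,
                           sd_type=0.1, sigma=1.0, beta=(0.0, 0.0))
        df["TMAX"] = rng.normal(0, 1, len(df))
        df["MoonIlluminatedFrac"] = rng.uniform(0, 1, len(df))
        lin = (beta_true["Intercept"]
               + beta_true["SunAlt"] * df["SunAlt"]
               + beta_true["MoonIlluminatedFrac"] * df["MoonIlluminatedFrac"]
               + beta_true["TMAX"] * df["TMAX"]
               + beta_true["SunAlt:MoonIlluminatedFrac"] * df["SunAlt"]
               * df["MoonIlluminatedFrac"]
               + beta_true["SunAlt:TMAX"] * df["SunAlt"] * df["TMAX"]
               + beta_true["MoonIlluminatedFrac:TMAX"]
               * df["MoonIlluminatedFrac"] * df["TMAX"]
               + beta_true["SunAlt:MoonIlluminatedFrac:TMAX"] * df["SunAlt"]
               * df["MoonIlluminatedFrac"] * df["TMAX"])
        df["log_velocity"] += lin
        fit = inf.fit_lme(inf.build_candidate_models()[8], df)
        for name, true_val in beta_true.items():
            est = fit.params[name]
            half = 1.96 * fit.bse[name]
            covered += (est - half <= true_val <= est + half)
            total += 1
    assert 0.85 <= covered / total <= 1.0


# --- final model and marginal means -------------------------------------------

def _categorized(rng, n=1500, n_ind=4, effects=None):
    lds = ["Dark Moon Night", "Mid Moon Night", "Full Moon Night",
           "Dark Moon Crepuscular", "Mid Moon Crepuscular",
           "Full Moon Crepuscular", "Day"]
    df = pd.DataFrame({
        "individual_id": rng.choice([f"A{i}" for i in range(n_ind)], n),
        "type": rng.choice(["True", "Predicted"], n),
        "timestamp": pd.date_range("2020-01-01", periods=n, freq="5min"),
        "LunarDiel": rng.choice(lds, n),
        "Season": rng.choice(["Hot", "Cool"], n),
        "Species": rng.choice(["ocelot", "bobcat"], n),
    })
    y = rng.normal(0, 1, n)
    if effects:
        for (ld, se, sp), mu in effects.items():
            mask = ((df["LunarDiel"] == ld) & (df["Season"] == se)
                    & (df["Species"] == sp))
            y[mask.to_numpy()] += mu
    df["log_velocity"] = y
    return df


def test_final_model_all_28_cells_estimable():
    rng = np.random.default_rng(11)
    df = _categorized(rng, n=2000)
    fit = inf.fit_final_model(df)
    emm = inf.estimate_marginal_means(fit, ["LunarDiel", "Season", "Species"])
    assert len(emm.grid) == 7 * 2 * 2
    assert np.isfinite(emm.grid["emmean"]).all()
    assert np.isfinite(emm.grid["SE"]).all()
    assert (emm.grid["lower"] < emm.grid["upper"]).all()


def test_single_level_season_collapses_to_two_factor_fit():
    rng = np.random.default_rng(12)
    df = _categorized(rng, n=800)
    df["Season"] = "Cool"
    full = inf.fit_final_model(df)
    reduced = inf.fit_lme(
        inf.ModelSpec("ld_sp", "C(LunarDiel) * C(Species)"), df)
    assert full.loglik == pytest.approx(reduced.loglik, abs=1e-5)


def test_balanced_one_factor_emmeans_equal_cell_means():
    # iid data, saturated one-factor model: marginal means are arithmetic
    # cell means (exact at the independence boundary; the ML fit lands
    # close enough on iid data)
    rng = np.random.default_rng(13)
    n = 900
    df = pd.DataFrame({
        "individual_id": rng.choice(["A", "B", "C"], n),
        "type": "True",
        "timestamp": pd.date_range("2020-01-01", periods=n, freq="5min"),
        "LunarDiel": np.tile(["Day", "Dark Moon Night", "Full Moon Night"],
                             n // 3),
        "Season": "Cool", "Species": "ocelot",
    })
    df["log_velocity"] = rng.normal(0, 1, n)
    fit = inf.fit_lme(inf.ModelSpec("one", "C(LunarDiel)"), df)
    emm = inf.estimate_marginal_means(fit, ["LunarDiel"])
    cell_means = df.groupby("LunarDiel")["log_velocity"].mean()
    for _, row in emm.grid.iterrows():
        assert row["emmean"] == pytest.approx(
            cell_means[row["LunarDiel"]], abs=1e-2)


def test_unbalanced_marginal_mean_differs_from_raw_mean_in_predicted_direction():
    # 2x2 with cell B2 (high mean) over-represented in group A=a2: the raw
    # a2 mean is pulled up relative to the equally weighted marginal mean
    rng = np.random.default_rng(14)
    cells = {("a1", "b1"): (200, 0.0), ("a1", "b2"): (200, 1.0),
             ("a2", "b1"): (60, 0.0), ("a2", "b2"): (340, 1.0)}
    rows = []
    t0 = pd.Timestamp("2020-01-01")
    k = 0
    for (a, b), (n_c, mu) in cells.items():
        for _ in range(n_c):
            rows.append({"individual_id": "X", "type": "True",
                         "timestamp": t0 + pd.Timedelta(minutes=5 * k),
                         "A": a, "B": b,
                         "log_velocity": mu + rng.normal(0, 0.3)})
            k += 1
    df = pd.DataFrame(rows)
    fit = inf.fit_lme(inf.ModelSpec("ab", "C(A) * C(B)"), df)
    emm = inf.estimate_marginal_means(fit, ["A"])
    emm_a2 = float(emm.grid.loc[emm.grid["A"] == "a2", "emmean"].iloc[0])
    raw_a2 = df.loc[df["A"] == "a2", "log_velocity"].mean()
    # raw mean overweights the high-mean cell; equal-weight emm sits lower
    assert emm_a2 < raw_a2
    assert emm_a2 == pytest.approx(0.5, abs=0.1)


def test_centered_covariate_at_mean_leaves_means_unchanged():
    rng = np.random.default_rng(15)
    n = 600
    df = pd.DataFrame({
        "individual_id": rng.choice(["A", "B"], n), "type": "True",
        "timestamp": pd.date_range("2020-01-01", periods=n, freq="5min"),
        "LunarDiel": np.tile(["Day", "Dark Moon Night"], n // 2),
        "x": rng.normal(0, 1, n),
    })
    df["x"] -= df["x"].mean()
    df["log_velocity"] = (df["LunarDiel"] == "Day") * 1.0 + rng.normal(0, 1, n)
    f0 = inf.fit_lme(inf.ModelSpec("m0", "C(LunarDiel)"), df)
    f1 = inf.fit_lme(inf.ModelSpec("m1", "C(LunarDiel) + x"), df)
    e0 = inf.estimate_marginal_means(f0, ["LunarDiel"]).grid
    e1 = inf.estimate_marginal_means(f1, ["LunarDiel"]).grid
    np.testing.assert_allclose(e0["emmean"], e1["emmean"], atol=0.02)


# --- contrasts -----------------------------------------------------------------

def _toy_emm(means, ses=None, k_factors=("cell",)):
    grid = pd.DataFrame({"cell": [f"c{i}" for i in range(len(means))],
                         "emmean": means})
    q = len(means)
    L = np.eye(q)
    cov = np.diag((ses if ses is not None else np.ones(q)) ** 2
                  if ses is not None else np.ones(q))
    grid["SE"] = np.sqrt(np.diag(cov))
    grid["df"] = 100
    grid["lower"] = grid["emmean"] - 2 * grid["SE"]
    grid["upper"] = grid["emmean"] + 2 * grid["SE"]
    return inf.EmmResult(grid=grid, L=L, cov_beta=cov, ddf=100,
                         factors=list(k_factors))


def test_identical_cells_contrast_zero_with_p_one():
    emm = _toy_emm(np.array([1.0, 1.0]))
    tab = inf.pairwise_contrasts(emm)
    assert len(tab) == 1
    assert tab.iloc[0]["estimate"] == 0.0
    assert tab.iloc[0]["p.value"] == 1.0


def test_contrast_antisymmetry():
    emm = _toy_emm(np.array([2.0, 0.5, -1.0]))
    tab = inf.pairwise_contrasts(emm)
    flipped = _toy_emm(np.array([2.0, 0.5, -1.0])[::-1])
    tab_f = inf.pairwise_contrasts(flipped)
    est = dict(zip(tab["contrast"], tab["estimate"]))
    # c0 - c2 in one ordering equals -(c2' - c0') in the flipped ordering
    assert est["c0 - c2"] == pytest.approx(
        -float(tab_f.loc[tab_f["contrast"] == "c0 - c2", "estimate"].iloc[0]))


def test_tukey_adjusted_p_at_least_unadjusted():
    rng = np.random.default_rng(16)
    emm = _toy_emm(rng.normal(0, 1, 5))
    tuk = inf.pairwise_contrasts(emm, adjust="tukey")
    raw = inf.pairwise_contrasts(emm, adjust="none")
    assert (tuk["p.value"].to_numpy() >= raw["p.value"].to_numpy() - 1e-12).all()


def test_family_of_size_one_yields_empty_table():
    grid = pd.DataFrame({"Species": ["ocelot"], "cell": ["c0"],
                         "emmean": [0.5], "SE": [0.1], "df": [50],
                         "lower": [0.3], "upper": [0.7]})
    emm = inf.EmmResult(grid=grid, L=np.eye(1), cov_beta=np.eye(1), ddf=50,
                        factors=["Species", "cell"])
    tab = inf.pairwise_contrasts(emm, group_by=["Species"])
    assert len(tab) == 0


def _tukey_sf_oracle(q, k, nu):
    """P(studentized range > q) by direct numeric integration."""

    def outer(u):
        # u = s^2 * nu ~ chi2(nu); s the pooled-sd scale factor
        s = np.sqrt(u / nu)

        def inner(z):
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(inner, -9, 9, limit=200)
        return k * val * chi2.pdf(u, nu)

    cdf, _ = integrate.quad(outer, 1e-9, chi2.ppf(1 - 1e-10, nu), limit=200)
    return 1.0 - cdf


def test_tukey_p_matches_numeric_integration_oracle():
    # k = 3 equal-variance balanced cells at moderate residual df
    for q in (2.0, 3.5):
        mine = float(studentized_range.sf(q, 3, 30))
        oracle = _tukey_sf_oracle(q, 3, 30)
        assert abs(mine - oracle) < 1e-4
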
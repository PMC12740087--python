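"""Survival estimators against hand and brute-force oracles, Gompertz MLE
recovery, Aalen reductions, and the velocity mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from climbmet import demography as dem
from climbmet import synthetic as syn
from conftest import random_survival_table


def brute_force_km(entry, exit_, event):
    """Product-limit by literal definition (delayed-entry risk sets)."""
    times = sorted(set(exit_[event == 1]))
    s, out = 1.0, []
    for t in times:
        n = sum((e < t) & (x >= t) for e, x in zip(entry, exit_))
        d = sum((x == t) & (ev == 1) for x, ev in zip(exit_, event))
        s *= 1 - d / n
        out.append((t, s))
    return out


def brute_force_na(entry, exit_, event):
    times = sorted(set(exit_[event == 1]))
    h, out = 0.0, []
    for t in times:
        n = sum((e < t) & (x >= t) for e, x in zip(entry, exit_))
        d = sum((x == t) & (ev == 1) for x, ev in zip(exit_, event))
        h += d / n
        out.append((t, h))
    return out


def test_km_simple_two_deaths():
    rec = pd.DataFrame({"entry_age": [0, 0], "exit_age": [2.0, 4.0], "event": [1, 1]})
    km = dem.kaplan_meier(rec)
    np.testing.assert_allclose(km.surv, [0.5, 0.0])


def test_km_hand_example_with_censor(toy_survival):
    km = dem.kaplan_meier(toy_survival)
    np.testing.assert_allclose(km.surv, [2 / 3, 0.0])
    assert km.evaluate(2.5)[0] == pytest.approx(2 / 3)
    assert km.evaluate(0.5)[0] == 1.0


def test_km_all_censored_warns():
    rec = pd.DataFrame({"entry_age": [0, 0], "exit_age": [2.0, 4.0], "event": [0, 0]})
    with pytest.warns(UserWarning, match="censored"):
        km = dem.kaplan_meier(rec)
    assert km.times.size == 0


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=60)
def test_km_matches_brute_force_on_small_tables(seed):
    rec = random_survival_table(np.random.default_rng(seed))
    km = dem.kaplan_meier(rec)
    oracle = brute_force_km(rec["entry_age"].to_numpy(), rec["exit_age"].to_numpy(),
                            rec["event"].to_numpy())
    assert len(km.times) == len(oracle)
    for (t, s), tt, ss in zip(oracle, km.times, km.surv):
        assert t == tt and abs(s - ss) < 1e-12


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=30)
def test_km_matches_lifelines(seed):
    from lifelines import KaplanMeierFitter

    rec = random_survival_table(np.random.default_rng(seed))
    km = dem.kaplan_meier(rec)
    kmf = KaplanMeierFitter().fit(rec["exit_age"], rec["event"],
                                  entry=rec["entry_age"])
    for t, s in zip(km.times, km.surv):
        assert abs(kmf.predict(t) - s) < 1e-9


def test_rmst_step_area_and_identity():
    rec = pd.DataFrame({"entry_age": [0, 0], "exit_age": [2.0, 4.0], "event": [1, 1]})
    rmst, se = dem.restricted_mean_lifespan(rec, 4.0)
    assert rmst == pytest.approx(3.0)
    # no censoring and horizon >= max death: equals the sample mean
    rng = np.random.default_rng(0)
    t = rng.exponential(10, size=200) + 1
    rec2 = pd.DataFrame({"entry_age": 0.0, "exit_age": t, "event": 1})
    rmst2, _ = dem.restricted_mean_lifespan(rec2, t.max() + 1)
    assert rmst2 == pytest.approx(t.mean())


def test_rmst_before_first_event():
    rec = pd.DataFrame({"entry_age": [0], "exit_age": [10.0], "event": [1]})
    rmst, se = dem.restricted_mean_lifespan(rec, 5.0)
    assert rmst == 5.0 and se == 0.0


def test_log_rank_identical_groups_is_zero():
    rec = pd.DataFrame({"entry_age": 0.0, "exit_age": [2.0, 4, 6, 2, 4, 6],
                        "event": 1, "fraction": [0, 0, 0, 1, 1, 1]})
    chi2, df, p = dem.log_rank(rec)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_log_rank_single_event_time_hand_oracle():
    # 2x2 at one event time: group A: 1 death of 2 at risk; group B: 0 of 2
    rec = pd.DataFrame({"entry_age": 0.0,
                        "exit_age": [3.0, 9.0, 9.0, 9.0],
                        "event": [1, 0, 0, 0],
                        "fraction": [0, 0, 1, 1]})
    chi2, df, p = dem.log_rank(rec)
    # O-E for group A = 1 - 1*2/4 = 0.5; V = 1*3/3 * (2*4-4)/16 = 0.25
    assert chi2 == pytest.approx(0.5**2 / 0.25)


def test_log_rank_matches_lifelines():
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(5)
    rec = pd.DataFrame({
        "entry_age": 0.0,
        "exit_age": np.round(rng.exponential(20, 120) + 1, 1),
        "event": rng.integers(0, 2, 120),
        "fraction": rng.integers(0, 3, 120),
    })
    if rec.groupby("fraction")["event"].sum().min() == 0:
        rec.loc[0, "event"] = 1
    chi2, df, p = dem.log_rank(rec)
    ll = multivariate_logrank_test(rec["exit_age"], rec["fraction"], rec["event"])
    assert chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
    assert p == pytest.approx(ll.p_value, rel=1e-6)


# --- Gompertz -------------------------------------------------------------


def _one_group(alpha, beta, n, entry=0.0, seed=0, censor=0.0):
    return syn.simulate_lifespans(syn.CohortSpec(
        n_flies=n, fraction_probs=(0, 0, 1, 0, 0),
        alpha_by_fraction=(1, 1, alpha, 1, 1), beta_by_fraction=(0, 0, beta, 0, 0),
        entry_age_days=entry, censor_prob=censor, seed=seed))


def test_exponential_mle_closed_form():
    rec = _one_group(0.02, 0.0, 2000, seed=1)
    model = dem.fit_gompertz(rec, shared="all", fix_beta=0.0)
    fit = model.fits["all"]
    exposure = (rec["exit_age"] - rec["entry_age"]).sum()
    assert fit.alpha == pytest.approx(rec["event"].sum() / exposure, rel=1e-10)


def test_gompertz_parameter_recovery():
    rec = _one_group(1e-3, 0.1, 5000, entry=10.0, seed=2)
    fit = dem.fit_gompertz(rec, shared="all").fits["all"]
    assert abs(fit.alpha - 1e-3) / 1e-3 < 0.10
    assert abs(fit.beta - 0.1) / 0.1 < 0.05


def test_gompertz_loglik_matches_quadrature_oracle():
    rec = _one_group(1e-3, 0.1, 30, entry=5.0, seed=3, censor=0.1)
    alpha, beta = 8e-4, 0.12
    from climbmet.demography import _cum_exposure, _group_ll

    s = rec["entry_age"].to_numpy()
    t = rec["exit_age"].to_numpy()
    e = rec["event"].to_numpy()
    ll = _group_ll(alpha, beta, s, t, e)
    oracle = 0.0
    for si, ti, ei in zip(s, t, e):
        cumhaz = quad(lambda u: alpha * np.exp(beta * u), si, ti, epsabs=1e-12)[0]
        oracle += ei * np.log(alpha * np.exp(beta * ti)) - cumhaz
    assert ll == pytest.approx(oracle, abs=1e-6)


def test_gompertz_loglik_time_rescaling():
    """Under t -> ct the location MLE scales: alpha-hat -> alpha-hat/c,
    beta-hat -> beta-hat/c."""
    rec = _one_group(1e-3, 0.1, 2000, seed=4)
    fit = dem.fit_gompertz(rec, shared="all").fits["all"]
    rec2 = rec.copy()
    rec2[["entry_age", "exit_age"]] *= 2.0
    fit2 = dem.fit_gompertz(rec2, shared="all").fits["all"]
    assert fit2.beta == pytest.approx(fit.beta / 2, rel=1e-3)
    assert fit2.alpha == pytest.approx(fit.alpha / 2, rel=1e-3)


def test_lrt_identical_models_p_one():
    rec = _one_group(1e-3, 0.1, 500, seed=5)
    m = dem.fit_gompertz(rec, shared="all")
    chi2, df, p = dem.gompertz_lrt(m, m)
    assert p == 1.0 and df == 0


def test_lrt_power_against_planted_alpha_ratio():
    rejections = 0
    for seed in range(10):
        spec = syn.CohortSpec(
            n_flies=800, fraction_probs=(0.5, 0.5, 0, 0, 0),
            alpha_by_fraction=(1.2e-3, 3e-4, 1, 1, 1),
            beta_by_fraction=(0.11, 0.11, 0, 0, 0),
            entry_age_days=29.0, censor_prob=0.0, seed=seed)
        rec = syn.simulate_lifespans(spec)
        full = dem.fit_gompertz(rec, shared="beta")
        red = dem.fit_gompertz(rec, shared="all")
        if dem.gompertz_lrt(full, red)[2] < 0.05:
            rejections += 1
    assert rejections >= 9


def test_lrt_misnested_models_raise():
    spec = syn.CohortSpec(n_flies=400, fraction_probs=(0.5, 0.5, 0, 0, 0),
                          alpha_by_fraction=(3e-4, 3e-4, 1, 1, 1),
                          beta_by_fraction=(0.11, 0.11, 0, 0, 0),
                          censor_prob=0.0, seed=6)
    rec = syn.simulate_lifespans(spec)
    full = dem.fit_gompertz(rec, shared="all")     # 2 params
    red = dem.fit_gompertz(rec, shared="beta")     # 3 params
    with pytest.raises(ValueError):
        dem.gompertz_lrt(full, red)


# --- Aalen ----------------------------------------------------------------


def test_aalen_reduces_to_nelson_aalen():
    rng = np.random.default_rng(7)
    rec = random_survival_table(rng, max_n=5)
    rec = pd.concat([rec] * 3, ignore_index=True)
    rec["fraction"] = 2
    fit = dem.aalen_additive(rec, reference_group=2)
    oracle = brute_force_na(rec["entry_age"].to_numpy(), rec["exit_age"].to_numpy(),
                            rec["event"].to_numpy())
    np.testing.assert_allclose(fit.cumhaz[:, 0], [h for _, h in oracle], atol=1e-12)


def test_aalen_identical_groups_zero_covariate():
    base = pd.DataFrame({"entry_age": 0.0, "exit_age": [2.0, 4.0, 6.0],
                         "event": [1, 1, 1]})
    rec = pd.concat([base.assign(fraction=2), base.assign(fraction=0)],
                    ignore_index=True)
    fit = dem.aalen_additive(rec, reference_group=2)
    np.testing.assert_allclose(fit.cumhaz[:, 1], 0.0, atol=1e-12)


def test_aalen_three_fly_hand_oracle():
    # reference (f=2): dies at 2; other (f=0): dies at 1; one censored ref at 3
    rec = pd.DataFrame({
        "entry_age": [0.0, 0.0, 0.0],
        "exit_age": [1.0, 2.0, 3.0],
        "event": [1, 1, 0],
        "fraction": [0, 2, 2],
    })
    fit = dem.aalen_additive(rec, reference_group=2)
    # t=1: X = [[1,1],[1,0],[1,0]], d=(1,0,0) -> LS: intercept 0, indicator 1
    # t=2: X = [[1,0],[1,0]] (only refs remain), d=(1,0): singular for the
    # indicator column -> skipped
    np.testing.assert_allclose(fit.cumhaz[0], [0.0, 1.0], atol=1e-12)
    assert fit.skipped_times == [2.0]


def test_aalen_baseline_nondecreasing():
    rec = syn.simulate_lifespans(syn.CohortSpec(n_flies=300, seed=8))
    fit = dem.aalen_additive(rec, reference_group=2)
    assert (np.diff(fit.cumhaz[:, 0]) >= -1e-12).all()


def test_aalen_sup_test_runs():
    rec = syn.simulate_lifespans(syn.CohortSpec(n_flies=300, seed=9))
    fit = dem.aalen_additive(rec, reference_group=2, test="sup", n_resample=100)
    assert ((fit.tests["p"] > 0) & (fit.tests["p"] <= 1)).all()


# --- velocity mixed model -------------------------------------------------


def _velocity_table(n_vials=50, per_vial=10, vial_sd=1.0, resid_sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for v in range(n_vials):
        frac = v % 2 * 4  # bottom / top vials
        u = rng.normal(0, vial_sd)
        for _ in range(per_vial):
            age = rng.choice([30.0, 40.0])
            vel = 1.0 + 0.3 * frac - 0.02 * age - 0.002 * frac * age + u \
                + rng.normal(0, resid_sd)
            rows.append({"velocity": vel, "fraction": frac, "age": age,
                         "vial": f"v{v}", "position": v % 3,
                         "batch": (v // 2) % 3})
    return pd.DataFrame(rows)


def test_lmm_variance_recovery():
    fit = dem.fit_velocity_lmm(_velocity_table(seed=1))
    assert abs(fit.vial_sd - 1.0) < 0.15
    assert abs(fit.resid_sd - 0.5) < 0.075


def test_lmm_matches_statsmodels_ml():
    import statsmodels.formula.api as smf

    tab = _velocity_table(n_vials=20, per_vial=8, seed=2)
    fit = dem.fit_velocity_lmm(tab, position=None, batch=None)
    md = smf.mixedlm("velocity ~ fraction * age", tab, groups=tab["vial"])
    sm_fit = md.fit(reml=False)
    assert fit.fixed_effects["fraction"] == pytest.approx(
        sm_fit.params["fraction"], abs=1e-4)
    assert fit.vial_sd**2 == pytest.approx(
        float(sm_fit.cov_re.iloc[0, 0]), rel=0.02)


def test_lmm_single_vial_degenerates_to_ols():
    rng = np.random.default_rng(3)
    tab = pd.DataFrame({
        "velocity": rng.normal(size=30),
        "fraction": rng.integers(0, 5, 30).astype(float),
        "age": rng.choice([30.0, 40.0], 30),
        "vial": "v0",
    })
    with pytest.warns(UserWarning, match="one vial"):
        fit = dem.fit_velocity_lmm(tab, position=None, batch=None)
    X = np.column_stack([np.ones(len(tab)), tab["fraction"], tab["age"],
                         tab["fraction"] * tab["age"]])
    beta = np.linalg.lstsq(X, tab["velocity"], rcond=None)[0]
    np.testing.assert_allclose(fit.fixed_effects.to_numpy(), beta, atol=1e-8)
    assert fit.vial_sd == 0.0


def test_lmm_balanced_design_matches_cell_means():
    """Group, age and their interaction saturate a balanced 2x2 design, so
    the fitted cell means equal the observed cell means exactly."""
    rng = np.random.default_rng(4)
    rows = []
    for v in range(40):
        g = (v % 2) * 4.0
        a = 30.0 if v % 4 < 2 else 40.0
        for _ in range(5):
            rows.append({"velocity": 2.0 + 0.4 * g - 0.03 * a + rng.normal(0, 0.3),
                         "fraction": g, "age": a, "vial": f"v{v}"})
    tab = pd.DataFrame(rows)
    fit = dem.fit_velocity_lmm(tab, position=None, batch=None)
    b = fit.fixed_effects
    for (g, a), cell in tab.groupby(["fraction", "age"]):
        pred = b["intercept"] + b["fraction"] * g + b["age"] * a \
            + b["fraction:age"] * g * a
        assert pred == pytest.approx(cell["velocity"].mean(), abs=1e-8)
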
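"""Mortality estimation and contrasts across climbing fractions.

Estimators operate on per-fly survival records (``entry_age, exit_age,
event`` plus grouping columns) and all handle delayed entry: a fly is at
risk at age t iff entry_age < t <= exit_age, which encodes the fact that
fractionated cohorts enter observation alive at the fractionation age.

* Kaplan-Meier product-limit survivorship with Greenwood variance, and the
  restricted-mean lifespan (area under the curve up to a horizon).
* The Mantel-Cox log-rank test over pooled event times.
* Maximum-likelihood Gompertz fits, hazard mu(x) = alpha * exp(beta * x),
  with left truncation and right censoring; alpha is the age-independent
  mortality level and beta the demographic rate of aging.  Models may share
  alpha and/or beta across groups, so likelihood-ratio tests can ask
  whether either parameter is associated with climbing fraction.
* Aalen additive-hazard regression against a reference fraction: at each
  event time a least-squares increment on the at-risk design accumulates
  into cumulative regression functions H_a(t) with pointwise variances.
* A random-intercept linear mixed model for climbing velocity (vial as the
  grouping factor), fit by profiled maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fractionation import fraction_to_int

__all__ = [
    "KaplanMeier",
    "kaplan_meier",
    "restricted_mean_lifespan",
    "log_rank",
    "GompertzFit",
    "GompertzModel",
    "fit_gompertz",
    "gompertz_lrt",
    "AalenFit",
    "aalen_additive",
    "VelocityModelFit",
    "fit_velocity_lmm",
    "life_table",
]


def _arrays(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    entry = np.asarray(records["entry_age"], dtype=float)
    exit_ = np.asarray(records["exit_age"], dtype=float)
    event = np.asarray(records["event"], dtype=int)
    if np.any(exit_ < entry):
        raise ValueError("exit_age < entry_age in survival records")
    return entry, exit_, event


@dataclass
class KaplanMeier:
    """Right-continuous product-limit estimate with Greenwood variance."""

    times: np.ndarray          # distinct event (death) times
    surv: np.ndarray           # S(t) just after each event time
    var: np.ndarray            # Greenwood variance of S at each event time
    n_risk: np.ndarray
    n_death: np.ndarray

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """S(t), right-continuous (S drops at each death time)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.surv[np.clip(idx, 0, None)])
        return out


def kaplan_meier(records: pd.DataFrame) -> KaplanMeier:
    """Kaplan-Meier survivorship for one pooled set of records.

    Censored flies leave the risk set without producing a step.  If no
    deaths occur, S is identically 1 (with a warning).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    entry, exit_, event = _arrays(records)
    death_times = np.unique(exit_[event == 1])
    if death_times.size == 0:
        warnings.warn("all records censored: survivorship is identically 1")
        z = np.array([])
        return KaplanMeier(z, z, z, z, z)
    n_risk = np.array([np.sum((entry < t) & (exit_ >= t)) for t in death_times])
    n_death = np.array([np.sum((exit_ == t) & (event == 1)) for t in death_times])
    frac = 1.0 - n_death / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_risk > n_death,
                                n_death / (n_risk * (n_risk - n_death)), 0.0))
    var = surv**2 * gw
    return KaplanMeier(death_times, surv, var, n_risk, n_death)


def restricted_mean_lifespan(records: pd.DataFrame, horizon: float) -> tuple[float, float]:
    """Restricted-mean lifespan: area under S(t) from age 0 to ``horizon``.

    Returns ``(rmst, se)``; the standard error follows the Greenwood-based
    formula Var = sum_j A_j^2 d_j / (n_j (n_j - d_j)) where A_j is the area
    under S from the j-th event time to the horizon.
    """
    entry, _, _ = _arrays(records)
    if horizon <= entry.max():
        raise ValueError("horizon must exceed the largest entry age")
    km = kaplan_meier(records)
    ts = km.times[km.times < horizon]
    if ts.size == 0:
        return float(horizon), 0.0
    # step integral: S=1 before first event
    edges = np.concatenate([[0.0], ts, [horizon]])
    heights = np.concatenate([[1.0], km.surv[: ts.size]])
    widths = np.diff(edges)
    rmst = float(np.sum(heights * widths))
    # area from each event time to the horizon
    tail = np.cumsum((heights * widths)[::-1])[::-1]  # area from edges[j] to horizon
    a = tail[1:]  # area from t_j to horizon, j over events before horizon
    n_j = km.n_risk[: ts.size].astype(float)
    d_j = km.n_death[: ts.size].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(n_j > d_j, a**2 * d_j / (n_j * (n_j - d_j)), 0.0)
    return rmst, float(np.sqrt(np.sum(contrib)))


def log_rank(records: pd.DataFrame, group_col: str = "fraction") -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across the groups of ``group_col``.

    Returns ``(chi2, df, p)``.  Groups with nobody at risk at a given event
    time contribute nothing there.
    """
    entry, exit_, event = _arrays(records)
    groups = pd.Categorical(records[group_col])
    levels = groups.categories
    if len(levels) < 2:
        raise ValueError("log-rank needs >=2 groups")
    gidx = groups.codes
    times = np.unique(exit_[event == 1])
    G = len(levels)
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in times:
        at_risk = (entry < t) & (exit_ >= t)
        n_j = at_risk.sum()
        if n_j == 0:
            continue
        d_mask = (exit_ == t) & (event == 1)
        d_j = d_mask.sum()
        n_g = np.bincount(gidx[at_risk], minlength=G).astype(float)
        d_g = np.bincount(gidx[d_mask], minlength=G).astype(float)
        O += d_g
        E += d_j * n_g / n_j
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1.0)
            V += c * (np.diag(n_g * n_j) - np.outer(n_g, n_g)) / n_j**2
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    df = G - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Gompertz maximum likelihood


@dataclass
class GompertzFit:
    """Per-group Gompertz MLE."""

    alpha: float
    beta: float
    log_likelihood: float
    n: int
    n_deaths: int
    converged: bool


@dataclass
class GompertzModel:
    """A (possibly multi-group) Gompertz fit.

    ``shared`` is "none" (alpha and beta per group), "beta" (common beta),
    or "all" (one alpha, one beta for everything).
    """

    fits: dict = field(default_factory=dict)
    shared: str = "none"
    log_likelihood: float = 0.0
    n_params: int = 0
    converged: bool = True


def _cum_exposure(beta: float, t: np.ndarray, s: np.ndarray) -> np.ndarray:
    """D = (e^{beta t} - e^{beta s}) / beta, the integral of e^{beta x} over
    [s, t]; alpha * D is the cumulative hazard.  Stable as beta -> 0."""
    u = t - s
    if abs(beta) < 1e-8:
        return u * (1.0 + beta * (t + s) / 2.0)
    return np.exp(beta * s) * np.expm1(beta * u) / beta


def _profile_ll(beta: float, groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                ) -> tuple[float, list[float]]:
    """Log-likelihood at the profile MLE alpha_g = d_g / sum(D_g(beta))."""
    ll = 0.0
    alphas = []
    for s, t, e in groups:
        D = _cum_exposure(beta, t, s)
        d = e.sum()
        sumD = D.sum()
        if d == 0 or sumD <= 0:
            alphas.append(np.nan)
            continue
        a = d / sumD
        alphas.append(a)
        ll += d * np.log(a) + beta * float(t[e == 1].sum()) - d
    return ll, alphas


def _optimize_beta(groups, beta_bounds=(-0.05, 1.0)) -> tuple[float, float, list[float], bool]:
    grid = np.linspace(beta_bounds[0], beta_bounds[1], 60)
    vals = [_profile_ll(b, groups)[0] for b in grid]
    b0 = grid[int(np.argmax(vals))]
    lo = max(beta_bounds[0], b0 - 0.05)
    hi = min(beta_bounds[1], b0 + 0.05)
    res = optimize.minimize_scalar(lambda b: -_profile_ll(b, groups)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    beta = float(res.x)
    ll, alphas = _profile_ll(beta, groups)
    return beta, ll, alphas, bool(res.success)


def _group_ll(alpha: float, beta: float, s, t, e) -> float:
    D = _cum_exposure(beta, t, s)
    return float(e.sum() * np.log(alpha) + beta * t[e == 1].sum() - alpha * D.sum())


def fit_gompertz(
    records: pd.DataFrame,
    shared: str = "none",
    group_col: str = "fraction",
    fix_beta: float | None = None,
) -> GompertzModel:
    """Fit Gompertz mortality by maximum likelihood, per group of
    ``group_col``, with left truncation at entry age and right censoring.

    The per-fly likelihood uses density
    f(t) = alpha e^{beta t} exp(-(alpha/beta)(e^{beta t} - e^{beta entry}))
    for deaths and the matching survivor term for censored flies.  For any
    fixed beta the alpha MLE is deaths / cumulative exposure, so fitting
    profiles alpha out and optimizes over beta alone (per group, shared, or
    with ``fix_beta`` pinning beta, whose beta=0 case is the exponential
    model with alpha-hat = deaths / total exposure).
    """
    if shared not in ("none", "beta", "all"):
        raise ValueError("shared must be 'none', 'beta', or 'all'")
    df = records
    if group_col in df.columns and shared != "all":
        keys = sorted(df[group_col].unique(), key=fraction_to_int
                      if df[group_col].dtype == object else None)
        parts = {k: df[df[group_col] == k] for k in keys}
    else:
        parts = {"all": df}
    arrays = {}
    for k, part in parts.items():
        s, t, e = _arrays(part)
        if e.sum() == 0:
            raise ValueError(f"group {k!r} has no deaths; Gompertz MLE undefined")
        arrays[k] = (s, t, e)

    model = GompertzModel(shared=shared)
    total_ll = 0.0
    if fix_beta is not None:
        for k, (s, t, e) in arrays.items():
            D = _cum_exposure(fix_beta, t, s)
            a = e.sum() / D.sum()
            ll = _group_ll(a, fix_beta, s, t, e)
            model.fits[k] = GompertzFit(a, fix_beta, ll, len(t), int(e.sum()), True)
            total_ll += ll
        model.n_params = len(arrays)
    elif shared in ("beta", "all"):
        beta, ll, alphas, ok = _optimize_beta(list(arrays.values()))
        for (k, (s, t, e)), a in zip(arrays.items(), alphas):
            gll = _group_ll(a, beta, s, t, e)
            model.fits[k] = GompertzFit(a, beta, gll, len(t), int(e.sum()), ok)
        total_ll = ll
        model.n_params = len(arrays) + 1
        model.converged = ok
    else:
        for k, (s, t, e) in arrays.items():
            beta, ll, alphas, ok = _optimize_beta([(s, t, e)])
            model.fits[k] = GompertzFit(alphas[0], beta, ll, len(t), int(e.sum()), ok)
            total_ll += ll
            model.converged &= ok
        model.n_params = 2 * len(arrays)
    if not model.converged:
        warnings.warn("Gompertz optimizer did not report convergence")
    model.log_likelihood = total_ll
    return model


def gompertz_lrt(full: GompertzModel, reduced: GompertzModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Gompertz models.

    Returns ``(chi2, df, p)`` with chi2 = 2 * (ll_full - ll_reduced); a
    materially negative statistic signals optimizer failure.
    """
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if chi2 < -1e-6:
        raise RuntimeError(f"negative LRT statistic ({chi2:.3g}): optimizer failure")
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Aalen additive hazards


@dataclass
class AalenFit:
    """Cumulative regression functions of the additive-hazard model."""

    times: np.ndarray             # event times with usable increments
    cumhaz: np.ndarray            # (T, p) cumulative H_a per covariate
    variance: np.ndarray          # (T, p) pointwise variance estimates
    columns: list
    tests: pd.DataFrame           # per-covariate statistic and p
    skipped_times: list = field(default_factory=list)


def aalen_additive(
    records: pd.DataFrame,
    reference_group=2,
    group_col: str = "fraction",
    test: str = "endpoint",
    n_resample: int = 500,
    seed: int = 0,
) -> AalenFit:
    """Aalen additive-hazard regression with a reference fraction baseline.

    The design is an intercept plus one indicator per non-reference group;
    at each event time the death indicator is least-squares regressed on the
    at-risk design and the increments accumulate into H_a(t).  Pointwise
    variances come from the squared-increment estimator.  The per-covariate
    test is the endpoint statistic z = H_a(tau) / SE(tau) by default
    (``test="sup"`` uses the supremum of |H_a|/SE over event times with a
    sign-flip resampling null).
    """
    entry, exit_, event = _arrays(records)
    groups = records[group_col].to_numpy()
    levels = [g for g in pd.unique(groups)]
    if reference_group not in levels:
        raise ValueError(f"reference group {reference_group!r} absent from data")
    others = sorted([g for g in levels if g != reference_group])
    cols = ["baseline"] + [f"{group_col}={g}" for g in others]
    X_full = np.column_stack(
        [np.ones(len(records))] + [(groups == g).astype(float) for g in others])

    times_all = np.unique(exit_[event == 1])
    incs, vincs, used, skipped = [], [], [], []
    p = X_full.shape[1]
    for t in times_all:
        at_risk = (entry < t) & (exit_ >= t)
        X = X_full[at_risk]
        d = ((exit_ == t) & (event == 1))[at_risk].astype(float)
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < p:
            skipped.append(float(t))
            continue
        Xminus = np.linalg.solve(XtX, X.T)
        incs.append(Xminus @ d)
        vincs.append((Xminus**2 * d) @ np.ones(len(d)))
        used.append(t)
    times = np.array(used)
    if times.size == 0:
        raise ValueError("no estimable event times")
    inc = np.array(incs)
    vinc = np.array(vincs)
    cumhaz = np.cumsum(inc, axis=0)
    variance = np.cumsum(vinc, axis=0)

    se_final = np.sqrt(variance[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "endpoint":
            z = cumhaz[-1] / se_final
            pvals = 2.0 * stats.norm.sf(np.abs(z))
        elif test == "sup":
            se = np.sqrt(np.maximum(variance, 1e-300))
            z_path = np.abs(cumhaz) / se
            z = np.nanmax(z_path, axis=0)
            rng = np.random.default_rng(seed)
            signs = rng.choice([-1.0, 1.0], size=(n_resample, len(times), 1))
            null_paths = np.cumsum(signs * inc[None], axis=1)
            null_sup = np.nanmax(np.abs(null_paths) / se[None], axis=1)
            pvals = (1 + (null_sup >= z).sum(axis=0)) / (1 + n_resample)
        else:
            raise ValueError("test must be 'endpoint' or 'sup'")
    tests = pd.DataFrame({"stat": z, "p": pvals}, index=cols)
    return AalenFit(times, cumhaz, variance, cols, tests, skipped)


# ---------------------------------------------------------------------------
# Velocity mixed model


@dataclass
class VelocityModelFit:
    """Random-intercept LMM fit for climbing velocity."""

    fixed_effects: pd.Series
    se: pd.Series
    p_values: pd.Series
    vial_sd: float
    resid_sd: float
    log_likelihood: float
    n: int


def _lmm_suffstats(X: np.ndarray, y: np.ndarray, vial_codes: np.ndarray):
    order = np.argsort(vial_codes, kind="stable")
    X, y, v = X[order], y[order], vial_codes[order]
    starts = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
    blocks = []
    for i, s0 in enumerate(starts):
        s1 = starts[i + 1] if i + 1 < len(starts) else len(v)
        Xi, yi = X[s0:s1], y[s0:s1]
        blocks.append((Xi.T @ Xi, Xi.T @ yi, float(yi @ yi),
                       Xi.sum(axis=0), float(yi.sum()), s1 - s0))
    return blocks


def _lmm_profile(lam: float, blocks, n: int):
    p = blocks[0][0].shape[0]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for XtX, Xty, yty, x1, y1, ni in blocks:
        c = lam / (1.0 + lam * ni)
        XtVX += XtX - c * np.outer(x1, x1)
        XtVy += Xty - c * x1 * y1
        ytVy += yty - c * y1 * y1
        logdet += np.log1p(lam * ni)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    rss = ytVy - beta @ XtVy
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2, XtVX


def fit_velocity_lmm(
    table: pd.DataFrame,
    response: str = "velocity",
    group: str = "fraction",
    age: str = "age",
    position: str | None = "position",
    batch: str | None = "batch",
    vial: str = "vial",
) -> VelocityModelFit:
    """Fit velocity ~ group + age + group:age [+ position + batch] with a
    vial random intercept, by profiled maximum likelihood.

    For a fixed variance ratio lambda = var_vial / var_resid the GLS
    solution is closed-form, so the fit is a 1-D search over lambda.  With a
    single vial the model degenerates to OLS (with a warning).  Fixed-effect
    p-values are Wald tests on the GLS covariance.
    """
    y = np.asarray(table[response], dtype=float)
    g = np.asarray(table[group], dtype=float)
    a = np.asarray(table[age], dtype=float)
    parts = {"intercept": np.ones(len(y)), group: g, age: a, f"{group}:{age}": g * a}
    for cat in (position, batch):
        if cat is not None and cat in table.columns:
            dummies = pd.get_dummies(table[cat], prefix=cat, drop_first=True)
            for c in dummies.columns:
                parts[c] = dummies[c].to_numpy(dtype=float)
    names = list(parts)
    X = np.column_stack([parts[k] for k in names])
    vials = pd.Categorical(table[vial])
    if len(vials.categories) < 2:
        warnings.warn("only one vial: random intercept unidentified, fitting OLS")
    blocks = _lmm_suffstats(X, y, vials.codes.astype(int))
    n = len(y)

    grid = np.concatenate([[0.0], np.geomspace(1e-4, 1e3, 40)])
    lls = [_lmm_profile(l, blocks, n)[0] for l in grid]
    l0 = grid[int(np.argmax(lls))]
    if l0 > 0:
        res = optimize.minimize_scalar(
            lambda u: -_lmm_profile(np.exp(u), blocks, n)[0],
            bounds=(np.log(max(l0 / 10, 1e-6)), np.log(l0 * 10 + 1e-6)),
            method="bounded", options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        if _lmm_profile(lam, blocks, n)[0] < _lmm_profile(0.0, blocks, n)[0]:
            lam = 0.0
    else:
        lam = 0.0
    ll, beta, sigma2, XtVX = _lmm_profile(lam, blocks, n)
    cov = sigma2 * np.linalg.pinv(XtVX)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(zstat))
    return VelocityModelFit(
        fixed_effects=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        p_values=pd.Series(pv, index=names),
        vial_sd=float(np.sqrt(lam * sigma2)),
        resid_sd=float(np.sqrt(sigma2)),
        log_likelihood=float(ll),
        n=n,
    )


def life_table(records: pd.DataFrame, interval: float = 2.5) -> pd.DataFrame:
    """Interval life table: n at risk, deaths, censored, S and its SE."""
    entry, exit_, event = _arrays(records)
    km = kaplan_meier(records)
    lo = np.floor(entry.min() / interval) * interval
    hi = np.ceil(exit_.max() / interval) * interval
    edges = np.arange(lo, hi + interval, interval)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        at_risk = int(np.sum((entry < a + 1e-9) & (exit_ >= a)))
        deaths = int(np.sum((exit_ >= a) & (exit_ < b) & (event == 1)))
        cens = int(np.sum((exit_ >= a) & (exit_ < b) & (event == 0)))
        s = float(km.evaluate(b - 1e-9)[0]) if km.times.size else 1.0
        idx = np.searchsorted(km.times, b - 1e-9, side="right") - 1
        se = float(np.sqrt(km.var[idx])) if idx >= 0 and km.times.size else 0.0
        rows.append({"age_lo": a, "age_hi": b, "n_risk": at_risk,
                     "deaths": deaths, "censored": cens, "S": s, "SE": se})
    return pd.DataFrame(rows)
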
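"""Ordinal metabolome screens.

Single-metabolite screen
    For each metabolite, the ordinal climbing fraction is regressed on age
    (categorical Week 4 / Week 6), the metabolite, and their interaction in
    a cumulative-logit mixed model with a replicate random intercept.
    Likelihood-ratio tests against the nested models give per-metabolite
    p-values for the metabolite main effect and for the metabolite-by-age
    interaction, each BH-corrected across metabolites.

Pair-interaction (differential-covariance) screen
    Fraction and age main effects are first removed from each metabolite by
    least squares; for every metabolite pair (i, k) the ordinal fraction is
    then regressed on the two residuals and their product in a fixed-effects
    cumulative-logit model, and the product term is LRT-tested.  A
    significant product term means the pair's covariance pattern changes
    along the ordinal climbing axis.  The FDR family is either the
    correlation-prefiltered pairs (default, mirroring a screen restricted
    to pairs that covary at all) or all N(N-1)/2 pairs.

Label-permutation null
    Climbing-fraction labels are permuted across samples, preserving the
    within-sample metabolite covariance, and the full pair screen is re-run
    per permutation.  The count of FDR-significant pairs forms the
    (discrete) null; a continuous family statistic (sum of the pair LRT
    chi-squares) is tracked alongside because its permutation p-value is
    exactly lattice-uniform under the null, while the count-based one is
    conservative wherever counts tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covnet import pearson_matrix
from .fractionation import fraction_to_int
from .ordinal import fit_clmm, fit_cumlogit_batch
from .preprocess import MetabolomeMatrix

__all__ = [
    "bh_fdr",
    "residualize_main_effects",
    "screen_single_metabolites",
    "screen_pair_interactions",
    "PermutationNull",
    "permutation_null_pairs",
]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    NaN p-values propagate as NaN and are excluded from the ranking.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def residualize_main_effects(
    matrix: pd.DataFrame,
    fraction: np.ndarray,
    age: np.ndarray,
) -> pd.DataFrame:
    """Remove fraction, age, and fraction-by-age means from each metabolite.

    With both factors categorical plus their interaction, the least-squares
    fit is the fraction-by-age cell-mean model, so the residual is simply
    each value minus its cell mean; residuals have exactly zero mean in
    every occupied cell, and empty cells need no special handling.
    """
    frac = np.asarray([fraction_to_int(f) for f in np.asarray(fraction)])
    age = np.asarray(age)
    cell = pd.Series([f"{f}|{a}" for f, a in zip(frac, age)], index=matrix.index)
    return matrix - matrix.groupby(cell).transform("mean")


def _design_codes(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frac = meta["fraction"].map(fraction_to_int).to_numpy()
    ages = np.unique(meta["age_week"])
    age_ind = (meta["age_week"].to_numpy() == ages.max()).astype(float)
    rep = meta["replicate"].to_numpy()
    return frac, age_ind, rep


def screen_single_metabolites(
    mm: MetabolomeMatrix,
    fdr: float = 0.05,
    quad_order: int = 10,
) -> pd.DataFrame:
    """Per-metabolite ordinal screen with replicate random intercept.

    Returns a DataFrame (one row per metabolite) with the metabolite
    main-effect LRT (``chi2_met, p_met, q_met``), the metabolite-by-age
    interaction LRT (``chi2_int, p_int, q_int``), the main-effect direction
    (``beta_met`` > 0: higher abundance predicts higher climbing), and a
    ``converged`` flag; non-converged fits are excluded from the FDR family.
    """
    frac, age_ind, rep = _design_codes(mm.meta)
    x = mm.data.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)

    null = fit_clmm(frac, age_ind[:, None], rep, n_levels=5, quad_order=quad_order)
    rows = []
    for j, name in enumerate(mm.data.columns):
        met = x[:, j]
        X_red = np.column_stack([age_ind, met])
        X_full = np.column_stack([age_ind, met, age_ind * met])
        red = fit_clmm(frac, X_red, rep, n_levels=5, quad_order=quad_order)
        full = fit_clmm(frac, X_full, rep, n_levels=5, quad_order=quad_order)
        ok = red.converged and full.converged and null.converged \
            and not (red.separation or full.separation)
        chi_met = max(2.0 * (red.log_likelihood - null.log_likelihood), 0.0)
        chi_int = max(2.0 * (full.log_likelihood - red.log_likelihood), 0.0)
        rows.append(
            {
                "metabolite": name,
                "beta_met": red.beta[1],
                "chi2_met": chi_met,
                "p_met": stats.chi2.sf(chi_met, 1) if ok else np.nan,
                "chi2_int": chi_int,
                "p_int": stats.chi2.sf(chi_int, 1) if ok else np.nan,
                "sigma_rep": red.sigma,
                "converged": ok,
            }
        )
    out = pd.DataFrame(rows)
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} metabolite fits excluded from the FDR family")
    out["q_met"] = bh_fdr(out["p_met"].to_numpy())
    out["q_int"] = bh_fdr(out["p_int"].to_numpy())
    out["significant"] = out["q_met"] <= fdr
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    return (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _pair_lrt_batch(resid_z: np.ndarray, frac: np.ndarray,
                    pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LRT chi-square (and validity flag) of the product term for each pair.

    ``resid_z`` is the standardized residual matrix, ``pairs`` an (m, 2)
    index array; the batched Newton fitter handles all pairs at once.
    """
    if len(pairs) == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    zi = resid_z[:, pairs[:, 0]].T          # (m, n)
    zk = resid_z[:, pairs[:, 1]].T
    prod = _standardize((zi * zk).T).T
    X_full = np.stack([zi, zk, prod], axis=2)
    X_red = X_full[:, :, :2]
    y = np.broadcast_to(frac, (len(pairs), len(frac)))
    full = fit_cumlogit_batch(X_full, y, n_levels=5)
    red = fit_cumlogit_batch(X_red, y, n_levels=5)
    chi2 = np.maximum(2.0 * (full["loglik"] - red["loglik"]), 0.0)
    ok = full["converged"] & red["converged"] & ~full["separation"] & ~red["separation"]
    return chi2, ok


def screen_pair_interactions(
    residuals: pd.DataFrame,
    meta: pd.DataFrame,
    family: str = "prefiltered",
    fdr: float = 0.05,
    corr_fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential-covariance screen over metabolite pairs.

    ``residuals`` is the main-effect-residualized matrix (see
    :func:`residualize_main_effects`).  With ``family="prefiltered"`` only
    pairs whose overall Pearson correlation passes BH FDR ``corr_fdr`` enter
    the interaction-test family; ``family="all"`` tests every pair.
    Returns one row per family pair with correlation and interaction
    statistics plus per-fraction correlations; results are symmetric in
    (i, k) and reported with i < k.
    """
    if family not in ("prefiltered", "all"):
        raise ValueError("family must be 'prefiltered' or 'all'")
    frac = meta["fraction"].map(fraction_to_int).to_numpy()
    x = residuals.to_numpy(dtype=float)
    names = list(residuals.columns)
    n, m = x.shape

    r_all, p_all = pearson_matrix(x)
    iu = np.triu_indices(m, k=1)
    q_all = np.full(len(iu[0]), np.nan)
    finite = np.isfinite(p_all[iu])
    q_all[finite] = bh_fdr(p_all[iu][finite])

    if family == "prefiltered":
        keep = finite & (q_all <= corr_fdr)
    else:
        keep = finite
    pairs = np.column_stack([iu[0][keep], iu[1][keep]])

    z = _standardize(x)
    chi2, ok = _pair_lrt_batch(z, frac, pairs)
    p_int = np.where(ok, stats.chi2.sf(chi2, 1), np.nan)
    if len(ok) and (~ok).any():
        warnings.warn(f"{int((~ok).sum())} pair fits excluded from the FDR family")

    out = pd.DataFrame(
        {
            "i": pairs[:, 0],
            "k": pairs[:, 1],
            "met_i": [names[a] for a in pairs[:, 0]],
            "met_k": [names[b] for b in pairs[:, 1]],
            "r": r_all[pairs[:, 0], pairs[:, 1]] if len(pairs) else [],
            "p_corr": p_all[pairs[:, 0], pairs[:, 1]] if len(pairs) else [],
            "q_corr": q_all[keep],
            "lrt_chi2": chi2,
            "p_int": p_int,
        }
    )
    out["q_int"] = bh_fdr(out["p_int"].to_numpy()) if len(out) else pd.Series(dtype=float)
    out["significant"] = out["q_int"] <= fdr
    for f in range(5):
        sel = frac == f
        if sel.sum() >= 4 and len(pairs):
            rs, ps = [], []
            for a, b in pairs:
                r_, p_ = stats.pearsonr(x[sel, a], x[sel, b])
                rs.append(r_)
                ps.append(p_)
            out[f"r_f{f}"] = rs
            out[f"p_f{f}"] = ps
        else:
            out[f"r_f{f}"] = np.nan
            out[f"p_f{f}"] = np.nan
    return out


@dataclass
class PermutationNull:
    """Result of the climbing-label permutation test for the pair screen."""

    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    null_mean: float
    observed_chi2_sum: float
    null_chi2_sums: np.ndarray
    empirical_p_chi2: float
    n_perm: int


def _screen_counts(x: np.ndarray, frac: np.ndarray, age: np.ndarray,
                   family: str, fdr: float, corr_fdr: float) -> tuple[int, float]:
    """Discovery count and chi2-sum for one labelling (helper for the
    permutation loop); mirrors screen_pair_interactions without the
    per-fraction reporting."""
    # fraction-by-age cell demeaning, pure numpy for the permutation loop
    _, cell = np.unique(np.asarray(frac) * 1000 + np.asarray(age), return_inverse=True)
    ncell = cell.max() + 1
    counts = np.bincount(cell, minlength=ncell).astype(float)
    sums = np.zeros((ncell, x.shape[1]))
    np.add.at(sums, cell, x)
    resid = x - sums[cell] / counts[cell, None]
    m = x.shape[1]
    iu = np.triu_indices(m, k=1)
    if family == "prefiltered":
        _, p_all = pearson_matrix(resid)
        pv = p_all[iu]
        finite = np.isfinite(pv)
        q = np.full(pv.shape, np.nan)
        q[finite] = bh_fdr(pv[finite])
        keep = finite & (q <= corr_fdr)
    else:
        keep = np.ones(len(iu[0]), dtype=bool)
    pairs = np.column_stack([iu[0][keep], iu[1][keep]])
    chi2, ok = _pair_lrt_batch(_standardize(resid), frac, pairs)
    pv_int = np.where(ok, stats.chi2.sf(chi2, 1), np.nan)
    q_int = bh_fdr(pv_int) if len(pv_int) else np.empty(0)
    count = int(np.nansum(q_int <= fdr)) if len(q_int) else 0
    return count, float(chi2[ok].sum()) if len(chi2) else 0.0


def permutation_null_pairs(
    mm: MetabolomeMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    family: str = "prefiltered",
    fdr: float = 0.05,
    corr_fdr: float = 0.05,
) -> PermutationNull:
    """Permute climbing-fraction labels across samples and re-run the full
    pair screen each time.

    Empirical p-values use the add-one convention
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: empirical p is unstable")
    frac = mm.meta["fraction"].map(fraction_to_int).to_numpy()
    age = mm.meta["age_week"].to_numpy()
    x = mm.data.to_numpy(dtype=float)

    obs_count, obs_chi2 = _screen_counts(x, frac, age, family, fdr, corr_fdr)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    chi2s = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(frac))
        counts[b], chi2s[b] = _screen_counts(x, frac[perm], age, family, fdr, corr_fdr)
    p_count = (1 + int((counts >= obs_count).sum())) / (1 + n_perm)
    p_chi2 = (1 + int((chi2s >= obs_chi2).sum())) / (1 + n_perm)
    return PermutationNull(obs_count, counts, p_count, float(counts.mean()),
                           obs_chi2, chi2s, p_chi2, n_perm)
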
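"""Metabolome normalization and QC.

The processing chain is ordered and enforced:

    raw -> log_center -> correct_batch -> residualize_run_order
        -> remove_outliers -> (PCA / downstream screens)

* ``log_center``: natural-log transform, then subtract each sample's row
  mean (log2 available via ``base=2``).
* ``correct_batch``: location/scale batch adjustment with parametric
  empirical-Bayes shrinkage of per-batch effects toward a cross-metabolite
  prior (normal prior on additive effects, inverse-gamma on multiplicative
  ones), the canonical ComBat-style algorithm.  ``shrink=False`` reduces to
  plain per-batch standardization in the standardized space.
* ``residualize_run_order``: per-metabolite simple linear regression on
  injection order; residuals keep their original column means.
* ``remove_outliers``: Mahalanobis distance of each sample in PC1-4 score
  space; samples farther than 4 SD above the mean distance are dropped.
* ``pca_tw``: PCA on metabolite-scaled data with sequential Tracy-Widom
  (beta=1) significance for the leading eigenvalues at alpha = 0.01, using
  Patterson-style effective-size standardization and an embedded quantile
  table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetabolomeMatrix",
    "log_center",
    "correct_batch",
    "residualize_run_order",
    "remove_outliers",
    "PCAResult",
    "pca_tw",
    "preprocess_pipeline",
]

_STATES = ["raw", "centered", "batch_corrected", "residualized", "qc_filtered"]


@dataclass
class MetabolomeMatrix:
    """A samples x metabolites matrix plus per-sample metadata and a
    processing-state flag; state transitions are monotone along the chain
    raw -> centered -> batch_corrected -> residualized -> qc_filtered."""

    data: pd.DataFrame
    meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.data.index.equals(self.meta.index):
            raise ValueError("matrix and metadata indexes differ")
        needed = {"age_week", "fraction", "replicate", "batch", "run_order"}
        missing = needed - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        if self.meta[sorted(needed)].isna().any().any():
            raise ValueError("metadata contains missing values")
        dup = self.meta.groupby("batch")["run_order"].apply(lambda s: s.duplicated().any())
        if dup.any():
            raise ValueError("run_order must be unique within each batch")

    def _require(self, state: str) -> None:
        if _STATES.index(self.state) != _STATES.index(state):
            raise ValueError(
                f"pipeline order violated: operation expects state {state!r}, "
                f"matrix is {self.state!r}"
            )


def log_center(mm: MetabolomeMatrix, base: float | None = None) -> MetabolomeMatrix:
    """Log-transform (natural log by default) and mean-center each sample.

    Raw values must be strictly positive; the first offending cell is named
    in the error.
    """
    mm._require("raw")
    x = mm.data.to_numpy(dtype=float)
    bad = np.argwhere(x <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive raw abundance at sample {mm.data.index[i]!r}, "
            f"metabolite {mm.data.columns[j]!r}: cannot log-transform"
        )
    lx = np.log(x) if base is None else np.log(x) / np.log(base)
    lx = lx - lx.mean(axis=1, keepdims=True)
    return MetabolomeMatrix(pd.DataFrame(lx, index=mm.data.index, columns=mm.data.columns),
                            mm.meta, "centered")


def _eb_iterate(z_sum, z_sumsq, n_b, gamma_hat, delta2_hat, gamma_bar, tau2,
                a_prior, b_prior, tol=1e-6, max_iter=500):
    """Standard parametric EB iteration for batch location/scale effects."""
    g_star = gamma_hat.copy()
    d_star = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + d_star * gamma_bar) / (n_b * tau2 + d_star)
        sum2 = z_sumsq - 2.0 * g_new * z_sum + n_b * g_new**2
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - g_star)), np.max(np.abs(d_new - d_star)))
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def correct_batch(mm: MetabolomeMatrix, shrink: bool = True) -> MetabolomeMatrix:
    """Remove extraction-batch location/scale effects.

    Per metabolite: standardize against the pooled mean and variance,
    estimate per-batch additive and multiplicative effects, shrink them
    toward the cross-metabolite prior by the parametric EB iteration
    (``shrink=False`` uses the raw per-batch estimates), and back-adjust.
    A single batch leaves the data unchanged; a batch with one sample gets
    its scale adjustment disabled (logged).
    """
    mm._require("centered")
    batches = pd.Categorical(mm.meta["batch"])
    levels = list(batches.categories)
    x = mm.data.to_numpy(dtype=float)
    if len(levels) <= 1:
        return MetabolomeMatrix(mm.data.copy(), mm.meta, "batch_corrected")

    codes = batches.codes
    n, m = x.shape
    n_b = np.bincount(codes, minlength=len(levels)).astype(float)
    batch_mean = np.stack([x[codes == b].mean(axis=0) for b in range(len(levels))])
    grand = (n_b[:, None] * batch_mean).sum(axis=0) / n
    resid = x - batch_mean[codes]
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.maximum(var_pooled, 1e-30)
    sd = np.sqrt(var_pooled)
    z = (x - grand) / sd

    z_adj = np.empty_like(z)
    for b in range(len(levels)):
        mask = codes == b
        zb = z[mask]
        gamma_hat = zb.mean(axis=0)
        if n_b[b] < 2:
            warnings.warn(
                f"batch {levels[b]!r} has a single sample: scale adjustment disabled")
            delta2_hat = np.ones(m)
            scale_ok = False
        else:
            # population (ddof=0) variance keeps the location/scale step
            # exactly idempotent against the 1/n pooled variance
            delta2_hat = zb.var(axis=0, ddof=0)
            scale_ok = True
        if shrink and scale_ok:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            M = delta2_hat.mean()
            V = delta2_hat.var(ddof=1)
            a_prior = (2.0 * V + M**2) / V
            b_prior = (M * V + M**3) / V
            g_star, d_star = _eb_iterate(zb.sum(axis=0), (zb**2).sum(axis=0),
                                         n_b[b], gamma_hat, delta2_hat,
                                         gamma_bar, tau2, a_prior, b_prior)
        else:
            g_star, d_star = gamma_hat, delta2_hat
        z_adj[mask] = (zb - g_star) / np.sqrt(np.maximum(d_star, 1e-30))

    out = z_adj * sd + grand
    return MetabolomeMatrix(pd.DataFrame(out, index=mm.data.index, columns=mm.data.columns),
                            mm.meta, "batch_corrected")


def residualize_run_order(mm: MetabolomeMatrix) -> MetabolomeMatrix:
    """Regress each metabolite on LC-MS run order and keep the residuals,
    restoring the original column means."""
    mm._require("batch_corrected")
    order = mm.meta["run_order"].to_numpy(dtype=float)
    x = mm.data.to_numpy(dtype=float)
    oc = order - order.mean()
    denom = float(oc @ oc)
    if denom == 0.0:
        warnings.warn("constant run order: residualization is the identity")
        return MetabolomeMatrix(mm.data.copy(), mm.meta, "residualized")
    slope = (oc @ (x - x.mean(axis=0))) / denom
    out = x - np.outer(oc, slope)
    return MetabolomeMatrix(pd.DataFrame(out, index=mm.data.index, columns=mm.data.columns),
                            mm.meta, "residualized")


def _pc_scores(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores and eigenvalues of metabolite-scaled PCA (top k components)."""
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0, ddof=1)
    xs = xs / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    ev = s**2 / (x.shape[0] - 1)
    k = min(k, np.sum(s > 1e-10))
    return u[:, :k] * s[:k], ev[:k]


def remove_outliers(mm: MetabolomeMatrix, n_pcs: int = 4, n_sd: float = 4.0,
                    ) -> tuple[MetabolomeMatrix, list]:
    """Drop samples whose Mahalanobis distance in PC1-4 score space exceeds
    the mean distance by more than ``n_sd`` standard deviations.

    Computed once (not iteratively).  With fewer than ``n_pcs`` informative
    components all available ones are used (logged).  Returns the filtered
    matrix and the list of removed sample ids.
    """
    mm._require("residualized")
    x = mm.data.to_numpy(dtype=float)
    if x.shape[0] < 6:
        raise ValueError("need at least 6 samples for outlier screening")
    scores, ev = _pc_scores(x, n_pcs)
    if scores.shape[1] < n_pcs:
        warnings.warn(f"only {scores.shape[1]} informative PCs available")
    d = np.sqrt(np.sum(scores**2 / ev, axis=1))
    cut = d.mean() + n_sd * d.std(ddof=1)
    removed = list(mm.data.index[d > cut])
    keep = ~mm.data.index.isin(removed)
    return (
        MetabolomeMatrix(mm.data.loc[keep], mm.meta.loc[keep], "qc_filtered"),
        removed,
    )


# Tracy-Widom (beta=1) upper-tail quantiles, tail probability -> statistic.
_TW1_TAIL = np.array([
    [0.10, 0.4501],
    [0.05, 0.9793],
    [0.025, 1.4538],
    [0.01, 2.0234],
    [0.005, 2.4224],
    [0.001, 3.2724],
])


def _tw_pvalue(stat: float) -> float:
    """Upper-tail p for a TW(beta=1) statistic by log-interpolation of the
    embedded quantile table; clamped outside the table's range."""
    xs = _TW1_TAIL[:, 1]
    logp = np.log(_TW1_TAIL[:, 0])
    if stat < xs[0]:
        return 1.0  # beyond the table: only "not small" is claimed
    if stat >= xs[-1]:
        return 0.001
    return float(np.exp(np.interp(stat, xs, logp)))


def _tw_quantile(alpha: float) -> float:
    logp = np.log(_TW1_TAIL[:, 0])[::-1]
    xs = _TW1_TAIL[:, 1][::-1]
    return float(np.interp(np.log(alpha), logp, xs))


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    tw_stats: np.ndarray
    tw_pvalues: np.ndarray
    n_significant: int
    alpha: float = 0.01
    removed_samples: list = field(default_factory=list)


def pca_tw(mm: MetabolomeMatrix, alpha: float = 0.01) -> PCAResult:
    """PCA on metabolite-scaled data with sequential Tracy-Widom tests.

    Eigenvalues of the sample correlation structure are standardized with
    the Patterson effective-size formulas and compared, from the top down,
    to TW(beta=1) quantiles; ``n_significant`` counts the leading run that
    passes at ``alpha``.  More metabolites than samples is handled through
    the SVD duality automatically.
    """
    if mm.state == "raw":
        raise ValueError("run log_center before PCA")
    x = mm.data.to_numpy(dtype=float)
    n, p = x.shape
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0, ddof=1)
    xs = xs / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    ev = s**2 / (n - 1)
    r = int(np.sum(s > 1e-9 * s[0]))
    ev = ev[:r]
    scores = pd.DataFrame(u[:, :r] * s[:r], index=mm.data.index,
                          columns=[f"PC{i+1}" for i in range(r)])
    loadings = pd.DataFrame(vt[:r].T, index=mm.data.columns, columns=scores.columns)
    var_frac = ev / (s**2 / (n - 1)).sum()

    tw_stats = np.full(r, np.nan)
    tw_p = np.full(r, np.nan)
    for i in range(r - 1):
        tail = ev[i:]
        m = tail.size
        S, S2 = tail.sum(), (tail**2).sum()
        denom = m * S2 - S**2
        if denom <= 0:
            break
        n_hat = (m + 2) * S**2 / denom
        ell = m * tail[0] / S
        sq_n = np.sqrt(max(n_hat - 1.0, 1e-12))
        sq_m = np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_hat
        sigma = (sq_n + sq_m) / n_hat * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        tw_stats[i] = (ell - mu) / sigma
        tw_p[i] = _tw_pvalue(tw_stats[i])

    crit = _tw_quantile(alpha)
    n_sig = 0
    for i in range(r):
        if np.isfinite(tw_stats[i]) and tw_stats[i] > crit:
            n_sig += 1
        else:
            break
    return PCAResult(scores, loadings, ev, var_frac, tw_stats, tw_p, n_sig, alpha)


def preprocess_pipeline(matrix: pd.DataFrame, meta: pd.DataFrame,
                        log: bool = True, shrink: bool = True,
                        n_sd: float = 4.0) -> tuple[MetabolomeMatrix, dict]:
    """Run the full chain on a raw (or already log-scale) matrix.

    Returns the QC-filtered matrix and a QC report dict (removed samples,
    per-batch effect magnitudes, eigenvalue table).
    """
    state = "raw" if log else "centered"
    mm = MetabolomeMatrix(matrix, meta, state)
    if log:
        mm = log_center(mm)
    pre_batch_means = mm.data.groupby(meta["batch"]).mean().mean(axis=1)
    mm = correct_batch(mm, shrink=shrink)
    mm = residualize_run_order(mm)
    mm, removed = remove_outliers(mm, n_sd=n_sd)
    pca = pca_tw(mm)
    report = {
        "n_samples_in": int(len(matrix)),
        "n_samples_out": int(len(mm.data)),
        "removed_samples": removed,
        "batch_mean_offsets": {str(k): float(v) for k, v in pre_batch_means.items()},
        "n_significant_pcs": int(pca.n_significant),
        "variance_fractions": [float(v) for v in pca.variance_fractions[:10]],
    }
    return mm, report
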
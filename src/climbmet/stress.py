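"""Bang-assay analysis: proportion transform and beta regression.

The bang (mechanical-stress) assay scores the proportion of flies alive
24 h after vortexing.  Per-vial proportions y in [0, 1] are shrunk to the
open interval by

    y' = (y * (n - 1) + 0.5) / n

(n = flies in the vial), then modelled by beta regression with a logit
mean link and constant precision phi.  The climbing-fraction effect is
tested by a likelihood-ratio test between nested mean models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["transform_proportion", "BetaRegFit", "fit_betareg", "fraction_effect_lrt"]


def transform_proportion(y, n):
    """Interior-shrunk proportion y' = (y*(n-1) + 0.5) / n.

    Maps [0, 1] into (0, 1) for any n >= 1 and is strictly monotone in y
    for n >= 2 (a single-fly vial carries no gradation: y' = 1/2).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("vial counts must be >= 1")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return (y * (n - 1.0) + 0.5) / n


@dataclass
class BetaRegFit:
    """Beta regression fit (logit mean link, constant precision)."""

    coef: pd.Series
    se: pd.Series
    phi: float
    log_likelihood: float
    converged: bool
    n: int

    def fitted_mean(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(np.asarray(X, dtype=float) @ self.coef.to_numpy())


def _betareg_fit(y: np.ndarray, X: np.ndarray, names: list[str]) -> BetaRegFit:
    from statsmodels.othermod.betareg import BetaModel

    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta regression needs responses strictly inside (0, 1)")
    eps = np.finfo(float).eps
    if np.any((y < 8 * eps) | (y > 1 - 8 * eps)):
        raise ValueError("responses at machine boundary; transform them first")
    model = BetaModel(y, X, exog_precision=np.ones((len(y), 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=500)
    conv = bool(getattr(res.mle_retvals, "get", lambda *_: True)("converged", True)) \
        if isinstance(res.mle_retvals, dict) else True
    if not conv:
        warnings.warn("beta regression did not converge")
    k = X.shape[1]
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    return BetaRegFit(
        coef=pd.Series(params[:k], index=names),
        se=pd.Series(bse[:k], index=names),
        phi=float(np.exp(params[k])),
        log_likelihood=float(res.llf),
        converged=conv,
        n=len(y),
    )


def _design(df: pd.DataFrame, fraction_coding: str, with_fraction: bool) -> tuple[np.ndarray, list[str]]:
    from .fractionation import fraction_to_int

    frac = df["fraction"].map(fraction_to_int).to_numpy(dtype=float)
    shaken = (df["treatment"].astype(str) == "vortex").astype(float).to_numpy()
    cols = {"intercept": np.ones(len(df))}
    if with_fraction:
        if fraction_coding == "ordinal":
            cols["fraction"] = frac
            cols["treatment"] = shaken
            cols["fraction:treatment"] = frac * shaken
        elif fraction_coding == "categorical":
            for f in sorted(np.unique(frac))[1:]:
                cols[f"fraction={int(f)}"] = (frac == f).astype(float)
            cols["treatment"] = shaken
            for f in sorted(np.unique(frac))[1:]:
                cols[f"fraction={int(f)}:treatment"] = (frac == f).astype(float) * shaken
        else:
            raise ValueError("fraction_coding must be 'ordinal' or 'categorical'")
    else:
        cols["treatment"] = shaken
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def fit_betareg(counts: pd.DataFrame, fraction_coding: str = "ordinal") -> BetaRegFit:
    """Fit survival-proportion ~ fraction + treatment + fraction:treatment.

    ``counts`` columns: vial, fraction, treatment ('vortex'/'control'),
    n_flies, n_alive_24h.  The ordinal coding (default) enters fraction as
    0..4, expressing the monotone trend; ``fraction_coding="categorical"``
    uses indicators.
    """
    y = transform_proportion(counts["n_alive_24h"] / counts["n_flies"], counts["n_flies"])
    X, names = _design(counts, fraction_coding, with_fraction=True)
    return _betareg_fit(y, X, names)


def fraction_effect_lrt(counts: pd.DataFrame, fraction_coding: str = "ordinal",
                        ) -> tuple[float, int, float]:
    """LRT for any climbing-fraction effect on post-trauma survival.

    Compares the full model (fraction + treatment + fraction:treatment)
    against treatment-only; returns (chi2, df, p).
    """
    y = transform_proportion(counts["n_alive_24h"] / counts["n_flies"], counts["n_flies"])
    X_full, names_f = _design(counts, fraction_coding, with_fraction=True)
    X_red, names_r = _design(counts, fraction_coding, with_fraction=False)
    full = _betareg_fit(y, X_full, names_f)
    red = _betareg_fit(y, X_red, names_r)
    df = len(names_f) - len(names_r)
    chi2 = max(2.0 * (full.log_likelihood - red.log_likelihood), 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))
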
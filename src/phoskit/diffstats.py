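"""Two-group differential testing with empirical-Bayes variance moderation.

Per feature, a (weighted) least-squares two-group model is fit to the
per-channel log2 ratios: the effect is the treatment-mean minus the
control-mean, with residual variance s2 on d = n_obs - 2 degrees of
freedom.  Residual variances are then shrunk toward a pooled prior: the
s2 are modeled as scaled inverse-chi-square draws around a prior variance
s0^2 with d0 prior degrees of freedom, estimated by method of moments on
log s2 using digamma/trigamma moment matching (Newton inversion of the
trigamma function).  The moderated t statistic

    t = beta / sqrt(s2_post * v),   s2_post = (d0*s0^2 + d*s2) / (d0 + d)

is referred to a t distribution with d0 + d degrees of freedom (normal
when d0 is infinite), v being the sum of inverse effective group sizes.
P-values are two-sided and adjusted by the Benjamini-Hochberg step-up;
features with adjusted p <= alpha are called significant, with direction
given by the sign of the effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateDataError
from .ingest import Design

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "log2fc",
    "s2",
    "df",
    "t_mod",
    "p_value",
    "p_adj",
    "direction",
    "significant",
]


# ---------------------------------------------------------------------------
# per-feature least squares


def fit_feature_model(
    values: np.ndarray,
    design: Design,
    weights: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Weighted least-squares two-group fit of one feature's ratio row.

    ``values`` is ordered by ``design.channels``.  Returns
    (beta, s2, d): the difference of (weighted) group means, the residual
    variance, and the residual degrees of freedom d = n_obs - 2.  With all
    weights equal this is the pooled two-sample estimator.

    Raises DegenerateDataError when either condition has fewer than two
    usable observations.
    """
    values = np.asarray(values, dtype=float)
    w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    is_treat = np.array([design.conditions[c] == "treatment" for c in design.channels])
    ok = np.isfinite(values) & (w > 0)
    n_c = int(np.sum(ok & ~is_treat))
    n_t = int(np.sum(ok & is_treat))
    if n_c < 2 or n_t < 2:
        raise DegenerateDataError(
            f"insufficient data: {n_c} control / {n_t} treatment observations (need >= 2 each)"
        )
    wc = np.where(ok & ~is_treat, w, 0.0)
    wt = np.where(ok & is_treat, w, 0.0)
    v = np.nan_to_num(values)
    mean_c = np.sum(wc * v) / np.sum(wc)
    mean_t = np.sum(wt * v) / np.sum(wt)
    beta = mean_t - mean_c
    fitted = np.where(is_treat, mean_t, mean_c)
    resid = np.where(ok, v - fitted, 0.0)
    d = n_c + n_t - 2
    s2 = float(np.sum(w * np.where(ok, resid, 0.0) ** 2) / d)
    return float(beta), s2, d


def fit_all_features(
    matrix: pd.DataFrame,
    design: Design,
    weights: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list]:
    """Vectorized two-group fits over a features x channels matrix.

    Returns (frame with columns log2fc, s2, df, v; list of skipped feature
    ids with insufficient observations).  ``v`` is the per-feature sum of
    inverse effective group sizes, 1/sum(w_control) + 1/sum(w_treatment).
    """
    cols = design.channels
    X = matrix[cols].to_numpy(dtype=float)
    W = (
        np.ones_like(X)
        if weights is None
        else weights.reindex(index=matrix.index, columns=cols).to_numpy(dtype=float)
    )
    is_treat = np.array([design.conditions[c] == "treatment" for c in cols])
    ok = np.isfinite(X) & (W > 0)
    Wm = np.where(ok, W, 0.0)
    Xm = np.nan_to_num(X)

    n_c = np.sum(ok & ~is_treat, axis=1)
    n_t = np.sum(ok & is_treat, axis=1)
    usable = (n_c >= 2) & (n_t >= 2)

    wc = Wm * ~is_treat
    wt = Wm * is_treat
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_wc = wc.sum(axis=1)
        sum_wt = wt.sum(axis=1)
        mean_c = (wc * Xm).sum(axis=1) / sum_wc
        mean_t = (wt * Xm).sum(axis=1) / sum_wt
        beta = mean_t - mean_c
        fitted = np.where(is_treat, mean_t[:, None], mean_c[:, None])
        resid2 = np.where(ok, Xm - fitted, 0.0) ** 2
        d = n_c + n_t - 2
        s2 = (Wm * resid2).sum(axis=1) / d
        v = 1.0 / sum_wc + 1.0 / sum_wt

    out = pd.DataFrame(
        {"log2fc": beta, "s2": s2, "df": d, "v": v}, index=matrix.index
    )[usable]
    skipped = list(matrix.index[~usable])
    if skipped:
        logger.info("%d features skipped: insufficient per-group observations", len(skipped))
    return out, skipped


# ---------------------------------------------------------------------------
# empirical-Bayes prior


@dataclass(frozen=True)
class ModerationPrior:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ConfigError(f"prior d0 must be > 0, got {self.d0}")
        if not self.s0_sq > 0:
            raise ConfigError(f"prior s0_sq must be > 0, got {self.s0_sq}")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone transformation update x <- x + tri*(1 - tri/y)/tetra
    which converges for all y > 0.
    """
    if y <= 0:
        raise ValueError(f"trigamma_inverse requires y > 0, got {y}")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * max(x, 1.0):
            break
    return x


def estimate_prior(s2: np.ndarray, d: np.ndarray) -> ModerationPrior:
    """Method-of-moments fit of (d0, s0_sq) from residual variances.

    Works on e_g = log s2_g - psi(d_g/2) + log(d_g/2), whose mean and
    excess spread identify the prior:  solve
    trigamma(d0/2) = var(e) - mean(trigamma(d_g/2)); if the spread does
    not exceed the sampling contribution, d0 = inf and s0_sq = exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if int(ok.sum()) == 0:
        raise DegenerateDataError("all residual variances are zero or unusable")
    if int(ok.sum()) < 2:
        raise DegenerateDataError("need >= 2 features with positive residual variance")
    n_zero = int(np.sum(np.isfinite(s2) & (s2 <= 0)))
    if n_zero:
        logger.info("%d features with zero residual variance excluded from prior", n_zero)
    s2, d = s2[ok], d[ok]
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(np.mean(special.polygamma(1, d / 2.0)))
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderation and p-values


def moderate(
    beta: np.ndarray,
    s2: np.ndarray,
    d: np.ndarray,
    prior: ModerationPrior | None,
    v: np.ndarray | float,
    d0_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    ``v`` is the design scale, 1/n_c + 1/n_t (inverse effective group
    sizes).  ``d0_override`` permits d0 = 0, under which moderation
    vanishes and the classical pooled two-sample t is recovered.
    Returns (t_mod, p, s2_post).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float), beta.shape)
    if d0_override is not None:
        d0, s0_sq = d0_override, (prior.s0_sq if prior else 1.0)
    else:
        d0, s0_sq = prior.d0, prior.s0_sq
    if np.any(d0 + d <= 0):
        raise ConfigError("total degrees of freedom d0 + d must be > 0")
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        t_mod = beta / np.sqrt(s2_post * v)
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        t_mod = beta / np.sqrt(s2_post * v)
        p = 2.0 * stats.t.sf(np.abs(t_mod), d0 + d)
    return t_mod, p, s2_post


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# calling


def call_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Annotate results with direction and the significance call.

    A feature is significant iff its adjusted p-value is <= alpha (the
    boundary is inclusive).  Adds a volcano-ready ``neg_log10_p_adj``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    out = results.copy()
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = out["p_adj"] <= alpha
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out


def volcano_table(results: pd.DataFrame, categories: pd.Series | None = None) -> pd.DataFrame:
    vol = results[["log2fc", "neg_log10_p_adj", "significant", "direction"]].copy()
    if categories is not None:
        vol["category"] = categories.reindex(vol.index)
    return vol


def run_differential(
    matrix: pd.DataFrame,
    design: Design,
    weights: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Fit, moderate, adjust and call over a full ratio matrix.

    Features with insufficient observations are excluded before prior
    estimation (their residual variance is undefined).
    """
    fits, _skipped = fit_all_features(matrix, design, weights)
    if fits.empty:
        raise DegenerateDataError("no feature has enough observations to fit")
    prior = estimate_prior(fits["s2"].to_numpy(), fits["df"].to_numpy())
    t_mod, p, s2_post = moderate(
        fits["log2fc"].to_numpy(),
        fits["s2"].to_numpy(),
        fits["df"].to_numpy(),
        prior,
        fits["v"].to_numpy(),
    )
    results = fits.copy()
    results["t_mod"] = t_mod
    results["s2_post"] = s2_post
    results["p_value"] = p
    results["p_adj"] = adjust_bh(p)
    return call_significant(results, alpha=alpha), prior
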
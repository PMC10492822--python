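"""Joining methylation and diversity on the 1-kb grid; Fig-5-style models.

A WindowTable row carries, per full-coverage 1-kb window with at least one
CpG: the CpG count, mean %methylation per CpG, the count and proportion of
highly methylated CpGs, the mean absolute inter-population %methylation
difference, pi (plus its log with a small floor) and F_ST.  On this surface
we compute Pearson/Spearman correlations, a zero-inflated negative-binomial
(NB2) regression of methylated-CpG counts on log pi, and a zero-inflated
beta-binomial regression of the methylated proportion on log pi.

The ZINB fit delegates to statsmodels' ZeroInflatedNegativeBinomialP; the
zero-inflated beta-binomial has no installed implementation and is fit here
by direct maximum likelihood (logit mean link, intra-class correlation rho,
constant zero-inflation mass), with method-of-moments multi-starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.tools.numdiff import approx_hess1

PI_FLOOR = 1e-6  # floor applied to pi before log-transforming


@dataclass
class ZinbFit:
    beta0: float
    beta1: float
    theta: float          # NB2 dispersion (variance mu + mu^2/theta)
    pi0: float            # zero-inflation probability
    loglik: float
    converged: bool
    se: dict = field(default_factory=dict)
    flag: str = ""


@dataclass
class ZibbFit:
    beta0: float
    beta1: float
    rho: float            # beta-binomial intra-class correlation
    pi0: float
    loglik: float
    converged: bool
    se: dict = field(default_factory=dict)
    flag: str = ""


def build_window_table(sites: pd.DataFrame, site_mean_pct: np.ndarray,
                       classes: np.ndarray, window_index: np.ndarray,
                       diversity: pd.DataFrame,
                       site_absdiff: np.ndarray | None = None,
                       high_threshold_pct: float = 50.0) -> pd.DataFrame:
    """Aggregate CpG-level columns per window and join diversity statistics.

    Retains windows with complete sequence data across the kilobase (callable
    denominator equal to the window width and finite pi) and >= 1 CpG; other
    windows are dropped.
    """
    classes = np.asarray(classes)
    n_win = len(diversity)
    inside = window_index >= 0
    wi = window_index[inside]
    n_cpgs = np.bincount(wi, minlength=n_win).astype(float)
    sum_pct = np.bincount(wi, weights=np.asarray(site_mean_pct, float)[inside],
                          minlength=n_win)
    n_high = np.bincount(wi, weights=(classes[inside] == "high").astype(float),
                         minlength=n_win)
    out = diversity.copy().reset_index(drop=True)
    out["window_id"] = np.arange(n_win)
    out["n_cpgs"] = n_cpgs
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_pct_meth"] = np.where(n_cpgs > 0, sum_pct / n_cpgs, np.nan)
        out["n_high"] = n_high
        out["prop_high"] = np.where(n_cpgs > 0, n_high / n_cpgs, np.nan)
    if site_absdiff is not None:
        sum_diff = np.bincount(wi, weights=np.abs(np.asarray(site_absdiff, float))[inside],
                               minlength=n_win)
        out["mean_abs_diff"] = np.where(n_cpgs > 0, sum_diff / n_cpgs, np.nan)
    width = (out["end"] - out["start"] + 1).to_numpy(float)
    complete = np.isfinite(out["pi"].to_numpy())
    if "callable_bp" in out.columns:
        complete &= out["callable_bp"].to_numpy(float) >= width
    keep = complete & (n_cpgs > 0)
    out = out.loc[keep].reset_index(drop=True)
    out["log_pi"] = np.log(np.maximum(out["pi"].to_numpy(), PI_FLOOR))
    return out


def correlations(x, y) -> dict:
    """Pearson r (with t statistic and p) and tie-corrected Spearman rho."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return {"pearson_r": np.nan, "pearson_t": np.nan, "pearson_p": np.nan,
                "spearman_rho": np.nan, "spearman_p": np.nan, "n": int(x.size),
                "degenerate": True}
    pr = stats.pearsonr(x, y)
    r = float(pr.statistic)
    n = x.size
    t = r * np.sqrt((n - 2) / max(1.0 - r ** 2, np.finfo(float).tiny))
    sr = stats.spearmanr(x, y)
    return {"pearson_r": r, "pearson_t": float(t), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "n": int(n), "degenerate": False}


def exclude_unmethylated_windows(table: pd.DataFrame,
                                 site_mean_pct: np.ndarray,
                                 window_index: np.ndarray,
                                 threshold: float = 10.0) -> pd.DataFrame:
    """Keep windows containing at least one CpG at >= ``threshold`` %meth.

    ``table`` must carry the ``window_id`` column written by
    :func:`build_window_table`, aligned with ``window_index`` values.
    """
    if "window_id" not in table.columns:
        raise ValueError("table must carry a window_id column aligned with window_index")
    meth = np.asarray(site_mean_pct, float) >= threshold
    inside = window_index >= 0
    idx = window_index[inside & meth]
    meth_windows = set(idx.tolist())
    keep = table["window_id"].isin(meth_windows).to_numpy()
    return table.loc[keep].reset_index(drop=True)


# --- zero-inflated NB2 -----------------------------------------------------

def zinb_loglik(params, y, x) -> float:
    """Log-likelihood of the zero-inflated NB2 model (direct form).

    params = (beta0, beta1, theta, pi0); log mu = beta0 + beta1 x.
    """
    beta0, beta1, theta, pi0 = params
    y = np.asarray(y, float)
    mu = np.exp(beta0 + beta1 * np.asarray(x, float))
    log_nb = (special.gammaln(y + theta) - special.gammaln(theta)
              - special.gammaln(y + 1)
              + theta * np.log(theta / (mu + theta))
              + y * np.log(mu / (mu + theta)))
    zero = y == 0
    ll = np.empty_like(y)
    ll[zero] = np.log(pi0 + (1 - pi0) * np.exp(log_nb[zero]))
    ll[~zero] = np.log1p(-pi0) + log_nb[~zero]
    return float(ll.sum())


def zinb_fit(y, x) -> ZinbFit:
    """Zero-inflated NB2 regression of counts on a single covariate.

    Non-convergence and degenerate data return a flagged fit, not an
    exception.  SEs are Hessian-based where available.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.size < 50:
        raise ValueError("need >= 50 windows to fit")
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite (floor pi before log)")
    if np.all(y == 0):
        return ZinbFit(np.nan, np.nan, np.nan, 1.0, 0.0, False,
                       flag="all-zero response; pi0 at boundary")
    exog = np.column_stack([np.ones_like(x), x])
    model = ZeroInflatedNegativeBinomialP(y, exog, exog_infl=np.ones((y.size, 1)), p=2)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "nm"):
            try:
                res = model.fit(method=method, maxiter=2000, disp=0)
            except Exception:
                continue
            if res.mle_retvals.get("converged", False):
                break
    if res is None:
        return ZinbFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                       flag="optimizer failure")
    names = list(res.params.index) if hasattr(res.params, "index") else None
    p = np.asarray(res.params)
    # parameter order: inflate_const, const, x1, alpha
    pi0 = float(special.expit(p[0]))
    beta0, beta1 = float(p[1]), float(p[2])
    alpha = float(p[-1])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    se = {}
    try:
        bse = np.asarray(res.bse)
        se = {"beta0": float(bse[1]), "beta1": float(bse[2]),
              "inflate_const": float(bse[0]), "alpha": float(bse[-1])}
    except Exception:
        pass
    return ZinbFit(beta0=beta0, beta1=beta1, theta=theta, pi0=pi0,
                   loglik=float(res.llf),
                   converged=bool(res.mle_retvals.get("converged", False)), se=se)


# --- zero-inflated beta-binomial ------------------------------------------

def betabinom_logpmf(y, m, mu, rho) -> np.ndarray:
    """Beta-binomial log pmf with mean mu and intra-class correlation rho,
    shape pair (a, b) = (mu (1-rho)/rho, (1-mu)(1-rho)/rho).

    Below rho = 1e-7 the gammaln differences lose precision (shapes ~ 1/rho),
    so the exact binomial limit is evaluated instead.
    """
    y = np.asarray(y, float)
    m = np.asarray(m, float)
    mu = np.asarray(mu, float)
    log_choose = (special.gammaln(m + 1) - special.gammaln(y + 1)
                  - special.gammaln(m - y + 1))
    if rho < 1e-7:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = y * np.log(mu) + (m - y) * np.log1p(-mu)
        t = np.where((y == 0) & (mu == 0), 0.0, t)
        t = np.where((y == m) & (mu == 1), 0.0, t)
        return log_choose + t
    lam = (1.0 - rho) / rho
    a = mu * lam
    b = (1.0 - mu) * lam
    return log_choose + special.betaln(y + a, m - y + b) - special.betaln(a, b)


def zibb_loglik(params, y, m, x) -> float:
    """Log-likelihood of the zero-inflated beta-binomial model.

    params = (beta0, beta1, rho, pi0); logit mu = beta0 + beta1 x; the
    zero-inflation mass pi0 sits on y = 0.
    """
    beta0, beta1, rho, pi0 = params
    y = np.asarray(y, float)
    mu = special.expit(beta0 + beta1 * np.asarray(x, float))
    log_bb = betabinom_logpmf(y, m, mu, rho)
    zero = y == 0
    ll = np.empty_like(y)
    ll[zero] = np.log(pi0 + (1 - pi0) * np.exp(log_bb[zero]))
    ll[~zero] = np.log1p(-pi0) + log_bb[~zero]
    return float(ll.sum())


def _zibb_unpack(t):
    return t[0], t[1], float(special.expit(t[2])), float(special.expit(t[3]))


def zibb_fit(y, m, x) -> ZibbFit:
    """Zero-inflated beta-binomial regression of y successes of m on x.

    Maximum likelihood with unconstrained reparameterization (logit rho,
    logit pi0) and method-of-moments multi-starts; non-convergence returns a
    flagged fit.
    """
    y = np.asarray(y, float)
    m = np.asarray(m, float)
    x = np.asarray(x, float)
    if np.any(y > m):
        raise ValueError("y must be <= m per window")
    if np.any(m <= 0):
        raise ValueError("windows with m = 0 are excluded by precondition")
    p_obs = float(np.clip(y.sum() / m.sum(), 1e-4, 1 - 1e-4))
    frac_zero = float((y == 0).mean())
    starts = []
    for pi0_0 in (min(frac_zero * 0.5, 0.9), 0.05):
        for rho_0 in (0.05, 0.3):
            starts.append(np.array([special.logit(p_obs), 0.0,
                                    special.logit(rho_0),
                                    special.logit(max(pi0_0, 1e-3))]))

    def neg(t):
        b0, b1, rho, pi0 = _zibb_unpack(t)
        rho = min(max(rho, 1e-10), 1 - 1e-10)
        pi0 = min(max(pi0, 1e-12), 1 - 1e-12)
        return -zibb_loglik((b0, b1, rho, pi0), y, m, x)

    best = None
    for t0 in starts:
        try:
            r = optimize.minimize(neg, t0, method="Nelder-Mead",
                                  options={"maxiter": 4000, "fatol": 1e-8, "xatol": 1e-8})
        except Exception:
            continue
        if best is None or r.fun < best.fun:
            best = r
    if best is None:
        return ZibbFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                       flag="optimizer failure")
    b0, b1, rho, pi0 = _zibb_unpack(best.x)
    se = {}
    try:
        H = approx_hess1(best.x, neg)
        cov = np.linalg.inv(H)
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        se = {"beta0": float(d[0]), "beta1": float(d[1])}
    except Exception:
        pass
    return ZibbFit(beta0=float(b0), beta1=float(b1), rho=rho, pi0=pi0,
                   loglik=float(-best.fun), converged=bool(best.success), se=se)
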
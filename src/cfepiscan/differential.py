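"""Negative-binomial differential-region engine.

The model for window *i*, sample *j* is K_ij ~ NB(mu_ij, alpha_i) with
log mu_ij = x_j' beta_i + log s_j, variance mu + alpha mu^2.  The group
coefficient (SCZ vs HC) is tested with a Wald z-test and reported on the
log2 scale; windows with p below the calling threshold and |log2FC| above
the fold-change gate are labelled hyper (up in SCZ) or hypo (down).

Pipeline per modality:

1. median-of-ratios size factors,
2. per-window method-of-moments dispersion, blended geometrically with a
   robust a0 + a1/mu mean-dispersion trend,
3. per-window NB GLM by iteratively reweighted least squares with the
   design intercept + group + standardized age + gender (+ batch for 5mC)
   and offset log s_j,
4. Wald p-values, hypo/hyper calls, per-region power at the study's
   |log2FC|/lfcSE effect size,
5. a log2(normalized + 1) variance-stabilizing transform feeding
   hierarchical clustering of samples on 1 - Pearson correlation distance.

All windows are fitted jointly with batched linear algebra; the per-window
problems are small (n samples x a handful of coefficients).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

__all__ = [
    "NBWaldDifferential",
    "build_design",
    "size_factors",
    "estimate_dispersion",
    "fit_nb_glm",
    "wald_test",
    "call_regions",
    "vst",
    "cluster_samples",
    "region_power",
]

ALPHA_MIN = 1e-8
LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(meta, modality="5mC"):
    """Design matrix: intercept, group (SCZ=1), standardized age, gender (M=1)
    and treatment-coded batch indicators (5mC only; reference = first batch
    lexicographically)."""
    cols = {"intercept": np.ones(len(meta))}
    cols["group"] = (meta["group"].to_numpy() == "SCZ").astype(float)
    age = meta["age"].to_numpy(dtype=float)
    sd = age.std(ddof=0)
    cols["age"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
    cols["gender"] = (meta["gender"].to_numpy() == "M").astype(float)
    if modality == "5mC" and "batch" in meta.columns:
        levels = sorted(meta["batch"].unique())
        for lev in levels[1:]:
            cols[f"batch_{lev}"] = (meta["batch"].to_numpy() == lev).astype(float)
    X = pd.DataFrame(cols, index=meta.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    return X


# ---------------------------------------------------------------------------
# normalization & dispersion
# ---------------------------------------------------------------------------

def size_factors(K):
    """Median-of-ratios size factors.

    s_j = median over all-positive windows of K_ij / geometric-mean_i.
    """
    K = np.asarray(K, dtype=float)
    pos = (K > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no window with all-positive counts; cannot normalize")
    logK = np.log(K[pos])
    log_geo = logK.mean(axis=1, keepdims=True)
    return np.exp(np.median(logK - log_geo, axis=0))


def estimate_dispersion(K, s, alpha_min=ALPHA_MIN, trend=True):
    """Per-window dispersion: method-of-moments blended with an a0 + a1/mu trend.

    MoM on normalized counts: alpha_hat = max((var - mean)/mean^2, alpha_min).
    A robust (Huber) regression of alpha_hat on 1/mean gives the trend; the
    final estimate is the geometric mean of the raw and trend values.  With
    fewer than 20 windows the trend is skipped with a warning.
    """
    K = np.asarray(K, dtype=float)
    Q = K / np.asarray(s)[None, :]
    mean = Q.mean(axis=1)
    var = Q.var(axis=1, ddof=1)
    safe_mean = np.maximum(mean, 1e-12)
    raw = np.maximum((var - mean) / safe_mean**2, alpha_min)
    if not trend or K.shape[0] < 20:
        if trend and K.shape[0] < 20:
            warnings.warn("fewer than 20 windows: dispersion trend skipped", stacklevel=2)
        return raw
    import statsmodels.api as sm

    ok = mean > 0
    Xt = np.column_stack([np.ones(ok.sum()), 1.0 / safe_mean[ok]])
    try:
        fit = sm.RLM(raw[ok], Xt, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = fit.params
    except Exception:  # singular tiny inputs
        a0, a1 = float(np.median(raw[ok])), 0.0
    fitted = np.maximum(a0 + a1 / safe_mean, alpha_min)
    return np.maximum(np.sqrt(raw * fitted), alpha_min)


# ---------------------------------------------------------------------------
# NB GLM (batched IRLS)
# ---------------------------------------------------------------------------

def fit_nb_glm(K, X, s, alpha, max_iter=100, tol=1e-8):
    """Fit NB GLMs with log link and offset log(s) for one or many windows.

    Parameters
    ----------
    K : (W, n) or (n,) counts
    X : (n, p) design
    s : (n,) size factors
    alpha : (W,) or scalar dispersions

    Returns a dict of arrays: ``beta`` (natural log), ``se`` (per
    coefficient), ``mu`` fitted means, ``converged`` flags.  Standard errors
    come from the expected Fisher information at the optimum.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    X = np.asarray(X, dtype=float)
    s = np.asarray(s, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (K.shape[0],)).copy()
    W_, n = K.shape
    p = X.shape[1]
    offset = np.log(s)

    # initialize from a log-linear LS fit on shifted counts
    z0 = np.log((K + 0.5) / s[None, :])
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (W, p)

    converged = np.zeros(W_, dtype=bool)
    active = np.ones(W_, dtype=bool)
    mu = np.empty_like(K)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        m = np.exp(eta)
        w = m / (1.0 + alpha[idx, None] * m)
        z = (eta - offset[None, :]) + (K[idx] - m) / m
        A = np.einsum("ji,wj,jk->wik", X, w, X)
        b = np.einsum("ji,wj,wj->wi", X, w, z)
        A += np.eye(p)[None, :, :] * 1e-10
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        mu[idx] = m
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # final quantities for every window at the last beta
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("ji,wj,jk->wik", X, w, X) + np.eye(p)[None, :, :] * 1e-10
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.einsum("wii->wi", cov), 0.0))
    return {"beta": beta, "se": se, "mu": mu, "converged": converged}


def wald_test(beta_log2, lfc_se_log2):
    """Two-sided Wald p-value, p = 2(1 - Phi(|beta/SE|))."""
    beta_log2 = np.asarray(beta_log2, dtype=float)
    se = np.asarray(lfc_se_log2, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be positive")
    return 2.0 * stats.norm.sf(np.abs(beta_log2 / se))


def call_regions(results, p_thresh=5e-4, lfc_thresh=0.5, adjust=False):
    """Label windows hyper/hypo/none from p-value and log2FC gates.

    ``adjust=True`` applies BH and gates on the adjusted p instead (off by
    default: calling uses raw p with the fold-change gate).
    """
    res = results.copy()
    pv = res["pvalue"].to_numpy()
    if adjust:
        from statsmodels.stats.multitest import multipletests

        pv = multipletests(pv, method="fdr_bh")[1]
        res["padj"] = pv
    ok = res.get("converged", pd.Series(True, index=res.index)).to_numpy(bool)
    call = np.where(
        ok & (pv < p_thresh) & (res["log2FC"] > lfc_thresh),
        "hyper",
        np.where(ok & (pv < p_thresh) & (res["log2FC"] < -lfc_thresh), "hypo", "none"),
    )
    res["call"] = call
    return res


def vst(K, s):
    """Variance-stabilizing transform used for clustering/QC: log2(K/s + 1)."""
    return np.log2(np.asarray(K, dtype=float) / np.asarray(s)[None, :] + 1.0)


def cluster_samples(transformed):
    """Average-linkage hierarchical clustering of samples (columns) on
    1 - Pearson correlation; returns (linkage, labels at k=2)."""
    T = np.asarray(transformed, dtype=float)
    if T.shape[0] < 2:
        raise ValueError("need at least 2 called regions to cluster")
    sd = T.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant sample column: correlation distance undefined")
    C = np.corrcoef(T.T)
    D = 1.0 - C
    Z = hierarchy.linkage(D[np.triu_indices_from(D, k=1)], method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, labels


def region_power(d, n1, n2, alpha=0.005):
    """Two-sided two-sample t-test power at standardized effect size d.

    Noncentrality d*sqrt(n1*n2/(n1+n2)), df = n1+n2-2; at d=0 the power is
    exactly alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    d = np.abs(np.asarray(d, dtype=float))
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t loses accuracy at large noncentrality; fall back
    # to the asymptotic normal form there
    approx = stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp)
    power = np.where(np.isnan(power), approx, power)
    return power if power.ndim else float(power)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class NBWaldDifferential(BaseEstimator):
    """Covariate-adjusted NB Wald differential test over count windows.

    Parameters
    ----------
    p_thresh, lfc_thresh : calling gates (raw Wald p < p_thresh and
        |log2FC| > lfc_thresh).
    power_alpha : significance level for the per-region power computation.
    adjust : apply BH before calling (off by default).

    Fitted attributes
    -----------------
    size_factors_, dispersions_, design_, results_ : per-sample factors,
    per-window dispersions, design matrix and the results table with columns
    baseMean, log2FC, lfcSE, pvalue, call, power, converged.
    """

    def __init__(self, p_thresh=5e-4, lfc_thresh=0.5, power_alpha=0.005,
                 adjust=False, max_iter=100, tol=1e-8):
        self.p_thresh = p_thresh
        self.lfc_thresh = lfc_thresh
        self.power_alpha = power_alpha
        self.adjust = adjust
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, counts, meta, modality="5mC"):
        """``counts``: windows x samples DataFrame (optional chrom/start/end
        columns are carried through); ``meta``: sample table with group, age,
        gender, batch aligned to the count columns."""
        meta_cols = [c for c in ("chrom", "start", "end") if c in counts.columns]
        sample_cols = [c for c in counts.columns if c not in meta_cols]
        K = counts[sample_cols].to_numpy(dtype=float)
        meta = meta.set_index("sample_id").loc[sample_cols].reset_index()
        X = build_design(meta, modality=modality)
        s = size_factors(K)
        alpha = estimate_dispersion(K, s)
        fit = fit_nb_glm(K, X.to_numpy(), s, alpha, max_iter=self.max_iter, tol=self.tol)
        g = list(X.columns).index("group")
        log2fc = fit["beta"][:, g] / LN2
        lfc_se = fit["se"][:, g] / LN2
        pv = wald_test(log2fc, np.maximum(lfc_se, 1e-12))
        n2 = int((meta["group"] == "SCZ").sum())
        n1 = len(meta) - n2
        res = counts[meta_cols].copy()
        res["baseMean"] = (K / s[None, :]).mean(axis=1)
        res["log2FC"] = log2fc
        res["lfcSE"] = lfc_se
        res["pvalue"] = pv
        res["converged"] = fit["converged"]
        res = call_regions(res, self.p_thresh, self.lfc_thresh, adjust=self.adjust)
        res["power"] = region_power(
            np.abs(log2fc) / np.maximum(lfc_se, 1e-12), n1, n2, self.power_alpha
        )
        self.size_factors_ = pd.Series(s, index=sample_cols, name="size_factor")
        self.dispersions_ = alpha
        self.design_ = X
        self.results_ = res
        self.sample_cols_ = sample_cols
        return self

    def transform(self, counts):
        """VST of the fitted samples' counts (log2 normalized + 1)."""
        K = counts[self.sample_cols_].to_numpy(dtype=float)
        return pd.DataFrame(
            vst(K, self.size_factors_.to_numpy()), index=counts.index, columns=self.sample_cols_
        )
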
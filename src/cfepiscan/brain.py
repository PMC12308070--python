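"""Epigenome-brain-structure association.

Brain structural measures (cortical thickness CT, cortical volume CV,
surface area SA, subcortical volume SV) are residualized against nuisance
covariates (age and gender; plus intracranial volume for all classes except
CT, which does not scale with head size), with the raw median added back to
keep values on their original scale.  Group differences use per-measure
rank-sum tests with Benjamini-Hochberg FDR.  Region-measure association
combines two routes computed on the matched-imaging subset:

* a univariate Spearman screen over every region x measure pair, BH-adjusted
  jointly, with measures retained when enough regions hit them
  (>= 5 for 5mC, >= 10 for 5hmC), and
* a sparse canonical correlation analysis via penalized matrix
  decomposition (PMD): rank-1 factors of M = X'Z with L1-constrained,
  unit-L2 weight vectors obtained by alternating soft-thresholded updates,
  three components by deflation, penalties tuned against row-permuted data.

Measures supported by both routes are reported as reliable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Residualizer",
    "residualize",
    "covariates_for_class",
    "group_difference",
    "spearman_screen",
    "soft_threshold",
    "SparseCCA",
    "scca_tune",
    "intersect_findings",
]

COUNT_THRESHOLDS = {"5mC": 5, "5hmC": 10}


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def covariates_for_class(meta, measure_class):
    """Covariate matrix by measure class: CT and region data use age+gender;
    CV/SA/SV add ICV."""
    cols = [meta["age"].to_numpy(float), (meta["gender"].to_numpy() == "M").astype(float)]
    if measure_class in ("CV", "SA", "SV"):
        cols.append(meta["icv"].to_numpy(float))
    return np.column_stack(cols)


def residualize(values, covariates, add_back_median=True):
    """OLS residuals of ``values`` on ``covariates`` (+ intercept), plus the
    raw median so adjusted values stay on the original scale."""
    y = np.asarray(values, dtype=float)
    C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ beta
    if add_back_median:
        resid = resid + np.median(y, axis=0)
    return resid


class Residualizer(BaseEstimator):
    """Transformer removing age/gender(/ICV) variance from measures.

    Parameters: ``add_back_median``.  ``fit(X, meta, classes)`` learns the
    per-measure OLS coefficients; ``transform`` applies them (same samples).
    """

    def __init__(self, add_back_median=True):
        self.add_back_median = add_back_median

    def fit(self, X, meta, classes=None):
        X = pd.DataFrame(X)
        self.columns_ = X.columns
        self.coef_ = {}
        self.medians_ = X.median(axis=0)
        self.meta_ = meta
        self.classes_ = classes
        return self

    def transform(self, X, meta=None, classes=None):
        X = pd.DataFrame(X)
        meta = self.meta_ if meta is None else meta
        classes = self.classes_ if classes is None else classes
        out = {}
        for col in X.columns:
            cls = classes[col] if classes is not None else "CT"
            C = covariates_for_class(meta, cls)
            out[col] = residualize(X[col].to_numpy(), C, self.add_back_median)
        return pd.DataFrame(out, index=X.index)

    def fit_transform(self, X, meta, classes=None):
        return self.fit(X, meta, classes).transform(X)


# ---------------------------------------------------------------------------
# group differences
# ---------------------------------------------------------------------------

def group_difference(adjusted, groups, alpha=0.05):
    """Per-measure two-sided rank-sum SCZ vs HC with BH across measures.

    Returns a DataFrame (statistic, pvalue, padj, direction, significant);
    direction is sign(median SCZ - median HC).  Constant measures get p = 1.
    """
    groups = np.asarray(groups)
    scz = adjusted.loc[groups == "SCZ"]
    hc = adjusted.loc[groups == "HC"]
    if len(scz) < 2 or len(hc) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for col in adjusted.columns:
        a, b = scz[col].to_numpy(), hc[col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((col, len(a) * len(b) / 2, 1.0, 0.0))
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append((col, float(res.statistic), float(res.pvalue),
                     float(np.sign(np.median(a) - np.median(b)))))
    out = pd.DataFrame(rows, columns=["measure", "statistic", "pvalue", "direction"])
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["padj"] < alpha
    return out.set_index("measure")


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def _rank_z(M):
    R = np.apply_along_axis(stats.rankdata, 0, M)
    R -= R.mean(axis=0, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=0))
    norm[norm == 0] = 1.0
    return R / norm


def spearman_screen(region_matrix, measure_matrix, count_threshold, fdr=0.05):
    """All-pairs Spearman rho/p between regions and measures with joint BH.

    Both matrices are samples x features aligned on the same (imaging
    subset) samples.  p-values use the t approximation
    t = rho sqrt((n-2)/(1-rho^2)).  Returns a dict: ``pairs`` (long table),
    ``significant`` pairs at BH < fdr, ``per_measure_counts`` and the
    ``retained`` measures with count >= count_threshold.
    """
    X = pd.DataFrame(region_matrix)
    Z = pd.DataFrame(measure_matrix)
    n = len(X)
    if n < 3 or len(Z) != n:
        raise ValueError("need >= 3 shared samples with aligned rows")
    rho = _rank_z(X.to_numpy(float)).T @ _rank_z(Z.to_numpy(float))
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    pairs = pd.DataFrame(
        {
            "region": np.repeat(X.columns, Z.shape[1]),
            "measure": np.tile(Z.columns, X.shape[1]),
            "rho": rho.ravel(),
            "pvalue": p.ravel(),
        }
    )
    pairs["padj"] = multipletests(pairs["pvalue"], method="fdr_bh")[1]
    sig = pairs[pairs["padj"] < fdr]
    counts = sig.groupby("measure", sort=False)["region"].nunique()
    retained = sorted(counts[counts >= count_threshold].index)
    return {
        "pairs": pairs,
        "significant": sig,
        "per_measure_counts": counts,
        "retained": retained,
        "n_pairs": len(pairs),
    }


# ---------------------------------------------------------------------------
# sparse CCA via penalized matrix decomposition
# ---------------------------------------------------------------------------

def default_penalty_grid(p, q, fractions=(0.15, 0.3, 0.45, 0.6)):
    """Candidate (c1, c2) pairs as fractions of the maximal L1 bound sqrt(dim),
    clamped to the feasible range [1, sqrt(dim)]."""
    c1s = sorted({min(max(f * np.sqrt(p), 1.0), np.sqrt(p)) for f in fractions})
    c2s = sorted({min(max(f * np.sqrt(q), 1.0), np.sqrt(q)) for f in fractions})
    return [(c1, c2) for c1 in c1s for c2 in c2s]


def soft_threshold(a, c):
    """sign(a) * max(|a| - c, 0)."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("threshold must be >= 0")
    return np.sign(a) * np.maximum(np.abs(a) - c, 0.0)


def _l1_ball_update(v, c):
    """Unit-L2 vector proportional to S(v, delta) with ||.||_1 <= c, delta by bisection."""
    norm = np.linalg.norm(v)
    if norm == 0:
        return v
    u = v / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(v).max()
    for _ in range(100):
        mid = (lo + hi) / 2
        w = soft_threshold(v, mid)
        nw = np.linalg.norm(w)
        l1 = np.abs(w).sum() / nw if nw > 0 else 0.0
        if l1 > c:
            lo = mid
        else:
            hi = mid
    w = soft_threshold(v, hi)
    nw = np.linalg.norm(w)
    return w / nw if nw > 0 else w


class SparseCCA(BaseEstimator):
    """Sparse CCA by penalized matrix decomposition of M = X'Z.

    Each component maximizes u'Mv subject to ||u||_2 <= 1, ||v||_2 <= 1,
    ||u||_1 <= c1, ||v||_1 <= c2 by alternating soft-thresholded updates
    (threshold set by bisection so the L1 constraint binds), initialized
    from the leading singular vector; subsequent components deflate
    M <- M - d u v'.  With penalties at their maxima (sqrt p, sqrt q) the
    components coincide with the truncated SVD of M.

    Parameters
    ----------
    c1, c2 : L1 bounds in [1, sqrt(p)] / [1, sqrt(q)]; None = maximum.
    n_components : number of factors (default 3).
    standardize : column-standardize X and Z before forming M.

    Fitted attributes: ``u_`` (p, K), ``v_`` (q, K), ``d_`` (K,) factor
    values, ``correlations_`` canonical correlations of Xu vs Zv,
    ``converged_`` per component.
    """

    def __init__(self, c1=None, c2=None, n_components=3, tol=1e-6, max_iter=200,
                 standardize=True, random_state=0):
        self.c1 = c1
        self.c2 = c2
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    @staticmethod
    def _standardize(A):
        A = np.asarray(A, dtype=float)
        sd = A.std(axis=0)
        sd[sd == 0] = 1.0
        return (A - A.mean(axis=0)) / sd

    def fit(self, X, Z):
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        if self.standardize:
            X, Z = self._standardize(X), self._standardize(Z)
        p, q = X.shape[1], Z.shape[1]
        c1 = np.sqrt(p) if self.c1 is None else float(self.c1)
        c2 = np.sqrt(q) if self.c2 is None else float(self.c2)
        if not (1 <= c1 <= np.sqrt(p) + 1e-9 and 1 <= c2 <= np.sqrt(q) + 1e-9):
            raise ValueError("penalties must lie in [1, sqrt(dim)]")
        M = X.T @ Z
        us, vs, ds, corrs, convs = [], [], [], [], []
        self.objective_histories_ = []
        for _ in range(self.n_components):
            u, v, d, conv = self._fit_rank1(M, c1, c2)
            M = M - d * np.outer(u, v)
            us.append(u)
            vs.append(v)
            ds.append(d)
            convs.append(conv)
            xu, zv = X @ u, Z @ v
            if xu.std() > 0 and zv.std() > 0:
                corrs.append(float(np.corrcoef(xu, zv)[0, 1]))
            else:
                corrs.append(0.0)
        self.u_ = np.column_stack(us)
        self.v_ = np.column_stack(vs)
        self.d_ = np.array(ds)
        self.correlations_ = np.array(corrs)
        self.converged_ = np.array(convs)
        return self

    def _fit_rank1(self, M, c1, c2):
        # initialize v with the leading right singular vector
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        v = Vt[0]
        u = np.zeros(M.shape[0])
        obj_prev = -np.inf
        conv = False
        history = []
        for _ in range(self.max_iter):
            u = _l1_ball_update(M @ v, c1)
            v = _l1_ball_update(M.T @ u, c2)
            obj = float(u @ M @ v)
            history.append(obj)
            if abs(obj - obj_prev) < self.tol * max(1.0, abs(obj)):
                conv = True
                break
            obj_prev = obj
        self.objective_histories_.append(np.array(history))
        # sign convention: first nonzero element of u positive
        nz = np.flatnonzero(u)
        if nz.size and u[nz[0]] < 0:
            u, v = -u, -v
        return u, v, float(u @ M @ v), conv

    def active_sets(self, rel_tol=0.1):
        """Indices contributing to any component, for the u and v sides.

        A coefficient counts as contributing when its magnitude exceeds
        ``rel_tol`` times the largest magnitude in its component — weights
        numerically nonzero but negligible against the leading loadings are
        treated as zero.
        """

        def active(Wm):
            scale = np.abs(Wm).max(axis=0, keepdims=True)
            scale[scale == 0] = 1.0
            return sorted(np.flatnonzero(np.any(np.abs(Wm) > rel_tol * scale, axis=1)))

        return active(self.u_), active(self.v_)


def scca_tune(X, Z, penalty_grid, n_perm=25, seed=0, z_flag=2.0):
    """Pick PMD penalties by the permutation z-score of the first canonical
    correlation.

    For each (c1, c2) on the grid the first-component correlation on the real
    data is compared (after Fisher transform) with its distribution over
    ``n_perm`` row-permutations of X; the grid point with the largest z-score
    wins.  The z-scores use the null standard deviation pooled across grid
    points: sparse settings produce artificially concentrated permutation
    nulls, and a per-point scale would always favour the sparsest penalty.
    Returns ``(c1, c2, best_z, no_signal_flag)``.
    """
    grid = list(penalty_grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)

    def null_stats(c1, c2, perms):
        model = SparseCCA(c1=c1, c2=c2, n_components=1, random_state=seed).fit(X, Z)
        r = np.clip(model.correlations_[0], -0.9999, 0.9999)
        null = []
        for pm in perms:
            m0 = SparseCCA(c1=c1, c2=c2, n_components=1, random_state=seed).fit(X[pm], Z)
            null.append(np.clip(m0.correlations_[0], -0.9999, 0.9999))
        null_z = np.arctanh(null)
        return np.arctanh(r) - null_z.mean(), null_z.std(ddof=1)

    sel_perms = [rng.permutation(len(X)) for _ in range(n_perm)]
    rows = []
    for c1, c2 in grid:
        gap, sd = null_stats(c1, c2, sel_perms)
        rows.append((c1, c2, gap, sd))
    pooled_sd = max(float(np.mean([row[3] for row in rows])), 1e-12)
    z_best = max(row[2] / pooled_sd for row in rows)
    # one-standard-error rule: sparsest penalty within 1 SD of the best z
    near = [row for row in rows if row[2] / pooled_sd >= z_best - 1.0]
    c1, c2, _, _ = min(near, key=lambda row: row[0] ** 2 + row[1] ** 2)
    # unbiased z for the selected point on fresh permutations (the selection
    # step maximizes over the grid, which would inflate a reused z)
    eval_perms = [rng.permutation(len(X)) for _ in range(n_perm)]
    gap, sd = null_stats(c1, c2, eval_perms)
    z = float(gap / max(sd, 1e-12))
    return c1, c2, z, z < z_flag


def intersect_findings(screen_retained, scca_active_measures, atrophy_set, screen_pairs=None):
    """Measures supported by both the screen and sCCA, with atrophy flags.

    Returns a dict: ``reliable`` measures, ``atrophy_flagged`` subset, and
    ``pairs`` (significant screen pairs restricted to reliable measures,
    when ``screen_pairs`` is given).
    """
    reliable = sorted(set(screen_retained) & set(scca_active_measures))
    flagged = sorted(set(reliable) & set(atrophy_set))
    pairs = None
    if screen_pairs is not None:
        pairs = screen_pairs[screen_pairs["measure"].isin(reliable)].reset_index(drop=True)
    return {"reliable": reliable, "atrophy_flagged": flagged, "pairs": pairs}
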
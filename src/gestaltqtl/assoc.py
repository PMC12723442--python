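"""Mixed-linear-model association engine.

The model is y = X beta + u + eps with u ~ N(0, sigma_g^2 K) for a
kinship matrix K and eps ~ N(0, sigma_e^2 I).  Following the EMMA
approach, K is eigendecomposed once and the REML log-likelihood is
maximized over the single variance ratio delta = sigma_e^2 / sigma_g^2
on a dense log grid with local refinement, making the per-trait fit a
one-dimensional, deterministic optimization.

The per-SNP scan defaults to P3D ("population parameters previously
determined"): variance components are estimated once under the null model
and reused for every locus, which makes 100-permutation reruns feasible.
MLMM adds forward-backward stepwise inclusion of significant loci as
fixed-effect cofactors.  Permutation of trait values yields an empirical
null p-value pool, and Benjamini-Hochberg converts p-values to q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MixedLinearModel",
    "reml_fit",
    "snp_scan",
    "mlmm",
    "permutation_null",
    "PermutationNull",
    "empirical_pvalues",
    "bh_fdr",
]


class AssociationError(ValueError):
    pass


def eigen_kinship(K: np.ndarray, psd_tol: float = 1e-6):
    """Symmetric eigendecomposition of K with small-negative clipping.

    Eigenvalues in [-psd_tol * max_eig, 0) are clipped to zero (recorded);
    anything more negative raises: the matrix is not a kinship matrix.
    """
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise AssociationError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise AssociationError("K must be symmetric")
    S, U = np.linalg.eigh(K)
    floor = -psd_tol * max(S.max(), 1.0)
    if S.min() < floor:
        raise AssociationError(f"K is not PSD (min eigenvalue {S.min():.3g})")
    return np.clip(S, 0.0, None), U


def _drop_collinear(X: np.ndarray):
    """Column indices of a full-column-rank subset of X (QR pivoting)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return keep


class MixedLinearModel(BaseEstimator):
    """EMMA-style REML fit of a single-kinship mixed model.

    Parameters
    ----------
    n_grid : size of the log10(delta) grid searched before refinement.
    log10_delta_range : bounds of the grid.
    psd_tol : relative tolerance for negative kinship eigenvalues.

    Fitted attributes (trailing underscore): ``delta_``, ``sigma_g2_``,
    ``sigma_e2_``, ``beta_``, ``loglik_``, ``heritability_``,
    ``boundary_`` (None, "lower" or "upper" when delta sits at a grid
    bound, e.g. under an identity kinship where the split is
    unidentifiable).
    """

    def __init__(self, n_grid: int = 100, log10_delta_range: tuple = (-5.0, 5.0),
                 psd_tol: float = 1e-6):
        self.n_grid = n_grid
        self.log10_delta_range = log10_delta_range
        self.psd_tol = psd_tol

    # -- REML machinery -----------------------------------------------------

    def _reml_pieces(self, delta, ys, Xs, S):
        w = S + delta
        sw = np.sqrt(w)
        Xt = Xs / sw[:, None]
        yt = ys / sw
        beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        return w, Xt, yt, beta, rss

    def _reml_ll(self, delta, ys, Xs, S, logdet_XX):
        n, q = Xs.shape
        w, Xt, _, _, rss = self._reml_pieces(delta, ys, Xs, S)
        if rss <= 0:
            return -np.inf
        sign, logdet_XWX = np.linalg.slogdet(Xt.T @ Xt)
        if sign <= 0:
            return -np.inf
        nq = n - q
        return 0.5 * (
            nq * np.log(nq / (2.0 * np.pi)) - nq - nq * np.log(rss)
            - np.log(w).sum() + logdet_XX - logdet_XWX
        )

    def fit(self, X, y, K=None, eig=None):
        y = np.asarray(y, float).ravel()
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        n = y.size
        if not np.all(np.isfinite(y)):
            raise AssociationError("y must be finite")
        if y.std() == 0:
            raise AssociationError("y is constant")
        if eig is None:
            if K is None:
                K = np.eye(n)
            eig = eigen_kinship(K, self.psd_tol)
        S, U = eig
        keep = _drop_collinear(X)
        if len(keep) < X.shape[1]:
            warnings.warn("dropping collinear fixed-effect columns")
        X = X[:, keep]
        self.kept_columns_ = keep
        ys = U.T @ y
        Xs = U.T @ X
        sign, logdet_XX = np.linalg.slogdet(X.T @ X)
        if sign <= 0:
            raise AssociationError("X has no full-rank subset")

        lo, hi = self.log10_delta_range
        grid = np.logspace(lo, hi, self.n_grid)
        lls = np.array([self._reml_ll(d, ys, Xs, S, logdet_XX) for d in grid])
        best = int(np.argmax(lls))
        bl = np.log10(grid[max(best - 1, 0)])
        bh = np.log10(grid[min(best + 1, self.n_grid - 1)])
        res = optimize.minimize_scalar(
            lambda t: -self._reml_ll(10.0 ** t, ys, Xs, S, logdet_XX),
            bounds=(bl, bh), method="bounded",
        )
        cand = [(self._reml_ll(10.0 ** res.x, ys, Xs, S, logdet_XX), 10.0 ** res.x),
                (lls[best], grid[best])]
        ll, delta = max(cand, key=lambda t: t[0])

        w, Xt, yt, beta, rss = self._reml_pieces(delta, ys, Xs, S)
        q = Xs.shape[1]
        sigma_g2 = rss / (n - q)
        if rss < 1e-12:
            warnings.warn("zero residual after fixed effects; variance at boundary")
        self.delta_ = float(delta)
        self.sigma_g2_ = float(sigma_g2)
        self.sigma_e2_ = float(delta * sigma_g2)
        self.beta_ = beta
        self.loglik_ = float(ll)
        self.heritability_ = float(1.0 / (1.0 + delta))
        flat = np.allclose(lls, lls[0], atol=1e-6)
        if best == 0 or flat:
            self.boundary_ = "lower"
        elif best == self.n_grid - 1:
            self.boundary_ = "upper"
        else:
            self.boundary_ = None
        self._eig = (S, U)
        self._rot = (ys, Xs)
        self.n_, self.q_ = n, q
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, self.kept_columns_] @ self.beta_


def reml_fit(y, X, K, **kwargs) -> MixedLinearModel:
    """Fit the mixed model by REML (thin wrapper over MixedLinearModel)."""
    return MixedLinearModel(**kwargs).fit(X, y, K=K)


# ---------------------------------------------------------------------------
# per-SNP scan


def _gls_scan_core(yt, Xt, Gt):
    """Vectorized GLS t-tests of each column of Gt added to Xt.

    All inputs are already whitened (divided by sqrt(S + delta) in the
    eigenbasis of K).  Returns (beta, se, tstat, gPg) arrays.
    """
    n, q = Xt.shape
    Q, _ = np.linalg.qr(Xt)
    resid_y = yt - Q @ (Q.T @ yt)
    rss0 = float(resid_y @ resid_y)
    PG = Gt - Q @ (Q.T @ Gt)
    gPg = np.einsum("ij,ij->j", PG, PG)
    gPy = PG.T @ resid_y
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gPy / gPg
        rss = np.maximum(rss0 - beta * gPy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gPg)
        tstat = beta / se
    return beta, se, tstat, gPg, df


def snp_scan(y, X, K, G, p3d: bool = True, missing: str = "drop",
             null: MixedLinearModel | None = None, loci: pd.DataFrame | None = None,
             collinear_tol: float = 1e-8) -> pd.DataFrame:
    """Mixed-model association test of every locus (column of G).

    With ``p3d=True`` (default) the variance ratio delta comes from the
    null model and each locus needs only a generalized-least-squares
    t-test in the whitened space; ``p3d=False`` refits REML per locus.
    Missing dosages: ``"drop"`` excludes the affected samples for that
    locus exactly (its own small GLS fit); ``"impute"`` mean-imputes.
    Monomorphic or covariate-collinear loci get NaN p and a flag.

    Returns a DataFrame (one row per locus) with effect, se, stat, df, p
    and flag, indexed like ``loci`` (or integer positions).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    G = np.asarray(G, float)
    n, m = G.shape
    if null is None:
        null = MixedLinearModel().fit(X, y, K=K)
    S, U = null._eig
    delta = null.delta_
    ys, Xs = null._rot
    w = S + delta
    sw = np.sqrt(w)
    yt = ys / sw
    Xt = Xs / sw[:, None]

    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    dfs = np.full(m, np.nan)
    flag = np.array(["ok"] * m, dtype=object)

    has_nan = np.isnan(G).any(axis=0)
    mono = np.nanstd(G, axis=0) < 1e-12
    flag[mono] = "monomorphic"

    if missing == "impute" and has_nan.any():
        G = G.copy()
        mu = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = np.take(mu, idx[1])
        has_nan[:] = False

    full = ~has_nan & ~mono
    if full.any():
        if p3d:
            Gt = (U.T @ G[:, full]) / sw[:, None]
            b, s, t, gPg, df = _gls_scan_core(yt, Xt, Gt)
            scale = np.nanstd(G[:, full], axis=0) ** 2 * n
            coll = gPg <= collinear_tol * np.maximum(scale, 1.0)
            idx = np.flatnonzero(full)
            effect[idx], se[idx], tstat[idx], dfs[idx] = b, s, t, df
            pval[idx] = 2.0 * stats.t.sf(np.abs(t), df)
            for k in idx[coll]:
                flag[k] = "collinear"
                effect[k] = se[k] = tstat[k] = pval[k] = np.nan
        else:
            for k in np.flatnonzero(full):
                r = _single_locus_exact(y, X, G[:, k], S, U, p3d=False)
                effect[k], se[k], tstat[k], dfs[k], pval[k], flag[k] = r

    if missing == "drop" and (has_nan & ~mono).any():
        K = np.asarray(K, float) if K is not None else np.eye(n)
        for k in np.flatnonzero(has_nan & ~mono):
            ok = ~np.isnan(G[:, k])
            Ksub = K[np.ix_(ok, ok)]
            Ssub, Usub = eigen_kinship(Ksub)
            r = _single_locus_exact(
                y[ok], X[ok], G[ok, k], Ssub, Usub, p3d=p3d, delta=delta
            )
            effect[k], se[k], tstat[k], dfs[k], pval[k], flag[k] = r

    out = pd.DataFrame(
        {"effect": effect, "se": se, "stat": tstat, "df": dfs, "p": pval, "flag": flag}
    )
    if loci is not None:
        out = pd.concat([loci.reset_index(drop=True), out], axis=1)
    return out


def _single_locus_exact(y, X, g, S, U, p3d=True, delta=None):
    """One-locus GLS (or full REML) test on a sample subset."""
    if g.std() < 1e-12:
        return np.nan, np.nan, np.nan, np.nan, np.nan, "monomorphic"
    if not p3d or delta is None:
        null = MixedLinearModel().fit(X, y, eig=(S, U))
        delta = null.delta_
    sw = np.sqrt(S + delta)
    yt = (U.T @ y) / sw
    Xt = (U.T @ X) / sw[:, None]
    Gt = ((U.T @ g) / sw)[:, None]
    b, s, t, gPg, df = _gls_scan_core(yt, Xt, Gt)
    if gPg[0] <= 1e-8 * max(g.std() ** 2 * y.size, 1.0):
        return np.nan, np.nan, np.nan, np.nan, np.nan, "collinear"
    p = 2.0 * stats.t.sf(abs(t[0]), df)
    return b[0], s[0], t[0], df, p, "ok"


# ---------------------------------------------------------------------------
# MLMM forward-backward stepwise scan


@dataclass
class MlmmResult:
    results: pd.DataFrame
    cofactors: list = field(default_factory=list)
    trace: list = field(default_factory=list)


def _order_key(loci: pd.DataFrame | None, m: int):
    """Deterministic tie-break rank: lowest (chrom, bp), else column order."""
    if loci is not None and {"chrom", "bp"}.issubset(loci.columns):
        chrom = pd.factorize(loci["chrom"], sort=True)[0]
        return np.lexsort((loci["bp"].to_numpy(), chrom)).argsort()
    return np.arange(m)


def mlmm(y, X, K, G, loci: pd.DataFrame | None = None, max_steps: int = 10,
         entry_threshold: float = 0.05, correction: str = "bonferroni",
         p3d: bool = True, missing: str = "drop") -> MlmmResult:
    """Multi-locus mixed model: forward-backward stepwise cofactor selection.

    Forward: rescan, add the most significant locus as a fixed cofactor
    while its multiple-testing-corrected p-value is below
    ``entry_threshold`` and fewer than ``max_steps`` cofactors are in the
    model.  Backward: drop cofactors whose corrected p-value in the full
    model exceeds the threshold, most non-significant first.  Reported
    per-locus statistics are conditional on the retained cofactors.  Ties
    break on the lowest (chrom, bp).
    """
    G = np.asarray(G, float)
    n, m = G.shape
    order = _order_key(loci, m)
    mult = m  # Bonferroni family size: all scanned loci

    def corrected(p):
        if correction == "bonferroni":
            return min(p * mult, 1.0)
        raise ValueError(correction)

    cofactors: list[int] = []
    trace = []
    for step in range(max_steps):
        X_aug = np.column_stack([X] + [G[:, c] for c in cofactors]) if cofactors else X
        res = snp_scan(y, X_aug, K, G, p3d=p3d, missing=missing)
        res.loc[cofactors, "p"] = np.nan  # cofactors are not candidates
        p = res["p"].to_numpy()
        if np.all(np.isnan(p)):
            break
        cand = np.flatnonzero(~np.isnan(p))
        best = cand[np.lexsort((order[cand], p[cand]))[0]]
        p_corr = corrected(p[best])
        if p_corr >= entry_threshold:
            break
        cofactors.append(int(best))
        trace.append({"step": step + 1, "action": "add", "locus": int(best),
                      "p": float(p[best]), "p_corrected": float(p_corr)})

    # backward elimination
    changed = True
    while changed and cofactors:
        changed = False
        stats_c = {}
        for c in list(cofactors):
            others = [o for o in cofactors if o != c]
            X_aug = np.column_stack([X] + [G[:, o] for o in others]) if others else X
            r = snp_scan(y, X_aug, K, G[:, [c]], p3d=p3d, missing=missing)
            stats_c[c] = r["p"].iloc[0]
        worst = max(stats_c, key=lambda c: (np.inf if np.isnan(stats_c[c]) else stats_c[c]))
        p_worst = stats_c[worst]
        if np.isnan(p_worst) or corrected(p_worst) >= entry_threshold:
            cofactors.remove(worst)
            trace.append({"action": "drop", "locus": int(worst),
                          "p": float(p_worst) if not np.isnan(p_worst) else None})
            changed = True

    X_final = np.column_stack([X] + [G[:, c] for c in cofactors]) if cofactors else X
    final = snp_scan(y, X_final, K, G, p3d=p3d, missing=missing, loci=loci)
    final["is_cofactor"] = False
    for c in cofactors:
        others = [o for o in cofactors if o != c]
        X_aug = np.column_stack([X] + [G[:, o] for o in others]) if others else X
        r = snp_scan(y, X_aug, K, G[:, [c]], p3d=p3d, missing=missing)
        for col in ("effect", "se", "stat", "df", "p"):
            final.loc[c, col] = r[col].iloc[0]
        final.loc[c, "flag"] = r["flag"].iloc[0]
        final.loc[c, "is_cofactor"] = True
    return MlmmResult(results=final, cofactors=cofactors, trace=trace)


# ---------------------------------------------------------------------------
# permutation calibration


@dataclass
class PermutationNull:
    """Null p-values from trait-shuffling permutations (n_perm x n_loci)."""

    pvalues: np.ndarray
    seed: int | None = None

    def pool(self) -> np.ndarray:
        p = self.pvalues.ravel()
        return p[~np.isnan(p)]

    def min_p_per_perm(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmin(self.pvalues, axis=1)

    def genomewide_threshold(self, alpha: float = 0.05) -> float:
        """Family-wise alpha threshold: alpha-quantile of per-permutation min p."""
        return float(np.quantile(self.min_p_per_perm(), alpha))


def permutation_null(y, X, K, G, n_perm: int = 100, seed=None,
                     reestimate: bool = True) -> PermutationNull:
    """Shuffle trait values and rerun the scan ``n_perm`` times.

    Covariates, kinship and genotypes stay fixed; only y is permuted
    (within the analysis level -- individual rows at individual level,
    colony rows at colony level, i.e. the rows of the matrices given).
    Variance components are re-estimated per permutation by default.
    The permuted scans always run P3D with mean-imputed missing dosages:
    the genotype rotation is computed once and reused, which is what
    makes 100 permutations affordable.  Reproducible under ``seed``.
    """
    if n_perm < 1:
        raise AssociationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    G = np.asarray(G, float)
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(mu, idx[1])
    null0 = MixedLinearModel().fit(X, y, K=K)
    S, U = null0._eig
    Gs = U.T @ G  # rotate once; K, X, G are fixed across permutations
    Xs = U.T @ X
    out = np.full((n_perm, G.shape[1]), np.nan)
    mono = np.nanstd(G, axis=0) < 1e-12
    for b in range(n_perm):
        yp = y[rng.permutation(y.size)]
        if reestimate:
            null_b = MixedLinearModel().fit(X, yp, eig=(S, U))
            delta = null_b.delta_
        else:
            delta = null0.delta_
        sw = np.sqrt(S + delta)
        yt = (U.T @ yp) / sw
        _, _, t, gPg, df = _gls_scan_core(yt, Xs / sw[:, None], Gs / sw[:, None])
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p[mono | (gPg <= 1e-10)] = np.nan
        out[b] = p
    return PermutationNull(pvalues=out, seed=seed)


def empirical_pvalues(p_obs, null_pool) -> np.ndarray:
    """Pooled-ECDF empirical p-values with the add-one rule.

    p_emp = (1 + #{null <= p_obs}) / (1 + pool size); monotone in p_obs,
    never zero; NaN observations stay NaN.
    """
    pool = np.sort(np.asarray(null_pool, float).ravel())
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise AssociationError("empty null pool")
    p_obs = np.asarray(p_obs, float)
    counts = np.searchsorted(pool, p_obs, side="right")
    emp = (1.0 + counts) / (1.0 + pool.size)
    emp = np.where(np.isnan(p_obs), np.nan, emp)
    return emp


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing entries pass through.

    q_(i) = min_{j >= i} m p_(j) / j, capped at 1.
    """
    p = np.asarray(p, float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q
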
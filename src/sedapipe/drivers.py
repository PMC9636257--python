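"""Multivariate and regression analysis of composition-driver relationships.

Implements the analytical back end of the pipeline: redundancy analysis
(RDA) with AIC-guided forward selection and Pillai's-trace permutation
tests, a Poisson generalized additive model for richness with outlier
screening and Durbin-Watson diagnostics, piecewise structural equation
models evaluated with Fisher's C, and the small numerical helpers shared by
the presentation layer (fourth-root transform, loess smoothing).

Conventions
-----------
* Community matrices enter RDA fourth-root transformed (variance
  stabilization for proportional indices in [0, 1]).
* Permutation p-values are computed as (1 + #{perm >= obs}) / (1 + n_perm),
  with unrestricted row permutations.
* The stepwise RDA criterion is AIC = n * ln(RSS / n) + 2 (k + 1) with RSS
  the total residual sum of squares of the multivariate least-squares fit
  and k the number of selected covariates; a candidate is accepted only if
  it both lowers AIC and tests significant (marginal permutation test).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, stats

__all__ = [
    "RDAResult",
    "GAMResult",
    "SEMResult",
    "transform_fourth_root",
    "rda",
    "forward_select",
    "pillai_test",
    "gam_poisson",
    "durbin_watson",
    "piecewise_sem",
    "loess_smooth",
]


def transform_fourth_root(matrix):
    """Elementwise fourth root (x >= 0)."""
    x = np.asarray(matrix, dtype=float) if not isinstance(matrix, pd.DataFrame) else matrix
    if np.any(np.asarray(x) < 0):
        raise ValueError("fourth-root transform requires non-negative values")
    return x ** 0.25


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RDAResult:
    total_inertia: float
    constrained_inertia: float
    proportion_explained: float  # percent of total variance
    eigenvalues: np.ndarray
    axis_proportions: np.ndarray  # percent of total variance per axis
    site_scores: np.ndarray
    biplot_scores: pd.DataFrame
    variables: list
    term_p_values: dict = field(default_factory=dict)
    axis_p_values: list = field(default_factory=list)
    n_permutations: int | None = None
    seed: int | None = None


def _as_matrix(M):
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.columns)
    M = np.asarray(M, dtype=float)
    return M, [f"v{j}" for j in range(M.shape[1])]


def _check_rank(Xs: np.ndarray, names: list) -> None:
    _, R, piv = linalg.qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient covariates (collinear): {bad}")


def rda(Y, X) -> RDAResult:
    """Redundancy analysis: constrained ordination of Y on covariates X.

    Y is column-centered, X standardized; the fitted values of the
    multivariate least-squares regression are eigen-decomposed.  Inertia is
    variance (sums of squares / (n - 1)), matching the usual ordination
    convention; the constrained and unconstrained parts add up to the total.
    """
    Ym, _ = _as_matrix(Y)
    Xm, xnames = _as_matrix(X)
    n, m = Ym.shape
    if Xm.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if n <= Xm.shape[1]:
        raise ValueError("need more samples than covariates")
    if np.isnan(Ym).any() or np.isnan(Xm).any():
        raise ValueError("missing values not allowed")

    Yc = Ym - Ym.mean(axis=0)
    sd = Xm.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [xnames[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant covariates: {bad}")
    Xs = (Xm - Xm.mean(axis=0)) / sd
    _check_rank(Xs, xnames)

    B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yfit = Xs @ B
    U, s, Vt = np.linalg.svd(Yfit, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > eig.max() * 1e-12 if eig.size and eig.max() > 0 else np.zeros_like(eig, bool)
    eig = eig[keep]
    total = float((Yc**2).sum()) / (n - 1)
    constrained = float(eig.sum())
    site_scores = U[:, keep] * s[keep]
    bip = pd.DataFrame(
        {f"RDA{k + 1}": [np.corrcoef(Xs[:, j], site_scores[:, k])[0, 1]
                          if site_scores[:, k].std() > 0 else 0.0
                          for j in range(Xs.shape[1])]
         for k in range(site_scores.shape[1])},
        index=xnames,
    )
    return RDAResult(
        total_inertia=total,
        constrained_inertia=constrained,
        proportion_explained=100.0 * constrained / total if total > 0 else 0.0,
        eigenvalues=eig,
        axis_proportions=100.0 * eig / total if total > 0 else eig * 0,
        site_scores=site_scores,
        biplot_scores=bip,
        variables=xnames,
    )


# ---------------------------------------------------------------------------
# Pillai's trace permutation tests
# ---------------------------------------------------------------------------

def _proj(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _pillai(H: np.ndarray, E: np.ndarray) -> float:
    return float(np.trace(H @ np.linalg.pinv(H + E)))


def pillai_test(
    Y, X, term: str | None = None, n_perm: int = 999, seed: int = 0
) -> dict:
    """Permutation test of an RDA model (or one term of it) via Pillai's trace.

    Whole model (``term=None``): rows of the centered Y are permuted.  For a
    single term the test is partial: Y is residualized on the remaining
    covariates, the reduced-model residuals are permuted and the reduced fit
    added back (Freedman-Lane), and the statistic contrasts the full against
    the reduced projection.  p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    Ym, _ = _as_matrix(Y)
    Xm, xnames = _as_matrix(X)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    Xs = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)

    if term is None:
        P = _proj(Xs)
        T = Yc.T @ Yc
        Tinv = np.linalg.pinv(T)  # total SSCP is permutation-invariant
        obs = float(np.trace((Yc.T @ P @ Yc) @ Tinv))
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        Yp = Yc[perms]  # (n_perm, n, m)
        PY = np.einsum("nk,pkm->pnm", P, Yp)
        H = np.einsum("pnm,pnl->pml", Yp, PY)
        vals = np.einsum("pml,lm->p", H, Tinv)
        count = int(np.sum(vals >= obs - 1e-12))
        stat = obs
    else:
        if term not in xnames:
            raise ValueError(f"unknown term {term!r}")
        j = xnames.index(term)
        others = [k for k in range(Xs.shape[1]) if k != j]
        P_full = _proj(Xs)
        P_red = _proj(Xs[:, others]) if others else np.zeros((n, n))
        D = P_full - P_red
        fit_red = P_red @ Yc
        res_red = Yc - fit_red

        def statf(Ystar):
            H = Ystar.T @ D @ Ystar
            E = Ystar.T @ (np.eye(n) - P_full) @ Ystar
            return _pillai(H, E)

        obs = statf(Yc)
        count = 0
        for _ in range(n_perm):
            Ystar = fit_red + res_red[rng.permutation(n)]
            if statf(Ystar) >= obs - 1e-12:
                count += 1
        stat = obs
    return {
        "statistic": stat,
        "p_value": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
        "term": term,
    }


def axis_significance(Y, X, n_perm: int = 999, seed: int = 0) -> list[float]:
    """Marginal permutation p-value per constrained axis (eigenvalue null)."""
    Ym, _ = _as_matrix(Y)
    base = rda(Y, X)
    rng = np.random.default_rng(seed)
    n_axes = len(base.eigenvalues)
    counts = np.zeros(n_axes)
    for _ in range(n_perm):
        Yp = Ym[rng.permutation(Ym.shape[0])]
        eig = rda(Yp, X).eigenvalues
        for k in range(n_axes):
            v = eig[k] if k < len(eig) else 0.0
            if v >= base.eigenvalues[k] - 1e-15:
                counts[k] += 1
    return [(1 + c) / (1 + n_perm) for c in counts]


def _rda_aic(Yc: np.ndarray, Xs: np.ndarray | None, k: int) -> float:
    n = Yc.shape[0]
    if Xs is None or Xs.shape[1] == 0:
        rss = float((Yc**2).sum())
    else:
        B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
        rss = float(((Yc - Xs @ B) ** 2).sum())
    return n * np.log(rss / n) + 2 * (k + 1)


def forward_select(
    Y, X, n_perm: int = 199, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Stepwise covariate selection for RDA (AIC + marginal permutation test).

    Starting from the empty model, the candidate minimizing the AIC is
    added when it both improves AIC and has a marginal permutation p-value
    below ``alpha``; after each addition a drop phase removes variables
    whose exclusion improves AIC.  Candidates collinear with the current
    selection are skipped.  Deterministic under ``seed``.
    """
    Ym, _ = _as_matrix(Y)
    Xm, xnames = _as_matrix(X)
    Yc = Ym - Ym.mean(axis=0)
    Xs = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0, ddof=1)
    cols = {name: Xs[:, j] for j, name in enumerate(xnames)}

    selected: list[str] = []
    trail = []
    rng_seed = itertools.count(seed)

    def design(names):
        return np.column_stack([cols[v] for v in names]) if names else None

    current_aic = _rda_aic(Yc, None, 0)
    improved = True
    while improved:
        improved = False
        best = None
        for cand in xnames:
            if cand in selected:
                continue
            Xc = design(selected + [cand])
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                continue  # collinear with selection
            aic = _rda_aic(Yc, Xc, len(selected) + 1)
            if aic < current_aic - 1e-9 and (best is None or aic < best[0]):
                best = (aic, cand)
        if best is not None:
            aic, cand = best
            p = pillai_test(
                Yc, pd.DataFrame({v: cols[v] for v in selected + [cand]}),
                term=cand, n_perm=n_perm, seed=next(rng_seed),
            )["p_value"]
            trail.append({"step": "try_add", "variable": cand, "aic": aic, "p": p})
            if p < alpha:
                selected.append(cand)
                current_aic = aic
                improved = True
                # drop phase
                for v in list(selected[:-1]):
                    rest = [w for w in selected if w != v]
                    aic_drop = _rda_aic(Yc, design(rest), len(rest))
                    if aic_drop < current_aic - 1e-9:
                        selected = rest
                        current_aic = aic_drop
                        trail.append({"step": "drop", "variable": v, "aic": aic_drop})
    return {"selected": selected, "aic": current_aic, "trail": trail}


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

def durbin_watson(residuals) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2 on residuals ordered by age."""
    e = np.asarray(residuals, dtype=float)
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValueError("all residuals are zero: Durbin-Watson undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


# ---------------------------------------------------------------------------
# Poisson GAM (penalized regression splines, P-IRLS, GCV)
# ---------------------------------------------------------------------------

@dataclass
class GAMResult:
    covariates: list
    coefficients: np.ndarray
    alphas: dict
    edf: float
    edf_per_smooth: dict
    fitted: np.ndarray
    linear_predictor: np.ndarray
    deviance: float
    deviance_residuals: np.ndarray
    pearson_residuals: np.ndarray
    outliers: list
    used_index: np.ndarray
    dw_statistic: float | None
    lag1_autocorrelation: float | None
    prediction_grid: dict  # covariate -> DataFrame(x, mean, lower, upper)
    glm_coefficients: np.ndarray


def _smooth_basis(x: np.ndarray, k: int = 10, degree: int = 3):
    """Uniform-knot B-spline basis split into linear part + penalized part.

    Returns (linear column, Z penalized columns, predictor closure).  The
    second-order difference penalty has null space {1, x} (uniform knots),
    which is carried by the intercept and the linear column, so as the
    penalty goes to infinity the smooth collapses exactly onto a straight
    line.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("constant covariate in smooth")
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])

    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    lam, U = np.linalg.eigh(S)
    null = lam < 1e-10 * lam.max()
    Upos, lpos = U[:, ~null], lam[~null]

    def basis(xx):
        xx = np.clip(xx, lo, hi)
        B = interpolate.BSpline.design_matrix(xx, t, degree).toarray()
        return B

    Bx = basis(x)
    Z_raw = Bx @ Upos / np.sqrt(lpos)  # identity penalty in this parametrization
    zmean = Z_raw.mean(axis=0)
    xmean = x.mean()

    def predict_columns(xx):
        B = basis(np.asarray(xx, dtype=float))
        Z = B @ Upos / np.sqrt(lpos) - zmean
        return (np.asarray(xx, dtype=float) - xmean), Z

    return x - xmean, Z_raw - zmean, predict_columns


def _pirls(Xd: np.ndarray, y: np.ndarray, pen_diag: np.ndarray, max_iter=100, tol=1e-10):
    """Penalized IRLS for Poisson log link.  Returns (beta, edf, deviance, cov)."""
    n = len(y)
    eta = np.log(np.maximum(y, 0.5))
    beta = None
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        XtW = Xd.T * w
        A = XtW @ Xd + np.diag(pen_diag)
        b = XtW @ z
        beta_new = np.linalg.solve(A, b)
        eta_new = Xd @ beta_new
        if beta is not None and np.max(np.abs(eta_new - eta)) < tol:
            beta, eta = beta_new, eta_new
            break
        beta, eta = beta_new, eta_new
    mu = np.exp(eta)
    w = mu
    XtW = Xd.T * w
    A = XtW @ Xd + np.diag(pen_diag)
    Ainv = np.linalg.inv(A)
    edf = float(np.trace(Ainv @ (XtW @ Xd)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2 * np.sum(dev_terms))
    return beta, edf, deviance, Ainv


def gam_poisson(
    richness,
    covariates: pd.DataFrame,
    ages=None,
    k: int = 10,
    alphas=None,
    screen_outliers: bool = True,
    outlier_threshold: float = 3.0,
    grid_points: int = 500,
) -> GAMResult:
    """Poisson GAM for taxon richness with smooth covariate effects.

    One penalized cubic regression spline per covariate (basis dimension
    ``k``, second-order difference penalty), fitted by penalized IRLS;
    smoothing parameters chosen by GCV over a log grid (coordinate descent)
    unless fixed via ``alphas``.  A companion Poisson GLM (linear terms)
    screens outliers (|Pearson residual| > 3), which are removed before the
    final fit.  Residual autocorrelation is summarized by the
    Durbin-Watson statistic on age-ordered deviance residuals.
    """
    y = np.asarray(richness, dtype=float)
    if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
        raise ValueError("richness must be non-negative integers")
    names = list(covariates.columns)
    Xr = covariates.to_numpy(dtype=float)
    n = len(y)
    if Xr.shape[0] != n:
        raise ValueError("richness and covariates misaligned")

    # companion GLM for outlier screening
    Xlin = np.column_stack([np.ones(n)] + [Xr[:, j] for j in range(Xr.shape[1])])
    glm_beta, _, _, _ = _pirls(Xlin, y, np.zeros(Xlin.shape[1]))
    mu_glm = np.exp(Xlin @ glm_beta)
    pearson_glm = (y - mu_glm) / np.sqrt(mu_glm)
    outliers = (
        list(np.nonzero(np.abs(pearson_glm) > outlier_threshold)[0])
        if screen_outliers
        else []
    )
    use = np.setdiff1d(np.arange(n), outliers)

    yu, Xu = y[use], Xr[use]
    smooths = []
    blocks = [np.ones((len(use), 1))]
    pen_template = [0.0]
    for j in range(Xu.shape[1]):
        lin, Z, predcols = _smooth_basis(Xu[:, j], k=k)
        smooths.append((lin, Z, predcols))
        blocks.append(lin[:, None])
        pen_template.append(0.0)
        blocks.append(Z)
        pen_template.extend([np.nan] * Z.shape[1])  # placeholder -> alpha_j
    Xd = np.column_stack(blocks)
    pen_template = np.asarray(pen_template)

    slot = []
    start = 1
    for j, (_, Z, _) in enumerate(smooths):
        cols = slice(start + 1, start + 1 + Z.shape[1])
        slot.append(cols)
        start += 1 + Z.shape[1]

    def pen_diag(alpha_vec):
        d = np.where(np.isnan(pen_template), 0.0, pen_template).copy()
        for j, cols in enumerate(slot):
            d[cols] = alpha_vec[j]
        return d

    if alphas is None:
        # GCV with the customary gamma = 1.4 degrees-of-freedom inflation,
        # which guards against undersmoothing
        grid = 10.0 ** np.arange(-3, 11)
        gamma = 1.4
        alpha_vec = np.ones(len(smooths))
        for _ in range(2):  # coordinate-descent passes
            for j in range(len(smooths)):
                best = None
                for a in grid:
                    trial = alpha_vec.copy()
                    trial[j] = a
                    _, edf, dev, _ = _pirls(Xd, yu, pen_diag(trial))
                    gcv = len(yu) * dev / (len(yu) - gamma * edf) ** 2
                    if best is None or gcv < best[0]:
                        best = (gcv, a)
                alpha_vec[j] = best[1]
    else:
        alpha_vec = np.asarray([alphas[name] for name in names], dtype=float)

    beta, edf, deviance, Ainv = _pirls(Xd, yu, pen_diag(alpha_vec))
    eta = Xd @ beta
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dterm = np.where(yu > 0, yu * np.log(yu / mu), 0.0) - (yu - mu)
    dev_res = np.sign(yu - mu) * np.sqrt(np.maximum(2 * dterm, 0))
    pearson = (yu - mu) / np.sqrt(mu)

    # per-smooth edf
    XtW = Xd.T * mu
    Hdiag_full = Ainv @ (XtW @ Xd)
    edf_per = {}
    for j, name in enumerate(names):
        cols = list(range(slot[j].start - 1, slot[j].stop))  # linear + Z columns
        edf_per[name] = float(np.trace(Hdiag_full[np.ix_(cols, cols)]))

    dw = lag1 = None
    if ages is not None:
        order = np.argsort(np.asarray(ages, dtype=float)[use], kind="stable")
        e = dev_res[order]
        dw = durbin_watson(e)
        lag1 = float(np.corrcoef(e[:-1], e[1:])[0, 1]) if len(e) > 2 else np.nan

    grids = {}
    for j, name in enumerate(names):
        xx = np.linspace(Xu[:, j].min(), Xu[:, j].max(), grid_points)
        row_blocks = [np.ones((grid_points, 1))]
        for jj, (_, Z, predcols) in enumerate(smooths):
            if jj == j:
                lin_g, Z_g = predcols(xx)
            else:
                lin_g, Z_g = predcols(np.full(grid_points, Xu[:, jj].mean()))
            row_blocks.append(lin_g[:, None])
            row_blocks.append(Z_g)
        Xg = np.column_stack(row_blocks)
        eta_g = Xg @ beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Ainv, Xg), 0))
        grids[name] = pd.DataFrame(
            {
                "x": xx,
                "mean": np.exp(eta_g),
                "lower": np.exp(eta_g - 1.96 * se),
                "upper": np.exp(eta_g + 1.96 * se),
            }
        )

    return GAMResult(
        covariates=names,
        coefficients=beta,
        alphas={name: float(a) for name, a in zip(names, alpha_vec)},
        edf=edf,
        edf_per_smooth=edf_per,
        fitted=mu,
        linear_predictor=eta,
        deviance=deviance,
        deviance_residuals=dev_res,
        pearson_residuals=pearson,
        outliers=outliers,
        used_index=use,
        dw_statistic=dw,
        lag1_autocorrelation=lag1,
        prediction_grid=grids,
        glm_coefficients=glm_beta,
    )


# ---------------------------------------------------------------------------
# Piecewise SEM
# ---------------------------------------------------------------------------

@dataclass
class SEMResult:
    paths: pd.DataFrame  # from, to, coefficient, std_coefficient, p_value
    independence_claims: pd.DataFrame  # u, v, conditioning, p_value
    fisher_c: float
    df: int
    p_value: float
    marginal_r2: dict


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept: returns (coefs, p-values for non-intercept, r2)."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for regression")
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    return beta, pvals, r2


def piecewise_sem(edges: list[tuple[str, str]], data: pd.DataFrame) -> SEMResult:
    """Piecewise structural equation model over a user-specified DAG.

    Each endogenous variable is regressed (OLS) on its parents; path
    coefficients are standardized as raw * SD(x) / SD(y).  Model fit is
    Shipley's d-separation test: for every non-adjacent variable pair with
    at least one endogenous member, the implied conditional independence
    (given the union of both parents) is tested by the partial regression
    p-value, and the claims combine into Fisher's C = -2 sum ln p with
    df = 2k, compared against a chi-square upper tail.
    """
    import networkx as nx

    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("the path diagram must be acyclic")
    missing = [v for v in g.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")

    sd = data.std(ddof=1)
    rows = []
    r2 = {}
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        y = data[node].to_numpy(dtype=float)
        X = data[parents].to_numpy(dtype=float)
        beta, pvals, rsq = _ols(y, X)
        r2[node] = rsq
        for i, p in enumerate(parents):
            rows.append(
                {
                    "from": p,
                    "to": node,
                    "coefficient": beta[i + 1],
                    "std_coefficient": beta[i + 1] * sd[p] / sd[node],
                    "p_value": pvals[i + 1],
                }
            )
    paths = pd.DataFrame(rows, columns=["from", "to", "coefficient", "std_coefficient", "p_value"])

    # d-separation basis set (pairs with both members exogenous are free)
    order = list(nx.topological_sort(g))
    rank = {v: i for i, v in enumerate(order)}
    ancestors = {v: nx.ancestors(g, v) for v in g.nodes}
    exogenous = {v for v in g.nodes if g.in_degree(v) == 0}
    claims = []
    for u, v in itertools.combinations(sorted(g.nodes, key=rank.get), 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if u in exogenous and v in exogenous:
            continue
        a, b = (u, v) if v not in ancestors[u] else (v, u)  # b = non-ancestor: response
        cond = sorted((set(g.predecessors(a)) | set(g.predecessors(b))) - {a, b})
        y = data[b].to_numpy(dtype=float)
        X = data[cond + [a]].to_numpy(dtype=float)
        _, pvals, _ = _ols(y, X)
        claims.append(
            {"u": a, "v": b, "conditioning": tuple(cond), "p_value": float(pvals[-1])}
        )
    claims_df = pd.DataFrame(claims, columns=["u", "v", "conditioning", "p_value"])

    kclaims = len(claims_df)
    if kclaims:
        pvals = np.clip(claims_df["p_value"].to_numpy(), 1e-300, 1.0)
        C = float(-2 * np.sum(np.log(pvals)))
        df = 2 * kclaims
        p = float(stats.chi2.sf(C, df))
    else:
        C, df, p = 0.0, 0, 1.0
    return SEMResult(
        paths=paths,
        independence_claims=claims_df,
        fisher_c=C,
        df=df,
        p_value=p,
        marginal_r2=r2,
    )


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

def loess_smooth(y, x=None, span: float = 0.1, degree: int = 2) -> np.ndarray:
    """Local polynomial regression (tricube weights) at the observed points.

    ``span`` is the fraction of points in each local window (at least
    ``degree + 1``); weights follow the tricube kernel scaled by the
    window's largest distance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        h = d[idx].max()
        if h == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.maximum(w, 0)
        if w.sum() == 0 or np.count_nonzero(w) <= degree:
            w = w + 1e-12
        xc = x[idx] - x[i]
        V = np.vander(xc, degree + 1, increasing=True)
        WV = V * w[:, None]
        beta, *_ = np.linalg.lstsq(WV.T @ V, WV.T @ y[idx], rcond=None)
        out[i] = beta[0]
    return out
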
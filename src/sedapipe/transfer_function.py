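"""Weighted-averaging partial least squares (WA-PLS) transfer function.

Calibrates assemblage composition (here: chironomid head-capsule counts in
a modern lake training set) to an environmental variable (mean July air
temperature, deg C) and reconstructs it from fossil assemblages.

The component-extraction algorithm is the standard iterative one: species
scores are the weighted averages of current site scores, new site scores
the weighted averages of species scores, each component is orthogonalized
(site-total weighted inner product) against the previous ones and
standardized, the environmental variable is regressed on the components
(weighted least squares, site totals as weights), and the residuals seed
the next component.  With one component this reduces exactly to classical
weighted averaging with (weighted) inverse deshrinking.

Assemblages are converted to proportions and square-root transformed before
fitting, so predictions are invariant to the absolute count scale.
Uncertainty comes from bootstrap cross-validation: calibration sites are
resampled with replacement, the model refitted, and out-of-bag sites
predicted; RMSEP pools the out-of-bag errors, and the sample-specific error
is eSEP(s) = sqrt(s1(s)^2 + RMSEP^2) with s1 the standard deviation of the
bootstrap predictions for s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WAPLSModel",
    "amalgamate_low_counts",
    "wapls_fit",
    "wapls_predict",
    "bootstrap_validate",
]


# ---------------------------------------------------------------------------
# Sample amalgamation
# ---------------------------------------------------------------------------

def amalgamate_low_counts(
    counts: pd.DataFrame,
    depths: pd.Series,
    min_count: float = 40,
    exceptions=frozenset(),
):
    """Merge adjacent low-count samples until each unit reaches ``min_count``.

    ``counts`` is samples x taxa in stratigraphic order; ``depths`` gives
    each sample's depth (cm).  Greedy: the topmost deficient unit merges
    with whichever neighbour is nearer in depth (tie: the upper one).
    Samples in ``exceptions`` may stay below the minimum (per-sample
    override).  Returns ``(merged_counts, merged_depths, amalgamation_map)``
    where the map sends each merged unit id to the raw sample ids it contains.
    """
    exceptions = set(exceptions)
    units = [[sid] for sid in counts.index]
    totals = [float(counts.loc[sid].sum()) for sid in counts.index]
    vecs = [counts.loc[sid].astype(float).copy() for sid in counts.index]
    deps = [float(depths[sid]) for sid in counts.index]

    def deficient():
        for i, t in enumerate(totals):
            if t < min_count and not (set(units[i]) & exceptions):
                return i
        return None

    while len(units) > 1:
        i = deficient()
        if i is None:
            break
        if i == 0:
            j = 1
        elif i == len(units) - 1:
            j = i - 1
        else:
            j = i - 1 if abs(deps[i - 1] - deps[i]) <= abs(deps[i + 1] - deps[i]) else i + 1
        lo, hi = sorted((i, j))
        w = totals[lo] + totals[hi]
        deps[lo] = (
            (deps[lo] * totals[lo] + deps[hi] * totals[hi]) / w
            if w > 0
            else (deps[lo] + deps[hi]) / 2
        )
        vecs[lo] = vecs[lo] + vecs[hi]
        totals[lo] = w
        units[lo] = units[lo] + units[hi]
        del units[hi], totals[hi], vecs[hi], deps[hi]

    if len(units) == 1 and totals[0] < min_count and not (set(units[0]) & exceptions):
        warnings.warn("all samples amalgamated into one unit, still below min_count")

    ids = ["+".join(u) for u in units]
    merged = pd.DataFrame([v.to_numpy() for v in vecs], index=ids, columns=counts.columns)
    merged_depths = pd.Series(deps, index=ids)
    amap = {mid: list(u) for mid, u in zip(ids, units)}
    return merged, merged_depths, amap


# ---------------------------------------------------------------------------
# WA-PLS
# ---------------------------------------------------------------------------

@dataclass
class WAPLSModel:
    taxa: list
    n_components: int
    sqrt_transform: bool
    species_scores: np.ndarray  # (n_components, n_taxa): u per component
    ortho_coefs: list  # per component a: coefficients on components 0..a-1
    score_means: np.ndarray
    score_sds: np.ndarray
    regression_coefs: np.ndarray  # intercept + one coefficient per component
    fitted: np.ndarray
    apparent_r2: float
    apparent_rmse: float
    performance: dict = field(default_factory=dict)  # filled by bootstrap_validate


def _prepare(Y: np.ndarray, sqrt_transform: bool) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if (Y < 0).any():
        raise ValueError("assemblage matrix must be non-negative")
    rs = Y.sum(axis=1, keepdims=True)
    if (rs == 0).any():
        raise ValueError("assemblage matrix has an empty sample")
    P = Y / rs
    return np.sqrt(P) if sqrt_transform else P


def wapls_fit(
    Y, x, n_components: int = 2, sqrt_transform: bool = True, taxa=None
) -> WAPLSModel:
    """Fit a WA-PLS transfer function on a calibration set.

    ``Y`` is sites x taxa (counts or proportions), ``x`` the observed
    environmental values.  Requires at least ``n_components + 1`` sites and
    at least ``n_components`` taxa.
    """
    if isinstance(Y, pd.DataFrame):
        taxa = list(Y.columns) if taxa is None else list(taxa)
        Y = Y.to_numpy(dtype=float)
    else:
        Y = np.asarray(Y, dtype=float)
        taxa = [f"taxon_{k}" for k in range(Y.shape[1])] if taxa is None else list(taxa)
    x = np.asarray(x, dtype=float)
    n, m = Y.shape
    if m < n_components:
        raise ValueError("fewer taxa than components")
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 calibration sites")

    Yt = _prepare(Y, sqrt_transform)
    row = Yt.sum(axis=1)
    col = Yt.sum(axis=0)
    keep = col > 0
    w = row / row.sum()

    def wmean(v):
        return float(np.sum(w * v))

    comps: list[np.ndarray] = []
    species_scores = np.zeros((n_components, m))
    ortho_coefs: list[np.ndarray] = []
    score_means = np.zeros(n_components)
    score_sds = np.zeros(n_components)

    r = x - wmean(x)
    coefs = np.array([wmean(x)])  # intercept-only fallback (degenerate data)
    for a in range(n_components):
        u = np.zeros(m)
        u[keep] = (Yt[:, keep] * r[:, None]).sum(axis=0) / col[keep]
        species_scores[a] = u
        f = (Yt * u[None, :]).sum(axis=1) / row
        oc = np.zeros(a)
        for b in range(a):
            oc[b] = np.sum(w * f * comps[b])  # components are w-orthonormal
            f = f - oc[b] * comps[b]
        mu = wmean(f)
        sd = np.sqrt(wmean((f - mu) ** 2))
        if sd <= 1e-12 * (abs(mu) + 1.0):
            # no compositional signal left (e.g. identical assemblages):
            # keep the components extracted so far; with none, the model
            # predicts the weighted mean of x everywhere.
            break
        f = (f - mu) / sd
        comps.append(f)
        ortho_coefs.append(oc)
        score_means[a] = mu
        score_sds[a] = sd
        # weighted regression of x on components so far
        X = np.column_stack([np.ones(n)] + comps)
        W = np.diag(w)
        coefs = np.linalg.solve(X.T @ W @ X, X.T @ W @ x)
        fitted = X @ coefs
        r = x - fitted

    used = len(comps)
    species_scores = species_scores[:used]
    score_means = score_means[:used]
    score_sds = score_sds[:used]
    fitted = np.column_stack([np.ones(n)] + comps) @ coefs
    resid = x - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    return WAPLSModel(
        taxa=taxa,
        n_components=used,
        sqrt_transform=sqrt_transform,
        species_scores=species_scores,
        ortho_coefs=ortho_coefs,
        score_means=score_means,
        score_sds=score_sds,
        regression_coefs=coefs,
        fitted=fitted,
        apparent_r2=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        apparent_rmse=float(np.sqrt(ss_res / n)),
    )


def _scores_for(model: WAPLSModel, Yt: np.ndarray) -> np.ndarray:
    """Standardized component scores for transformed assemblages."""
    row = Yt.sum(axis=1)
    if model.n_components == 0:
        return np.zeros((Yt.shape[0], 0))
    comps = []
    for a in range(model.n_components):
        f = (Yt * model.species_scores[a][None, :]).sum(axis=1) / row
        for b, cb in enumerate(model.ortho_coefs[a]):
            f = f - cb * comps[b]
        f = (f - model.score_means[a]) / model.score_sds[a]
        comps.append(f)
    return np.column_stack(comps)


def wapls_predict(model: WAPLSModel, fossil, taxa=None) -> np.ndarray:
    """Predict the environmental variable for fossil assemblages.

    Taxa absent from the calibration set are ignored (a warning lists
    them); a sample containing no calibration taxon at all is an error.
    """
    if isinstance(fossil, pd.DataFrame):
        taxa = list(fossil.columns)
        fossil = fossil.to_numpy(dtype=float)
    else:
        fossil = np.atleast_2d(np.asarray(fossil, dtype=float))
        taxa = list(taxa) if taxa is not None else list(model.taxa)
    pos = {t: k for k, t in enumerate(model.taxa)}
    unknown = [t for t in taxa if t not in pos]
    if unknown:
        warnings.warn(f"taxa absent from calibration ignored: {unknown}")
    aligned = np.zeros((fossil.shape[0], len(model.taxa)))
    for j, t in enumerate(taxa):
        if t in pos:
            aligned[:, pos[t]] += fossil[:, j]
    if (aligned.sum(axis=1) == 0).any():
        bad = list(np.nonzero(aligned.sum(axis=1) == 0)[0])
        raise ValueError(f"samples with no calibration taxon: rows {bad}")
    Yt = _prepare(aligned, model.sqrt_transform)
    comps = _scores_for(model, Yt)
    X = np.column_stack([np.ones(len(comps))] + [comps[:, a] for a in range(comps.shape[1])])
    return X @ model.regression_coefs


def bootstrap_validate(
    Y,
    x,
    fossil=None,
    n_components: int = 2,
    n_boot: int = 9999,
    seed: int = 0,
    sqrt_transform: bool = True,
    taxa=None,
    fossil_taxa=None,
) -> dict:
    """Bootstrap cross-validation: RMSEP, r^2, and per-fossil-sample eSEP.

    Per cycle the calibration sites are resampled with replacement, the
    model refitted, out-of-bag sites and fossil samples predicted.  RMSEP
    pools the out-of-bag residuals; r^2 is the squared correlation between
    mean out-of-bag prediction and observation; eSEP combines the bootstrap
    prediction spread with RMSEP in quadrature.  Deterministic under
    ``seed``.
    """
    if isinstance(Y, pd.DataFrame):
        taxa = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    else:
        Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_boot < 2:
        warnings.warn("n_boot < 2: eSEP is degenerate (no bootstrap spread)")
    rng = np.random.default_rng(seed)

    oob_sq, oob_cnt = [], np.zeros(n)
    oob_sum = np.zeros(n)
    if fossil is not None:
        if isinstance(fossil, pd.DataFrame):
            fossil_taxa = list(fossil.columns)
            fossil_arr = fossil.to_numpy(dtype=float)
        else:
            fossil_arr = np.atleast_2d(np.asarray(fossil, dtype=float))
            fossil_taxa = fossil_taxa or taxa
        fs_sum = np.zeros(fossil_arr.shape[0])
        fs_sumsq = np.zeros(fossil_arr.shape[0])
        n_f = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        try:
            model = wapls_fit(
                Y[idx], x[idx], n_components, sqrt_transform=sqrt_transform, taxa=taxa
            )
        except ValueError:
            continue  # degenerate resample (e.g. constant x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = wapls_predict(model, Y[oob], taxa=taxa)
            oob_sq.extend((pred - x[oob]) ** 2)
            oob_sum[oob] += pred
            oob_cnt[oob] += 1
            if fossil is not None:
                fp = wapls_predict(model, fossil_arr, taxa=fossil_taxa)
                fs_sum += fp
                fs_sumsq += fp**2
                n_f += 1

    rmsep = float(np.sqrt(np.mean(oob_sq)))
    seen = oob_cnt > 0
    mean_pred = np.full(n, np.nan)
    mean_pred[seen] = oob_sum[seen] / oob_cnt[seen]
    r = np.corrcoef(mean_pred[seen], x[seen])[0, 1]
    out = {"RMSEP": rmsep, "r2": float(r**2), "n_boot": n_boot, "seed": seed}
    if fossil is not None and n_f > 1:
        var = fs_sumsq / n_f - (fs_sum / n_f) ** 2
        s1 = np.sqrt(np.maximum(var, 0.0) * n_f / (n_f - 1))
        out["s1"] = s1
        out["eSEP"] = np.sqrt(s1**2 + rmsep**2)
        out["fossil_mean_prediction"] = fs_sum / n_f
    elif fossil is not None:
        out["eSEP"] = np.full(fossil_arr.shape[0], np.nan)
    return out
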
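"""Receptor-density mapping: spatial correlations and dominance analysis.

Relates a regional atrophy contrast map to receptor/transporter density
maps (typically 15 tracers across five neurotransmitter systems) in two
ways: per-receptor spatial correlation with parametric or permutation
significance, and all-subsets dominance analysis of a multiple regression
of the contrast map on all receptors.

Dominance analysis fits the OLS R^2 of every subset of predictors (2^m
fits). The incremental contribution of predictor i to a subset S not
containing it is R^2(S u {i}) - R^2(S); its *total dominance* is the
average over subset sizes of the mean increment at that size, and the
total dominances sum exactly to the full-model R^2 — an additive
decomposition of explained variance. *Relative importance* expresses each
total dominance as a percentage of the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .io import as_series
from .synthetic import ReceptorAtlas

__all__ = ["DominanceResult", "correlate_receptors", "dominance_analysis"]

MAX_PREDICTORS = 20  # 2^m subset fits; beyond this, pre-select predictors


@dataclass
class DominanceResult:
    """Additive R^2 decomposition over receptors.

    ``total_dominance`` per receptor sums to ``full_r2``;
    ``relative_importance`` is each share as a percentage of ``full_r2``.
    """

    total_dominance: pd.Series
    relative_importance: pd.Series
    full_r2: float
    n_subsets: int


def _atlas_frame(atlas) -> pd.DataFrame:
    return atlas.densities if isinstance(atlas, ReceptorAtlas) else pd.DataFrame(atlas)


def correlate_receptors(
    y,
    atlas,
    method: str = "pearson",
    null: str = "parametric",
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatial correlation of the contrast map with each receptor map.

    Returns a table (receptor, r, p, q) where q is the BH-FDR adjusted
    p across receptors. ``null='parametric'`` uses the analytic t-based
    test; ``null='shuffle'`` permutes the contrast map's regions (two-sided
    on |r|, add-one smoothing). Constant receptor columns are flagged with
    NaN correlations and excluded from adjustment.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if null not in ("parametric", "shuffle"):
        raise ValueError(f"unknown null type {null!r}")
    dens = _atlas_frame(atlas)
    ys = as_series(y)
    dens = dens.loc[ys.index] if set(ys.index) <= set(dens.index) else dens
    yv = ys.to_numpy()
    if yv.size < 5:
        raise ValueError("need at least 5 regions")

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    rng = np.random.default_rng(seed)
    for name in dens.columns:
        col = dens[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            rows.append((name, np.nan, np.nan, True))
            continue
        r_obs, p_par = corr(yv, col)
        if null == "parametric":
            p = p_par
        else:
            null_r = np.empty(n_null)
            for i in range(n_null):
                perm = yv[rng.permutation(yv.size)]
                null_r[i] = corr(perm, col)[0]
            p = (1.0 + np.count_nonzero(np.abs(null_r) >= abs(r_obs))) / (1.0 + n_null)
        rows.append((name, float(r_obs), float(p), False))

    out = pd.DataFrame(rows, columns=["receptor", "r", "p", "constant"]).set_index(
        "receptor"
    )
    ok = ~out["constant"]
    q = pd.Series(np.nan, index=out.index)
    if ok.any():
        q.loc[ok] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


def dominance_analysis(y, atlas) -> DominanceResult:
    """All-subsets dominance analysis of the contrast map on receptor maps.

    Receptor columns are z-scored for conditioning (R^2 is affine-invariant,
    so results are unchanged); subset R^2 values come from the Gram system
    of the standardized design, enumerated over all 2^m predictor subsets.
    """
    dens = _atlas_frame(atlas)
    ys = as_series(y)
    dens = dens.loc[ys.index] if set(ys.index) <= set(dens.index) else dens
    names = list(dens.columns)
    m = len(names)
    if m > MAX_PREDICTORS:
        raise ValueError(
            f"{m} predictors would need 2^{m} subset fits; pre-select at most "
            f"{MAX_PREDICTORS}"
        )
    X = dens.to_numpy(dtype=float)
    yv = ys.to_numpy()
    n = yv.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1 = {m + 1} regions, got {n}")

    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = names[int(np.argmin(sd))]
        raise ValueError(f"constant receptor column: {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    yc = yv - yv.mean()
    syy = yc @ yc
    if syy == 0:
        raise ValueError("constant contrast map")

    C = Xs.T @ Xs  # Gram matrix of standardized predictors
    c = Xs.T @ yc
    if np.linalg.matrix_rank(C) < m:
        raise ValueError("rank-deficient receptor design (collinear columns)")

    n_subsets = 1 << m
    r2 = np.zeros(n_subsets)
    members: list[np.ndarray] = [np.empty(0, dtype=int)] * n_subsets
    for mask in range(1, n_subsets):
        idx = np.flatnonzero([(mask >> j) & 1 for j in range(m)])
        members[mask] = idx
        beta = np.linalg.solve(C[np.ix_(idx, idx)], c[idx])
        r2[mask] = (c[idx] @ beta) / syy

    sizes = np.array([bin(mask).count("1") for mask in range(n_subsets)])
    total = np.zeros(m)
    for i in range(m):
        bit = 1 << i
        inc_sum = np.zeros(m)  # summed increments by |S| = 0..m-1
        inc_cnt = np.zeros(m)
        for mask in range(n_subsets):
            if mask & bit:
                continue
            s = sizes[mask]
            inc_sum[s] += r2[mask | bit] - r2[mask]
            inc_cnt[s] += 1
        total[i] = np.mean(inc_sum / inc_cnt)

    full = r2[n_subsets - 1]
    rel = 100.0 * total / full if full > 0 else np.full(m, np.nan)
    return DominanceResult(
        total_dominance=pd.Series(total, index=names, name="total_dominance"),
        relative_importance=pd.Series(rel, index=names, name="relative_importance"),
        full_r2=float(full),
        n_subsets=n_subsets,
    )
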
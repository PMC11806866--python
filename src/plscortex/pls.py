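"""Single-response partial least squares with bootstrap gene significance.

The association between a regional gene-expression matrix X (n regions x p
genes) and a regional atrophy contrast map Y (n x 1) is modelled by PLS
regression,

    X = Z V^T + E,      Y = Z b + e,

where Z holds latent component scores, V unit-norm gene weight vectors, b
the coefficients linking scores to Y, and E, e residuals. For a single
response, the first weight vector is proportional to the cross-covariance
X_c^T y_c of the centered blocks — the linear gene combination maximally
covarying with the contrast map. Only the first component (PLS1) is
consumed downstream; later components are computed by deflation.

Inference on PLS1 follows the resampling scheme standard in imaging
transcriptomics: the n regions are resampled with replacement jointly in X
and Y, the model refit per replicate, and each gene's z-score is its
original weight divided by the bootstrap standard error of the (sign-
aligned) replicate weights. Genes with VIP > 1 and two-sided p < 0.05 form
the PLS1+ (positive weight) and PLS1- (negative weight) sets. The
significance of the variance explained by PLS1 is assessed against a null
distribution obtained by permuting (or bootstrap-resampling) Y over regions
with X fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, check_aligned
from .utils import empirical_pvalue

__all__ = [
    "PLSModel",
    "GeneStats",
    "NullDistribution",
    "GeneSelection",
    "fit_pls1",
    "null_variance_explained",
    "bootstrap_gene_weights",
    "compute_vip",
    "select_genes",
]


@dataclass
class PLSModel:
    """Fitted PLS decomposition (k components, single response).

    ``scores`` (Z, n x k), ``weights`` (V, p x k, unit-norm columns),
    ``coefficients`` (b, k), ``x_residual`` (E), ``y_residual`` (e).
    ``variance_explained`` is 100 x R^2 of Y regressed on the first
    component's scores. The first component's sign is fixed so that
    corr(Z1, Y) >= 0.
    """

    k: int
    scores: np.ndarray
    weights: pd.DataFrame
    coefficients: np.ndarray
    x_residual: np.ndarray
    y_residual: np.ndarray
    variance_explained: float
    genes: list[str]
    regions: list[str]
    y_name: str = "t"

    @property
    def loadings(self) -> np.ndarray:
        """V^T (k x p), the gene loadings in transposed-weight form."""
        return self.weights.to_numpy().T

    @property
    def pls1_weights(self) -> pd.Series:
        return self.weights.iloc[:, 0]

    @property
    def pls1_scores(self) -> np.ndarray:
        return self.scores[:, 0]


@dataclass
class GeneStats:
    """Per-gene bootstrap inference for PLS1 weights.

    ``table`` columns: weight (original PLS1 weight), se (bootstrap SE),
    z (weight/se), p (two-sided normal tail), vip, degenerate (SE == 0 with
    nonzero weight).
    """

    table: pd.DataFrame
    n_boot: int
    seed: int
    n_redrawn: int = 0


@dataclass
class NullDistribution:
    """Observed statistic against a resampling null."""

    observed: float
    null_values: np.ndarray
    n_iterations: int
    p_value: float
    method: str = "permute"


@dataclass
class GeneSelection:
    """PLS1+/- gene sets passing the VIP and significance thresholds."""

    pls1_plus: list[str]
    pls1_minus: list[str]
    vip_cut: float
    alpha: float
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def all_genes(self) -> set[str]:
        return set(self.pls1_plus) | set(self.pls1_minus)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _pls1_weight(xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Unit-norm first weight vector: normalize(X_c^T y_c)."""
    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate fit: X and Y are uncorrelated everywhere")
    return w / norm


def _variance_explained(z: np.ndarray, yc: np.ndarray) -> float:
    """100 x R^2 of Y regressed (with intercept) on the score vector z."""
    zc = z - z.mean()
    denom = (zc @ zc) * (yc @ yc)
    if denom == 0:
        return 0.0
    return 100.0 * (zc @ yc) ** 2 / denom


def fit_pls1(x: ExpressionMatrix | pd.DataFrame | np.ndarray, y, k: int = 1) -> PLSModel:
    """Fit k PLS components of the contrast map on expression.

    Both blocks are centered internally. Weight vectors have unit Euclidean
    norm; the first component's sign is chosen so its scores correlate
    non-negatively with Y. Components beyond the first are obtained by
    deflating X (Y is deflated by the component regression).
    """
    if isinstance(x, ExpressionMatrix):
        genes, regions = x.genes, x.regions
        xv = x.values.to_numpy(dtype=float)
        yv = check_aligned(x, y)
    else:
        xv = np.asarray(getattr(x, "values", x), dtype=float)
        genes = list(x.columns) if isinstance(x, pd.DataFrame) else [
            f"g{i}" for i in range(xv.shape[1])
        ]
        regions = list(x.index) if isinstance(x, pd.DataFrame) else [
            f"r{i}" for i in range(xv.shape[0])
        ]
        yv = np.asarray(getattr(y, "t", y), dtype=float).ravel()

    n, p = xv.shape
    if n < 3:
        raise ValueError("need at least 3 regions")
    if yv.size != n:
        raise ValueError(f"response length {yv.size} != {n} regions")
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.ptp(yv) == 0:
        raise ValueError("degenerate response: Y is constant across regions")

    xc = _center(xv)
    yc = yv - yv.mean()

    Xd, yd = xc.copy(), yc.copy()
    W = np.empty((p, k))
    Z = np.empty((n, k))
    b = np.empty(k)
    for j in range(k):
        w = _pls1_weight(Xd, yd)
        z = Xd @ w
        if j == 0 and (z @ yc) < 0:  # sign convention: corr(Z1, Y) >= 0
            w, z = -w, -z
        zz = z @ z
        b[j] = (z @ yd) / zz
        p_load = (Xd.T @ z) / zz
        Xd = Xd - np.outer(z, p_load)
        yd = yd - b[j] * z
        W[:, j], Z[:, j] = w, z

    ve = _variance_explained(Z[:, 0], yc)
    return PLSModel(
        k=k,
        scores=Z,
        weights=pd.DataFrame(W, index=genes, columns=[f"pls{j + 1}" for j in range(k)]),
        coefficients=b,
        x_residual=Xd,
        y_residual=yd,
        variance_explained=ve,
        genes=list(genes),
        regions=list(regions),
    )


def null_variance_explained(
    x: ExpressionMatrix,
    y,
    n_iter: int = 5000,
    method: str = "permute",
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of PLS1 variance explained under resampled Y.

    Per iteration, Y's regional values are shuffled without replacement
    ('permute') or resampled with replacement ('bootstrap') while X is held
    fixed, PLS1 is refit, and its variance explained recorded. The empirical
    p-value uses add-one smoothing: (1 + #{null >= observed}) / (1 + n_iter).
    """
    if method not in ("permute", "bootstrap"):
        raise ValueError(f"unknown method {method!r}; use 'permute' or 'bootstrap'")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")

    xv = x.values.to_numpy(dtype=float) if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    yv = check_aligned(x, y) if isinstance(x, ExpressionMatrix) else np.asarray(y, float)
    xc = _center(xv)
    yc = yv - yv.mean()

    def ve_for(yvec: np.ndarray) -> float:
        yce = yvec - yvec.mean()
        if np.ptp(yce) == 0:
            return 0.0
        z = xc @ (xc.T @ yce)
        return _variance_explained(z, yce)

    observed = ve_for(yv)
    rng = np.random.default_rng(seed)
    n = yv.size
    null = np.empty(n_iter)
    for i in range(n_iter):
        if method == "permute":
            ynull = yc[rng.permutation(n)]
        else:
            ynull = yc[rng.integers(0, n, size=n)]
        null[i] = ve_for(ynull)

    p = empirical_pvalue(observed, null)
    return NullDistribution(
        observed=observed, null_values=null, n_iterations=n_iter, p_value=p,
        method=method,
    )


def bootstrap_gene_weights(
    x: ExpressionMatrix,
    y,
    n_boot: int = 5000,
    seed: int = 0,
    keep_replicates: bool = False,
) -> GeneStats:
    """Bootstrap PLS1 gene weights by resampling regions with replacement.

    Regions are resampled jointly in X and Y; PLS1 is refit per replicate
    and its weight vector sign-aligned to the original fit (flipped when the
    dot product is negative) so that the weight-vector sign indeterminacy
    does not inflate the standard errors. Per gene: SE = SD of aligned
    replicate weights (ddof=1), z = original weight / SE, p = two-sided
    standard-normal tail. A replicate with fewer than 3 distinct regions is
    redrawn (count reported). SE = 0 with a nonzero weight is flagged
    degenerate and assigned p = 0.

    Replicate weight vectors are expressed on the original fit's scale (the
    raw cross-covariance divided by the *observed* norm) rather than being
    re-normalized per replicate: z-scores are invariant to any common
    rescaling, but per-replicate renormalization adds spurious norm
    variability that deflates the SEs and makes the gene-level test
    anti-conservative under the null.

    With ``keep_replicates`` the aligned replicate weights are retained on
    the result (attribute ``replicates``) for percentile-based intervals.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")

    model = fit_pls1(x, y, k=1)
    w0 = model.pls1_weights.to_numpy()

    xv = x.values.to_numpy(dtype=float)
    yv = check_aligned(x, y)
    n, p = xv.shape
    xc0 = _center(xv)
    yc0 = yv - yv.mean()
    norm0 = np.linalg.norm(xc0.T @ yc0)  # common scale for all replicates

    rng = np.random.default_rng(seed)
    sum_w = np.zeros(p)
    sum_w2 = np.zeros(p)
    reps = np.empty((n_boot, p)) if keep_replicates else None
    n_redrawn = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size < 3 or np.ptp(yv[idx]) == 0:
            n_redrawn += 1
            continue
        xb = _center(xv[idx])
        yb = yv[idx] - yv[idx].mean()
        cross = xb.T @ yb
        if not np.any(cross):
            n_redrawn += 1
            continue
        wb = cross / norm0
        if wb @ w0 < 0:
            wb = -wb
        sum_w += wb
        sum_w2 += wb**2
        if reps is not None:
            reps[done] = wb
        done += 1

    mean_w = sum_w / n_boot
    var = (sum_w2 - n_boot * mean_w**2) / (n_boot - 1)
    se = np.sqrt(np.clip(var, 0.0, None))

    z, pvals, degenerate = _bootstrap_zscores(w0, se)

    vip = compute_vip(model)
    table = pd.DataFrame(
        {
            "weight": w0,
            "se": se,
            "z": z,
            "p": pvals,
            "vip": vip.to_numpy(),
            "degenerate": degenerate,
        },
        index=model.genes,
    )
    out = GeneStats(table=table, n_boot=n_boot, seed=seed, n_redrawn=n_redrawn)
    if reps is not None:
        out.replicates = pd.DataFrame(reps, columns=model.genes)  # type: ignore[attr-defined]
    return out


def _bootstrap_zscores(
    w0: np.ndarray, se: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z = weight/SE with two-sided normal p; SE=0 with nonzero weight is a
    degenerate (zero-bootstrap-variance) gene: flagged, z infinite, p = 0."""
    degenerate = (se == 0) & (w0 != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, np.where(w0 != 0, np.inf, 0.0))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[degenerate] = 0.0
    return z, pvals, degenerate


def compute_vip(model: PLSModel) -> pd.Series:
    """Variable importance in projection per gene.

    VIP_j = sqrt( p * sum_k [ SSY_k * (w_jk / ||w_k||)^2 ] / sum_k SSY_k ),
    where SSY_k is the Y sum of squares explained by component k. With a
    single component this reduces to sqrt(p) * |w_j| / ||w||, and the mean
    of VIP^2 over genes is exactly 1.
    """
    W = model.weights.to_numpy()
    p, k = W.shape
    zz = (model.scores**2).sum(axis=0)
    ssy = (model.coefficients**2) * zz  # per-component explained Y sum of squares
    total = ssy.sum()
    if total == 0:
        raise ValueError("degenerate model: zero explained variance")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / total)
    return pd.Series(vip, index=model.genes, name="vip")


def select_genes(
    stats_: GeneStats,
    vip_cut: float = 1.0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> GeneSelection:
    """Select PLS1+ / PLS1- genes: VIP > vip_cut and p < alpha (strict).

    The default thresholds (VIP > 1, uncorrected p < 0.05) follow standard
    imaging-transcriptomics practice; ``fdr=True`` applies Benjamini-
    Hochberg adjustment to the bootstrap p-values first.
    """
    t = stats_.table
    pv = t["p"].to_numpy()
    if fdr:
        from .enrichment import bh_fdr

        pv = bh_fdr(pv)
    passing = (t["vip"].to_numpy() > vip_cut) & (pv < alpha)
    plus = t.index[passing & (t["weight"].to_numpy() > 0)].tolist()
    minus = t.index[passing & (t["weight"].to_numpy() < 0)].tolist()
    return GeneSelection(
        pls1_plus=plus,
        pls1_minus=minus,
        vip_cut=vip_cut,
        alpha=alpha,
        weights=t["weight"].copy(),
    )
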
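"""Gene-set overlap testing: permutation nulls, hypergeometric ORA, BH-FDR.

Two complementary tests of whether a signature gene set (e.g. PLS1+/-)
shares more genes with a target list (e.g. a pathology-related gene list)
than chance expects:

* a permutation test that draws random gene sets of the signature's size
  from the background universe and counts overlaps with the target,
  yielding an empirical one-sided p (add-one smoothed so p is never 0);
* the exact hypergeometric tail P(X >= observed), which is both the
  analytic limit of the permutation scheme and the standard
  over-representation (ORA) statistic used against GMT term collections,
  with Benjamini-Hochberg FDR control across terms.

Target lists are intersected with the background before testing; both raw
and restricted sizes are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .utils import empirical_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "EnrichmentResult",
    "permutation_overlap_test",
    "hypergeometric_tail",
    "ora",
    "bh_fdr",
]


@dataclass
class PermutationResult:
    """Observed overlap against a random-gene-set null."""

    observed: int
    null_counts: np.ndarray
    p_value: float
    query_size: int
    target_size: int
    target_size_raw: int
    background_size: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= min(self.query_size, self.target_size):
            raise ValueError("observed overlap outside feasible range")


@dataclass
class EnrichmentResult:
    """Per-term over-representation table with BH-FDR q-values."""

    table: pd.DataFrame
    background_size: int
    q_threshold: float


def _as_set(genes) -> set[str]:
    members = getattr(genes, "members", genes)
    return {str(g).strip().upper() for g in members}


def hypergeometric_tail(
    overlap: int, query_size: int, target_size: int, background_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(background, target, query)."""
    if min(overlap, query_size, target_size, background_size) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(query_size, target_size):
        raise ValueError("overlap exceeds min(query_size, target_size)")
    if max(query_size, target_size) > background_size:
        raise ValueError("set sizes exceed background size")
    return float(
        stats.hypergeom.sf(overlap - 1, background_size, target_size, query_size)
    )


def permutation_overlap_test(
    query,
    target,
    background,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Random-gene-set permutation test of query/target overlap.

    Each draw samples |query| genes uniformly without replacement from the
    background and counts the overlap with the target (restricted to the
    background); p = (1 + #{null >= observed}) / (1 + n_perm), one-sided
    for enrichment.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    q = _as_set(query)
    t_raw = _as_set(target)
    bg = sorted(_as_set(background))
    bg_set = set(bg)
    stray = q - bg_set
    if stray:
        raise ValueError(
            f"query genes absent from background: {sorted(stray)[:5]}"
        )
    t = t_raw & bg_set
    if len(t) < len(t_raw):
        logger.info(
            "target restricted from %d to %d genes inside background",
            len(t_raw), len(t),
        )

    observed = len(q & t)
    rng = np.random.default_rng(seed)
    in_target = np.fromiter((g in t for g in bg), dtype=bool, count=len(bg))
    k = len(q)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(len(bg), size=k, replace=False)
        null[i] = int(in_target[idx].sum())

    p = empirical_pvalue(observed, null)
    return PermutationResult(
        observed=observed,
        null_counts=null,
        p_value=p,
        query_size=k,
        target_size=len(t),
        target_size_raw=len(t_raw),
        background_size=len(bg),
        seed=seed,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query,
    terms: dict[str, set[str]],
    background,
    q_threshold: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of the query against a GMT collection.

    Every term is intersected with the background before testing; BH-FDR is
    applied across all tested terms and terms with q < ``q_threshold`` are
    flagged significant.
    """
    if not terms:
        raise ValueError("empty term collection")
    q = _as_set(query)
    bg = _as_set(background)
    stray = q - bg
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)[:5]}")

    rows = []
    overlaps = []
    for name, members in terms.items():
        t = _as_set(members) & bg
        ov = sorted(q & t)
        p = (
            hypergeometric_tail(len(ov), len(q), len(t), len(bg))
            if t
            else 1.0
        )
        rows.append((name, len(t), len(ov), p))
        overlaps.append(ov)

    table = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "p"]
    ).set_index("term")
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < q_threshold
    table["overlap_genes"] = [",".join(ov) for ov in overlaps]
    return EnrichmentResult(
        table=table, background_size=len(bg), q_threshold=q_threshold
    )
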
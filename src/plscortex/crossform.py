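"""Cross-form comparison of PLS1 gene selections.

Given per-form PLS1+/- gene selections (e.g. one per genetic disease form),
computes pairwise intersections of the significant genes and labels each
shared gene concordant (same weight sign in both forms) or discordant
(opposite sign), plus the intersection across all forms and an upset-style
membership matrix for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .pls import GeneSelection

logger = logging.getLogger(__name__)

__all__ = ["ConcordanceTable", "compare_selections"]


@dataclass
class ConcordanceTable:
    """Pairwise sharing and sign-concordance of significant genes.

    ``pairs`` has one row per form pair with shared/concordant/discordant
    counts and the concordance fraction; ``shared_genes`` maps each pair to
    a per-gene table of signs; ``membership`` is a gene x form matrix with
    +1 (PLS1+), -1 (PLS1-) or 0 (not selected); ``common_to_all`` is the
    intersection of significant genes across every form.
    """

    pairs: pd.DataFrame
    shared_genes: dict[tuple[str, str], pd.DataFrame]
    membership: pd.DataFrame
    common_to_all: list[str]


def _sign_of(sel: GeneSelection, gene: str) -> int:
    return 1 if gene in sel.pls1_plus else -1


def compare_selections(selections: dict[str, GeneSelection]) -> ConcordanceTable:
    """Intersect significant gene sets across forms and score sign concordance."""
    if len(selections) < 2:
        raise ValueError("need at least 2 forms to compare")
    for form, sel in selections.items():
        if not sel.all_genes:
            logger.warning("form '%s' has an empty gene selection", form)

    forms = list(selections)
    all_sig = {f: selections[f].all_genes for f in forms}

    rows = []
    shared_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in combinations(forms, 2):
        shared = sorted(all_sig[a] & all_sig[b])
        signs_a = [_sign_of(selections[a], g) for g in shared]
        signs_b = [_sign_of(selections[b], g) for g in shared]
        conc = sum(sa == sb for sa, sb in zip(signs_a, signs_b))
        disc = len(shared) - conc
        frac = conc / len(shared) if shared else float("nan")
        rows.append((a, b, len(shared), conc, disc, frac))
        shared_tables[(a, b)] = pd.DataFrame(
            {"gene": shared, f"sign_{a}": signs_a, f"sign_{b}": signs_b}
        ).set_index("gene")

    pairs = pd.DataFrame(
        rows,
        columns=["form_a", "form_b", "shared", "concordant", "discordant",
                 "concordance_fraction"],
    )

    universe = sorted(set().union(*all_sig.values())) if any(all_sig.values()) else []
    membership = pd.DataFrame(0, index=universe, columns=forms, dtype=int)
    for f in forms:
        sel = selections[f]
        membership.loc[[g for g in sel.pls1_plus if g in membership.index], f] = 1
        membership.loc[[g for g in sel.pls1_minus if g in membership.index], f] = -1
    membership.index.name = "gene"

    common = sorted(set.intersection(*all_sig.values())) if forms else []
    return ConcordanceTable(
        pairs=pairs,
        shared_genes=shared_tables,
        membership=membership,
        common_to_all=common,
    )
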
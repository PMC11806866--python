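"""Reading, validating and aligning expression matrices and gene sets.

The expression matrix arrives as delimited text (regions x genes after a
published atlas-processing protocol); contrast maps and receptor atlases are
keyed to the same parcellation labels. This module validates orientation,
uniqueness and missingness, aligns everything on a shared region index, and
reads/writes gene lists (one symbol per line) and GMT gene-set collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signature import ContrastMap

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_expression",
    "write_expression",
    "align_regions",
    "column_standardize",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "canonicalize_symbols",
]


def canonicalize_symbols(symbols) -> list[str]:
    """Uppercase, whitespace-stripped gene symbols (no alias resolution)."""
    return [str(s).strip().upper() for s in symbols]


@dataclass
class GeneSet:
    """A named set of gene symbols in canonical (uppercase) form."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set '{self.name}' is empty")
        self.members = set(canonicalize_symbols(self.members))


@dataclass
class ExpressionMatrix:
    """Region x gene matrix of normalized expression values.

    ``values`` has region labels as the index and unique gene symbols as
    columns; no missing values survive validation.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 3:
            raise ValueError("expression matrix needs at least 3 regions")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate gene column: {dup}")
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def regions(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, transpose_if_needed: bool = True) -> ExpressionMatrix:
    """Read a delimited region x gene matrix, auto-detecting orientation.

    Expression matrices have many more genes than regions, so a file with
    more rows than columns is treated as transposed (genes as rows) and
    flipped when ``transpose_if_needed`` is set. Rows or columns containing
    any missing value are dropped with logged counts; non-numeric cells
    raise a parse error naming the offending coordinates.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValueError(f"duplicate gene column: {label}")
        seen.add(label)

    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[0]
            raise ValueError(f"non-numeric cell at row '{row}', column '{col}'")
    if transpose_if_needed and df.shape[0] > df.shape[1]:
        logger.info("transposing %s: detected genes-as-rows orientation", path)
        df = df.T

    n_bad_rows = int(df.isna().any(axis=1).sum())
    if n_bad_rows:
        logger.warning("dropping %d regions with missing values", n_bad_rows)
        df = df.dropna(axis=0)
    n_bad_cols = int(df.isna().any(axis=0).sum())
    if n_bad_cols:
        logger.warning("dropping %d genes with missing values", n_bad_cols)
        df = df.dropna(axis=1)

    df.columns = canonicalize_symbols(df.columns)
    return ExpressionMatrix(values=df)


def write_expression(x: ExpressionMatrix, path) -> None:
    x.values.to_csv(path, sep=_sep_for(path), index_label="region")


def align_regions(
    x: ExpressionMatrix, y: ContrastMap
) -> tuple[ExpressionMatrix, ContrastMap]:
    """Restrict both inputs to their common regions, in x's original order."""
    common = [r for r in x.regions if r in set(y.regions)]
    if not common:
        raise ValueError(
            "no common region labels; expression has e.g. "
            f"{x.regions[:3]}, contrast has e.g. {y.regions[:3]}"
        )
    if len(common) < 3:
        raise ValueError(f"only {len(common)} regions in common; need at least 3")
    x2 = ExpressionMatrix(values=x.values.loc[common])
    y2 = ContrastMap(
        t=y.t.loc[common],
        df=y.df,
        target=y.target,
        reference=y.reference,
        metadata=dict(y.metadata),
    )
    return x2, y2


def column_standardize(x: ExpressionMatrix, mode: str = "center") -> ExpressionMatrix:
    """Per-gene centering ('center'), z-scoring ('zscore'), or identity ('none').

    Under 'zscore', constant genes cannot be scaled and are dropped with a
    warning.
    """
    if mode == "none":
        return x
    v = x.values
    if mode == "center":
        return ExpressionMatrix(values=v - v.mean(axis=0))
    if mode == "zscore":
        sd = v.std(axis=0, ddof=0)
        constant = sd[sd == 0].index
        if len(constant):
            logger.warning("dropping %d constant genes under zscore", len(constant))
            v = v.drop(columns=constant)
            sd = sd.drop(index=constant)
        return ExpressionMatrix(values=(v - v.mean(axis=0)) / sd)
    raise ValueError(f"unknown standardization mode: {mode!r}")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        raw = [line.strip() for line in fh]
    return canonicalize_symbols(
        [s for s in raw if s and not s.startswith("#")]
    )


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(canonicalize_symbols(genes))):
            fh.write(g + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT collection: name <tab> description <tab> member symbols."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"malformed GMT line {i + 1} in {path}")
                continue
            name, _desc, *members = parts
            terms[name] = set(canonicalize_symbols(m for m in members if m))
    if not terms:
        raise ValueError(f"no gene sets found in {path}")
    return terms


def write_gmt(terms: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in terms.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def as_series(y) -> pd.Series:
    """Coerce a ContrastMap or Series-like to a float Series."""
    if isinstance(y, ContrastMap):
        return y.t.astype(float)
    return pd.Series(y, dtype=float)


def check_aligned(x: ExpressionMatrix, y) -> np.ndarray:
    """Return y as an array aligned with x's regions (by label if possible)."""
    ys = as_series(y)
    if set(ys.index) >= set(x.regions):
        return ys.loc[x.regions].to_numpy()
    if len(ys) == x.n:
        return ys.to_numpy()
    raise ValueError(
        f"response has {len(ys)} values but expression has {x.n} regions"
    )
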
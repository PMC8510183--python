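"""Count-table I/O and preprocessing arithmetic.

Count tables are plain :class:`pandas.DataFrame` objects with features
(genera or AMR genes) on the rows and samples on the columns.  The
preprocessing chain applied to metagenomic mapping output is

1. :func:`halve_pairs` — mapped *proper pairs* count each fragment twice,
   so every entry is divided by two ("raw count table"),
2. :func:`genome_size_normalize` — divide each taxon row by its genome
   size so abundant-but-large genomes are not over-counted,
3. :func:`total_sum_scale` — close each sample to relative abundances.

The composition is scale-invariant per sample: multiplying a raw column by
any positive constant leaves the final relative abundances unchanged.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "halve_pairs",
    "genome_size_normalize",
    "total_sum_scale",
    "aggregate",
]


def read_table(path) -> pd.DataFrame:
    """Read a tab-delimited feature × sample table (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a feature × sample table as TSV, 12 significant digits."""
    df.to_csv(path, sep="\t", float_format="%.12g")


def _check_nonnegative(df: pd.DataFrame, what: str) -> None:
    vals = df.to_numpy()
    if (vals < 0).any():
        i, j = map(int, np.argwhere(vals < 0)[0])
        raise ValueError(
            f"{what}: negative entry at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )


def halve_pairs(raw: pd.DataFrame, allow_odd: bool = False) -> pd.DataFrame:
    """Divide every mapped-fragment count by two (paired-end mapping).

    Parameters
    ----------
    raw
        Mapped read counts; features × samples.
    allow_odd
        If False (default), an odd entry is an error — proper-pair mapping
        yields even read counts, so an odd value signals an upstream
        problem.  If True, odd entries are halved to x.5.
    """
    _check_nonnegative(raw, "halve_pairs")
    vals = raw.to_numpy()
    if not allow_odd:
        odd = np.mod(vals, 2) != 0
        if odd.any():
            i, j = map(int, np.argwhere(odd)[0])
            raise ValueError(
                f"halve_pairs: odd count {vals[i, j]} at feature "
                f"{raw.index[i]!r}, sample {raw.columns[j]!r}; pass "
                f"allow_odd=True to permit half-integer results"
            )
    return raw / 2


def genome_size_normalize(
    table: pd.DataFrame,
    genome_sizes_bp: pd.Series,
    scale_bp: float = 1e6,
) -> pd.DataFrame:
    """Divide each feature row by its genome (or gene) size.

    ``scale_bp`` sets the size unit (default per Mbp) so magnitudes stay of
    the order of the counts; the constant cancels under total-sum scaling.
    """
    sizes = genome_sizes_bp.reindex(table.index)
    missing = table.index[sizes.isna()].tolist()
    if missing:
        raise ValueError(f"genome_size_normalize: no genome size for {missing}")
    bad = table.index[sizes <= 0].tolist()
    if bad:
        raise ValueError(f"genome_size_normalize: non-positive genome size for {bad}")
    return table.div(sizes / scale_bp, axis=0)


def total_sum_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Close every sample column to sum 1 (relative abundance).

    All-zero columns are retained as zeros with a warning rather than
    dropped, so sample bookkeeping downstream stays intact.
    """
    _check_nonnegative(table, "total_sum_scale")
    totals = table.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"total_sum_scale: all-zero sample(s) retained as zeros: "
            f"{list(table.columns[zero])}",
            UserWarning,
            stacklevel=2,
        )
    return table.div(totals.where(~zero, 1.0), axis=1)


def aggregate(
    table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    unmapped: str = "error",
) -> pd.DataFrame:
    """Sum feature rows into groups (genus → phylum, gene → AMR class, ...).

    Total mass per sample is conserved.  ``unmapped`` controls features
    absent from the map: ``"error"`` raises, ``"unassigned"`` routes them
    to an ``"unassigned"`` group.
    """
    mapped = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = mapped.reindex(table.index)
    if labels.isna().any():
        missing = table.index[labels.isna()].tolist()
        if unmapped == "error":
            raise ValueError(f"aggregate: unmapped feature(s): {missing}")
        elif unmapped == "unassigned":
            labels = labels.fillna("unassigned")
        else:
            raise ValueError(f"aggregate: unknown unmapped policy {unmapped!r}")
    out = table.groupby(labels).sum()
    out.index.name = table.index.name
    return out
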
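"""Antimicrobial-resistance gene quantification (FPKM) and summaries.

AMR gene abundance is expressed as fragments per kilobase of reference gene
per million *bacterial* fragments (FPKM): gene fragments are normalized by
gene length and by each sample's bacterial sequencing depth, so resistome
abundance is comparable across samples regardless of eukaryotic/viral
content.  Gene-level FPKM aggregates additively into antimicrobial-class
abundance, and resistome structure is compared against taxonomic structure
per sample matrix with a Procrustes/protest analysis on matched PCoA
ordinations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import counts as _counts
from .diversity import rarefy_curve
from .ordination import ProcrustesResult, bray_curtis, hellinger, pcoa, procrustes_protest

__all__ = [
    "bacterial_totals",
    "fpkm",
    "class_abundance",
    "amr_rarefaction",
    "resistome_vs_taxonomy",
]


def bacterial_totals(taxa_counts: pd.DataFrame, taxa_meta: pd.DataFrame,
                     bacterial_phyla) -> pd.Series:
    """Per-sample bacterial fragment totals (eukaryote/archaeal/viral taxa excluded)."""
    phyla = taxa_meta["phylum"].reindex(taxa_counts.index)
    mask = phyla.isin(list(bacterial_phyla)).to_numpy()
    return taxa_counts.loc[mask].sum(axis=0)


def fpkm(
    gene_counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    bacterial_fragment_totals: pd.Series,
) -> pd.DataFrame:
    """FPKM_gj = fragments_gj / (length_g / 1000) / (bacterial_total_j / 1e6)."""
    lengths = gene_lengths_bp.reindex(gene_counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = list(gene_counts.index[lengths.isna() | (lengths <= 0)])
        raise ValueError(f"fpkm: missing/non-positive gene length for {bad}")
    totals = bacterial_fragment_totals.reindex(gene_counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        bad = list(gene_counts.columns[totals.isna() | (totals <= 0)])
        raise ValueError(f"fpkm: zero bacterial fragment total for sample(s) {bad}")
    per_kb = gene_counts.div(lengths / 1000.0, axis=0)
    return per_kb.div(totals / 1e6, axis=1)


def class_abundance(
    fpkm_table: pd.DataFrame,
    gene_classes: pd.Series,
    sheet: pd.DataFrame | None = None,
) -> dict:
    """Aggregate FPKM to antimicrobial classes.

    Returns ``classes`` (class × sample FPKM), ``total`` (per-sample total
    AMR FPKM), ``shares_pct`` (per-sample class percentage shares), and,
    when a sample sheet is given, ``matrix_mean_shares_pct`` (shares
    averaged per sample matrix).
    """
    classes = _counts.aggregate(fpkm_table, gene_classes)
    total = classes.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = classes.div(total.where(total > 0, 1.0), axis=1) * 100.0
    out = {"classes": classes, "total": total, "shares_pct": shares}
    if sheet is not None:
        matrix = sheet.loc[shares.columns, "matrix"]
        out["matrix_mean_shares_pct"] = shares.T.groupby(matrix).mean().T
    return out


def amr_rarefaction(
    gene_counts: pd.DataFrame,
    depths,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene-richness rarefaction per sample (fragments subsampled without
    replacement, same contract as taxonomic rarefaction)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for sample in gene_counts.columns:
        curve = rarefy_curve(gene_counts[sample], depths, iterations, rng)
        curve = curve.assign(sample_id=sample)
        frames.append(curve.reset_index())
    return pd.concat(frames, ignore_index=True)


def resistome_vs_taxonomy(
    taxa_counts: pd.DataFrame,
    amr_table: pd.DataFrame,
    sheet: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> dict[str, ProcrustesResult]:
    """Procrustes/protest comparison of resistome vs taxonomy per matrix.

    For each sample matrix, both tables are Hellinger-transformed,
    Bray-Curtis dissimilarities are embedded by PCoA, and the two
    ordinations (first min(n−1, axes) principal coordinates) are compared
    with a permutation protest.  Matrices with fewer than 4 samples are
    skipped with a warning.  ``amr_table`` may be gene- or class-level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results: dict[str, ProcrustesResult] = {}
    common = [s for s in taxa_counts.columns if s in amr_table.columns]
    sheet = sheet.loc[common]
    for matrix, msheet in sheet.groupby("matrix", sort=True):
        ids = list(msheet.index)
        if len(ids) < 4:
            warnings.warn(
                f"resistome_vs_taxonomy: matrix {matrix} has <4 samples; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        coords = []
        for table in (taxa_counts[ids], amr_table[ids]):
            res = pcoa(bray_curtis(hellinger(table)))
            k = min(len(ids) - 1, res.coordinates.shape[1])
            coords.append(res.coordinates.iloc[:, :k])
        results[matrix] = procrustes_protest(
            coords[0], coords[1], n_permutations=n_permutations, seed=rng
        )
    return results
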
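"""Permutational multivariate statistics and differential abundance.

PERMANOVA partitions squared pairwise dissimilarities into between- and
within-group sums of squares and assesses the pseudo-F by permuting group
labels; it is paired with a multivariate dispersion-homogeneity check
(betadisper) because heterogeneous dispersions can masquerade as location
effects.  Differential abundance uses a per-taxon negative-binomial Wald
test with custom size factors (sample total / mean of totals) — a
deliberately transparent approximation to DESeq2-style analysis, with
method-of-moments dispersions shrunk toward a fitted mean-dispersion trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ordination import DistanceMatrix, pcoa

__all__ = [
    "PermanovaResult",
    "permanova",
    "betadisper",
    "BetadisperResult",
    "dissimilarity_groups",
    "GroupTestResult",
    "storage_pair_grouping",
    "dissimilarity_to_baseline",
    "custom_size_factors",
    "nb_wald_test",
    "DiffAbundanceResult",
    "significance_counts",
]


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    betadisper_p: float | None = None


@dataclass
class BetadisperResult:
    f_statistic: float
    p_value: float
    n_permutations: int
    distances: pd.Series | None = None


def _align_groups(dm: DistanceMatrix, groups: pd.Series) -> np.ndarray:
    g = pd.Series(groups).reindex(list(dm.ids))
    if g.isna().any():
        missing = [s for s, v in g.items() if pd.isna(v)]
        raise ValueError(f"group labels missing for samples: {missing}")
    return g.to_numpy()


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    G = np.zeros((n, n_groups))
    G[np.arange(n), codes] = 1.0
    sizes = G.sum(axis=0)
    ss_within = float((((G.T @ d2) * G.T).sum(axis=1) / (2 * sizes)).sum())
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA (adonis-style) on a dissimilarity matrix.

    SS_total = Σ_{i<j} d²_ij / N; SS_within sums, per group, the squared
    dissimilarities among its members over the group size.  The p-value
    permutes group labels and uses the add-one estimator.
    """
    labels = _align_groups(dm, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("permanova: need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        singles = [u for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"permanova: singleton group(s): {singles}")
    d2 = dm.data**2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniq))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(codes))
        f_perm, _ = _permanova_stats(d2, codes[perm], len(uniq))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), p, n_permutations)


def _dispersion_distances(
    pos_coords: np.ndarray, neg_coords: np.ndarray, codes: np.ndarray, n_groups: int
) -> np.ndarray:
    d2 = np.zeros(len(codes))
    for g in range(n_groups):
        m = codes == g
        cp = pos_coords[m].mean(axis=0)
        sq = ((pos_coords[m] - cp) ** 2).sum(axis=1)
        if neg_coords.shape[1]:
            cn = neg_coords[m].mean(axis=0)
            sq = sq - ((neg_coords[m] - cn) ** 2).sum(axis=1)
        d2[m] = sq
    return np.sqrt(np.clip(d2, 0.0, None))


def betadisper(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> BetadisperResult:
    """Homogeneity of multivariate dispersions (betadisper + permutest).

    Samples are embedded by PCoA keeping every axis; squared distances to
    the group centroid add contributions from positive-eigenvalue axes and
    subtract those from negative-eigenvalue axes (imaginary components of a
    non-Euclidean embedding).  A one-way ANOVA F on the distances is
    assessed by permuting group labels.
    """
    labels = _align_groups(dm, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("betadisper: every group needs at least two samples")
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh((centered + centered.T) / 2)
    scale = max(np.abs(eigvals).max(), 1.0)
    pos = eigvals > 1e-9 * scale
    neg = eigvals < -1e-9 * scale
    pos_coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_coords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    def f_stat(c):
        dist = _dispersion_distances(pos_coords, neg_coords, c, len(uniq))
        grp = [dist[c == g] for g in range(len(uniq))]
        return sps.f_oneway(*grp).statistic, dist

    f_obs, dist_obs = f_stat(codes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        f_perm, _ = f_stat(codes[rng.permutation(n)])
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return BetadisperResult(
        float(f_obs), p, n_permutations,
        distances=pd.Series(dist_obs, index=list(dm.ids)),
    )


@dataclass
class GroupTestResult:
    levene_p_raw: float
    levene_p_log: float
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame | None
    group_sizes: dict


def storage_pair_grouping(sheet: pd.DataFrame) -> Callable[[str, str], str]:
    """Label sample pairs as within-replicate / within-matrix / between-matrix.

    Within-replicate means same matrix and same storage condition (the
    samples differ only by technical replicate).
    """
    matrix = sheet["matrix"]
    cond = sheet["condition"]

    def label(a: str, b: str) -> str:
        if matrix[a] != matrix[b]:
            return "between_matrix"
        if cond[a] == cond[b]:
            return "within_replicate"
        return "within_matrix"

    return label


def dissimilarity_groups(
    dm: DistanceMatrix,
    pair_grouping: Callable[[str, str], str | None],
    alpha: float = 0.05,
) -> GroupTestResult:
    """Levene, Kruskal-Wallis and (if warranted) Dunn tests on dissimilarity groups.

    ``pair_grouping(id_a, id_b)`` assigns each unordered sample pair to a
    group (or None to exclude it).  Dunn pairwise z-tests with Holm
    adjustment run only when the Kruskal-Wallis p-value < ``alpha``; groups
    with fewer than two values are excluded with a warning.
    """
    values: dict[str, list[float]] = {}
    ids = dm.ids
    for i, j in combinations(range(len(ids)), 2):
        g = pair_grouping(ids[i], ids[j])
        if g is None:
            continue
        v = dm.data[i, j]
        if np.isnan(v):
            continue
        values.setdefault(g, []).append(v)
    small = [g for g, v in values.items() if len(v) < 2]
    if small:
        warnings.warn(
            f"dissimilarity_groups: excluding group(s) with <2 values: {small}",
            UserWarning,
            stacklevel=2,
        )
        for g in small:
            del values[g]
    if len(values) < 2:
        raise ValueError("dissimilarity_groups: need at least two groups")
    names = sorted(values)
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    # Levene degenerates (0/0) when within-group deviations have no spread
    with np.errstate(invalid="ignore", divide="ignore"):
        lev_raw = float(sps.levene(*arrays).pvalue)
        logs = [np.log(a[a > 0]) for a in arrays]
        lev_log = (
            float(sps.levene(*logs).pvalue)
            if all(len(x) >= 2 for x in logs)
            else float("nan")
        )
    kw = sps.kruskal(*arrays)
    dunn = None
    if kw.pvalue < alpha:
        dunn = _dunn_test(names, arrays)
    return GroupTestResult(
        levene_p_raw=lev_raw,
        levene_p_log=lev_log,
        kruskal_h=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        dunn=dunn,
        group_sizes={g: len(v) for g, v in zip(names, arrays)},
    )


def _dunn_test(names, arrays) -> pd.DataFrame:
    """Dunn pairwise z-tests on pooled ranks with tie correction, Holm-adjusted."""
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(names), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"group_a": gi, "group_b": gj, "z": z,
                     "p_value": 2 * sps.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1]
    return out


def dissimilarity_to_baseline(dm: DistanceMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean dissimilarity (± SE) of each stored condition to the 0 h replicates.

    For every sample matrix and storage condition, averages all cross
    dissimilarities between that condition's replicates and the matrix's
    0 h replicates (3 × 3 = 9 pairs at the default design).  The 0 h row
    reports the within-replicate dissimilarities (3 pairs), i.e. the
    technical variation floor.
    """
    sheet = sheet.loc[list(dm.ids)]
    pos = {s: i for i, s in enumerate(dm.ids)}
    rows = []
    for matrix, msheet in sheet.groupby("matrix", sort=True):
        base = msheet.index[msheet["time_h"] == 0]
        if len(base) == 0:
            raise ValueError(f"dissimilarity_to_baseline: no 0 h samples for {matrix}")
        bidx = [pos[s] for s in base]
        within = [dm.data[a, b] for a, b in combinations(bidx, 2)]
        rows.append(_baseline_row(matrix, "0h", within))
        for cond, csheet in msheet[msheet["time_h"] != 0].groupby("condition", sort=True):
            cidx = [pos[s] for s in csheet.index]
            vals = [dm.data[a, b] for a in cidx for b in bidx]
            rows.append(_baseline_row(matrix, cond, vals))
    return pd.DataFrame(rows)


def _baseline_row(matrix, condition, vals):
    v = np.asarray(vals, dtype=float)
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return {
        "matrix": matrix,
        "condition": condition,
        "mean_dissimilarity": float(v.mean()),
        "se": float(se),
        "n_pairs": len(v),
    }


def custom_size_factors(raw_counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factor: column total / mean of column totals.

    The factors average exactly 1 by construction.
    """
    totals = raw_counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"custom_size_factors: zero-total sample(s): {zero}")
    return totals / totals.mean()


@dataclass
class DiffAbundanceResult:
    table: pd.DataFrame
    comparison: tuple
    excluded: list
    alpha: float


def _fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by nonnegative least squares on informative taxa."""
    ok = (base_mean > 1.0) & (disp > 1e-6)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        from scipy.optimize import nnls

        coef, _ = nnls(A, disp[ok])
    else:  # too few informative taxa: flat fallback at the median
        med = np.median(disp[disp > 1e-6]) if (disp > 1e-6).any() else 0.01
        coef = np.array([med, 0.0])
    trend = coef[0] + coef[1] / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, 1e-6)


def nb_wald_test(
    raw_counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
    comparison: tuple | None = None,
    alpha: float = 0.01,
    shrink_weight: float = 0.5,
) -> DiffAbundanceResult:
    """Per-taxon negative-binomial Wald test between two conditions.

    The model is mu_ij = s_j q_i 2^(beta_i x_j) with x the condition
    indicator; beta is estimated as the log2 ratio of size-factor-normalized
    group means.  Dispersions are method-of-moments per taxon, floored at
    1e-8 and shrunk (geometric mean, weight ``shrink_weight``) toward a
    fitted a0 + a1/mu trend across taxa, which stabilizes the n=3 case.
    The Wald SE follows from Var(K) = mu + alpha mu² by the delta method.
    Taxa with zero counts in both groups are excluded and reported.
    """
    groups = pd.Series(groups).reindex(raw_counts.columns)
    if comparison is None:
        levels = list(pd.unique(groups.dropna()))
        if len(levels) != 2:
            raise ValueError("nb_wald_test: need exactly two condition levels")
        comparison = (levels[0], levels[1])
    ref, alt = comparison
    cols_ref = groups.index[groups == ref]
    cols_alt = groups.index[groups == alt]
    if len(cols_ref) < 2 or len(cols_alt) < 2:
        raise ValueError("nb_wald_test: need >= 2 replicates per condition")
    s = size_factors.reindex(raw_counts.columns)
    y = raw_counts.div(s, axis=1)
    y1 = y[cols_ref].to_numpy(dtype=float)
    y2 = y[cols_alt].to_numpy(dtype=float)
    nonzero = (y1.sum(axis=1) + y2.sum(axis=1)) > 0
    excluded = list(raw_counts.index[~nonzero])
    taxa = raw_counts.index[nonzero]
    y1, y2 = y1[nonzero], y2[nonzero]
    n1, n2 = y1.shape[1], y2.shape[1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    base_mean = np.concatenate([y1, y2], axis=1).mean(axis=1)

    # method-of-moments dispersion, pooled within groups
    v_pooled = ((n1 - 1) * y1.var(axis=1, ddof=1) + (n2 - 1) * y2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    mu_pooled = np.maximum((n1 * m1 + n2 * m2) / (n1 + n2), 1e-8)
    disp_mom = np.maximum((v_pooled - mu_pooled) / mu_pooled**2, 1e-8)
    trend = _fit_dispersion_trend(base_mean, disp_mom)
    disp = np.exp(
        shrink_weight * np.log(trend) + (1 - shrink_weight) * np.log(disp_mom)
    )
    disp = np.clip(disp, 1e-8, 20.0)

    # zero group means get a half-fragment floor so the Wald SE stays finite
    floor1 = 0.5 / (n1 * float(s[cols_ref].mean()))
    floor2 = 0.5 / (n2 * float(s[cols_alt].mean()))
    m1a = np.maximum(m1, floor1)
    m2a = np.maximum(m2, floor2)
    lfc = np.log2(m2a / m1a)

    inv_s1 = float((1.0 / s[cols_ref]).sum())
    inv_s2 = float((1.0 / s[cols_alt]).sum())
    var_m1 = (m1a * inv_s1 / n1**2) + disp * m1a**2 / n1
    var_m2 = (m2a * inv_s2 / n2**2) + disp * m2a**2 / n2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_m1 / (m1a**2 * ln2sq) + var_m2 / (m2a**2 * ln2sq))
    wald = np.where(se > 0, lfc / se, 0.0)
    pvals = 2 * sps.norm.sf(np.abs(wald))
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "se": se,
            "wald": wald,
            "p_value": pvals,
            "significant": pvals < alpha,
            "dispersion": disp,
        },
        index=taxa,
    )
    table.index.name = "taxon"
    return DiffAbundanceResult(table=table, comparison=comparison, excluded=excluded, alpha=alpha)


def significance_counts(
    results: Mapping[tuple, DiffAbundanceResult],
) -> pd.DataFrame:
    """Count, per taxon and condition, significant pairwise comparisons.

    Mirrors the per-condition significance annotation of differential
    abundance box plots: each significant pair increments both of its
    conditions for the taxon in question.
    """
    conditions = sorted({c for pair in results for c in pair})
    taxa = sorted({t for r in results.values() for t in r.table.index})
    out = pd.DataFrame(0, index=taxa, columns=conditions)
    for (a, b), res in results.items():
        sig = res.table.index[res.table["significant"]]
        out.loc[sig, a] += 1
        out.loc[sig, b] += 1
    out.index.name = "taxon"
    return out
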
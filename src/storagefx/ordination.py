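"""Dissimilarities and ordination.

Beta-diversity geometry follows the community-ecology standard: Bray-Curtis
dissimilarities computed on Hellinger-transformed counts, embedded with
principal-coordinates analysis (classical MDS).  Constrained structure is
examined with canonical correspondence analysis (chi-square distance on the
raw count table), and pairs of ordinations are compared with a symmetric
Procrustes rotation whose significance is assessed by row permutation
("protest").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "ProcrustesResult",
    "hellinger",
    "bray_curtis",
    "pcoa",
    "stress_data",
    "cca",
    "procrustes_protest",
    "cluster_supports",
]

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal.

    ``data`` is an n × n float array, ``ids`` the sample labels in matrix
    order.  Undefined dissimilarities (e.g. between two all-zero samples)
    are stored as NaN.
    """

    ids: tuple
    data: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids")
        finite = np.isfinite(d)
        if not np.all((np.abs(d - d.T) <= _SYM_TOL) | ~(finite & finite.T)):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def subset(self, ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    """Sample coordinates plus the inertia decomposition of an ordination."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    total_inertia: float
    constrained_inertia: float | None = None
    feature_scores: pd.DataFrame | None = None
    constraint_centroids: pd.DataFrame | None = None


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p_value: float
    n_permutations: int


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of per-sample relative abundance.

    Squared entries of each sample column sum to 1, which tempers the
    dominance of highly abundant taxa in downstream dissimilarities.
    """
    vals = table.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("hellinger: negative entries")
    totals = vals.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"hellinger: all-zero sample(s): {list(table.columns[zero])}",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    return pd.DataFrame(
        np.sqrt(vals / safe), index=table.index, columns=table.columns
    )


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i); the dissimilarity between two
    all-zero samples is undefined and stored as NaN with a warning.
    """
    X = table.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("bray_curtis: negative entries")
    num = squareform(pdist(X, metric="cityblock"), checks=False)
    tot = X.sum(axis=1)
    den = tot[:, None] + tot[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn(
            "bray_curtis: undefined dissimilarity between all-zero samples (NaN)",
            UserWarning,
            stacklevel=2,
        )
    return DistanceMatrix(tuple(table.columns), d)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> OrdinationResult:
    """Principal-coordinates analysis (classical metric MDS).

    Gower double-centering of −d²/2 followed by a symmetric
    eigendecomposition.  Coordinates use only positive eigenvalues
    (eigenvector × sqrt(eigenvalue)); negative eigenvalues — possible for
    non-Euclidean dissimilarities such as Bray-Curtis — are reported in
    ``eigenvalues`` but contribute no axes and no correction is applied.
    Variance explained is relative to the sum of positive eigenvalues.
    """
    d = dm.data
    if np.isnan(d).any():
        raise ValueError("pcoa: distance matrix contains undefined entries")
    n = len(dm)
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh((centered + centered.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > eig_tol * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    cols = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
        total_inertia=float(eigvals.sum()),
    )


def stress_data(
    dm: DistanceMatrix, result: OrdinationResult, k: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Pair original dissimilarities with ordination distances in k axes.

    Returns the paired table and a Spearman rank correlation summarizing
    how faithfully the first k axes reproduce the dissimilarity ranking
    (NaN when fewer than three pairs exist).
    """
    coords = result.coordinates.to_numpy()
    if k is None:
        k = coords.shape[1]
    ord_d = pdist(coords[:, :k])
    orig = dm.condensed()
    pairs = pd.DataFrame({"original": orig, "ordination": ord_d})
    if len(orig) < 3:
        rho = float("nan")
    else:
        rho = float(spearmanr(orig, ord_d).statistic)
    return pairs, rho


def _chi_square_residuals(table: pd.DataFrame):
    """Chi-square standardized residuals of a samples × features table."""
    X = table.to_numpy(dtype=float).T  # samples × features
    sample_ids = list(table.columns)
    feature_ids = list(table.index)
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        dropped = [s for s, ok in zip(sample_ids, row_ok) if not ok] + [
            f for f, ok in zip(feature_ids, col_ok) if not ok
        ]
        warnings.warn(
            f"cca: dropping zero-sum samples/features: {dropped}",
            UserWarning,
            stacklevel=3,
        )
        X = X[np.ix_(row_ok, col_ok)]
        sample_ids = [s for s, ok in zip(sample_ids, row_ok) if ok]
        feature_ids = [f for f, ok in zip(feature_ids, col_ok) if ok]
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c, sample_ids, feature_ids


def cca(table: pd.DataFrame, factor: pd.Series, eig_tol: float = 1e-10) -> OrdinationResult:
    """Canonical correspondence analysis constrained by one factor.

    Operates on the *raw* count table (chi-square distance).  The
    chi-square standardized residual matrix Q = (P − rcᵀ)/sqrt(rcᵀ) is
    projected onto the weighted indicator space of the factor levels and
    the projection is decomposed by SVD; constrained inertia is the sum of
    squared singular values, total inertia is ΣQ² (the chi-square statistic
    over the grand total).

    Sample coordinates are weighted linear-combination scores
    (u_k s_k / sqrt(r)); ``feature_scores`` are column scores
    (v_k / sqrt(c)), suitable for biplots.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("cca: negative entries")
    Q, r, c, sample_ids, feature_ids = _chi_square_residuals(table)
    levels = pd.Series(factor).reindex(sample_ids)
    if levels.isna().any():
        raise ValueError("cca: factor missing for some samples")
    uniq = levels.unique()
    if len(uniq) < 2:
        raise ValueError("cca: factor must have at least two levels")
    total_inertia = float((Q**2).sum())
    # weighted indicator design, centered by row-weighted means
    Z = pd.get_dummies(levels).to_numpy(dtype=float)
    Z = Z - r @ Z  # weighted centering (Σ r_i = 1)
    Zw = np.sqrt(r)[:, None] * Z
    # projection of Q onto span(Zw)
    u_z, s_z, _ = np.linalg.svd(Zw, full_matrices=False)
    keep = s_z > 1e-10 * max(s_z[0], 1.0)
    basis = u_z[:, keep]
    Qfit = basis @ (basis.T @ Q)
    U, S, Vt = np.linalg.svd(Qfit, full_matrices=False)
    pos = S**2 > eig_tol * max(S[0] ** 2, 1.0) if S.size else np.array([], bool)
    U, S, Vt = U[:, pos], S[pos], Vt[pos]
    constrained = float((S**2).sum())
    cols = [f"CCA{i + 1}" for i in range(S.size)]
    coords = pd.DataFrame(
        (U * S) / np.sqrt(r)[:, None], index=sample_ids, columns=cols
    )
    feats = pd.DataFrame(Vt.T / np.sqrt(c)[:, None], index=feature_ids, columns=cols)
    centroids = coords.groupby(levels).mean()
    prop = S**2 / total_inertia if total_inertia > 0 else np.zeros(S.size)
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=S**2,
        proportion_explained=prop,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        feature_scores=feats,
        constraint_centroids=centroids,
    )


def _center_scale(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    norm = np.sqrt((X**2).sum())
    if norm == 0:
        raise ValueError("procrustes: configuration has zero variance")
    return X / norm


def _procrustes_m2(Xc: np.ndarray, Yc: np.ndarray) -> float:
    s = np.linalg.svd(Xc.T @ Yc, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_protest(
    coords_a: pd.DataFrame,
    coords_b: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes comparison of two ordinations with protest.

    Both configurations are centered and scaled to unit sum of squares;
    the optimal rotation gives m² = 1 − (Σ singular values)², and the
    Procrustes correlation is sqrt(1 − m²).  The permutation p-value
    shuffles the sample rows of B and uses the add-one estimator
    (1 + #{m²_perm ≤ m²_obs}) / (1 + n_permutations).
    """
    if set(coords_a.index) != set(coords_b.index):
        raise ValueError("procrustes_protest: sample labels differ")
    B = coords_b.loc[coords_a.index]
    Xc = _center_scale(coords_a.to_numpy(dtype=float))
    Yc = _center_scale(B.to_numpy(dtype=float))
    # pad to common column count so the cross-product is well-defined
    k = max(Xc.shape[1], Yc.shape[1])
    Xc = np.pad(Xc, ((0, 0), (0, k - Xc.shape[1])))
    Yc = np.pad(Yc, ((0, 0), (0, k - Yc.shape[1])))
    m2 = _procrustes_m2(Xc, Yc)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = Xc.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _procrustes_m2(Xc, Yc[perm]) <= m2:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return ProcrustesResult(
        m2=m2,
        correlation=float(np.sqrt(max(0.0, 1.0 - m2))),
        p_value=p,
        n_permutations=n_permutations,
    )


@dataclass
class HeatmapSupports:
    standardized: pd.DataFrame
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray
    selected_features: list = field(default_factory=list)


def cluster_supports(
    rel_table: pd.DataFrame,
    sample_dm: DistanceMatrix,
    n_top: int = 30,
) -> HeatmapSupports:
    """Heat-map supports: top-abundance genera, z-scored, with linkages.

    Selects the ``n_top`` genera with the highest mean relative abundance,
    standardizes each row to zero mean / unit variance, and builds
    complete-linkage trees: genera from 1 − Pearson correlation, samples
    from the supplied Bray-Curtis distance matrix.  Genera are ordered
    lexicographically before clustering so ties break deterministically.
    """
    sub = rel_table.loc[:, list(sample_dm.ids)]
    top = sub.mean(axis=1).sort_values(ascending=False).index[:n_top]
    top = sorted(top)
    if len(top) < 2:
        raise ValueError("cluster_supports: fewer than two features selected")
    M = sub.loc[top].to_numpy(dtype=float)
    sd = M.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = [g for g, s in zip(top, sd) if s == 0]
        raise ValueError(f"cluster_supports: constant feature(s): {bad}")
    Z = (M - M.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = np.corrcoef(Z)
    gd = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(gd, 0.0)
    gd = (gd + gd.T) / 2
    feat_link = linkage(squareform(gd, checks=False), method="complete")
    samp_link = linkage(sample_dm.condensed(), method="complete")
    return HeatmapSupports(
        standardized=pd.DataFrame(Z, index=top, columns=sub.columns),
        feature_linkage=feat_link,
        sample_linkage=samp_link,
        selected_features=list(top),
    )
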
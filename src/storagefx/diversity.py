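"""Alpha diversity and rarefaction.

All estimators operate on raw (integer) count vectors, since richness
estimation is only meaningful on counts of discrete sequencing fragments.
Chao1 uses the bias-corrected form, which stays finite when no doubletons
are observed; Shannon entropy uses the natural logarithm.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "chao1",
    "shannon_pielou",
    "simpson",
    "alpha_table",
    "rarefy_curve",
]


def _as_vector(counts, integer: bool = False) -> np.ndarray:
    x = np.asarray(counts, dtype=float).ravel()
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if integer and not np.allclose(x, np.round(x)):
        raise ValueError(
            "richness estimation needs integer-valued raw counts; "
            "use the unnormalized (raw) count table"
        )
    return x


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1) / (2(F2+1)).

    F1 and F2 are the numbers of singleton and doubleton features.
    Always ≥ observed richness, with equality iff F1 ≤ 1.
    """
    x = _as_vector(counts, integer=True)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_pielou(counts) -> tuple[float, float]:
    """Shannon entropy (natural log) and Pielou's evenness J = H / ln S_obs.

    J is NaN when fewer than two features are present (evenness undefined).
    """
    x = _as_vector(counts)
    total = x.sum()
    if total == 0:
        return 0.0, float("nan")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    s_obs = p.size
    j = h / math.log(s_obs) if s_obs >= 2 else float("nan")
    return h, j


def simpson(counts) -> float:
    """Simpson diversity 1 − Σ p_i² (probability two draws differ)."""
    x = _as_vector(counts)
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x / total
    return float(1.0 - (p**2).sum())


def alpha_table(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity (Chao1, Shannon, Pielou, Simpson)."""
    rows = []
    for sample in raw_counts.columns:
        x = raw_counts[sample].to_numpy()
        h, j = shannon_pielou(x)
        rows.append(
            {
                "sample_id": sample,
                "richness": int((x > 0).sum()),
                "chao1": chao1(x),
                "shannon": h,
                "pielou": j,
                "simpson": simpson(x),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def rarefy_curve(
    counts,
    depths,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean observed richness when subsampling to each depth.

    Subsampling is without replacement (multivariate hypergeometric),
    repeated ``iterations`` times per depth.  Returns a DataFrame indexed
    by depth with columns ``mean_richness`` and ``sd``.
    """
    x = np.round(_as_vector(counts, integer=True)).astype(np.int64)
    total = int(x.sum())
    depths = [int(d) for d in depths]
    if any(d < 0 for d in depths):
        raise ValueError("depths must be nonnegative")
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total count {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for d in depths:
        rich = np.empty(iterations)
        for it in range(iterations):
            sub = rng.multivariate_hypergeometric(x, d)
            rich[it] = (sub > 0).sum()
        rows.append({"depth": d, "mean_richness": rich.mean(), "sd": rich.std(ddof=1) if iterations > 1 else 0.0})
    return pd.DataFrame(rows).set_index("depth")
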
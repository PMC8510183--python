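"""Mock-community expectations and spike-in background correction.

A spiked sample contains, for each mock genus, reads from the spike *and*
reads from the native community (the mock genera occur naturally in feces
and sewage).  Because relative abundances are compositional, the native
background in a spiked sample is not simply the unspiked abundance: the
spike compresses everything else.  The correction estimates a per
(matrix, condition) factor f = (nonmock mass in spiked) / (nonmock mass in
unspiked) from genera that cannot contain spike reads, scales the unspiked
mock abundances by f to estimate the background inside the spiked sample,
and subtracts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import total_sum_scale
from .synth import MockSpec

__all__ = [
    "expected_mock_profile",
    "background_factor",
    "correct_spiked",
    "SpikeCorrection",
    "mock_condition_profiles",
]


def expected_mock_profile(mock_spec: MockSpec) -> pd.Series:
    """Expected relative read abundance of the 8 mock members.

    Member weight ∝ cells_per_mg × genome_size_bp × extraction_efficiency,
    closed to sum 1: read yield scales with input cells, DNA per cell
    (genome size) and how efficiently that cell class lyses.
    """
    w = np.array(
        [
            m.cells_per_mg * m.genome_size_bp * m.extraction_efficiency
            for m in mock_spec.members
        ]
    )
    if w.sum() <= 0:
        raise ValueError("expected_mock_profile: zero total weight")
    return pd.Series(
        w / w.sum(), index=pd.Index(mock_spec.genera, name="genus")
    )


def _condition_means(table: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per (matrix, condition); columns become a MultiIndex."""
    key = pd.MultiIndex.from_frame(sheet.loc[table.columns, ["matrix", "condition"]])
    return table.T.groupby(key).mean().T


def background_factor(
    spiked: pd.DataFrame,
    unspiked: pd.DataFrame,
    mock_genera,
    sheet: pd.DataFrame,
    scale: str = "tss",
) -> pd.Series:
    """Spiked/unspiked factor per (matrix, condition) from nonmock genera.

    f = Σ nonmock abundance in the spiked replicate means / Σ nonmock
    abundance in the unspiked replicate means.  ``scale`` chooses whether
    tables are closed to relative abundance first ("tss", default) or used
    as-is ("raw").
    """
    if scale == "tss":
        spiked = total_sum_scale(spiked)
        unspiked = total_sum_scale(unspiked)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    mock = set(mock_genera)
    nonmock_s = spiked.loc[[g for g in spiked.index if g not in mock]]
    nonmock_u = unspiked.loc[[g for g in unspiked.index if g not in mock]]
    ms = _condition_means(nonmock_s, sheet).sum(axis=0)
    mu = _condition_means(nonmock_u, sheet).sum(axis=0)
    mu = mu.reindex(ms.index)
    if mu.isna().any():
        missing = list(ms.index[mu.isna()])
        raise ValueError(f"background_factor: no unspiked match for {missing}")
    if (mu == 0).any():
        bad = list(ms.index[mu == 0])
        raise ValueError(f"background_factor: zero nonmock mass in unspiked {bad}")
    f = ms / mu
    f.name = "background_factor"
    return f


@dataclass
class SpikeCorrection:
    corrected: pd.DataFrame  # mock genus × spiked sample
    background: pd.DataFrame  # estimated background per spiked sample
    clamped: pd.DataFrame  # bool: raw correction was negative
    factors: pd.Series  # f per (matrix, condition)


def correct_spiked(
    spiked: pd.DataFrame,
    unspiked: pd.DataFrame,
    mock_genera,
    sheet: pd.DataFrame,
    factors: pd.Series | None = None,
    scale: str = "tss",
    clamp: bool = True,
) -> SpikeCorrection:
    """Background-correct mock genera in spiked samples.

    background_g = f × (unspiked replicate-mean abundance of g) for the
    sample's (matrix, condition); corrected_g = spiked_g − background_g.
    Negative corrections are clamped to zero and flagged (set
    ``clamp=False`` to keep them).  Mock genera absent from both tables are
    reported and skipped.
    """
    if factors is None:
        factors = background_factor(spiked, unspiked, mock_genera, sheet, scale=scale)
    if scale == "tss":
        spiked = total_sum_scale(spiked)
        unspiked = total_sum_scale(unspiked)
    mock = [g for g in mock_genera]
    absent = [g for g in mock if g not in spiked.index and g not in unspiked.index]
    if absent:
        warnings.warn(
            f"correct_spiked: mock genera absent from both tables, skipped: {absent}",
            UserWarning,
            stacklevel=2,
        )
        mock = [g for g in mock if g not in absent]
    spiked_m = spiked.reindex(mock).fillna(0.0)
    unspiked_m = unspiked.reindex(mock).fillna(0.0)
    u_means = _condition_means(unspiked_m, sheet)
    key = sheet.loc[spiked_m.columns]
    background = pd.DataFrame(index=spiked_m.index, columns=spiked_m.columns, dtype=float)
    for sid in spiked_m.columns:
        cell = (key.loc[sid, "matrix"], key.loc[sid, "condition"])
        background[sid] = factors[cell] * u_means[cell]
    corrected = spiked_m - background
    clamped = corrected < 0
    if clamp:
        corrected = corrected.clip(lower=0.0)
    return SpikeCorrection(
        corrected=corrected, background=background, clamped=clamped, factors=factors
    )


def mock_condition_profiles(
    corrected: pd.DataFrame,
    sheet: pd.DataFrame,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-member log2 abundance relative to the 0 h mean, with t-based CIs.

    For each matrix, every member's corrected abundance is divided by its
    mean at 0 h and log2-scaled; the confidence interval reflects replicate
    variation at each (matrix, condition).  Members with a zero 0 h mean
    are flagged and excluded.
    """
    meta = sheet.loc[corrected.columns]
    rows = []
    for matrix, msheet in meta.groupby("matrix", sort=True):
        base_ids = msheet.index[msheet["time_h"] == 0]
        if len(base_ids) == 0:
            raise ValueError(f"mock_condition_profiles: no 0 h samples for {matrix}")
        base_mean = corrected[base_ids].mean(axis=1)
        zero = base_mean.index[base_mean <= 0]
        if len(zero):
            warnings.warn(
                f"mock_condition_profiles: zero 0 h mean for {list(zero)} in "
                f"{matrix}; excluded",
                UserWarning,
                stacklevel=2,
            )
        for cond, csheet in msheet.groupby("condition", sort=True):
            vals = corrected[csheet.index]
            for genus in corrected.index:
                if genus in zero:
                    continue
                with np.errstate(divide="ignore"):
                    log2r = np.log2(vals.loc[genus].to_numpy() / base_mean[genus])
                finite = log2r[np.isfinite(log2r)]
                if finite.size == 0:
                    continue
                m = float(finite.mean())
                if finite.size > 1:
                    se = finite.std(ddof=1) / np.sqrt(finite.size)
                    tq = sps.t.ppf(0.5 + ci_level / 2, df=finite.size - 1)
                    lo, hi = m - tq * se, m + tq * se
                else:
                    lo = hi = m
                rows.append(
                    {
                        "matrix": matrix,
                        "condition": cond,
                        "genus": genus,
                        "log2_rel_abundance": m,
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                        "n": int(finite.size),
                    }
                )
    return pd.DataFrame(rows)
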
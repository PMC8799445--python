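"""Screening analytics for antibody-pair selection.

Given a per-strip signal table (from the imaging pipeline or the synthetic
generator), these functions compute the standard pair-screening summaries:
replicate-averaged signals per capture x detection pair and matrix,
blank-subtracted signals (antigen-spiked mean minus the same pair's
antigen-free mean), pair heatmaps, signal-to-noise (S/N) and
signal-minus-noise (S-N) metrics, cross-reactivity ranking against a
second antigen, and Pearson correlation between two quantification methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairSummary",
    "blank_subtract",
    "pair_summaries",
    "pair_heatmap",
    "cross_reactivity_rank",
    "method_correlation",
]

PAIR_KEYS = ["capture", "detection"]


@dataclass(frozen=True)
class PairSummary:
    """Screening metrics for one capture/detection pair."""

    capture: str
    detection: str
    mean_signal: dict
    blank_mean: float
    blank_subtracted: dict
    s_over_n: dict | None
    s_minus_n: dict
    n_replicates: dict


def _check_table(table: pd.DataFrame) -> None:
    required = {"capture", "detection", "matrix", "signal"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    if not np.isfinite(table["signal"]).all():
        raise ValueError("screen table contains non-finite signals")


def blank_subtract(
    table: pd.DataFrame, blank_matrix: str = "blank"
) -> pd.DataFrame:
    """Blank-subtracted replicate means per (capture, detection, matrix).

    For every pair, the mean signal in each antigen matrix minus that
    pair's own blank-matrix mean.  Blank rows map to ~0 (exactly 0 when
    subtracted from their own mean).  Every pair must have at least one
    blank replicate.

    Returns a table with columns ``capture, detection, matrix,
    mean_signal, n_replicates, blank_mean, blank_subtracted``.
    """
    _check_table(table)
    grouped = (
        table.groupby(PAIR_KEYS + ["matrix"], sort=True)["signal"]
        .agg(mean_signal="mean", n_replicates="size")
        .reset_index()
    )
    blanks = grouped[grouped["matrix"] == blank_matrix][
        PAIR_KEYS + ["mean_signal"]
    ].rename(columns={"mean_signal": "blank_mean"})
    pairs = grouped[PAIR_KEYS].drop_duplicates()
    missing = pairs.merge(blanks, on=PAIR_KEYS, how="left")
    missing = missing[missing["blank_mean"].isna()]
    if len(missing):
        names = [
            f"({r.capture}, {r.detection})" for r in missing.itertuples()
        ]
        raise ValueError(
            f"pairs with no blank-matrix replicates: {', '.join(names)}"
        )
    out = grouped.merge(blanks, on=PAIR_KEYS, how="left")
    out["blank_subtracted"] = out["mean_signal"] - out["blank_mean"]
    return out


def pair_summaries(
    table: pd.DataFrame, blank_matrix: str = "blank", global_blank: bool = False
) -> pd.DataFrame:
    """Per-pair screening metrics: S-N and S/N for every antigen matrix.

    ``S-N = mean_signal - blank_mean`` exactly; ``S/N = mean_signal /
    blank_mean`` and is NaN where the blank mean is not positive.  The
    noise term is the pair's own blank mean by default; with
    ``global_blank=True`` the plate-wide blank mean is used instead.
    """
    bs = blank_subtract(table, blank_matrix=blank_matrix)
    if global_blank:
        g = bs.loc[bs["matrix"] == blank_matrix, "mean_signal"].mean()
        bs = bs.assign(blank_mean=g)
        bs["blank_subtracted"] = bs["mean_signal"] - g
    out = bs.rename(columns={"blank_subtracted": "s_minus_n"}).copy()
    out["s_over_n"] = np.where(
        out["blank_mean"] > 0, out["mean_signal"] / out["blank_mean"], np.nan
    )
    return out


def pair_heatmap(
    table: pd.DataFrame,
    antigen_matrix: str,
    value: str = "signal",
) -> pd.DataFrame:
    """Capture x detection matrix of replicate-averaged signals.

    Rows are capture antibodies, columns detection antibodies, cells the
    mean over replicates for the requested matrix.  Cells absent from the
    table are NaN (flagged, not imputed).
    """
    needed = {"capture", "detection", "matrix", value}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    sub = table[table["matrix"] == antigen_matrix]
    return sub.pivot_table(
        index="capture", columns="detection", values=value, aggfunc="mean"
    )


def cross_reactivity_rank(
    bs_table: pd.DataFrame,
    ag1_matrix: str,
    ag2_matrix: str,
    ag2_threshold: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank pairs by target signal, filtering out cross-reactive ones.

    ``bs_table`` is :func:`blank_subtract` output.  Returns ``(ranked,
    scatter)``: the scatter table holds every pair with x = blank-subtracted
    signal on the off-target antigen (ag2) and y = on the target (ag1);
    the ranked table keeps pairs with ag2 signal <= ``ag2_threshold``,
    sorted by descending ag1 signal (ties by capture then detection label,
    so ranking is deterministic and stable under positive rescaling).
    """
    def _wide(matrix: str, name: str) -> pd.DataFrame:
        sub = bs_table[bs_table["matrix"] == matrix]
        return sub[PAIR_KEYS + ["blank_subtracted"]].rename(
            columns={"blank_subtracted": name}
        )

    scatter = _wide(ag1_matrix, "ag1_signal").merge(
        _wide(ag2_matrix, "ag2_signal"), on=PAIR_KEYS, how="inner"
    )
    ranked = scatter[scatter["ag2_signal"] <= ag2_threshold].sort_values(
        ["ag1_signal", "capture", "detection"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ranked, scatter


def method_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation between two quantification methods.

    Returns ``(R, p)`` with the two-sided p-value from the t transform.
    Requires at least 3 finite pairs and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
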
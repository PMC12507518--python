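"""Gain/loss summaries of Diff-score distributions across a variant set.

For an evolutionary collection of substitutions (e.g. the human-lineage
variants of accelerated regions), each motif's column of Diff scores asks
whether the substitutions systematically gained or lost binding sites for
that TF.  Two statistics are computed per motif:

* **EPPS** — the empirical probability of positive shift: the proportion
  of variants with a strictly positive Diff.  Exact zeros are neither
  gains nor losses and are excluded from both numerator and denominator.
  Under the null of no directional preference EPPS = 0.5, so results are
  usually reported centred (EPPS - 0.5), positive meaning net gain.
* a **shift test** — by default a one-sample Wilcoxon signed-rank test of
  the Diff distribution against location zero (two-sided); a two-sample
  rank-sum comparison against a sampled zero-mean normal is available as
  an alternative.  P-values are Benjamini–Hochberg adjusted across motifs.

``summarize_gain_loss`` emits one row per motif — centred EPPS, n, raw
and FDR-adjusted p — sorted by centred EPPS, ready for a volcano-style
plot of EPPS against -log10(FDR p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_scoring import DiffMatrix


def compute_epps(diffs: np.ndarray | pd.Series) -> float:
    """Proportion of strictly positive Diffs among non-zero, non-missing ones.

    Returns NaN for an empty (or all-zero / all-missing) column.
    """
    values = np.asarray(diffs, dtype=float)
    values = values[np.isfinite(values)]
    values = values[values != 0.0]
    if values.size == 0:
        return float("nan")
    return float((values > 0).mean())


def shift_test(
    diffs: np.ndarray | pd.Series,
    min_n: int = 10,
    method: str = "signed_rank",
    seed: int | None = None,
) -> float:
    """Two-sided p-value for a location shift of the Diff distribution from 0.

    ``signed_rank`` (default) is a one-sample Wilcoxon signed-rank test
    against location zero, using the normal approximation (which handles
    the tied absolute values that discretized scores produce).
    ``rank_sum_normal`` draws a zero-mean normal sample matched in size
    and scale and runs a two-sample rank-sum test against it; it needs a
    ``seed`` for reproducibility.

    Returns NaN when fewer than ``min_n`` non-zero values remain; all-zero
    input gives p = 1 (no shift detectable).
    """
    values = np.asarray(diffs, dtype=float)
    values = values[np.isfinite(values)]
    nonzero = values[values != 0.0]
    if values.size and nonzero.size == 0:
        return 1.0
    if nonzero.size < min_n:
        return float("nan")
    if method == "signed_rank":
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="approx")
        return float(res.pvalue)
    if method == "rank_sum_normal":
        rng = np.random.default_rng(seed)
        scale = nonzero.std(ddof=1)
        if scale == 0:
            scale = 1.0
        null_sample = rng.normal(0.0, scale, size=nonzero.size)
        res = stats.ranksums(nonzero, null_sample)
        return float(res.pvalue)
    raise ValueError(f"unknown shift-test method {method!r}")


def fdr_correct(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through."""
    pvalues = np.asarray(pvalues, dtype=float)
    adjusted = np.full(pvalues.shape, np.nan)
    ok = np.isfinite(pvalues)
    if ok.any():
        adjusted[ok] = multipletests(pvalues[ok], method="fdr_bh")[1]
    return adjusted


def summarize_gain_loss(
    diff: DiffMatrix | pd.DataFrame,
    min_n: int = 10,
    method: str = "signed_rank",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-motif EPPS / shift-test table, sorted by centred EPPS (descending).

    Columns: ``motif``, ``n`` (non-zero Diffs), ``epps``, ``epps_centered``,
    ``p_value``, ``fdr_p``.
    """
    data = diff.data if isinstance(diff, DiffMatrix) else diff
    if data.shape[1] < 1:
        raise ValueError("Diff matrix has no motif columns")
    rows = []
    for motif in data.columns:
        col = data[motif].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        nonzero = col[col != 0.0]
        rows.append(
            {
                "motif": motif,
                "n": int(nonzero.size),
                "epps": compute_epps(col),
                "p_value": shift_test(col, min_n=min_n, method=method, seed=seed),
            }
        )
    table = pd.DataFrame(rows)
    table["epps_centered"] = table["epps"] - 0.5
    table["fdr_p"] = fdr_correct(table["p_value"].to_numpy())
    table = table[["motif", "n", "epps", "epps_centered", "p_value", "fdr_p"]]
    return table.sort_values("epps_centered", ascending=False).reset_index(drop=True)
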
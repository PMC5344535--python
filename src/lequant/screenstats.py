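"""Screen bookkeeping and small statistics.

Covers the arithmetic around a transcriptomic gain/loss-of-function screen —
inclusive fold-change filtering, the expected number of false positives
implied by a false-discovery rate — and a Monte-Carlo permutation test for
equal means in a one-way layout, as used to compare per-segment expression
between genotypes.  Multiple-comparison procedures (Dunnett, Kruskal-Wallis,
Fisher's exact) are deliberately not re-implemented; use scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenTable",
    "fold_change_filter",
    "expected_false_positives",
    "mc_oneway_test",
    "oneway_statistic",
]


@dataclass
class ScreenTable:
    """Per-gene signed fold changes.

    Fold change is a signed ratio: +2.0 means 2-fold up, -1.5 means 1.5-fold
    down, so |FC| >= 1 always; gene ids must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        for col in ("gene_id", "fold_change"):
            if col not in df.columns:
                raise ValueError(f"screen table missing column {col!r}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        fc = df["fold_change"].to_numpy(dtype=float)
        if not np.all(np.abs(fc) >= 1.0):
            raise ValueError("invalid fold changes: |FC| must be >= 1")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def fold_change_filter(
    table: ScreenTable, threshold: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition genes regulated by at least ``threshold``-fold.

    The comparison is inclusive ("equal to or higher than"): up-regulated
    genes have FC >= +threshold, down-regulated FC <= -threshold; genes
    between -threshold and +threshold are excluded.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    fc = table.data["fold_change"]
    up = table.data[fc >= threshold].reset_index(drop=True)
    down = table.data[fc <= -threshold].reset_index(drop=True)
    return up, down


def expected_false_positives(n_identified: int, fdr: float) -> tuple[float, int]:
    """Expected number of false positives among ``n_identified`` hits at a
    given false-discovery rate: ``n * fdr``, plus its nearest integer."""
    if n_identified < 0:
        raise ValueError("n_identified must be >= 0")
    if not 0.0 <= fdr <= 1.0:
        raise ValueError("fdr must be in [0, 1]")
    expected = n_identified * fdr
    return expected, int(round(expected))


def oneway_statistic(values: np.ndarray, sizes: np.ndarray) -> float:
    """Between-group sum of squares of group means about the grand mean.

    ``values`` is the pooled observation vector, grouped contiguously with
    group sizes ``sizes``.  Any permutation-exchangeable F-type statistic
    yields the same permutation p-value; this one is the cheapest.
    """
    grand = values.mean()
    out = 0.0
    start = 0
    for n in sizes:
        out += n * (values[start : start + n].mean() - grand) ** 2
        start += n
    return float(out)


def mc_oneway_test(
    groups,
    n_resamples: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation test for equal means in a one-way layout.

    Observations are pooled and randomly relabelled to groups of the
    original sizes ``n_resamples`` times; the p-value is
    ``(1 + #{S* >= S_obs}) / (1 + n_resamples)`` where S is the
    between-group sum of squares about the grand mean.  The add-one
    estimator avoids p = 0 and makes the test valid at any resample count.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs >= 2 observations")
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sizes = np.array([len(g) for g in arrays])
    pooled = np.concatenate(arrays)
    observed = oneway_statistic(pooled, sizes)

    edges = np.concatenate([[0], np.cumsum(sizes)])
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_resamples, len(pooled))).copy(), axis=1
    )
    grand = pooled.mean()
    stats = np.zeros(n_resamples)
    for lo, hi, n in zip(edges[:-1], edges[1:], sizes):
        stats += n * (perms[:, lo:hi].mean(axis=1) - grand) ** 2
    count = int(np.sum(stats >= observed - 1e-12 * max(abs(observed), 1.0)))
    return (1 + count) / (1 + n_resamples)
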
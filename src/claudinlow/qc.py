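"""Compendium quality control.

When expression profiles from several microarray studies are merged, poorly
hybridized or mis-processed samples stand out as having aberrant
housekeeping-gene profiles.  The filter here computes pairwise Spearman
correlations between samples restricted to a housekeeping gene set (68
probe sets in the reference analysis) and keeps a sample only if it
correlates above a threshold (default 0.95) with at least half of the other
samples.

"Half of the dataset" is read as half of the *other* samples — the sample's
perfect self-correlation is excluded, so a sample cannot vote for itself.
The filter runs in a single pass; removals do not trigger re-filtering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    housekeeping_genes: list[str] = field(default_factory=list)
    correlation_threshold: float = 0.95
    min_fraction_of_dataset: float = 0.5

    def __post_init__(self) -> None:
        if not -1 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (-1, 1)")
        if not 0 < self.min_fraction_of_dataset <= 1:
            raise ValueError("min_fraction_of_dataset must be in (0, 1]")
        if not self.housekeeping_genes:
            raise ValueError("housekeeping gene list must be non-empty")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average-tied ranks.

    Returns NaN (with a log message) when either vector is constant, where
    the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman_rho undefined for constant input; returning NaN")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Average-tied ranks of each column of a genes-by-samples array."""
    return np.apply_along_axis(stats.rankdata, 0, values)


def housekeeping_filter(matrix: ExpressionMatrix, config: QCConfig,
                        ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition samples into kept and dropped by the housekeeping rule.

    A sample is kept iff its housekeeping-restricted Spearman correlation
    exceeds ``correlation_threshold`` with at least
    ``ceil(min_fraction_of_dataset * (N - 1))`` other samples.  Pairs where
    either sample has a constant housekeeping vector (undefined rho) never
    count toward the threshold.

    Returns ``(kept_ids, dropped_ids, summary)`` where ``summary`` has one
    row per sample with its pass count, requirement, and median rho.
    """
    missing = [g for g in config.housekeeping_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"housekeeping genes absent from matrix: {missing}")
    hk = matrix.values.loc[config.housekeeping_genes].to_numpy()
    n = hk.shape[1]
    sample_ids = matrix.sample_ids
    constant = np.ptp(hk, axis=0) == 0
    ranks = _rank_columns(hk)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.nan)  # self-correlation excluded

    required = math.ceil(config.min_fraction_of_dataset * (n - 1))
    passes = np.nansum(rho > config.correlation_threshold, axis=1).astype(int)
    keep = passes >= required
    if n == 1:
        keep[:] = True  # a singleton dataset has nothing to disagree with

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        median_rho = np.nanmedian(rho, axis=1) if n > 1 else np.full(n, np.nan)
    summary = pd.DataFrame({
        "sample_id": sample_ids,
        "pass_count": passes,
        "required": required,
        "median_rho": median_rho,
        "kept": keep,
    })
    kept = [s for s, k in zip(sample_ids, keep) if k]
    dropped = [s for s, k in zip(sample_ids, keep) if not k]
    logger.info("housekeeping filter kept %d / %d samples", len(kept), n)
    return kept, dropped, summary


def center_batches(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive per-batch shifts gene by gene.

    For each gene the per-batch mean is subtracted and the global gene mean
    restored, so per-batch gene means coincide afterwards.  Batches of size
    one are left uncentered with a warning (their shift is unidentifiable).
    A lightweight location adjustment only — not a full batch-effect model.
    """
    if matrix.batch_labels is None:
        raise ValueError("center_batches requires batch labels")
    values = matrix.values.copy()
    batches = matrix.batch_labels
    global_mean = values.mean(axis=1)
    for batch, cols in values.T.groupby(batches, observed=True):
        if len(cols) < 2:
            warnings.warn(f"batch {batch!r} has a single sample; left uncentered",
                          stacklevel=2)
            continue
        batch_mean = cols.mean(axis=0)
        values[cols.index] = values[cols.index].sub(batch_mean, axis=0).add(global_mean, axis=0)
    return ExpressionMatrix(
        values=values,
        batch_labels=matrix.batch_labels.copy(),
        subtype_labels=None if matrix.subtype_labels is None else matrix.subtype_labels.copy(),
        housekeeping_genes=list(matrix.housekeeping_genes),
    )
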
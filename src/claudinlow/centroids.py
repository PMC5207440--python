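"""Nearest-centroid molecular subtyping by Spearman correlation.

Seven intrinsic subtypes are distinguished: luminal A, luminal B,
HER2-enriched, basal-like, normal-like, molecular apocrine and claudin-low.
For each subtype a *standardized centroid* is computed over a classifier
gene set: the within-subtype mean expression of each gene divided by its
within-subtype standard deviation.  A new sample is assigned to the subtype
whose centroid has the highest Spearman rank correlation with the sample's
expression vector, provided that correlation reaches a cutoff (0.3 by
default); otherwise the sample is left unclassified.  Because assignment is
rank-based it is invariant to any strictly monotone transform of the
sample's values.

Centroids are re-derived here from any labeled reference set rather than
taken from a published table, so the classifier is exercisable on synthetic
or user-supplied references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix
from .stats import percent

logger = logging.getLogger(__name__)

EXPRESSION_SUBTYPES = (
    "luminal A", "luminal B", "HER2-enriched", "basal-like",
    "normal-like", "molecular apocrine", "claudin-low",
)
UNCLASSIFIED = "unclassified"
DEFAULT_CUTOFF = 0.3


@dataclass
class SubtypeCentroidSet:
    """Standardized centroids: a genes-by-subtypes DataFrame.

    ``centroids.loc[g, s]`` is the mean expression of gene ``g`` within
    subtype ``s`` divided by its within-subtype standard deviation (sample
    SD, n-1 denominator).
    """

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        if self.centroids.isna().any().any():
            raise ValueError("centroids must not contain missing values")
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate genes in centroid set")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def classifier_genes(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class SubtypeAssignment:
    sample_id: str
    best_subtype: str | None
    correlations: dict[str, float] = field(default_factory=dict)
    cutoff_used: float = DEFAULT_CUTOFF
    tie: bool = False

    @property
    def classified(self) -> bool:
        return self.best_subtype is not None


def train_centroids(matrix: ExpressionMatrix, classifier_genes: list[str],
                    ) -> SubtypeCentroidSet:
    """Compute standardized centroids from a subtype-labeled reference set.

    Every labeled subtype needs at least two samples.  Genes whose
    within-subtype SD is zero in *any* subtype are dropped from the
    classifier set globally (all centroids must share one gene list for
    rank correlation) and logged.
    """
    if matrix.subtype_labels is None:
        raise ValueError("training requires subtype labels")
    missing = [g for g in classifier_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"classifier genes absent from matrix: {missing[:10]}")
    if pd.Index(classifier_genes).has_duplicates:
        raise ValueError("classifier gene list has duplicates")
    labels = matrix.subtype_labels.dropna()
    sub = matrix.values.loc[classifier_genes, labels.index]
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"subtypes with fewer than 2 samples: {dict(small)}")
    means = sub.T.groupby(labels, observed=True).mean().T
    sds = sub.T.groupby(labels, observed=True).std(ddof=1).T
    zero_sd = (sds == 0).any(axis=1)
    if zero_sd.any():
        dropped = list(sds.index[zero_sd])
        logger.info("dropping %d zero-SD genes from classifier set: %s",
                    len(dropped), dropped[:10])
        means, sds = means[~zero_sd], sds[~zero_sd]
    if means.empty:
        raise ValueError("no classifier genes survive the zero-SD filter")
    return SubtypeCentroidSet(centroids=means / sds)


def assign_subtype(sample: pd.Series, centroids: SubtypeCentroidSet,
                   cutoff: float = DEFAULT_CUTOFF) -> SubtypeAssignment:
    """Assign one sample by maximal Spearman correlation with the centroids.

    The best subtype is reported only when its correlation reaches the
    cutoff; an exact tie for the maximum yields unclassified with the tie
    flag set.
    """
    genes = centroids.classifier_genes
    missing = [g for g in genes if g not in sample.index]
    if missing:
        raise KeyError(f"sample missing classifier genes: {missing[:10]}")
    vec = sample.loc[genes].to_numpy(dtype=float)
    if np.isnan(vec).any():
        bad = [g for g, v in zip(genes, sample.loc[genes]) if np.isnan(v)]
        raise ValueError(f"sample has missing values for genes: {bad[:10]}")
    sample_ranks = stats.rankdata(vec)
    rhos: dict[str, float] = {}
    for s in centroids.subtypes:
        cent_ranks = stats.rankdata(centroids.centroids[s].to_numpy())
        if np.ptp(sample_ranks) == 0 or np.ptp(cent_ranks) == 0:
            rhos[s] = float("nan")
            continue
        rhos[s] = float(np.corrcoef(sample_ranks, cent_ranks)[0, 1])
    finite = {s: r for s, r in rhos.items() if np.isfinite(r)}
    name = str(sample.name) if sample.name is not None else ""
    if not finite:
        return SubtypeAssignment(name, None, rhos, cutoff)
    best_rho = max(finite.values())
    winners = [s for s, r in finite.items() if r == best_rho]
    if len(winners) > 1:
        return SubtypeAssignment(name, None, rhos, cutoff, tie=True)
    if best_rho >= cutoff:
        return SubtypeAssignment(name, winners[0], rhos, cutoff)
    return SubtypeAssignment(name, None, rhos, cutoff)


def classify_compendium(matrix: ExpressionMatrix, centroids: SubtypeCentroidSet,
                        cutoff: float = DEFAULT_CUTOFF,
                        ) -> tuple[list[SubtypeAssignment], pd.DataFrame]:
    """Assign every sample of a (QC-passed) compendium.

    Returns the per-sample assignments and a frequency table over the
    centroid subtypes plus unclassified, with percentages to one decimal.
    """
    assignments = [
        assign_subtype(matrix.values[s], centroids, cutoff)
        for s in matrix.sample_ids
    ]
    n = len(assignments)
    rows = []
    for s in centroids.subtypes + [UNCLASSIFIED]:
        if s == UNCLASSIFIED:
            k = sum(1 for a in assignments if not a.classified)
        else:
            k = sum(1 for a in assignments if a.best_subtype == s)
        rows.append({"subtype": s, "n": k, "percent": percent(k, n) if n else float("nan")})
    return assignments, pd.DataFrame(rows)


def assignments_to_frame(assignments: list[SubtypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments: one row per sample, one rho column per subtype."""
    if not assignments:
        return pd.DataFrame(columns=["sample_id", "call"])
    subtypes = list(assignments[0].correlations)
    rows = []
    for a in assignments:
        row = {"sample_id": a.sample_id,
               "call": a.best_subtype if a.classified else UNCLASSIFIED}
        row.update({f"rho_{s}": a.correlations.get(s, float("nan")) for s in subtypes})
        rows.append(row)
    return pd.DataFrame(rows)
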
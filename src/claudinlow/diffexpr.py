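"""Claudin-low signature derivation by moderated differential expression.

Per-gene two-group statistics use an empirical-Bayes variance model: each
gene's pooled residual variance s² (d residual degrees of freedom) is
shrunk toward a prior variance s0² with d0 prior degrees of freedom,

    s̃² = (d0·s0² + d·s²) / (d0 + d),

and the moderated t-statistic t = Δ / (s̃·√(1/nₐ + 1/n_b)) is referred to a
t-distribution with d0 + d degrees of freedom (the moderated F is t² for a
single contrast).  The hyperparameters (d0, s0²) are fitted by matching
moments of log s² using digamma/trigamma identities for the log of a scaled
chi-square variable.  As d0 → 0 the ordinary pooled t-test is recovered; as
d0 → ∞ every gene shares the prior variance.

Multiple testing uses the Benjamini-Yekutieli step-up procedure, valid
under arbitrary dependence: Benjamini-Hochberg inflated by the harmonic
factor c(m) = Σ_{k=1..m} 1/k.

A gene enters the claudin-low signature when, in every one of the six
comparisons of claudin-low against another subtype, its adjusted p-value is
below alpha, its fold change is at least the threshold (default 2-fold,
i.e. |log2 FC| ≥ 1), and the direction of change is the same throughout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .data_io import ExpressionMatrix, SignatureGene

logger = logging.getLogger(__name__)

CL_LABEL = "claudin-low"


@dataclass
class DEConfig:
    """Signature-selection thresholds.

    ``fold_change_min`` is on the natural scale (2 means two-fold, i.e.
    |log2 FC| >= 1); ``alpha`` applies to the BY-adjusted p-values.
    """

    fold_change_min: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_change_min < 1:
            raise ValueError("fold_change_min must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x approximation
    x0 = 0.5 + 1.0 / y
    f = lambda x: special.polygamma(1, x) - y
    # bracket: trigamma is decreasing
    lo, hi = x0, x0
    while f(lo) < 0:
        lo /= 2
    while f(hi) > 0:
        hi *= 2
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) from per-gene variances.

    Matches the mean and variance of log s² to those of the log of a scaled
    F variable.  When the observed spread of log s² does not exceed what
    the residual chi-square alone explains, the prior degrees of freedom
    are infinite (full shrinkage) and a warning is emitted.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all genes have zero residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    e_mean = float(np.mean(e))
    excess = float(np.mean((e - e_mean) ** 2) * len(e) / (len(e) - 1)) - float(special.polygamma(1, df / 2))
    if excess <= 0 or not np.isfinite(excess):
        warnings.warn("under-dispersed gene variances; using infinite prior df "
                      "(full shrinkage)", stacklevel=2)
        d0 = math.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        # E[e] = log s0^2 - digamma(d0/2) + log(d0/2)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - math.log(d0 / 2)))
    return d0, s0_2


def moderated_two_group_stats(matrix: ExpressionMatrix,
                              group_a: list[str], group_b: list[str],
                              prior_df: float | None = None,
                              ) -> pd.DataFrame:
    """Per-gene moderated t/F statistics for group A versus group B.

    ``prior_df`` overrides the fitted prior degrees of freedom d0 (0
    disables shrinkage; ``math.inf`` forces every gene onto the prior
    variance); by default d0 is fitted from the data.  The log2 fold change
    is mean(A) - mean(B).  Returns a DataFrame indexed by gene with columns
    log2_fold_change, moderated_t, moderated_F, p_value, by_adjusted_p.
    """
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    xa = matrix.values[a].to_numpy(dtype=float)
    xb = matrix.values[b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if (s2 == 0).all():
        raise ValueError("all genes have zero variance")

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float("nan")
    elif math.isinf(prior_df):
        d0, s0_2 = math.inf, float(np.exp(
            np.mean(np.log(s2[s2 > 0]) - special.digamma(df_resid / 2) + math.log(df_resid / 2))))
    else:
        d0 = float(prior_df)
        _, s0_2 = fit_variance_prior(s2, df_resid)

    if d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    if math.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({
        "log2_fold_change": lfc,
        "moderated_t": t,
        "moderated_F": t ** 2,
        "p_value": p,
    }, index=matrix.values.index)
    out["by_adjusted_p"] = by_adjust(out["p_value"].to_numpy())
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    out.attrs["residual_df"] = df_resid
    return out


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    adj_(i) = min over j >= i of min(1, p_(j) · m · c(m) / j) with
    c(m) = Σ_{k=1..m} 1/k, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def derive_cl_signature(matrix: ExpressionMatrix,
                        config: DEConfig | None = None,
                        cl_label: str = CL_LABEL,
                        prior_df: float | None = None,
                        ) -> tuple[list[SignatureGene], dict[str, pd.DataFrame]]:
    """Derive the claudin-low signature from a subtype-labeled matrix.

    Runs one moderated comparison of claudin-low against each other
    subtype; a gene is kept iff it is significant (BY-adjusted p < alpha),
    has |log2 FC| ≥ log2(fold_change_min), and changes in the same
    direction in *every* comparison.  Returns the signature genes (with
    their common direction relative to claudin-low) and the per-comparison
    statistics tables.
    """
    config = config or DEConfig()
    if matrix.subtype_labels is None:
        raise ValueError("signature derivation requires subtype labels")
    labels = matrix.subtype_labels.dropna()
    counts = labels.value_counts()
    if cl_label not in counts.index:
        raise ValueError(f"no samples labeled {cl_label!r}")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"subtypes with fewer than 2 samples: {dict(small)}")
    cl_ids = list(labels.index[labels == cl_label])
    others = [s for s in counts.index if s != cl_label]
    lfc_thresh = math.log2(config.fold_change_min)

    results: dict[str, pd.DataFrame] = {}
    keep = pd.Series(True, index=matrix.values.index)
    sign: pd.Series | None = None
    for other in others:
        other_ids = list(labels.index[labels == other])
        res = moderated_two_group_stats(matrix, cl_ids, other_ids, prior_df=prior_df)
        results[other] = res
        this_sign = np.sign(res["log2_fold_change"])
        passes = (
            (res["by_adjusted_p"] < config.alpha)
            & (res["log2_fold_change"].abs() >= lfc_thresh)
        )
        keep &= passes
        if sign is None:
            sign = this_sign
        else:
            keep &= this_sign == sign
    assert sign is not None
    signature = [
        SignatureGene(symbol=g, direction="up" if sign[g] > 0 else "down")
        for g in sorted(matrix.values.index[keep])
    ]
    logger.info("claudin-low signature: %d genes across %d comparisons",
                len(signature), len(others))
    return signature, results
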
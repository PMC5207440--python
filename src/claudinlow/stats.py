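"""Cohort association and survival statistics.

Covers the comparisons a clinical characteristics table needs: Pearson
chi-square (no continuity correction), the Cochran-Armitage test for trend
with equally spaced scores, Kruskal-Wallis, Kaplan-Meier estimation with
Greenwood standard errors and complementary log-log 95% bands, and the
k-group log-rank test.  All tests are two-sided.

Percentages are formatted with half-up rounding to one decimal, the
convention of clinical tables (so 49/72 prints as 68.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


def percent(k: float, n: float, decimals: int = 1) -> float:
    """Proportion ``k/n`` as a percentage, rounded half-up."""
    if n == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    scale = 10 ** decimals
    return math.floor(100.0 * k / n * scale + 0.5) / scale


@dataclass
class ContingencyTable:
    row_labels: list[str]
    column_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) != self.counts.shape[0] or len(self.column_labels) != self.counts.shape[1]:
            raise ValueError("label lengths must match the count matrix")


def chi_square_test(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, two-sided p).  Zero row or
    column margins are an error (expected counts undefined).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def cochran_armitage_trend(table: ContingencyTable | np.ndarray,
                           scores: np.ndarray | None = None) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    ``table`` is 2 x k with the first row counting "successes" in each of k
    ordered categories; ``scores`` default to 1..k.  Returns (Z, two-sided
    normal p).  Z is positive when the success proportion increases with
    the score.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("trend test needs a 2 x k table with k >= 2")
    x = counts[0]          # successes per column
    n = counts.sum(axis=0)  # column totals
    total = n.sum()
    if total == 0 or (n == 0).any():
        raise ValueError("degenerate margins in trend test")
    s = np.arange(1, counts.shape[1] + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    p_bar = x.sum() / total
    if p_bar in (0.0, 1.0):
        raise ValueError("degenerate margins: one row is empty")
    num = float(np.sum(s * (x - n * p_bar)))
    var = p_bar * (1 - p_bar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / total)
    z = num / math.sqrt(var)
    return z, float(2 * sps.norm.sf(abs(z)))


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test across g groups, with tie correction.

    Returns (H, df = g-1, chi-square p).  When every observation is
    identical the statistic is 0 by convention and p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), df, float(p)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with pointwise 95% bands.

    ``event_times`` are the distinct observed event times in ascending
    order; all other arrays are evaluated just after each event time.
    Confidence bands use the complementary log-log transform with
    Greenwood's variance.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (step function, S(0)=1)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        return float(self.ci_low[idx]), float(self.ci_high[idx])


def kaplan_meier(times, events, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood SE and cloglog 95% CI.

    Events at a time are processed before censorings at the same time (the
    usual convention).  All-censored input yields a curve identically 1
    with no event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1 or len(times) == 0:
        raise ValueError("times and events must be equal-length non-empty vectors")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    if len(event_times) == 0:
        empty = np.array([])
        return SurvivalCurve(empty, empty, empty, empty, empty)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))) over event times
    d = event_rows["observed"].to_numpy(dtype=float)
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = d / (n_at_risk * (n_at_risk - d))
        increments[~np.isfinite(increments)] = np.nan  # S hit 0: variance undefined
        cum = np.nancumsum(increments)
        se = surv * np.sqrt(cum)
    ci = kmf.confidence_interval_survival_function_
    ci_low = np.array([float(ci.iloc[ci.index.get_loc(t), 0]) for t in event_times])
    ci_high = np.array([float(ci.iloc[ci.index.get_loc(t), 1]) for t in event_times])
    return SurvivalCurve(event_times, surv, se, ci_low, ci_high)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square statistic, k-1 df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if not events.any():
        raise ValueError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Characteristics table (clinical-pathologic summary by subtype)

_KM_TIMEPOINTS = {"os": (3, 5, 10), "dfs": (5, 10), "lr": (5, 10)}


def _fmt_km(curve: SurvivalCurve, t: float) -> str:
    s = curve.at(t)
    lo, hi = curve.ci_at(t)
    return f"{100 * s:.1f} ({100 * lo:.1f}-{100 * hi:.1f})"


def _count_row(flags: pd.Series, by: pd.Series, groups: list[str]) -> dict[str, str]:
    out = {}
    for g in groups:
        sub = flags[by == g].dropna()
        k, n = int(sub.sum()), len(sub)
        out[g] = f"{k}/{n} ({percent(k, n)})" if n else "0/0"
    return out


def build_characteristics_table(calls: pd.DataFrame, clinical: pd.DataFrame,
                                cl_label: str = "claudin-low",
                                ) -> pd.DataFrame:
    """Summarize clinical-pathologic characteristics by subtype call.

    ``calls`` needs columns tumor_id and subtype (optionally aldh1_pos and
    cd44_cd24); ``clinical`` is a clinical-record table.  The output has
    one row per characteristic, one column per subtype present, a combined
    claudin-low-versus-rest pair of columns, and the p-value of the
    appropriate test (Kruskal-Wallis for age, chi-square for categorical
    rows, log-rank for event counts).  When only one subtype is present the
    claudin-low-versus-rest columns are suppressed with a note.
    """
    df = calls.merge(clinical, on="tumor_id", how="inner")
    if df.empty:
        raise ValueError("no tumors shared between calls and clinical tables")
    groups = [g for g in df["subtype"].unique()]
    n_total = len(df)
    is_cl = df["subtype"] == cl_label
    have_rest = is_cl.any() and (~is_cl).any()

    rows: list[dict] = []

    def add(name: str, per_group: dict[str, str], cl_vs_rest: str = "", p=None):
        row = {"characteristic": name, **per_group,
               "CL_vs_rest": cl_vs_rest if have_rest else "n/a (single group)",
               "p_value": "" if p is None else f"{p:.3g}"}
        rows.append(row)

    add("N (%)", {g: f"{int((df['subtype'] == g).sum())} ({percent(int((df['subtype'] == g).sum()), n_total)})"
                  for g in groups},
        f"{int((~is_cl).sum())}" if have_rest else "")

    # Age: mean (sd) with Kruskal-Wallis across groups
    age_groups = [df.loc[df["subtype"] == g, "age_years"].to_numpy() for g in groups]
    _, _, p_age = kruskal_wallis(age_groups) if len(groups) > 1 else (0, 0, None)
    add("Age mean (sd)",
        {g: f"{df.loc[df['subtype'] == g, 'age_years'].mean():.1f} "
            f"({df.loc[df['subtype'] == g, 'age_years'].std():.1f})" for g in groups},
        (f"{df.loc[~is_cl, 'age_years'].mean():.1f} ({df.loc[~is_cl, 'age_years'].std():.1f})"
         if have_rest else ""), p_age)

    def chi_p(flags: pd.Series) -> float | None:
        if len(groups) < 2:
            return None
        tab = pd.crosstab(df["subtype"], flags)
        if min(tab.shape) < 2 or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            return None
        _, _, p = chi_square_test(tab.to_numpy())
        return p

    binary_rows = [
        ("Age >= 50", df["age_years"] >= 50),
        ("Size >= 2 cm", df["tumor_size_cm"] >= 2),
        ("LVI positive", df["lvi"].astype(bool)),
        ("Extensive infiltrate", df["lymphocytic_infiltrate"] == "extensive"),
        ("Circumscribed margins", df["circumscribed_margin"].astype(bool)),
    ]
    for grade in ("I", "II", "III"):
        binary_rows.append((f"Grade {grade}", df["grade"] == grade))
    for arm in ("tamoxifen", "chemotherapy", "none"):
        binary_rows.append((f"Adjuvant {arm}", df["adjuvant"] == arm))
    for name, col in (("ALDH1 positive", "aldh1_pos"), ("CD44+/CD24-/low", "cd44_cd24")):
        if col in df.columns:
            binary_rows.append((name, df[col]))
    for name, flags in binary_rows:
        per_group = _count_row(flags, df["subtype"], groups)
        cl_rest = ""
        if have_rest:
            sub = flags[~is_cl].dropna()
            cl_rest = f"{int(sub.sum())}/{len(sub)} ({percent(int(sub.sum()), len(sub))})" if len(sub) else "0/0"
        add(name, per_group, cl_rest, chi_p(flags.dropna().astype(bool).reindex(df.index)))

    # Survival endpoints: event counts with log-rank p, then KM timepoints
    for endpoint, points in _KM_TIMEPOINTS.items():
        t_col, e_col = f"{endpoint}_time", f"{endpoint}_event"
        ev = df[e_col].astype(bool)
        p_lr = None
        if len(groups) > 1 and ev.any():
            _, _, p_lr = logrank_test(df[t_col], ev, df["subtype"])
        add(f"{endpoint.upper()} events",
            {g: f"{int(ev[df['subtype'] == g].sum())} "
                f"({percent(int(ev[df['subtype'] == g].sum()), int((df['subtype'] == g).sum()))})"
             for g in groups},
            f"{int(ev[~is_cl].sum())} ({percent(int(ev[~is_cl].sum()), int((~is_cl).sum()))})"
            if have_rest else "", p_lr)
        curves = {g: kaplan_meier(df.loc[df["subtype"] == g, t_col],
                                  df.loc[df["subtype"] == g, e_col]) for g in groups}
        rest_curve = kaplan_meier(df.loc[~is_cl, t_col], df.loc[~is_cl, e_col]) if have_rest else None
        for t in points:
            add(f"{t}-year {endpoint.upper()}",
                {g: _fmt_km(curves[g], t) for g in groups},
                _fmt_km(rest_curve, t) if rest_curve is not None else "")

    cols = ["characteristic"] + groups + ["CL_vs_rest", "p_value"]
    return pd.DataFrame(rows)[cols]
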
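"""Surrogate immunohistochemical (IHC) classifier for breast cancer
molecular subtypes, including the claudin-low class.

The classifier operates on Allred scores.  An Allred raw score is the sum of
a staining-intensity score (absent 0, weak 1, moderate 2, strong 3) and a
proportion-of-cells-stained category (none 0, <1% 1, 1-10% 2, 11-33% 3,
34-66% 4, 67-100% 5), giving a value of 0 or 2-8; a raw score of 1 cannot
occur because nonzero intensity forces a nonzero proportion.

Marker cutoffs (overridable via :class:`MarkerCutoffRules`):

* ER/PR positive: raw 3-8 (0 and 2 negative)
* HER2 positive: raw >= 6; raw 4-5 equivocal, resolved by FISH
  (HER2/CEP17 ratio >= 2 means amplified); raw <= 3 negative
* CK5, EGFR, CD24, CD44, ALDH1 positive: raw >= 4
* claudin 3/4/7 and E-cadherin "low": raw <= 4
* Ki67 high: >= 14% of nuclei stained

Decision rules: hormone-receptor (ER or PR) positive tumors split into
luminal A (HER2-negative and Ki67-low) versus luminal B (HER2-positive or
Ki67-high); HR-negative HER2-positive tumors are HER2-enriched; triple
negatives are claudin-low when at least two of the four adhesion markers
are low, otherwise basal-like when CK5 or EGFR is positive.  Claudin-low
takes precedence over basal-like: the reference claudin-low cell lines are
EGFR-positive yet remain claudin-low.  Triple negatives matching neither
rule fall into an explicit ``triple-negative-other`` category.  A tumor
whose first applicable rule needs an unavailable marker is ``unclassified``
with the missing marker named.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .data_io import VALID_ALLRED_RAW

# IHC call categories
LUMINAL_A = "luminal A"
LUMINAL_B = "luminal B"
HER2_ENRICHED = "HER2-enriched"
BASAL_LIKE = "basal-like"
CLAUDIN_LOW = "claudin-low"
TN_OTHER = "triple-negative-other"
UNCLASSIFIED = "unclassified"

IHC_SUBTYPES = (LUMINAL_A, LUMINAL_B, HER2_ENRICHED, BASAL_LIKE, CLAUDIN_LOW)
IHC_CALL_CATEGORIES = IHC_SUBTYPES + (TN_OTHER, UNCLASSIFIED)

ADHESION_MARKERS = ("CLDN3", "CLDN4", "CLDN7", "ECAD")

#: Proportion-category bin upper edges (percent stained -> category 0..5).
_PROPORTION_BINS = (0.0, 1.0, 10.0, 33.0, 66.0, 100.0)


@dataclass(frozen=True)
class AllredScore:
    """Composite Allred score: intensity (0-3) + proportion category (0-5)."""

    intensity: int
    proportion_category: int

    def __post_init__(self) -> None:
        if not 0 <= self.intensity <= 3:
            raise ValueError(f"intensity must be 0-3, got {self.intensity}")
        if not 0 <= self.proportion_category <= 5:
            raise ValueError(f"proportion category must be 0-5, got {self.proportion_category}")
        if (self.intensity == 0) != (self.proportion_category == 0):
            raise ValueError(
                "intensity and proportion must be zero together "
                f"(got intensity={self.intensity}, category={self.proportion_category})"
            )

    @property
    def raw(self) -> int:
        return self.intensity + self.proportion_category


def proportion_category(percent: float) -> int:
    """Map a percentage of stained cells to its Allred proportion category."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if percent == 0:
        return 0
    if percent < 1:
        return 1
    if percent <= 10:
        return 2
    if percent <= 33:
        return 3
    if percent <= 66:
        return 4
    return 5


def allred_raw(intensity: int, proportion_percent: float) -> AllredScore:
    """Build an Allred score from intensity and percent of cells stained.

    Raises on the inconsistent combinations (stain intensity without stained
    cells, or stained cells without intensity).
    """
    if (intensity == 0) != (proportion_percent == 0):
        raise ValueError(
            f"inconsistent Allred inputs: intensity={intensity}, percent={proportion_percent}"
        )
    return AllredScore(intensity=intensity, proportion_category=proportion_category(proportion_percent))


@dataclass(frozen=True)
class MarkerCutoffRules:
    """All marker cutoffs used by the subtype decision rules."""

    er_pr_positive_min: int = 3           # raw 3-8 positive, 0/2 negative
    her2_positive_min: int = 6
    her2_equivocal: tuple[int, int] = (4, 5)
    generic_positive_min: int = 4         # CK5, EGFR, CD24, CD44, ALDH1
    adhesion_low_max: int = 4             # CLDN3/4/7, ECAD
    ki67_high_min_percent: float = 14.0
    fish_amplified_min_ratio: float = 2.0
    min_adhesion_low_for_cl: int = 2


DEFAULT_RULES = MarkerCutoffRules()


def aggregate_cores(raw_scores: Sequence[int]) -> Optional[int]:
    """Collapse up to three replicate core scores for one tumor and marker.

    The highest available score wins; no scores at all means missing.
    """
    scores = [int(s) for s in raw_scores if s is not None and not (isinstance(s, float) and math.isnan(s))]
    if not scores:
        return None
    bad = set(scores) - VALID_ALLRED_RAW
    if bad:
        raise ValueError(f"invalid Allred raw scores: {sorted(bad)}")
    return max(scores)


def resolve_her2(raw: int, fish_ratio: Optional[float] = None,
                 rules: MarkerCutoffRules = DEFAULT_RULES) -> Optional[bool]:
    """HER2 status from the Allred score, with FISH for equivocal scores.

    Returns True (positive), False (negative), or None when the score is
    equivocal (4-5) and no FISH ratio is available.
    """
    if raw not in VALID_ALLRED_RAW:
        raise ValueError(f"invalid Allred raw score {raw}")
    if raw >= rules.her2_positive_min:
        return True
    lo, hi = rules.her2_equivocal
    if lo <= raw <= hi:
        if fish_ratio is None:
            return None
        return fish_ratio >= rules.fish_amplified_min_ratio
    return False


@dataclass
class TumorIHCProfile:
    """Aggregated per-tumor marker scores and the calls derived from them.

    ``marker_scores`` maps marker name to the aggregated Allred raw score
    (missing markers are simply absent or None).  Derived boolean calls are
    None when the underlying marker is missing (or, for HER2, unresolved).
    """

    tumor_id: str
    marker_scores: Mapping[str, Optional[int]] = field(default_factory=dict)
    ki67_percent: Optional[float] = None
    fish_ratio: Optional[float] = None
    rules: MarkerCutoffRules = DEFAULT_RULES

    def _score(self, marker: str) -> Optional[int]:
        s = self.marker_scores.get(marker)
        if s is None or (isinstance(s, float) and math.isnan(s)):
            return None
        return int(s)

    def _positive(self, marker: str, cutoff: int) -> Optional[bool]:
        s = self._score(marker)
        return None if s is None else s >= cutoff

    @property
    def er_pos(self) -> Optional[bool]:
        return self._positive("ER", self.rules.er_pr_positive_min)

    @property
    def pr_pos(self) -> Optional[bool]:
        return self._positive("PR", self.rules.er_pr_positive_min)

    @property
    def her2_status(self) -> Optional[bool]:
        s = self._score("HER2")
        if s is None:
            return None
        return resolve_her2(s, self.fish_ratio, self.rules)

    @property
    def ki67_high(self) -> Optional[bool]:
        if self.ki67_percent is None or (isinstance(self.ki67_percent, float) and math.isnan(self.ki67_percent)):
            return None
        return self.ki67_percent >= self.rules.ki67_high_min_percent

    @property
    def ck5_pos(self) -> Optional[bool]:
        return self._positive("CK5", self.rules.generic_positive_min)

    @property
    def egfr_pos(self) -> Optional[bool]:
        return self._positive("EGFR", self.rules.generic_positive_min)

    @property
    def aldh1_pos(self) -> Optional[bool]:
        return self._positive("ALDH1", self.rules.generic_positive_min)

    @property
    def adhesion_low_count(self) -> int:
        """Number of non-missing adhesion markers scoring low."""
        return sum(
            1 for m in ADHESION_MARKERS
            if self._score(m) is not None and self._score(m) <= self.rules.adhesion_low_max
        )

    @property
    def adhesion_missing(self) -> list[str]:
        return [m for m in ADHESION_MARKERS if self._score(m) is None]


@dataclass(frozen=True)
class SubtypeCall:
    tumor_id: str
    subtype: str
    reason: str

    def __post_init__(self) -> None:
        if self.subtype not in IHC_CALL_CATEGORIES:
            raise ValueError(f"unknown subtype call {self.subtype!r}")


def _tri(value: Optional[bool]) -> str:
    return {True: "+", False: "-", None: "?"}[value]


def classify_tumor(profile: TumorIHCProfile,
                   rules: MarkerCutoffRules | None = None) -> SubtypeCall:
    """Assign one tumor to a molecular subtype from its IHC profile.

    Missing data never raises: a tumor whose first applicable rule needs an
    unavailable marker becomes ``unclassified`` and the reason names the
    blocking marker.
    """
    if rules is not None and rules != profile.rules:
        profile = TumorIHCProfile(
            tumor_id=profile.tumor_id,
            marker_scores=profile.marker_scores,
            ki67_percent=profile.ki67_percent,
            fish_ratio=profile.fish_ratio,
            rules=rules,
        )
    r = profile.rules
    er, pr = profile.er_pos, profile.pr_pos
    her2 = profile.her2_status
    tid = profile.tumor_id

    # Hormone-receptor status: positive if either ER or PR is positive;
    # negative only when both are known negative.
    if er or pr:
        hr_pos = True
    elif er is False and pr is False:
        hr_pos = False
    else:
        missing = [m for m, v in (("ER", er), ("PR", pr)) if v is None]
        return SubtypeCall(tid, UNCLASSIFIED, f"missing:{','.join(missing)}")

    if hr_pos:
        ki67 = profile.ki67_high
        if her2 is True:
            return SubtypeCall(tid, LUMINAL_B, "HR+;HER2+")
        if ki67 is True:
            return SubtypeCall(tid, LUMINAL_B, f"HR+;HER2{_tri(her2)};Ki67-high")
        if her2 is None:
            return SubtypeCall(tid, UNCLASSIFIED, "missing:HER2")
        if ki67 is None:
            return SubtypeCall(tid, UNCLASSIFIED, "missing:Ki67")
        return SubtypeCall(tid, LUMINAL_A, "HR+;HER2-;Ki67-low")

    if her2 is True:
        return SubtypeCall(tid, HER2_ENRICHED, "HR-;HER2+")
    if her2 is None:
        return SubtypeCall(tid, UNCLASSIFIED, "missing:HER2")

    # Triple negative from here on.  Claudin-low takes precedence.
    low_n = profile.adhesion_low_count
    missing_adh = profile.adhesion_missing
    if low_n >= r.min_adhesion_low_for_cl:
        return SubtypeCall(tid, CLAUDIN_LOW, f"TN;adhesion-low:{low_n}")
    if low_n + len(missing_adh) >= r.min_adhesion_low_for_cl:
        # Missing adhesion markers could still make the tumor claudin-low.
        return SubtypeCall(tid, UNCLASSIFIED, f"missing:{','.join(missing_adh)}")
    ck5, egfr = profile.ck5_pos, profile.egfr_pos
    if ck5 or egfr:
        pos = [m for m, v in (("CK5", ck5), ("EGFR", egfr)) if v]
        return SubtypeCall(tid, BASAL_LIKE, f"TN;{'/'.join(pos)}+")
    if ck5 is None or egfr is None:
        missing = [m for m, v in (("CK5", ck5), ("EGFR", egfr)) if v is None]
        return SubtypeCall(tid, UNCLASSIFIED, f"missing:{','.join(missing)}")
    return SubtypeCall(tid, TN_OTHER, "TN;no-basal;no-CL")


def stemness_phenotype(profile: TumorIHCProfile) -> tuple[Optional[bool], Optional[bool]]:
    """Cancer stem-cell marker calls: (ALDH1 positive, CD44+/CD24-/low).

    The CD44+/CD24-/low phenotype requires CD44 positive (raw >= 4) and
    CD24 below the positivity cutoff; either marker missing yields None.
    """
    aldh1 = profile.aldh1_pos
    cd44 = profile._score("CD44")
    cd24 = profile._score("CD24")
    if cd44 is None or cd24 is None:
        cd44_cd24 = None
    else:
        r = profile.rules
        cd44_cd24 = cd44 >= r.generic_positive_min and cd24 < r.generic_positive_min
    return aldh1, cd44_cd24


def build_profiles(core_table: pd.DataFrame,
                   rules: MarkerCutoffRules = DEFAULT_RULES) -> list[TumorIHCProfile]:
    """Aggregate a core-level score table into per-tumor profiles.

    Allred markers aggregate by the highest core score; Ki67 (percent
    channel) likewise by the maximum percentage; the FISH ratio, when
    reported on several cores, by the maximum ratio.
    """
    profiles = []
    for tumor_id, group in core_table.groupby("tumor_id", sort=True):
        scores: dict[str, Optional[int]] = {}
        ki67 = None
        fish = None
        for marker, sub in group.groupby("marker"):
            if marker == "KI67":
                vals = sub["ki67_percent"].dropna()
                ki67 = float(vals.max()) if len(vals) else None
            else:
                scores[marker] = aggregate_cores(sub["allred_raw"].tolist())
        fish_vals = group["fish_ratio"].dropna()
        if len(fish_vals):
            fish = float(fish_vals.max())
        profiles.append(TumorIHCProfile(
            tumor_id=str(tumor_id), marker_scores=scores,
            ki67_percent=ki67, fish_ratio=fish, rules=rules,
        ))
    return profiles


def classify_cohort(core_table: pd.DataFrame,
                    clinical_table: pd.DataFrame | None = None,
                    rules: MarkerCutoffRules = DEFAULT_RULES,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every tumor in a core-level table.

    Returns ``(calls, frequency)`` where ``calls`` has one row per tumor
    (tumor_id, subtype, reason, aldh1_pos, cd44_cd24) and ``frequency``
    tabulates counts and percentages (one decimal) over call categories.
    """
    import warnings

    profiles = build_profiles(core_table, rules)
    if clinical_table is not None and len(profiles):
        known = set(clinical_table["tumor_id"].astype(str))
        orphans = [p.tumor_id for p in profiles if p.tumor_id not in known]
        if orphans:
            warnings.warn(
                f"{len(orphans)} tumors absent from the clinical table "
                f"(e.g. {orphans[:3]}); classified anyway",
                stacklevel=2,
            )
    rows = []
    for p in profiles:
        call = classify_tumor(p)
        aldh1, cd44_cd24 = stemness_phenotype(p)
        rows.append({
            "tumor_id": p.tumor_id, "subtype": call.subtype, "reason": call.reason,
            "aldh1_pos": aldh1, "cd44_cd24": cd44_cd24,
        })
    calls = pd.DataFrame(rows, columns=["tumor_id", "subtype", "reason", "aldh1_pos", "cd44_cd24"])
    freq = subtype_frequency(calls["subtype"] if len(calls) else pd.Series(dtype=str))
    return calls, freq


def subtype_frequency(calls: "pd.Series | Iterable[str]") -> pd.DataFrame:
    """Count calls per category with one-decimal percentages."""
    from .stats import percent

    s = pd.Series(list(calls), dtype=str)
    n = len(s)
    rows = []
    for cat in IHC_CALL_CATEGORIES:
        k = int((s == cat).sum())
        rows.append({"subtype": cat, "n": k, "percent": percent(k, n) if n else float("nan")})
    return pd.DataFrame(rows)
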
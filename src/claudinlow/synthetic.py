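"""Synthetic expression compendia and IHC/clinical cohorts.

Every downstream stage of the pipeline is testable without external
downloads because this module generates data with the statistical structure
the analysis assumes:

* :func:`simulate_expression_compendium` emulates a merged multi-study
  microarray compendium on the log2 scale — seven molecular subtypes with
  subtype-specific mean shifts on a classifier gene subset, a housekeeping
  subset whose means are identical across subtypes and batches, additive
  Gaussian batch shifts on everything else, and Gaussian residual noise.
* :func:`corrupt_samples` damages the housekeeping profile of a chosen
  fraction of samples (by permuting their housekeeping values), the failure
  mode the compendium QC filter is designed to catch.
* :func:`simulate_ihc_cohort` emulates a tissue-microarray cohort: per-tumor
  Allred scores drawn from subtype-conditional distributions consistent with
  the IHC decision rules, triplicate cores with dropouts, exponential event
  times with subtype-specific hazards and independent exponential censoring.

A single integer seed feeds every substream through ``numpy``'s
``SeedSequence`` spawning, so adding a stage never perturbs earlier streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .centroids import EXPRESSION_SUBTYPES
from .data_io import CLINICAL_COLUMNS, CORE_COLUMNS, ExpressionMatrix
from .ihc import (
    ADHESION_MARKERS, BASAL_LIKE, CLAUDIN_LOW, DEFAULT_RULES, HER2_ENRICHED,
    IHC_SUBTYPES, LUMINAL_A, LUMINAL_B, UNCLASSIFIED,
)

# ---------------------------------------------------------------------------
# Expression compendium


@dataclass
class ExpressionSimConfig:
    """Configuration of the expression-compendium simulator.

    ``effect_size`` is the magnitude (log2 units) of the subtype-specific
    mean shift applied to classifier genes; each classifier gene receives an
    independent random ±effect_size shift per subtype, which is what makes
    the subtype centroids mutually distinguishable.  ``noise_sd`` is the
    residual SD on the log2 scale (0.5 by default, a typical residual
    spread for normalized arrays).  Housekeeping gene means are drawn over
    a wide intensity range (log2 3-14, as housekeeping probe sets span on
    real arrays) so that clean samples rank-correlate strongly over them.
    """

    n_per_subtype: Mapping[str, int] | int = 50
    n_genes: int = 1000
    n_classifier_genes: int = 710
    n_housekeeping: int = 68
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_batches: int = 3
    batch_sd: float = 0.5
    seed: int = 0

    def counts(self) -> dict[str, int]:
        if isinstance(self.n_per_subtype, int):
            return {s: self.n_per_subtype for s in EXPRESSION_SUBTYPES}
        return dict(self.n_per_subtype)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts().values()):
            raise ValueError("subtype counts must be positive")
        if self.n_classifier_genes + self.n_housekeeping > self.n_genes:
            raise ValueError(
                "n_classifier_genes + n_housekeeping exceeds n_genes "
                f"({self.n_classifier_genes} + {self.n_housekeeping} > {self.n_genes})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")


def simulate_expression_compendium(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Generate a subtype- and batch-labeled log2 expression matrix.

    Classifier genes (``CLF...``) carry the subtype signal; housekeeping
    genes (``HK...``) share one mean across subtypes *and* batches; the
    remaining filler genes (``GEN...``) have a common mean plus batch
    shifts.  Deterministic for a fixed config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    rng_struct, rng_batch, rng_noise = (np.random.default_rng(s) for s in root.spawn(3))

    counts = config.counts()
    subtype_of_sample: list[str] = []
    for s in EXPRESSION_SUBTYPES:
        if s in counts:
            subtype_of_sample += [s] * counts[s]
    for s in counts:
        if s not in EXPRESSION_SUBTYPES:
            raise ValueError(f"unknown subtype {s!r}")
    n_samples = len(subtype_of_sample)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    n_clf, n_hk = config.n_classifier_genes, config.n_housekeeping
    n_fill = config.n_genes - n_clf - n_hk
    gene_ids = (
        [f"CLF{i + 1:04d}" for i in range(n_clf)]
        + [f"HK{i + 1:03d}" for i in range(n_hk)]
        + [f"GEN{i + 1:04d}" for i in range(n_fill)]
    )

    base = np.empty(config.n_genes)
    base[:n_clf] = rng_struct.normal(7.0, 1.0, n_clf)
    base[n_clf:n_clf + n_hk] = rng_struct.uniform(3.0, 14.0, n_hk)
    base[n_clf + n_hk:] = rng_struct.normal(7.0, 1.0, n_fill)

    # ±effect_size shift per (classifier gene, subtype)
    signs = rng_struct.choice([-1.0, 1.0], size=(n_clf, len(EXPRESSION_SUBTYPES)))
    shift = {s: signs[:, j] * config.effect_size for j, s in enumerate(EXPRESSION_SUBTYPES)}

    batches = rng_batch.integers(0, config.n_batches, n_samples)
    batch_offsets = rng_batch.normal(0.0, config.batch_sd, (config.n_batches, config.n_genes))
    batch_offsets[:, n_clf:n_clf + n_hk] = 0.0  # housekeeping immune to batch

    values = np.tile(base[:, None], (1, n_samples))
    for j, (subtype, batch) in enumerate(zip(subtype_of_sample, batches)):
        values[:n_clf, j] += shift[subtype]
        values[:, j] += batch_offsets[batch]
    values += rng_noise.normal(0.0, config.noise_sd, values.shape)

    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        batch_labels=pd.Series([f"batch{b + 1}" for b in batches], index=sample_ids),
        subtype_labels=pd.Series(subtype_of_sample, index=sample_ids),
        housekeeping_genes=gene_ids[n_clf:n_clf + n_hk],
    )


def corrupt_samples(matrix: ExpressionMatrix, fraction: float, seed: int,
                    housekeeping_genes: Sequence[str] | None = None,
                    ) -> tuple[ExpressionMatrix, list[str]]:
    """Permute the housekeeping values of a random fraction of samples.

    Exactly ``round(fraction * n_samples)`` samples are corrupted: each has
    its housekeeping values independently shuffled across genes, destroying
    its rank agreement with clean samples while leaving every other gene
    untouched.  Returns the new matrix and the corrupted sample ids.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    hk = list(housekeeping_genes) if housekeeping_genes is not None else list(matrix.housekeeping_genes)
    if not hk:
        raise ValueError("no housekeeping genes given or recorded on the matrix")
    rng = np.random.default_rng(seed)
    n = matrix.n_samples
    n_corrupt = int(round(fraction * n))
    chosen = sorted(rng.choice(n, size=n_corrupt, replace=False).tolist())
    values = matrix.values.copy()
    hk_idx = values.index.get_indexer(hk)
    arr = values.to_numpy()
    for j in chosen:
        arr[hk_idx, j] = rng.permutation(arr[hk_idx, j])
    out = ExpressionMatrix(
        values=pd.DataFrame(arr, index=values.index, columns=values.columns),
        batch_labels=None if matrix.batch_labels is None else matrix.batch_labels.copy(),
        subtype_labels=None if matrix.subtype_labels is None else matrix.subtype_labels.copy(),
        housekeeping_genes=list(matrix.housekeeping_genes),
    )
    return out, [matrix.sample_ids[j] for j in chosen]


# ---------------------------------------------------------------------------
# IHC / clinical cohort

_NEG = {0: 0.8, 2: 0.2}
_ADH_HIGH = {5: 0.2, 6: 0.3, 7: 0.3, 8: 0.2}
_ADH_LOW = {0: 0.6, 2: 0.2, 3: 0.1, 4: 0.1}

#: Subtype-conditional Allred score distributions, chosen to be consistent
#: with each subtype's defining IHC rule (validated at simulation time).
DEFAULT_MARKER_DISTS: dict[str, dict[str, dict[int, float]]] = {
    LUMINAL_A: {
        "ER": {6: 0.3, 7: 0.5, 8: 0.2}, "PR": {0: 0.2, 3: 0.2, 5: 0.3, 7: 0.3},
        "HER2": {0: 0.6, 2: 0.3, 5: 0.1}, "CK5": _NEG, "EGFR": _NEG,
        "CLDN3": _ADH_HIGH, "CLDN4": _ADH_HIGH, "CLDN7": _ADH_HIGH, "ECAD": _ADH_HIGH,
        "CD24": {4: 0.3, 5: 0.4, 6: 0.3}, "CD44": {0: 0.4, 2: 0.3, 4: 0.2, 6: 0.1},
        "ALDH1": {0: 0.7, 2: 0.25, 4: 0.05},
    },
    LUMINAL_B: {
        "ER": {6: 0.3, 7: 0.5, 8: 0.2}, "PR": {0: 0.3, 3: 0.3, 6: 0.4},
        "HER2": {0: 0.4, 2: 0.3, 7: 0.2, 8: 0.1}, "CK5": _NEG, "EGFR": _NEG,
        "CLDN3": _ADH_HIGH, "CLDN4": _ADH_HIGH, "CLDN7": _ADH_HIGH, "ECAD": _ADH_HIGH,
        "CD24": {4: 0.3, 5: 0.4, 6: 0.3}, "CD44": {0: 0.4, 2: 0.3, 4: 0.2, 6: 0.1},
        "ALDH1": {0: 0.6, 2: 0.3, 4: 0.1},
    },
    HER2_ENRICHED: {
        "ER": _NEG, "PR": _NEG,
        "HER2": {5: 0.15, 6: 0.2, 7: 0.35, 8: 0.3},
        "CK5": {0: 0.7, 2: 0.3}, "EGFR": {0: 0.5, 2: 0.2, 4: 0.2, 6: 0.1},
        "CLDN3": _ADH_HIGH, "CLDN4": _ADH_HIGH, "CLDN7": _ADH_HIGH, "ECAD": _ADH_HIGH,
        "CD24": {4: 0.4, 6: 0.6}, "CD44": {0: 0.3, 2: 0.3, 4: 0.2, 6: 0.2},
        "ALDH1": {0: 0.6, 2: 0.3, 4: 0.1},
    },
    BASAL_LIKE: {
        "ER": _NEG, "PR": _NEG, "HER2": _NEG,
        "CK5": {5: 0.2, 6: 0.3, 7: 0.3, 8: 0.2}, "EGFR": {5: 0.3, 6: 0.3, 7: 0.2, 8: 0.2},
        "CLDN3": _ADH_HIGH, "CLDN4": _ADH_HIGH, "CLDN7": _ADH_HIGH, "ECAD": _ADH_HIGH,
        "CD24": {0: 0.4, 2: 0.2, 4: 0.4}, "CD44": {4: 0.3, 6: 0.4, 8: 0.3},
        "ALDH1": {0: 0.4, 2: 0.3, 4: 0.2, 6: 0.1},
    },
    CLAUDIN_LOW: {
        "ER": _NEG, "PR": _NEG, "HER2": _NEG,
        "CK5": {0: 0.5, 2: 0.2, 4: 0.15, 6: 0.15},
        "EGFR": {0: 0.2, 2: 0.2, 4: 0.2, 6: 0.2, 8: 0.2},
        "CLDN3": _ADH_LOW, "CLDN4": {0: 0.5, 2: 0.2, 3: 0.2, 4: 0.1},
        "CLDN7": _ADH_LOW, "ECAD": {0: 0.5, 2: 0.3, 3: 0.1, 4: 0.1},
        "CD24": {0: 0.6, 2: 0.3, 3: 0.1}, "CD44": {4: 0.2, 5: 0.2, 6: 0.3, 8: 0.3},
        "ALDH1": {0: 0.5, 2: 0.3, 4: 0.1, 6: 0.1},
    },
}

#: Ki67 percent ranges (uniform), rule-consistent with the luminal A/B split.
DEFAULT_KI67_RANGES = {
    LUMINAL_A: (2.0, 12.0), LUMINAL_B: (20.0, 60.0), HER2_ENRICHED: (10.0, 60.0),
    BASAL_LIKE: (20.0, 80.0), CLAUDIN_LOW: (10.0, 70.0),
}

#: Whether equivocal HER2 scores (4-5) in this subtype FISH-amplify.
DEFAULT_FISH_AMPLIFIED = {
    LUMINAL_A: False, LUMINAL_B: True, HER2_ENRICHED: True,
    BASAL_LIKE: False, CLAUDIN_LOW: False,
}

#: Observed cohort subtype mix used as the default simulation frequencies.
DEFAULT_SUBTYPE_FREQUENCIES = {
    LUMINAL_A: 0.413, LUMINAL_B: 0.248, HER2_ENRICHED: 0.022,
    BASAL_LIKE: 0.056, CLAUDIN_LOW: 0.084, UNCLASSIFIED: 0.177,
}

#: Exponential hazards per subtype and endpoint (events/year), set so the
#: implied 10-year survival matches the cohort-scale figures the decision
#: rules were characterized on.
DEFAULT_HAZARDS = {
    LUMINAL_A: {"os": 0.0153, "dfs": 0.0326, "lr": 0.0051},
    LUMINAL_B: {"os": 0.0176, "dfs": 0.0420, "lr": 0.0071},
    HER2_ENRICHED: {"os": 0.0100, "dfs": 0.0567, "lr": 0.0237},
    BASAL_LIKE: {"os": 0.0241, "dfs": 0.0491, "lr": 0.0090},
    CLAUDIN_LOW: {"os": 0.0203, "dfs": 0.0322, "lr": 0.0013},
}

_AGE = {LUMINAL_A: (60.5, 10.3), LUMINAL_B: (58.3, 11.8), HER2_ENRICHED: (56.4, 11.1),
        BASAL_LIKE: (51.9, 10.9), CLAUDIN_LOW: (52.8, 11.9)}
_GRADE_P = {LUMINAL_A: (0.303, 0.661, 0.036), LUMINAL_B: (0.124, 0.684, 0.192),
            HER2_ENRICHED: (0.053, 0.526, 0.421), BASAL_LIKE: (0.023, 0.140, 0.837),
            CLAUDIN_LOW: (0.069, 0.250, 0.681)}
_SIZE_GE2_P = {LUMINAL_A: 0.131, LUMINAL_B: 0.261, HER2_ENRICHED: 0.333,
               BASAL_LIKE: 0.340, CLAUDIN_LOW: 0.329}
_ADJUVANT_P = {LUMINAL_A: (0.512, 0.028, 0.460), LUMINAL_B: (0.474, 0.077, 0.449),
               HER2_ENRICHED: (0.095, 0.429, 0.476), BASAL_LIKE: (0.094, 0.585, 0.321),
               CLAUDIN_LOW: (0.203, 0.405, 0.392)}
_EXTENSIVE_P = {LUMINAL_A: 0.011, LUMINAL_B: 0.091, HER2_ENRICHED: 0.333,
                BASAL_LIKE: 0.458, CLAUDIN_LOW: 0.419}
_CIRCUMSCRIBED_P = {LUMINAL_A: 0.170, LUMINAL_B: 0.228, HER2_ENRICHED: 0.286,
                    BASAL_LIKE: 0.385, CLAUDIN_LOW: 0.443}
_LVI_P = {LUMINAL_A: 0.108, LUMINAL_B: 0.210, HER2_ENRICHED: 0.048,
          BASAL_LIKE: 0.173, CLAUDIN_LOW: 0.127}


@dataclass
class CohortSimConfig:
    """Configuration of the TMA cohort simulator.

    ``subtype_frequencies`` covers the five IHC subtypes plus an
    ``unclassified`` mass (tumors generated with their HER2 and Ki67 stains
    lost, which the decision rules cannot classify).  ``censoring_rate`` is
    the hazard (per year) of the independent exponential censoring time.
    """

    n_tumors: int = 942
    subtype_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_FREQUENCIES))
    marker_score_distributions: Mapping[str, Mapping[str, Mapping[int, float]]] = field(
        default_factory=lambda: DEFAULT_MARKER_DISTS)
    ki67_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KI67_RANGES))
    fish_amplified: Mapping[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_FISH_AMPLIFIED))
    hazard_per_subtype: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_HAZARDS)
    censoring_rate: float = 0.02
    missing_core_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype frequencies must sum to 1, got {total}")
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        if not 0 <= self.missing_core_rate <= 1:
            raise ValueError("missing_core_rate must be in [0, 1]")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        for s, h in self.hazard_per_subtype.items():
            if any(v <= 0 for v in h.values()):
                raise ValueError(f"hazards must be positive ({s})")


def _check_rule_consistency(config: CohortSimConfig) -> None:
    """Warn when a score distribution contradicts its subtype's own rule."""
    rules = DEFAULT_RULES
    for subtype, dists in config.marker_score_distributions.items():
        def support(marker: str) -> list[int]:
            return sorted(dists.get(marker, {}))

        def warn(msg: str) -> None:
            warnings.warn(f"{subtype}: {msg}", stacklevel=3)

        er_max = max(support("ER"), default=0)
        pr_max = max(support("PR"), default=0)
        her2 = support("HER2")
        her2_can_pos = any(
            s >= rules.her2_positive_min
            or (rules.her2_equivocal[0] <= s <= rules.her2_equivocal[1]
                and config.fish_amplified.get(subtype, False))
            for s in her2)
        if subtype in (LUMINAL_A, LUMINAL_B):
            if er_max < rules.er_pr_positive_min and pr_max < rules.er_pr_positive_min:
                warn("luminal distribution can never be hormone-receptor positive")
            lo, hi = config.ki67_ranges.get(subtype, (0.0, 0.0))
            if subtype == LUMINAL_A and (hi >= rules.ki67_high_min_percent or her2_can_pos):
                warn("luminal A distribution allows HER2+ or Ki67-high tumors")
            if subtype == LUMINAL_B and lo < rules.ki67_high_min_percent and not her2_can_pos:
                warn("luminal B distribution allows HER2-/Ki67-low tumors")
        else:
            if er_max >= rules.er_pr_positive_min or pr_max >= rules.er_pr_positive_min:
                warn("non-luminal distribution allows hormone-receptor positivity")
            if subtype == HER2_ENRICHED and not her2_can_pos:
                warn("HER2-enriched distribution can never be HER2 positive")
            if subtype in (BASAL_LIKE, CLAUDIN_LOW) and her2_can_pos:
                warn("triple-negative distribution allows HER2 positivity")
        if subtype == CLAUDIN_LOW:
            always_low = sum(
                1 for m in ADHESION_MARKERS
                if support(m) and max(support(m)) <= rules.adhesion_low_max)
            if always_low < rules.min_adhesion_low_for_cl:
                warn("claudin-low distribution does not guarantee two low adhesion markers")
        if subtype == BASAL_LIKE:
            can_low = sum(
                1 for m in ADHESION_MARKERS
                if any(s <= rules.adhesion_low_max for s in support(m)))
            if can_low >= rules.min_adhesion_low_for_cl:
                warn("basal-like distribution may satisfy the claudin-low rule")
            if max(support("CK5"), default=0) < rules.generic_positive_min and \
               max(support("EGFR"), default=0) < rules.generic_positive_min:
                warn("basal-like distribution can never be CK5/EGFR positive")


def _draw_score(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(scores, p=probs))


def _core_variants(rng: np.random.Generator, score: int) -> list[int]:
    """Three core-level scores whose maximum is the tumor-level score."""
    cores = [score]
    for _ in range(2):
        cand = score - int(rng.choice([0, 0, 2]))  # occasional weaker core
        if cand <= 1:
            cand = 0
        cores.append(cand)
    return cores


def simulate_ihc_cohort(config: CohortSimConfig,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate (core score table, clinical table, true subtype labels).

    Each tumor gets three cores per marker minus independent dropouts at
    ``missing_core_rate``; "unclassified" tumors are real-subtype tumors
    whose HER2 and Ki67 stains are entirely missing.  Event times are
    exponential with the subtype's hazard, censored by a single independent
    exponential follow-up time per tumor.  Deterministic under the seed.
    """
    _check_rule_consistency(config)
    root = np.random.SeedSequence(config.seed)
    rng_sub, rng_marker, rng_core, rng_clin, rng_surv = (
        np.random.default_rng(s) for s in root.spawn(5))

    freq_labels = list(config.subtype_frequencies)
    freq_p = np.array([config.subtype_frequencies[s] for s in freq_labels])
    true_labels = [
        freq_labels[i] for i in rng_sub.choice(len(freq_labels), config.n_tumors, p=freq_p)
    ]
    real_p = np.array([config.subtype_frequencies.get(s, 0.0) for s in IHC_SUBTYPES])
    real_p = real_p / real_p.sum() if real_p.sum() > 0 else np.full(len(IHC_SUBTYPES), 1 / len(IHC_SUBTYPES))

    core_rows: list[dict] = []
    clin_rows: list[dict] = []
    for i, label in enumerate(true_labels):
        tumor_id = f"T{i + 1:04d}"
        if label == UNCLASSIFIED:
            base = IHC_SUBTYPES[int(rng_sub.choice(len(IHC_SUBTYPES), p=real_p))]
            drop_markers = {"HER2", "KI67"}
        else:
            base = label
            drop_markers = set()
        dists = config.marker_score_distributions[base]

        tumor_fish: float | None = None
        for marker, dist in dists.items():
            if marker in drop_markers:
                continue
            score = _draw_score(rng_marker, dist)
            fish = None
            if marker == "HER2" and DEFAULT_RULES.her2_equivocal[0] <= score <= DEFAULT_RULES.her2_equivocal[1]:
                if config.fish_amplified.get(base, False):
                    tumor_fish = float(rng_marker.uniform(2.2, 6.0))
                else:
                    tumor_fish = float(rng_marker.uniform(0.8, 1.8))
                fish = tumor_fish
            for core_index, core_score in enumerate(_core_variants(rng_core, score), start=1):
                if rng_core.random() < config.missing_core_rate:
                    continue
                core_rows.append({
                    "tumor_id": tumor_id, "core_index": core_index, "marker": marker,
                    "allred_raw": core_score, "ki67_percent": np.nan,
                    "fish_ratio": fish if core_index == 1 else np.nan,
                })
        if "KI67" not in drop_markers:
            lo, hi = config.ki67_ranges[base]
            pct = float(rng_marker.uniform(lo, hi))
            for core_index in range(1, 4):
                if rng_core.random() < config.missing_core_rate:
                    continue
                core_pct = pct if core_index == 1 else pct * float(rng_core.uniform(0.7, 1.0))
                core_rows.append({
                    "tumor_id": tumor_id, "core_index": core_index, "marker": "KI67",
                    "allred_raw": np.nan, "ki67_percent": core_pct, "fish_ratio": np.nan,
                })

        # clinical covariates conditioned on the underlying (base) subtype
        age_mu, age_sd = _AGE[base]
        age = float(np.clip(rng_clin.normal(age_mu, age_sd), 25, 95))
        grade = ("I", "II", "III")[int(rng_clin.choice(3, p=np.array(_GRADE_P[base]) / sum(_GRADE_P[base])))]
        size = float(rng_clin.uniform(2.0, 5.0) if rng_clin.random() < _SIZE_GE2_P[base]
                     else rng_clin.uniform(0.5, 2.0))
        adjuvant = ("tamoxifen", "chemotherapy", "none")[
            int(rng_clin.choice(3, p=np.array(_ADJUVANT_P[base]) / sum(_ADJUVANT_P[base])))]
        if rng_clin.random() < _EXTENSIVE_P[base]:
            infiltrate = "extensive"
        else:
            infiltrate = ("none", "minimal", "moderate")[int(rng_clin.choice(3, p=(0.4, 0.35, 0.25)))]
        hazards = config.hazard_per_subtype[base]
        censor = float(rng_surv.exponential(1.0 / config.censoring_rate)) \
            if config.censoring_rate > 0 else float("inf")
        record = {
            "tumor_id": tumor_id, "age_years": age, "tumor_size_cm": size, "grade": grade,
            "lvi": bool(rng_clin.random() < _LVI_P[base]),
            "lymphocytic_infiltrate": infiltrate,
            "circumscribed_margin": bool(rng_clin.random() < _CIRCUMSCRIBED_P[base]),
            "adjuvant": adjuvant,
        }
        for endpoint in ("os", "dfs", "lr"):
            t = float(rng_surv.exponential(1.0 / hazards[endpoint]))
            record[f"{endpoint}_time"] = min(t, censor)
            record[f"{endpoint}_event"] = t <= censor
        clin_rows.append(record)

    cores = pd.DataFrame(core_rows, columns=CORE_COLUMNS)
    clinical = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    labels = pd.Series(true_labels, index=clinical["tumor_id"].tolist(), name="true_subtype")
    return cores, clinical, labels
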
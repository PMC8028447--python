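"""Canopy vertical-heterogeneity analysis and group statistics.

This module holds the spatial analyses: within-leaf basal/central/top
gradients, per-layer vertical profiles with standard errors, ANOVA with
Fisher's LSD and compact-letter display, layer-relative ratios (bottom layer
L1 as control), the four-way classification of vertical JIP-parameter
patterns, and detection of the growth stage at which the vertical chlorophyll
profile reverses from bottom-heavy to top-heavy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .transients import LAYERS, STAGES


def standard_error(values: Sequence[float]) -> float:
    """SE = SD / sqrt(n) with the sample SD (n - 1 denominator); n >= 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("standard error needs at least two values")
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))


@dataclass(frozen=True)
class AnovaLsd:
    """One-way ANOVA with Fisher's LSD compact-letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """

    f_statistic: float
    p_value: float
    letters: tuple[str, ...]
    alpha: float
    df_error: int
    mse: float


def _compact_letters(means: np.ndarray, significant: np.ndarray) -> list[str]:
    """Insert-and-absorb compact-letter display.

    ``significant[i, j]`` flags pairs declared different; each maximal set of
    mutually non-different groups becomes one letter column, columns ordered
    by descending column-maximum mean so 'a' marks the highest means.
    """
    k = means.size
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                for split in (col - {j}, col - {i}):
                    if split and not any(split <= other for other in columns):
                        columns.append(split)
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: (-max(means[g] for g in c), tuple(sorted(c))))
    labels = ["" for _ in range(k)]
    for idx, col in enumerate(columns):
        # a..z then aa, ab, ... for pathological numbers of columns
        letter = ""
        n = idx
        while True:
            letter = chr(ord("a") + n % 26) + letter
            n = n // 26 - 1
            if n < 0:
                break
        for g in sorted(col):
            labels[g] += letter
    return labels


def anova_lsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaLsd:
    """One-way ANOVA F/p plus pairwise Fisher-LSD letters.

    Each group needs n >= 2.  When the pooled error mean square is zero, the
    F statistic degenerates: unequal means are then reported with p at the
    machine floor and separated letters; fully constant data share one letter
    with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least two observations")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    n_total = int(ns.sum())
    df_error = n_total - k
    sse = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    mse = sse / df_error

    if mse == 0.0:
        if np.allclose(means, means[0]):
            return AnovaLsd(0.0, 1.0, tuple(["a"] * k), alpha, df_error, 0.0)
        significant = ~np.isclose(means[:, None], means[None, :])
        letters = _compact_letters(means, significant)
        return AnovaLsd(float("inf"), float(np.finfo(float).tiny), tuple(letters), alpha, df_error, 0.0)

    f_stat, p_val = stats.f_oneway(*arrays)
    significant = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se_diff = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            t = abs(means[i] - means[j]) / se_diff
            p_pair = 2.0 * stats.t.sf(t, df_error)
            significant[i, j] = significant[j, i] = p_pair < alpha
    letters = _compact_letters(means, significant)
    return AnovaLsd(float(f_stat), float(p_val), tuple(letters), alpha, df_error, mse)


def within_leaf_gradient(
    basal: float, central: float, top: float, delta: float = 0.01
) -> str:
    """Classify the basal->central->top chlorophyll gradient of one leaf.

    ``increasing`` / ``decreasing`` require each step to exceed the relative
    tolerance ``delta``; ``flat`` means all three agree within tolerance;
    anything else is ``non_monotonic``.
    """
    def above(a: float, b: float) -> bool:
        return b > a * (1.0 + delta)

    def within(a: float, b: float) -> bool:
        return not above(a, b) and not above(b, a)

    if above(basal, central) and above(central, top):
        return "increasing"
    if above(central, basal) and above(top, central):
        return "decreasing"
    if within(basal, central) and within(central, top) and within(basal, top):
        return "flat"
    return "non_monotonic"


@dataclass(frozen=True)
class VerticalProfile:
    """Per-layer mean/SE/n of one quantity for one nitrogen x stage cell.

    Layers must form a contiguous bottom-up set starting at L1.
    """

    nitrogen: str
    stage: str
    quantity: str
    layers: tuple[str, ...]
    means: np.ndarray
    ses: np.ndarray
    ns: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "ses", np.asarray(self.ses, dtype=float))
        expected = LAYERS[: len(self.layers)]
        if tuple(self.layers) != expected:
            raise ValidationError(
                f"layers must be contiguous from L1, got {self.layers}"
            )
        if not (len(self.layers) == self.means.size == self.ses.size == len(self.ns)):
            raise ValidationError("profile fields must have equal length")
        if any(n < 1 for n in self.ns):
            raise ValidationError("each layer needs n >= 1")

    @classmethod
    def from_samples(
        cls, df: pd.DataFrame, value_col: str, nitrogen: str, stage: str
    ) -> "VerticalProfile":
        """Aggregate a long table (columns ``layer``, ``value_col``) into a
        profile; SE is reported as 0 for singleton layers."""
        grouped = df.groupby("layer")[value_col]
        layers = sorted(grouped.groups, key=lambda s: LAYERS.index(s))
        means, ses, ns = [], [], []
        for layer in layers:
            vals = grouped.get_group(layer).to_numpy(dtype=float)
            means.append(vals.mean())
            ses.append(standard_error(vals) if vals.size >= 2 else 0.0)
            ns.append(int(vals.size))
        return cls(nitrogen, stage, value_col, tuple(layers), np.array(means),
                   np.array(ses), tuple(ns))


def layer_relative_ratios(profile: VerticalProfile) -> dict[str, float]:
    """Each layer's mean relative to the bottom layer L1 (the control, == 1)."""
    l1 = profile.means[profile.layers.index("L1")]
    if l1 <= 0:
        raise ValidationError("L1 mean must be positive to form relative ratios")
    return {layer: float(m / l1) for layer, m in zip(profile.layers, profile.means)}


#: Peak/valley signatures of the four vertical-pattern categories of the
#: derived-parameter panel: (parameters peaking in the upper layers,
#: parameters dipping in the upper layers).
CATEGORY_SIGNATURES: dict[int, tuple[frozenset[str], frozenset[str]]] = {
    1: (frozenset({"PI_ABS", "ET0_RC", "ET0_CS", "phi_Eo", "psi_Eo"}), frozenset()),
    2: (frozenset({"N", "ABS_RC", "TR0_RC", "DI0_RC", "RE0_RC"}),
        frozenset({"RC_CS", "PI_ABS"})),
    3: (frozenset({"RE0_RC", "RE0_CS", "phi_Ro"}), frozenset()),
    4: (frozenset({"DI0_RC", "DI0_CS"}),
        frozenset({"PI_ABS", "ET0_RC", "phi_Eo", "ET0_CS"})),
}


@dataclass(frozen=True)
class CategoryMatch:
    category: int
    score: int
    tie: bool
    peaks: frozenset[str] = field(default_factory=frozenset)
    valleys: frozenset[str] = field(default_factory=frozenset)


def _upper_layers(layers: Sequence[str]) -> list[str]:
    """The upper half of the present layers, rounding up (L3-L5 of five,
    L2-L3 of three)."""
    n = len(layers)
    return list(layers)[n - (n + 1) // 2:]


def classify_stage_category(
    panel: Mapping[str, Mapping[str, float]], delta: float = 0.05
) -> CategoryMatch:
    """Match a stage's layer-relative parameter panel to one of the four
    vertical-pattern categories.

    ``panel`` maps parameter name -> {layer -> L1-relative ratio}.  A
    parameter *peaks* when the mean ratio of the upper layers exceeds
    1 + ``delta`` and *valleys* below 1 - ``delta``.  Each signature scores
    concordant indicators minus discordant ones; the argmax category wins,
    ties broken toward the lowest category id and flagged.
    """
    required = set().union(*(p | v for p, v in CATEGORY_SIGNATURES.values()))
    missing = sorted(required - set(panel))
    if missing:
        raise ValidationError(f"panel missing parameter(s): {missing}")

    peaks, valleys = set(), set()
    for name in required:
        profile = panel[name]
        if len(profile) < 3:
            raise ValidationError(f"parameter {name!r} has fewer than 3 layers")
        layers = sorted(profile, key=lambda s: LAYERS.index(s))
        upper_mean = float(np.mean([profile[l] for l in _upper_layers(layers)]))
        if upper_mean > 1.0 + delta:
            peaks.add(name)
        elif upper_mean < 1.0 - delta:
            valleys.add(name)

    scores: dict[int, int] = {}
    for cat, (sig_peaks, sig_valleys) in CATEGORY_SIGNATURES.items():
        score = 0
        for name in sig_peaks:
            score += (name in peaks) - (name in valleys)
        for name in sig_valleys:
            score += (name in valleys) - (name in peaks)
        scores[cat] = score
    best = max(scores.values())
    winners = sorted(cat for cat, s in scores.items() if s == best)
    return CategoryMatch(
        category=winners[0],
        score=best,
        tie=len(winners) > 1,
        peaks=frozenset(peaks),
        valleys=frozenset(valleys),
    )


def vertical_slope(profile: VerticalProfile) -> float:
    """Least-squares slope of the per-layer means against layer rank
    (1 = bottom).  Negative = bottom-heavy, positive = top-heavy."""
    ranks = np.arange(1, len(profile.layers) + 1, dtype=float)
    return float(np.polyfit(ranks, profile.means, 1)[0])


def detect_reversal_stage(
    profiles: Mapping[str, VerticalProfile],
    stage_order: Sequence[str] = STAGES,
) -> str | None:
    """First stage at which the vertical profile turns from bottom-heavy to
    top-heavy (slope sign flips negative -> positive); ``None`` without a
    sign change.  Stages with fewer than 3 layers are skipped with a warning.
    """
    seen_bottom_heavy = False
    for stage in stage_order:
        if stage not in profiles:
            continue
        profile = profiles[stage]
        if len(profile.layers) < 3:
            warnings.warn(f"stage {stage}: fewer than 3 layers, skipped", stacklevel=2)
            continue
        slope = vertical_slope(profile)
        if slope < 0:
            seen_bottom_heavy = True
        elif slope > 0 and seen_bottom_heavy:
            return stage
    return None
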
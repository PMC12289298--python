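"""Questionnaire scoring for the dyad study's survey battery.

Implements the scale definitions used in the study (child- and
parent-reported CDI, the DASS-21 stress subscale, GAD-7, PHQ-9, MAAS, and a
16-item training-feasibility survey), reverse coding, the feasibility
composites, Cronbach alpha reliability, and family-affluence banding.

Scores are raw-scale scores. T-score conversion for the CDI relies on
proprietary norms and is intentionally not implemented; pre-computed T scores
can be carried alongside raw scores as ordinary input columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleDefinition",
    "SurveyResponse",
    "SCALES",
    "FEASIBILITY_POSITIVE_ITEMS",
    "FEASIBILITY_NEGATIVE_ITEMS",
    "score_scale",
    "reverse_code",
    "feasibility_composites",
    "cronbach_alpha",
    "affluence_band",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Static description of one questionnaire scale.

    Parameters
    ----------
    scale_id : str
        Identifier, e.g. ``"phq9"``.
    n_items : int
        Number of items.
    item_min, item_max : int
        Inclusive response bounds shared by all items of the scale.
    reverse_items : frozenset[int]
        0-based indices of reverse-coded items.
    scoring : {"sum", "mean"}
        Aggregation rule.
    higher_is_worse : bool
        Interpretation direction of the aggregated score (True for symptom
        scales, False for e.g. trait mindfulness).
    """

    scale_id: str
    n_items: int
    item_min: int
    item_max: int
    reverse_items: frozenset = field(default_factory=frozenset)
    scoring: str = "sum"
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("scale must have at least one item")
        if self.item_min >= self.item_max:
            raise ValueError("item_min must be < item_max")
        if self.scoring not in ("sum", "mean"):
            raise ValueError(f"unknown scoring rule {self.scoring!r}")
        bad = set(self.reverse_items) - set(range(self.n_items))
        if bad:
            raise ValueError(f"reverse items {sorted(bad)} outside item range")


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent's item vector for one scale at one timepoint."""

    dyad_id: str
    respondent: str  # "child" | "parent"
    scale_id: str
    timepoint: str  # "pre" | "post" | "followup"
    items: tuple

    def __post_init__(self) -> None:
        if self.respondent not in ("child", "parent"):
            raise ValueError(f"unknown respondent {self.respondent!r}")
        if self.timepoint not in ("pre", "post", "followup"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


# The MAAS items describe lapses of present-moment attention (1=almost always
# to 6=almost never endorsing inattention), so the raw anchors already run in
# the "higher = more mindful" direction; no per-item reversal is needed and
# the scale is aggregated by mean, per standard practice.
SCALES: dict[str, ScaleDefinition] = {
    "cdi_child": ScaleDefinition("cdi_child", 12, 0, 2),
    "cdi_parent": ScaleDefinition("cdi_parent", 17, 0, 3),
    "dass_stress": ScaleDefinition("dass_stress", 7, 0, 3),
    "gad7": ScaleDefinition("gad7", 7, 0, 3),
    "phq9": ScaleDefinition("phq9", 9, 0, 3),
    "maas": ScaleDefinition(
        "maas", 14, 1, 6, scoring="mean", higher_is_worse=False
    ),
    "feasibility": ScaleDefinition(
        "feasibility",
        16,
        1,
        7,
        scoring="mean",
        higher_is_worse=False,
        reverse_items=frozenset({1, 3, 5, 7, 12}),
    ),
}

#: 0-based positions of the 11 positive- and 5 negative-feedback items in the
#: 16-item feasibility survey, in administration order (negative items are the
#: frustration, tiredness, difficulty, data-security-worry and uselessness
#: probes interleaved among the positive ones).
FEASIBILITY_NEGATIVE_ITEMS: tuple = (1, 3, 5, 7, 12)
FEASIBILITY_POSITIVE_ITEMS: tuple = tuple(
    i for i in range(16) if i not in FEASIBILITY_NEGATIVE_ITEMS
)


def reverse_code(x, lo, hi):
    """Reverse-code an item value on an inclusive ``[lo, hi]`` scale.

    Returns ``lo + hi - x``; applying it twice is the identity. Accepts
    scalars or arrays. Raises ``ValueError`` if any value is out of range.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"value outside [{lo}, {hi}]")
    out = lo + hi - arr
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


def _validate_items(response: SurveyResponse, definition: ScaleDefinition) -> np.ndarray:
    items = np.asarray(response.items, dtype=float)
    if items.shape != (definition.n_items,):
        raise ValueError(
            f"{definition.scale_id}: expected {definition.n_items} items, "
            f"got {items.shape}"
        )
    bad = np.flatnonzero((items < definition.item_min) | (items > definition.item_max))
    if bad.size:
        raise ValueError(
            f"{definition.scale_id}: item {bad[0]} value {items[bad[0]]} outside "
            f"[{definition.item_min}, {definition.item_max}]"
        )
    return items


def score_scale(response: SurveyResponse, definition: ScaleDefinition) -> float:
    """Score one survey response against its scale definition.

    Reverse-coded items are mapped by ``min + max - x`` before aggregation;
    aggregation is the scale's sum or mean rule.
    """
    items = _validate_items(response, definition)
    if definition.reverse_items:
        idx = sorted(definition.reverse_items)
        items = items.copy()
        items[idx] = definition.item_min + definition.item_max - items[idx]
    return float(items.sum() if definition.scoring == "sum" else items.mean())


def feasibility_composites(item_values) -> dict:
    """Feasibility-survey composites from 16 item values (raw or item means).

    ``positive_avg`` is the unweighted mean of the 11 positive-feedback items,
    ``negative_avg`` the unweighted mean of the 5 negative-feedback items on
    their raw 1-7 anchors, and ``overall_avg`` the mean of the positive items
    together with the reverse-coded negative items.
    """
    vals = np.asarray(item_values, dtype=float)
    if vals.shape != (16,):
        raise ValueError(f"expected 16 feasibility items, got shape {vals.shape}")
    if np.any(vals < 1) or np.any(vals > 7):
        raise ValueError("feasibility items must lie in [1, 7]")
    pos = vals[list(FEASIBILITY_POSITIVE_ITEMS)]
    neg = vals[list(FEASIBILITY_NEGATIVE_ITEMS)]
    overall = np.concatenate([pos, reverse_code(neg, 1, 7)])
    return {
        "positive_avg": float(pos.mean()),
        "negative_avg": float(neg.mean()),
        "overall_avg": float(overall.mean()),
    }


def cronbach_alpha(item_matrix) -> float:
    """Cronbach alpha internal-consistency reliability.

    Parameters
    ----------
    item_matrix : array-like, shape (n_respondents, n_items)

    Returns
    -------
    float
        ``k/(k-1) * (1 - sum(item variances) / variance(total scores))``,
        with sample (ddof=1) variances.

    Raises
    ------
    ValueError
        For fewer than 2 items or 3 respondents, or zero total-score
        variance (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def affluence_band(score) -> str:
    """Band a family-affluence composite: 0-2 low, 3-5 middle, >5 high."""
    if score < 0:
        raise ValueError("affluence score must be nonnegative")
    if score <= 2:
        return "low"
    if score <= 5:
        return "middle"
    return "high"
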
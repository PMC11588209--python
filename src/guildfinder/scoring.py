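"""Grouping quality against a known ground truth, and predictive power.

The *recovery quality* of one ground-truth group is the Jaccard similarity
between that group and its best-matching group in the evaluated output
(each truth group maximizes independently, so one output group may be the
best match of several truth groups).  The *overall score* is the mean
recovery quality over all truth groups: 1 iff every truth group appears
verbatim in the output.  For an equal-size truth with N groups, a k-group
output can score at most ``min(k, N) / N`` — the performance ceiling — a
bound attained by outputs that reproduce ``k - 1`` truth groups exactly
and lump the rest together.

Predictive power of a fitted group model is measured out of sample as
``R^2 = 1 - RSS / TSS`` on held-out observations (negative when the model
predicts worse than the test mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import Grouping

__all__ = [
    "ScoreReport",
    "jaccard",
    "recovery_quality",
    "overall_score",
    "performance_ceiling",
    "r2_out_of_sample",
    "score_report",
]


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity ``|A & B| / |A | B|`` of two non-empty sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    return len(a & b) / len(a | b)


def recovery_quality(truth_group, grouping: Grouping) -> float:
    """Jaccard similarity of a truth group to its best match in ``grouping``."""
    return max(jaccard(truth_group, g) for g in grouping.groups)


def overall_score(truth: Grouping, candidate: Grouping) -> float:
    """Mean recovery quality of all ground-truth groups, in [0, 1]."""
    if truth.n_species != candidate.n_species:
        raise ValueError(
            f"species universes differ: {truth.n_species} vs {candidate.n_species}"
        )
    return float(np.mean([recovery_quality(g, candidate) for g in truth.groups]))


def performance_ceiling(k: int, n_truth_groups: int) -> float:
    """Highest overall score a k-group output can reach against an
    equal-size truth of ``n_truth_groups`` groups: ``min(k, N) / N``."""
    if k < 1 or n_truth_groups < 1:
        raise ValueError("group counts must be >= 1")
    return min(k, n_truth_groups) / n_truth_groups


def r2_out_of_sample(predictions, observations) -> float:
    """``1 - RSS/TSS`` on held-out data, with TSS about the test-set mean.

    Can be negative; undefined (error) when the observations have zero
    variance.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need matching 1-D arrays of at least 2 observations")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 is undefined for zero-variance observations")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


@dataclass(frozen=True)
class ScoreReport:
    """Per-truth-group recovery qualities and their summary."""

    per_group: tuple[float, ...]
    overall: float
    k: int  # groups in the evaluated output
    n_truth_groups: int
    ceiling: float | None  # min(k, N)/N; None when truth groups are unequal

    def to_dict(self) -> dict:
        return {
            "per_group": list(self.per_group),
            "overall": self.overall,
            "k": self.k,
            "n_truth_groups": self.n_truth_groups,
            "ceiling": self.ceiling,
        }


def score_report(truth: Grouping, candidate: Grouping) -> ScoreReport:
    """Full quality report of ``candidate`` against ``truth``.

    The analytic ceiling is only reported when the truth groups are all the
    same size (the regime in which it is derived).
    """
    per = tuple(recovery_quality(g, candidate) for g in truth.groups)
    sizes = {len(g) for g in truth.groups}
    ceiling = performance_ceiling(candidate.k, truth.k) if len(sizes) == 1 else None
    return ScoreReport(
        per_group=per,
        overall=float(np.mean(per)),
        k=candidate.k,
        n_truth_groups=truth.k,
        ceiling=ceiling,
    )
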
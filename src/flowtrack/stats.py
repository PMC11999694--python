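"""Cohort-level behaviour statistics and between-condition comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .analysis import BEHAVIOR_CATEGORIES
from .benchmark import fin_fout, match_predicate

__all__ = [
    "CohortSummary",
    "aggregate_behavior",
    "compare_distributions",
    "significance_tier",
    "match_tracksets",
]


@dataclass
class CohortSummary:
    """Per-category counts and fractions of arrested cells (= 100%).

    The fraction error is the binomial standard error
    sqrt(p·(1−p)/N) ("statistical error of the mean").
    """

    n_tracks: int
    counts: dict
    fractions: dict
    errors: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "count": self.counts, "fraction": self.fractions,
            "stat_error": self.errors,
        })


def aggregate_behavior(categories) -> CohortSummary:
    """Behaviour-category counts, fractions and statistical errors."""
    cats = list(categories)
    n = len(cats)
    if n == 0:
        raise ValueError("no categorized tracks")
    counts = {c: 0 for c in BEHAVIOR_CATEGORIES}
    for c in cats:
        if c not in counts:
            raise ValueError(f"unknown behaviour category {c!r}")
        counts[c] += 1
    fractions = {c: k / n for c, k in counts.items()}
    errors = {c: float(np.sqrt(p * (1 - p) / n))
              for c, p in fractions.items()}
    return CohortSummary(n, counts, fractions, errors)


def significance_tier(p: float) -> str:
    """Conventional star tiers: ns / * / ** / *** / ****."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_distributions(sample_a, sample_b):
    """Two-sided Mann-Whitney U with tie correction, plus the star tier.

    The exact null distribution is used for small samples without ties
    (min n ≤ 20); otherwise the normal approximation with continuity and
    tie correction.  Returns ``(U, p, tier)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 20 and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), significance_tier(res.pvalue)


def match_tracksets(set_a, set_b, d_in_um: float = 17.0,
                    d_out_um: float = 25.0, guard: float | None = 0.5):
    """Duplicate-track pairs between two track sets and the deduplicated
    inventory.

    Tracks must be in a common coordinate frame (tile offsets applied).  The
    identity predicate is the same fin/fout machinery used for scoring;
    f_in/f_out are evaluated over the first track's assigned frames.
    Returns ``(pairs, inventory)`` where pairs are
    ``(idx_a, idx_b, fin, fout)`` and the inventory lists
    ``("a", idx)`` / ``("b", idx)`` entries for unique tracks (the ``a``
    member represents a duplicated pair).
    """
    def frames_pos(t):
        ok = t.flags != "gap"
        return t.frames[ok], t.positions[ok]

    candidates = []
    for i, ta in enumerate(set_a):
        fa, pa = frames_pos(ta)
        for j, tb in enumerate(set_b):
            fb, pb = frames_pos(tb)
            fin, fout = fin_fout(fa, pa, fb, pb, d_in_um, d_out_um)
            if match_predicate(fin, fout, guard):
                candidates.append((fin, fout, i, j))
    pairs, used_a, used_b = [], set(), set()
    for fin, fout, i, j in sorted(candidates, key=lambda c: (-c[0], c[2], c[3])):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, fin, fout))
    inventory = [("a", i) for i in range(len(set_a))] + \
                [("b", j) for j in range(len(set_b)) if j not in used_b]
    return pairs, inventory
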
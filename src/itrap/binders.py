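"""Per-clonotype expected-binder identification and the accuracy metric.

The idea: within a clonally expanded clonotype, the cognate pMHC is captured
with systematically higher UMI counts than ambient/leaked pMHCs.  The pMHC
whose UMI distribution across the clonotype's GEMs is significantly higher
(one-sided rank-sum, alpha = 0.05) than every competing pMHC is declared the
clonotype's expected binder.  Accuracy is then the fraction of GEMs whose
most abundant capture equals the expected binder of their clonotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger("itrap")


def _u_statistic(ranks: np.ndarray, idx) -> float:
    """Mann-Whitney U of the subset ``idx`` of the pooled sample, computed via
    the rank-sum formulation (midranks for ties)."""
    n1 = len(idx)
    r1 = ranks[list(idx)].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def rank_sum_greater(x, y, exact_limit: int = 12) -> float:
    """One-sided p-value that the values in ``x`` are stochastically greater
    than those in ``y``.

    For n1 + n2 <= ``exact_limit`` the p-value is exact: the Mann-Whitney U of
    the observed labelling is compared against its full permutation null
    (every assignment of labels to the pooled values), which is valid under
    ties.  For larger samples the tie-corrected normal approximation of
    ``scipy.stats.mannwhitneyu`` (with continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_greater requires non-empty samples")
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = _u_statistic(ranks, tuple(range(n1)))
        count = 0
        total = 0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, idx)
            if u >= obs - eps:
                count += 1
            total += 1
        return count / total
    return float(stats.mannwhitneyu(x, y, alternative="greater",
                                    method="asymptotic").pvalue)


@dataclass
class BinderAnnotation:
    """Expected-binder call for one clonotype."""

    ct_id: str
    expected_pmhc: str | None
    p_values: dict[str, float] = field(default_factory=dict)
    n_gems: int = 0
    n_competitors: int = 0
    alpha: float = 0.05


def _umi_vectors(captures_per_gem: list[list[dict]], zero_fill: bool) -> dict[str, np.ndarray]:
    """Per-pMHC UMI vectors across a clonotype's GEMs.

    With ``zero_fill`` (default behaviour of the annotator) each vector spans
    every member GEM, absences counted as 0; otherwise only GEMs where the
    pMHC was detected contribute.
    """
    n = len(captures_per_gem)
    per_feature: dict[str, dict[int, int]] = {}
    for i, caps in enumerate(captures_per_gem):
        for cap in caps:
            per_feature.setdefault(cap["feature_id"], {})[i] = cap["umi"]
    out = {}
    for feat, hits in per_feature.items():
        if zero_fill:
            vec = np.zeros(n)
            for i, u in hits.items():
                vec[i] = u
        else:
            vec = np.array(sorted(hits.values(), key=float), dtype=float)
        out[feat] = vec
    return out


def annotate_expected_binders(table: pd.DataFrame, min_gems: int = 10,
                              alpha: float = 0.05, zero_fill: bool = True,
                              exact_limit: int = 12) -> list[BinderAnnotation]:
    """Identify the expected binder of every clonotype with >= ``min_gems``
    member GEMs.

    The candidate is the pMHC with the highest mean UMI; it is declared the
    expected binder iff a one-sided rank-sum test against every competing
    pMHC detected in the clonotype gives p < ``alpha``.  A clonotype with a
    single detected pMHC is annotated to it directly.
    """
    annotations = []
    grouped = table[table["ct_id"].notna()].groupby("ct_id")
    for ct_id, grp in grouped:
        if len(grp) < min_gems:
            continue
        vectors = _umi_vectors(list(grp["captures"]), zero_fill)
        if not vectors:
            continue
        ann = BinderAnnotation(ct_id=str(ct_id), expected_pmhc=None,
                               n_gems=len(grp),
                               n_competitors=len(vectors) - 1, alpha=alpha)
        if len(vectors) == 1:
            ann.expected_pmhc = next(iter(vectors))
        else:
            candidate = max(vectors, key=lambda f: (vectors[f].mean(), f))
            ok = True
            for feat, vec in vectors.items():
                if feat == candidate:
                    continue
                p = rank_sum_greater(vectors[candidate], vec, exact_limit)
                ann.p_values[feat] = p
                if not p < alpha:
                    ok = False
            if ok:
                ann.expected_pmhc = candidate
        annotations.append(ann)
    n_hit = sum(a.expected_pmhc is not None for a in annotations)
    logger.info("annotated expected binders for %d / %d clonotypes of size >= %d",
                n_hit, len(annotations), min_gems)
    return annotations


def binders_frame(annotations: list[BinderAnnotation]) -> pd.DataFrame:
    """Tabular form of the annotations (the ``binders.csv`` schema)."""
    return pd.DataFrame([{
        "ct_id": a.ct_id,
        "expected_pmhc": a.expected_pmhc,
        "n_gems": a.n_gems,
        "n_competitors": a.n_competitors,
        "max_competitor_p": max(a.p_values.values()) if a.p_values else np.nan,
    } for a in annotations])


def top_capture(captures: list[dict]) -> tuple[str | None, bool]:
    """The highest-UMI capture's feature id and whether the top is tied."""
    if not captures:
        return None, False
    best = max(c["umi"] for c in captures)
    top = sorted(c["feature_id"] for c in captures if c["umi"] == best)
    return top[0], len(top) > 1


def compute_accuracy(table: pd.DataFrame,
                     annotations: list[BinderAnnotation]) -> tuple[float | None, pd.DataFrame]:
    """Fraction of GEMs (within clonotypes that have an expected binder) whose
    most abundant pMHC equals the expected binder.

    A tie for the top capture counts as a miss.  Returns the pooled accuracy
    (None if no GEM qualifies) and a per-clonotype breakdown.
    """
    expected = {a.ct_id: a.expected_pmhc for a in annotations
                if a.expected_pmhc is not None}
    rows = []
    for ct_id, grp in table[table["ct_id"].isin(expected)].groupby("ct_id"):
        exp = expected[ct_id]
        n_correct = 0
        for caps in grp["captures"]:
            feat, tied = top_capture(caps)
            if feat == exp and not tied:
                n_correct += 1
        rows.append({"ct_id": ct_id, "expected_pmhc": exp,
                     "n_gems": len(grp), "n_correct": n_correct})
    breakdown = pd.DataFrame(rows, columns=["ct_id", "expected_pmhc",
                                            "n_gems", "n_correct"])
    denom = int(breakdown["n_gems"].sum()) if len(breakdown) else 0
    if denom == 0:
        logger.warning("accuracy undefined: no GEMs in annotated clonotypes")
        return None, breakdown
    return float(breakdown["n_correct"].sum() / denom), breakdown


class ExpectedBinderAnnotator(BaseEstimator):
    """Learn per-clonotype expected binders from a clonotyped GEM table.

    Parameters mirror :func:`annotate_expected_binders`.  After ``fit`` the
    calls are available as ``annotations_`` (list of BinderAnnotation) and
    ``binders_`` (DataFrame).  ``score(X)`` returns the accuracy metric of a
    table against the fitted annotations.
    """

    def __init__(self, min_gems: int = 10, alpha: float = 0.05,
                 zero_fill: bool = True, exact_limit: int = 12):
        self.min_gems = min_gems
        self.alpha = alpha
        self.zero_fill = zero_fill
        self.exact_limit = exact_limit

    def fit(self, X: pd.DataFrame, y=None):
        self.annotations_ = annotate_expected_binders(
            X, min_gems=self.min_gems, alpha=self.alpha,
            zero_fill=self.zero_fill, exact_limit=self.exact_limit)
        self.binders_ = binders_frame(self.annotations_)
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        acc, _ = compute_accuracy(X, self.annotations_)
        return np.nan if acc is None else acc
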
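"""Data-driven UMI thresholds: exhaustive grid search for the accuracy-maximizing
cutoffs on the binder-annotated ("golden standard") clonotypes, then global
application.

Three thresholds are searched: the minimum UMI of the top pMHC capture, the
minimum ratio of the top to the second pMHC UMI (pMHC multiplets only), and
the minimum UMI of each selected TCR chain.  The published optimum on the
public 10x data is (5, 1.2, 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .binders import BinderAnnotation, ExpectedBinderAnnotator
from .errors import ConfigError

logger = logging.getLogger("itrap")

DEFAULT_GRID = {
    "umi_min_pmhc": tuple(range(1, 21)),
    "ratio_min": tuple(round(1.0 + 0.1 * i, 1) for i in range(21)),
    "umi_min_tcr": tuple(range(0, 6)),
}


@dataclass(frozen=True)
class ThresholdSet:
    """The three UMI cutoffs applied per GEM (all boundaries inclusive)."""

    umi_min_pmhc: int
    ratio_min: float
    umi_min_tcr: int

    def __post_init__(self):
        if self.umi_min_pmhc < 1 or self.umi_min_tcr < 0 or self.ratio_min < 1:
            raise ConfigError(f"invalid thresholds {self}")

    def as_dict(self) -> dict:
        return {"umi_min_pmhc": self.umi_min_pmhc, "ratio_min": self.ratio_min,
                "umi_min_tcr": self.umi_min_tcr}


def _ratio_fraction(ratio: float) -> Fraction:
    # decimal grid values like 1.2 become exact rationals (12/10), so the
    # boundary 6/5 >= 1.2 is decided by integer arithmetic, not floats
    return Fraction(str(ratio))


def gem_features(table: pd.DataFrame, exempt_imputed: bool = False) -> pd.DataFrame:
    """Per-GEM quantities the thresholds act on.

    Columns: ``top_umi``, ``second_umi`` (0 for capture singlets), ``top_feature``,
    ``top_tie``, ``min_chain_umi`` (+inf when no chain is subject to the cutoff).
    """
    tops, seconds, feats, ties, minchain = [], [], [], [], []
    has_a = table["cdr3_a"].notna().to_numpy() if "cdr3_a" in table.columns \
        else np.zeros(len(table), dtype=bool)
    has_b = table["cdr3_b"].notna().to_numpy() if "cdr3_b" in table.columns \
        else np.zeros(len(table), dtype=bool)
    for pos, caps in enumerate(table["captures"]):
        umis = sorted((c["umi"] for c in caps), reverse=True)
        top = umis[0]
        second = umis[1] if len(umis) > 1 else 0
        best = sorted(c["feature_id"] for c in caps if c["umi"] == top)
        tops.append(top)
        seconds.append(second)
        feats.append(best[0])
        ties.append(len(best) > 1)
        vals = []
        row = table.iloc[pos]
        if has_a[pos] and not (exempt_imputed and bool(row.get("imputed_a", False))):
            vals.append(row["umi_a"])
        if has_b[pos] and not (exempt_imputed and bool(row.get("imputed_b", False))):
            vals.append(row["umi_b"])
        minchain.append(min(vals) if vals else np.inf)
    return pd.DataFrame({
        "top_umi": tops, "second_umi": seconds, "top_feature": feats,
        "top_tie": ties, "min_chain_umi": minchain,
    }, index=table.index)


def _retained_mask(feats: pd.DataFrame, t: ThresholdSet) -> np.ndarray:
    frac = _ratio_fraction(t.ratio_min)
    top = feats["top_umi"].to_numpy(dtype=np.int64)
    second = feats["second_umi"].to_numpy(dtype=np.int64)
    ratio_ok = top * frac.denominator >= frac.numerator * second
    return (
        (top >= t.umi_min_pmhc)
        & ratio_ok
        & ~feats["top_tie"].to_numpy()
        & (feats["min_chain_umi"].to_numpy() >= t.umi_min_tcr)
    )


def apply_thresholds(table: pd.DataFrame, t: ThresholdSet,
                     exempt_imputed: bool = False) -> pd.DataFrame:
    """Filter GEMs by the thresholds and set ``assigned_pmhc`` to the top capture.

    A GEM survives iff its top capture UMI >= ``umi_min_pmhc``, the top/second
    UMI ratio >= ``ratio_min`` (trivially true for capture singlets; the ratio
    boundary is decided by exact rational comparison), every selected TCR
    chain UMI >= ``umi_min_tcr``, and the top capture is not tied.
    """
    feats = gem_features(table, exempt_imputed)
    mask = _retained_mask(feats, t)
    out = table[mask].copy()
    out["assigned_pmhc"] = feats.loc[mask, "top_feature"]
    return out.reset_index(drop=True)


def grid_search_thresholds(table: pd.DataFrame,
                           annotations: list[BinderAnnotation],
                           grid: dict | None = None,
                           exempt_imputed: bool = False
                           ) -> tuple[ThresholdSet, pd.DataFrame]:
    """Exhaustively evaluate the accuracy objective over the threshold grid.

    The objective is the accuracy restricted to GEMs of binder-annotated
    clonotypes that survive the candidate thresholds.  Ties are broken by
    (1) more retained GEMs, then (2) lexicographically smaller thresholds.
    Returns the winning ThresholdSet and the full objective trace.
    """
    grid = {**DEFAULT_GRID, **(grid or {})}
    points = list(itertools.product(grid["umi_min_pmhc"], grid["ratio_min"],
                                    grid["umi_min_tcr"]))
    if not points:
        raise ConfigError("empty threshold grid")
    expected = {a.ct_id: a.expected_pmhc for a in annotations
                if a.expected_pmhc is not None}
    if not expected:
        raise ConfigError("no binder-annotated clonotypes to optimize on")
    sub = table[table["ct_id"].isin(expected)]
    feats = gem_features(sub, exempt_imputed)
    top = feats["top_umi"].to_numpy(dtype=np.int64)
    second = feats["second_umi"].to_numpy(dtype=np.int64)
    tie = feats["top_tie"].to_numpy()
    minchain = feats["min_chain_umi"].to_numpy()
    correct = (feats["top_feature"].to_numpy()
               == sub["ct_id"].map(expected).to_numpy()) & ~tie

    rows = []
    best = None
    best_key = None
    for u, r, c in points:
        frac = _ratio_fraction(r)
        mask = ((top >= u)
                & (top * frac.denominator >= frac.numerator * second)
                & ~tie & (minchain >= c))
        n_ret = int(mask.sum())
        n_cor = int((mask & correct).sum())
        acc = n_cor / n_ret if n_ret else np.nan
        rows.append({"umi_min_pmhc": u, "ratio_min": r, "umi_min_tcr": c,
                     "n_retained": n_ret, "n_correct": n_cor, "accuracy": acc})
        if n_ret:
            key = (-acc, -n_ret, u, r, c)
            if best_key is None or key < best_key:
                best_key = key
                best = (u, r, c)
    trace = pd.DataFrame(rows)
    if best is None:
        raise ConfigError("no grid point retains any annotated GEM")
    result = ThresholdSet(*best)
    logger.info("grid search over %d points: optimum %s (accuracy %.4f)",
                len(points), result, -best_key[0])
    return result, trace


class UmiThresholdFilter(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: ``fit`` learns (or accepts) the UMI thresholds,
    ``transform`` applies them globally and assigns each surviving GEM its
    top-UMI pMHC.

    Parameters
    ----------
    thresholds : ThresholdSet or (int, float, int) tuple, optional
        Fixed thresholds; when given, ``fit`` performs no search.
    grid : dict, optional
        Overrides for the default search grid (keys ``umi_min_pmhc``,
        ``ratio_min``, ``umi_min_tcr``).
    min_gems, alpha, zero_fill
        Forwarded to the internal ExpectedBinderAnnotator when ``fit`` is not
        given pre-computed annotations.
    exempt_imputed : bool, default False
        Whether imputed chains (UMI recorded as 0) are exempt from the TCR
        chain cutoff.
    """

    def __init__(self, thresholds=None, grid=None, min_gems: int = 10,
                 alpha: float = 0.05, zero_fill: bool = True,
                 exempt_imputed: bool = False):
        self.thresholds = thresholds
        self.grid = grid
        self.min_gems = min_gems
        self.alpha = alpha
        self.zero_fill = zero_fill
        self.exempt_imputed = exempt_imputed

    def fit(self, X: pd.DataFrame, y=None, annotations=None):
        if self.thresholds is not None:
            t = self.thresholds
            self.thresholds_ = t if isinstance(t, ThresholdSet) else ThresholdSet(*t)
            self.trace_ = None
            return self
        if annotations is None:
            annotations = ExpectedBinderAnnotator(
                min_gems=self.min_gems, alpha=self.alpha,
                zero_fill=self.zero_fill).fit(X).annotations_
        self.thresholds_, self.trace_ = grid_search_thresholds(
            X, annotations, grid=self.grid, exempt_imputed=self.exempt_imputed)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise AttributeError("UmiThresholdFilter is not fitted")
        return apply_thresholds(X, self.thresholds_, self.exempt_imputed)
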
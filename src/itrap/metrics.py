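"""Benchmark metrics for a filter state: GEM retention, accuracy, binding
concordance, intra/inter kernel-similarity AUC, and the low-concordance
outlier classification.

Binding concordance of a (clonotype, pMHC) pair is the fraction of the
clonotype's GEMs assigned to that pMHC.  The similarity AUC quantifies how
well TCRs annotated to the same pMHC ("intra-specificity") can be separated
from TCRs of different specificities by the CDR3 alpha+beta kernel
similarity; scores live in [0, 2] and the AUC is reported on a 0-100 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .alleles import canonicalize_allele
from .binders import BinderAnnotation, compute_accuracy, top_capture
from .errors import ConfigError
from .kernel import DEFAULT_BETA, DEFAULT_K, paired_similarity

logger = logging.getLogger("itrap")


def ensure_assigned(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``assigned_pmhc`` set to the top-UMI capture where
    missing (unfiltered tables); top-capture ties yield no assignment."""
    if "assigned_pmhc" in table.columns and table["assigned_pmhc"].notna().all():
        return table
    out = table.copy()
    assigned = []
    for caps in out["captures"]:
        feat, tied = top_capture(caps)
        assigned.append(None if tied else feat)
    out["assigned_pmhc"] = assigned
    return out


def binding_concordance(table: pd.DataFrame,
                        gem_weighted: bool = True) -> tuple[pd.DataFrame, float]:
    """Per-(clonotype, pMHC) binding concordance and the dataset average in percent.

    The average is GEM-weighted by default: each GEM contributes the
    concordance of its own (clonotype, assigned pMHC) pair, so large unanimous
    clonotypes dominate.  ``gem_weighted=False`` averages the per-pair entries
    instead.
    """
    sub = table[table["ct_id"].notna() & table["assigned_pmhc"].notna()]
    if sub.empty:
        return pd.DataFrame(columns=["ct_id", "pmhc", "n_gems", "concordance"]), np.nan
    counts = (sub.groupby(["ct_id", "assigned_pmhc"]).size()
              .rename("n_gems").reset_index()
              .rename(columns={"assigned_pmhc": "pmhc"}))
    sizes = sub.groupby("ct_id").size()
    counts["concordance"] = counts["n_gems"] / counts["ct_id"].map(sizes)
    if gem_weighted:
        avg = float((counts["concordance"] * counts["n_gems"]).sum()
                    / counts["n_gems"].sum()) * 100.0
    else:
        avg = float(counts["concordance"].mean()) * 100.0
    return counts, avg


def classify_outliers(table: pd.DataFrame, concordance: pd.DataFrame,
                      annotations: list[BinderAnnotation],
                      haplotypes: dict[str, frozenset[str]] | None = None,
                      cutoff: float = 0.5) -> pd.DataFrame:
    """Categorize GEMs whose assigned-pair concordance is below ``cutoff``.

    Categories:
    - ``no_expected_binder``: the clonotype is too small / too ambiguous for
      an expected-binder call, so the assignment cannot be checked.
    - ``cross_reactivity``: the clonotype's dominant pMHC equals its expected
      binder and the expected binder is detected in the GEM at lower UMI than
      the assigned pMHC - the signature of a secondary (weaker) binding event.
    - ``dispersed_multiplet``: the clonotype binds many targets all at low
      concordance and the GEM itself carries pMHC multiplets - an ambient
      capture artifact.
    - ``other``: none of the above.

    ``hla_divergent`` flags GEMs whose assigned and expected pMHC restriction
    alleles differ.
    """
    expected = {a.ct_id: a.expected_pmhc for a in annotations
                if a.expected_pmhc is not None}
    conc = {(r.ct_id, r.pmhc): r.concordance for r in concordance.itertuples(index=False)}
    dominant = {}
    dispersed = {}
    for ct_id, grp in concordance.groupby("ct_id"):
        best = grp.sort_values(["concordance", "pmhc"], ascending=[False, True]).iloc[0]
        dominant[ct_id] = best["pmhc"]
        dispersed[ct_id] = bool((grp["concordance"] < cutoff).all() and len(grp) >= 3)

    rows = []
    for _, row in table.iterrows():
        pair = (row["ct_id"], row["assigned_pmhc"])
        c = conc.get(pair)
        if c is None or c >= cutoff:
            continue
        ct_id = row["ct_id"]
        exp = expected.get(ct_id)
        caps = {cap["feature_id"]: cap for cap in row["captures"]}
        if exp is None:
            category = "no_expected_binder"
        elif (dominant.get(ct_id) == exp and exp in caps
              and caps[exp]["umi"] < caps[row["assigned_pmhc"]]["umi"]):
            category = "cross_reactivity"
        elif dispersed.get(ct_id, False) and len(caps) >= 2:
            category = "dispersed_multiplet"
        else:
            category = "other"
        hla_divergent = False
        if exp is not None and exp in caps and row["assigned_pmhc"] in caps:
            hla_divergent = (canonicalize_allele(caps[exp]["hla_allele"])
                             != canonicalize_allele(caps[row["assigned_pmhc"]]["hla_allele"]))
        rows.append({"barcode_full": row["barcode_full"], "ct_id": ct_id,
                     "assigned_pmhc": row["assigned_pmhc"], "concordance": c,
                     "category": category, "hla_divergent": hla_divergent})
    return pd.DataFrame(rows, columns=["barcode_full", "ct_id", "assigned_pmhc",
                                       "concordance", "category", "hla_divergent"])


@dataclass
class SimilarityScores:
    """Per-clonotype maximal intra- and inter-specificity similarity scores."""

    intra: list = field(default_factory=list)
    inter: list = field(default_factory=list)
    seed: int = 0
    auc_pct: float = np.nan


def clonotype_specificities(table: pd.DataFrame) -> pd.DataFrame:
    """One row per paired-chain clonotype with its dominant assigned pMHC."""
    sub = table[table["ct_id"].notna() & table["assigned_pmhc"].notna()
                & table["cdr3_a"].notna() & table["cdr3_b"].notna()]
    if sub.empty:
        return pd.DataFrame(columns=["ct_id", "cdr3_a", "cdr3_b", "specificity"])
    rows = []
    for ct_id, grp in sub.groupby("ct_id"):
        counts = grp["assigned_pmhc"].value_counts()
        top_n = counts.max()
        spec = sorted(counts[counts == top_n].index)[0]
        rows.append({"ct_id": ct_id, "cdr3_a": grp["cdr3_a"].iloc[0],
                     "cdr3_b": grp["cdr3_b"].iloc[0], "specificity": spec})
    return pd.DataFrame(rows)


def intra_inter_scores(clonotypes: pd.DataFrame, seed: int = 0,
                       k_lengths=DEFAULT_K, beta: float = DEFAULT_BETA) -> SimilarityScores:
    """Maximal intra- and inter-specificity similarity per eligible clonotype.

    Clonotypes sharing a specificity form a "plateau".  For each clonotype in
    a plateau of size >= 2, the intra score is the maximum paired similarity
    against the other plateau members, and the inter score the maximum against
    an equally sized seeded random sample (without replacement, capped at
    availability) of clonotypes from other plateaus.
    """
    rng = np.random.default_rng(seed)
    scores = SimilarityScores(seed=seed)
    recs = clonotypes.sort_values("ct_id").reset_index(drop=True)
    tcrs = list(zip(recs["cdr3_a"], recs["cdr3_b"]))
    specs = recs["specificity"].to_numpy()
    for i in range(len(recs)):
        mates = [j for j in range(len(recs)) if specs[j] == specs[i] and j != i]
        if not mates:
            logger.debug("clonotype %s skipped: singleton plateau", recs["ct_id"][i])
            continue
        others = np.flatnonzero(specs != specs[i])
        if len(others) == 0:
            continue
        sample = rng.choice(others, size=min(len(mates), len(others)), replace=False)
        scores.intra.append(max(paired_similarity(tcrs[i], tcrs[j], k_lengths, beta)
                                for j in mates))
        scores.inter.append(max(paired_similarity(tcrs[i], tcrs[j], k_lengths, beta)
                                for j in sample))
    if scores.intra and scores.inter:
        scores.auc_pct = similarity_auc(scores)
    return scores


def similarity_auc(scores: SimilarityScores) -> float:
    """Tie-corrected rank AUC of intra vs inter scores, on a 0-100 scale."""
    if not scores.intra or not scores.inter:
        raise ConfigError("similarity AUC requires non-empty intra and inter lists")
    y = np.concatenate([np.ones(len(scores.intra)), np.zeros(len(scores.inter))])
    s = np.concatenate([scores.intra, scores.inter])
    return float(roc_auc_score(y, s)) * 100.0


@dataclass
class MetricsReport:
    """The four benchmark metrics for one filter state."""

    name: str
    n_gems: int
    n_clonotypes: int
    retention_pct: float
    accuracy_pct: float | None
    avg_concordance_pct: float
    similarity_auc_pct: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "name": self.name, "n_gems": self.n_gems,
            "n_clonotypes": self.n_clonotypes,
            "retention_pct": self.retention_pct,
            "accuracy_pct": self.accuracy_pct,
            "avg_concordance_pct": self.avg_concordance_pct,
            "similarity_auc_pct": self.similarity_auc_pct,
            "seed": self.seed,
        }


def metrics_report(table: pd.DataFrame, raw_n_gems: int,
                   annotations: list[BinderAnnotation], seed: int = 0,
                   name: str = "state", k_lengths=DEFAULT_K,
                   beta: float = DEFAULT_BETA) -> MetricsReport:
    """Compute retention, accuracy, average concordance and similarity AUC for
    a (possibly filtered) clonotyped table.

    ``raw_n_gems`` is the GEM count of the parent raw table the retention is
    measured against; ``annotations`` are the expected-binder calls the
    accuracy is judged by.
    """
    assigned = ensure_assigned(table)
    acc, _ = compute_accuracy(assigned, annotations)
    _, avg_conc = binding_concordance(assigned)
    plateaus = clonotype_specificities(assigned)
    scores = intra_inter_scores(plateaus, seed=seed, k_lengths=k_lengths, beta=beta)
    return MetricsReport(
        name=name,
        n_gems=len(table),
        n_clonotypes=int(table["ct_id"].nunique()) if "ct_id" in table.columns else 0,
        retention_pct=100.0 * len(table) / raw_n_gems if raw_n_gems else np.nan,
        accuracy_pct=None if acc is None else 100.0 * acc,
        avg_concordance_pct=avg_conc,
        similarity_auc_pct=scores.auc_pct,
        seed=seed,
    )
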
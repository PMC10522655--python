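"""Composable specificity filters: HLA-haplotype match, paired-chain
requirement, specificity-singlet removal and the platform's is_cell call.

Each filter is available both as a plain function on the canonical GEM table
and as a stateless sklearn transformer, so the whole cascade composes into a
Pipeline.  The default order mirrors the filter cascade: thresholds -> HLA ->
paired chains -> singlets -> is_cell; the recommended minimum is thresholds +
HLA match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .alleles import canonicalize_allele
from .errors import DataFormatError

logger = logging.getLogger("itrap")


@dataclass
class FilterState:
    """Bookkeeping of one filter application."""

    name: str
    gems_in: int
    gems_out: int
    clonotypes_out: int
    removed_by_reason: dict = field(default_factory=dict)


def _assigned_allele(row) -> str | None:
    """Canonical HLA allele of the GEM's assigned pMHC, from its own captures."""
    for cap in row["captures"]:
        if cap["feature_id"] == row["assigned_pmhc"]:
            return canonicalize_allele(cap["hla_allele"])
    return None


def filter_hla_match(table: pd.DataFrame,
                     haplotypes: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Keep GEMs whose assigned pMHC's restricting allele is carried by the
    donor (thymic-restriction check)."""
    missing = sorted(set(table["donor"]) - set(haplotypes))
    if missing:
        raise DataFormatError(
            f"no HLA haplotype for donor(s): {', '.join(missing)}")
    keep = []
    for _, row in table.iterrows():
        allele = _assigned_allele(row)
        keep.append(allele is not None and allele in haplotypes[row["donor"]])
    out = table[pd.Series(keep, index=table.index)].reset_index(drop=True)
    logger.info("HLA match filter: %d -> %d GEMs", len(table), len(out))
    return out


def filter_paired_chains(table: pd.DataFrame) -> pd.DataFrame:
    """Keep GEMs with exactly one selected alpha and one selected beta chain."""
    keep = table["cdr3_a"].notna() & table["cdr3_b"].notna()
    out = table[keep].reset_index(drop=True)
    logger.info("paired-chain filter: %d -> %d GEMs", len(table), len(out))
    return out


def filter_specificity_singlets(table: pd.DataFrame) -> pd.DataFrame:
    """Remove TCR-pMHC pairs supported by a single GEM.

    A (clonotype, assigned pMHC) pair seen only once is too susceptible to
    artifacts; pairs seen in two or more GEMs are kept.
    """
    counts = table.groupby(["ct_id", "assigned_pmhc"])["barcode_full"].transform("size")
    out = table[counts >= 2].reset_index(drop=True)
    logger.info("specificity-singlet filter: %d -> %d GEMs", len(table), len(out))
    return out


def filter_is_cell(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only barcodes the platform called as cells."""
    out = table[table["is_cell"].astype(bool)].reset_index(drop=True)
    logger.info("is_cell filter: %d -> %d GEMs", len(table), len(out))
    return out


def filter_state(name: str, table_in: pd.DataFrame,
                 table_out: pd.DataFrame) -> FilterState:
    n_ct = int(table_out["ct_id"].nunique()) if "ct_id" in table_out.columns else 0
    return FilterState(name=name, gems_in=len(table_in), gems_out=len(table_out),
                       clonotypes_out=n_ct,
                       removed_by_reason={name: len(table_in) - len(table_out)})


class _StatelessFilter(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self


class HlaMatchFilter(_StatelessFilter):
    """Transformer form of :func:`filter_hla_match`."""

    def __init__(self, haplotypes: dict[str, frozenset[str]] | None = None):
        self.haplotypes = haplotypes

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.haplotypes is None:
            raise DataFormatError("HlaMatchFilter requires a haplotype table")
        return filter_hla_match(X, self.haplotypes)


class PairedChainFilter(_StatelessFilter):
    """Transformer form of :func:`filter_paired_chains`."""

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_paired_chains(X)


class SpecificitySingletFilter(_StatelessFilter):
    """Transformer form of :func:`filter_specificity_singlets`."""

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_specificity_singlets(X)


class IsCellFilter(_StatelessFilter):
    """Transformer form of :func:`filter_is_cell`."""

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_is_cell(X)


FILTER_ORDER = ("threshold", "hla", "paired", "singlet", "is_cell")
RECOMMENDED_STEPS = ("threshold", "hla")
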
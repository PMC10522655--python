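"""Reading, curation and merging of the three input tables into the canonical GEM table.

A GEM (gel-bead in emulsion) is one droplet of the single-cell platform; the
canonical table has one row per GEM and carries its TCR chain annotations and
its pMHC capture counts.  Chain and capture records are held as lists of plain
dicts in object columns:

``chains``   : {chain_type, v_gene, j_gene, cdr3_aa, umi, productive, full_length}
``captures`` : {feature_id, peptide, hla_allele, umi, is_negative_control}

After clonotyping the table additionally carries the flat selected-chain
columns (``cdr3_a, v_a, j_a, umi_a, imputed_a`` and the beta equivalents),
``ct_id``, ``extra_chains`` and eventually ``assigned_pmhc``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .alleles import allele_set, canonicalize_allele
from .errors import DataFormatError, IntegrityError

logger = logging.getLogger("itrap")

IUPAC_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CONTIG_COLUMNS = [
    "barcode", "is_cell", "chain", "v_gene", "j_gene", "cdr3",
    "umis", "productive", "full_length",
]

_BARCODE_RE = re.compile(r"^([ACGT]{16})(?:-(\d+))?")


def _parse_bool(value, column: str, line: int):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "t", "1"):
        return True
    if s in ("false", "f", "0", "none", "nan", ""):
        return False
    raise DataFormatError(f"unparseable boolean {value!r} in column {column} (line {line})")


def read_contig_annotations(path) -> pd.DataFrame:
    """Read a Cellranger-style VDJ contig annotation CSV into tidy chain rows.

    Returns a DataFrame with one row per TRA/TRB contig:
    ``barcode, is_cell, chain_type, v_gene, j_gene, cdr3_aa, umi, productive,
    full_length``.  Contigs of other chains (Multi, IGH, ...) are dropped and
    counted in the log.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"contig file {path} is missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("contig file %s contains no data rows", path)
        return pd.DataFrame(columns=[
            "barcode", "is_cell", "chain_type", "v_gene", "j_gene",
            "cdr3_aa", "umi", "productive", "full_length",
        ])
    rows = []
    n_dropped = 0
    for i, rec in enumerate(df.to_dict("records"), start=2):
        chain = str(rec["chain"]).strip()
        if chain == "TRA":
            chain_type = "alpha"
        elif chain == "TRB":
            chain_type = "beta"
        else:
            n_dropped += 1
            continue
        try:
            umi = int(rec["umis"])
        except (TypeError, ValueError):
            raise DataFormatError(f"unparseable UMI count {rec['umis']!r} on line {i} of {path}")
        rows.append({
            "barcode": rec["barcode"],
            "is_cell": _parse_bool(rec["is_cell"], "is_cell", i),
            "chain_type": chain_type,
            "v_gene": rec["v_gene"],
            "j_gene": rec["j_gene"],
            "cdr3_aa": "" if pd.isna(rec["cdr3"]) else str(rec["cdr3"]),
            "umi": umi,
            "productive": _parse_bool(rec["productive"], "productive", i),
            "full_length": _parse_bool(rec["full_length"], "full_length", i),
        })
    if n_dropped:
        logger.info("dropped %d non-TRA/TRB contigs from %s", n_dropped, path)
    return pd.DataFrame(rows)


def read_panel(path) -> pd.DataFrame:
    """Read the pMHC panel CSV: ``feature_id,peptide,hla_allele,is_negative_control``."""
    df = pd.read_csv(path, dtype=str)
    need = ["feature_id", "peptide", "hla_allele", "is_negative_control"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise DataFormatError(f"panel file {path} is missing column(s): {', '.join(missing)}")
    df = df[need].copy()
    df["hla_allele"] = df["hla_allele"].map(canonicalize_allele)
    df["is_negative_control"] = [
        _parse_bool(v, "is_negative_control", i + 2)
        for i, v in enumerate(df["is_negative_control"])
    ]
    return df


def read_hla_haplotypes(path) -> dict[str, frozenset[str]]:
    """Read the long-format donor haplotype CSV ``donor_id,allele``."""
    df = pd.read_csv(path, dtype=str)
    if "donor_id" not in df.columns or "allele" not in df.columns:
        raise DataFormatError(f"HLA file {path} must have columns donor_id,allele")
    out = {}
    for donor, grp in df.groupby("donor_id"):
        out[str(donor)] = allele_set(grp["allele"])
        if not out[str(donor)]:
            raise DataFormatError(f"donor {donor} has an empty haplotype")
    return out


def read_pmhc_counts(path, panel: pd.DataFrame, features_path=None,
                     barcodes_path=None) -> pd.DataFrame:
    """Read pMHC UMI counts into tidy captures ``barcode, feature_id, peptide,
    hla_allele, umi, is_negative_control``.

    ``path`` is either a wide CSV (rows = barcodes, columns = feature ids)
    or a MatrixMarket triplet (rows = features, columns = barcodes) with
    accompanying one-column ``features_path`` / ``barcodes_path`` lists.
    Zero counts are suppressed; every feature id must exist in the panel.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if features_path is None or barcodes_path is None:
            raise DataFormatError("MTX input requires features and barcodes lists")
        mat = scipy.io.mmread(str(path)).tocoo()
        features = pd.read_csv(features_path, header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(barcodes_path, header=None)[0].astype(str).tolist()
        if mat.shape[0] != len(features) or mat.shape[1] != len(barcodes):
            raise DataFormatError(
                f"MTX shape {mat.shape} does not match {len(features)} features "
                f"x {len(barcodes)} barcodes")
        wide = pd.DataFrame.sparse.from_spmatrix(
            mat.T.tocsr(), index=barcodes, columns=features
        ).sparse.to_dense()
    else:
        wide = pd.read_csv(path, index_col=0)
    unknown = sorted(set(wide.columns) - set(panel["feature_id"]))
    if unknown:
        raise DataFormatError(f"feature id(s) not in panel: {', '.join(unknown)}")
    if (wide.to_numpy() < 0).any():
        raise DataFormatError(f"negative count in pMHC matrix {path}")
    info = panel.set_index("feature_id")
    long = wide.stack()
    long = long[long > 0]
    if long.empty:
        return pd.DataFrame(columns=[
            "barcode", "feature_id", "peptide", "hla_allele", "umi",
            "is_negative_control",
        ])
    out = long.rename("umi").reset_index()
    out.columns = ["barcode", "feature_id", "umi"]
    out["umi"] = out["umi"].astype(int)
    out["peptide"] = info.loc[out["feature_id"], "peptide"].to_numpy()
    out["hla_allele"] = info.loc[out["feature_id"], "hla_allele"].to_numpy()
    out["is_negative_control"] = info.loc[out["feature_id"], "is_negative_control"].to_numpy()
    return out[["barcode", "feature_id", "peptide", "hla_allele", "umi",
                "is_negative_control"]]


def split_barcode(barcode: str) -> tuple[str, str]:
    """Split a raw barcode into (16-nt core, well suffix; default '1')."""
    m = _BARCODE_RE.match(str(barcode))
    if not m:
        raise DataFormatError(f"barcode {barcode!r} does not start with a 16-nt ACGT core")
    core, well = m.groups()
    return core, well or "1"


def assemble_gem_table(chains: pd.DataFrame, captures: pd.DataFrame,
                       donor_id: str) -> pd.DataFrame:
    """Merge tidy chain and capture rows from one donor run into the canonical
    GEM table.

    Only barcodes carrying at least one TCR chain AND at least one pMHC
    capture are retained.  ``barcode_full = <core>-<well>-<donor_id>``, which
    keeps barcodes unique when runs from several donors are concatenated.
    """
    chain_cols = ["chain_type", "v_gene", "j_gene", "cdr3_aa", "umi",
                  "productive", "full_length"]
    cap_cols = ["feature_id", "peptide", "hla_allele", "umi", "is_negative_control"]

    chain_groups: dict[str, list[dict]] = {}
    cell_flag: dict[str, bool] = {}
    if len(chains):
        for bc, grp in chains.groupby("barcode", sort=False):
            chain_groups[bc] = grp[chain_cols].to_dict("records")
            cell_flag[bc] = bool(grp["is_cell"].any())
    cap_groups: dict[str, list[dict]] = {}
    if len(captures):
        for bc, grp in captures.groupby("barcode", sort=False):
            cap_groups[bc] = grp[cap_cols].to_dict("records")

    rows = []
    for bc in chain_groups:
        if bc not in cap_groups:
            continue
        core, well = split_barcode(bc)
        rows.append({
            "barcode_full": f"{core}-{well}-{donor_id}",
            "barcode_core": core,
            "donor": donor_id,
            "is_cell": cell_flag[bc],
            "chains": chain_groups[bc],
            "captures": cap_groups[bc],
        })
    table = pd.DataFrame(rows, columns=[
        "barcode_full", "barcode_core", "donor", "is_cell", "chains", "captures",
    ])
    if table["barcode_full"].duplicated().any():
        dup = table.loc[table["barcode_full"].duplicated(), "barcode_full"].iloc[0]
        raise IntegrityError(f"duplicate barcode {dup} within run {donor_id}")
    logger.info("assembled %d GEMs for donor %s (%d barcodes with chains, %d with captures)",
                len(table), donor_id, len(chain_groups), len(cap_groups))
    return table


def concat_runs(tables) -> pd.DataFrame:
    """Concatenate per-donor GEM tables into one combined table."""
    table = pd.concat(list(tables), ignore_index=True)
    if table["barcode_full"].duplicated().any():
        dup = table.loc[table["barcode_full"].duplicated(), "barcode_full"].iloc[0]
        raise IntegrityError(f"duplicate barcode across runs: {dup}")
    return table


def _chain_valid(chain: dict) -> str | None:
    """Return the removal reason for a chain, or None if it passes curation."""
    if not chain["productive"]:
        return "not_productive"
    if not chain["full_length"]:
        return "not_full_length"
    cdr3 = chain["cdr3_aa"]
    if not cdr3 or any(c not in IUPAC_AA for c in cdr3):
        return "non_iupac"
    return None


def curate_gems(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop chains that are unproductive, not full length or contain non-IUPAC
    residues; remove GEMs in which no chain survives.

    Returns the curated table and a tally of removals by reason (chain-level
    reasons plus ``gems_removed``).
    """
    tally: dict[str, int] = {"not_productive": 0, "not_full_length": 0,
                             "non_iupac": 0, "gems_removed": 0}
    new_chains = []
    keep = []
    for chains in table["chains"]:
        surviving = []
        for ch in chains:
            reason = _chain_valid(ch)
            if reason is None:
                surviving.append(ch)
            else:
                tally[reason] += 1
        new_chains.append(surviving)
        keep.append(bool(surviving))
    out = table.copy()
    out["chains"] = new_chains
    tally["gems_removed"] = int(len(keep) - sum(keep))
    out = out[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    logger.info("curation removed %d GEMs (%s)", tally["gems_removed"],
                ", ".join(f"{k}={v}" for k, v in tally.items() if k != "gems_removed"))
    return out, tally


# --- canonical CSV round trip -------------------------------------------------

_FLAT_COLS = ["ct_id", "cdr3_a", "v_a", "j_a", "umi_a", "imputed_a",
              "cdr3_b", "v_b", "j_b", "umi_b", "imputed_b", "assigned_pmhc"]


def write_gem_table(table: pd.DataFrame, path) -> None:
    """Write the canonical GEM table to CSV, serializing list columns as JSON."""
    out = table.copy()
    for col, json_col in (("captures", "pmhc_json"), ("chains", "chains_json"),
                          ("extra_chains", "extra_chains_json")):
        if col in out.columns:
            out[json_col] = [json.dumps(v) if isinstance(v, list) else ""
                             for v in out[col]]
            out = out.drop(columns=[col])
    out.to_csv(path, index=False)


def read_gem_table(path) -> pd.DataFrame:
    """Read a canonical GEM table CSV written by :func:`write_gem_table`."""
    df = pd.read_csv(path, dtype={"barcode_full": str, "barcode_core": str,
                                  "donor": str})
    for json_col, col in (("pmhc_json", "captures"), ("chains_json", "chains"),
                          ("extra_chains_json", "extra_chains")):
        if json_col in df.columns:
            df[col] = [json.loads(v) if isinstance(v, str) and v else []
                       for v in df[json_col]]
            df = df.drop(columns=[json_col])
    if "is_cell" in df.columns:
        df["is_cell"] = df["is_cell"].astype(bool)
    for col in ("imputed_a", "imputed_b"):
        if col in df.columns:
            df[col] = df[col].fillna(False).astype(bool)
    return df


# --- cross-dataset barcode alignment -----------------------------------------

def align_external_annotations(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Align two GEM tables that may use different barcode suffix dialects.

    Pass 1 matches on the full barcode; records left unmatched are matched in
    pass 2 on the (16-nt core, donor) pair.  A core matching more than one
    counterpart barcode within the same donor is reported as ambiguous rather
    than matched.

    Returns ``{"matches": [(bc_a, bc_b), ...], "pass1": n, "pass2": n,
    "ambiguous": [...]}``.
    """
    a = table_a[["barcode_full", "barcode_core", "donor"]]
    b = table_b[["barcode_full", "barcode_core", "donor"]]
    b_full = set(b["barcode_full"])
    matches = []
    pass1 = []
    for bc in a["barcode_full"]:
        if bc in b_full:
            pass1.append(bc)
    matched_a = set(pass1)
    matches = [(bc, bc) for bc in sorted(pass1)]

    rest_a = a[~a["barcode_full"].isin(matched_a)]
    rest_b = b[~b["barcode_full"].isin(matched_a)]
    b_by_key: dict[tuple, list[str]] = {}
    for bc, core, donor in rest_b.itertuples(index=False):
        b_by_key.setdefault((core, donor), []).append(bc)
    a_by_key: dict[tuple, list[str]] = {}
    for bc, core, donor in rest_a.itertuples(index=False):
        a_by_key.setdefault((core, donor), []).append(bc)

    pass2 = 0
    ambiguous = []
    for key, bcs_a in sorted(a_by_key.items()):
        bcs_b = b_by_key.get(key, [])
        if not bcs_b:
            continue
        if len(bcs_a) > 1 or len(bcs_b) > 1:
            ambiguous.append({"barcode_core": key[0], "donor": key[1],
                              "a": sorted(bcs_a), "b": sorted(bcs_b)})
            continue
        matches.append((bcs_a[0], bcs_b[0]))
        pass2 += 1
    return {"matches": matches, "pass1": len(pass1), "pass2": pass2,
            "ambiguous": ambiguous}
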
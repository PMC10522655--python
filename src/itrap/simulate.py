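"""Synthetic GEM simulator with known ground truth.

Emulates the phenomenology of single-cell immune profiling that the denoiser
has to cope with: clonally expanded T cells with one true cognate pMHC each
(restricted to an allele of the donor's haplotype), ambient pMHC captures at
low UMI drawn panel-wide, TCR chain dropout and spurious chain multiplets,
platform non-cell barcodes, and per-specificity CDR3 sequence motifs so that
TCRs sharing a cognate pMHC are mutually more similar than TCRs of different
specificities.

UMI counts are negative binomial (mean/shape parametrization); a zero draw
means the capture is simply not emitted.  Clonotype sizes follow a truncated
zipf law, mirroring the heavy-tailed clonal expansion of real repertoires.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError

logger = logging.getLogger("itrap")

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    The UMI defaults (signal NB mean 15, noise NB mean 2, ambient rate 3,
    chain dropout 0.1, 500 clonotypes) are the reference conditions used for
    recovery benchmarking throughout the test suite.
    """

    n_donors: int = 4
    alleles_per_donor: int = 6          # two each of HLA-A, -B, -C
    n_pmhc: int = 20
    n_negative_controls: int = 2
    n_clonotypes: int = 500
    size_zipf_a: float = 2.0            # clonotype size ~ zipf, truncated
    size_max: int = 80
    signal_umi_mean: float = 15.0
    signal_umi_shape: float = 5.0
    noise_umi_mean: float = 2.0
    noise_umi_shape: float = 2.0
    ambient_rate: float = 3.0           # Poisson noise features per GEM
    chain_dropout_prob: float = 0.1
    chain_multiplet_prob: float = 0.05
    tcr_umi_mean: float = 4.0
    tcr_umi_shape: float = 2.0
    motif_length: int = 5
    non_cell_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (self.noise_umi_mean < self.signal_umi_mean):
            raise ConfigError("noise UMI mean must be below the signal UMI mean")
        for p in (self.chain_dropout_prob, self.chain_multiplet_prob,
                  self.non_cell_rate):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_pmhc < 2 or self.n_clonotypes < 1 or self.n_donors < 1:
            raise ConfigError("need at least 2 pMHCs, 1 clonotype and 1 donor")
        if self.motif_length + 4 > 10:
            raise ConfigError("motif_length too long for a 10-residue CDR3")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _nb_counts(rng, mean, shape, size):
    """Negative binomial draws (mean/shape); zeros mean 'not emitted'."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def _random_seq(rng, length):
    return "".join(rng.choice(list(_AA), size=length))


def _cdr3(rng, motif: str) -> str:
    """Random CDR3 of length 10-18 with the specificity motif embedded."""
    length = int(rng.integers(10, 19))
    inner = length - 2 - len(motif)
    left = int(rng.integers(0, inner + 1))
    return ("C" + _random_seq(rng, left) + motif
            + _random_seq(rng, inner - left) + "F")


def _allele_catalogue():
    return ([f"A*{i:02d}:01" for i in range(1, 9)]
            + [f"B*{i:02d}:01" for i in range(1, 9)]
            + [f"C*{i:02d}:01" for i in range(1, 9)])


def simulate_dataset(config: SimConfig | None = None,
                     **overrides) -> tuple[pd.DataFrame, dict]:
    """Draw a canonical GEM table plus its ground truth.

    Returns ``(table, truth)`` where the table is in the assembled canonical
    format (``barcode_full, barcode_core, donor, is_cell, chains, captures``)
    and ``truth`` holds:

    - ``gems``: DataFrame per simulated GEM (``barcode_full, true_ct,
      true_pmhc, n_noise, dropped_chain, has_multiplet, emitted``); GEMs whose
      captures all drew zero are flagged ``emitted=False`` and are absent from
      the table.
    - ``clonotypes``: DataFrame per clonotype (identity, donor, cognate).
    - ``panel``, ``haplotypes``: the pMHC panel and donor -> allele sets.
    """
    config = (config or SimConfig()).replace(**overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    catalogue = _allele_catalogue()
    haplotypes = {}
    for d in range(1, config.n_donors + 1):
        alleles = []
        per_locus = max(1, config.alleles_per_donor // 3)
        for locus in ("A", "B", "C"):
            pool = [a for a in catalogue if a.startswith(locus)]
            alleles += list(rng.choice(pool, size=per_locus, replace=False))
        haplotypes[f"d{d}"] = frozenset(alleles)
    union = sorted(set().union(*haplotypes.values()))

    # pMHC panel: positive features restricted to alleles some donor carries
    panel_rows = []
    for i in range(config.n_pmhc):
        panel_rows.append({
            "feature_id": f"pMHC_{i:03d}",
            "peptide": _random_seq(rng, 9),
            "hla_allele": str(rng.choice(union)),
            "is_negative_control": False,
        })
    for i in range(config.n_negative_controls):
        panel_rows.append({
            "feature_id": f"ctrl_{i:02d}",
            "peptide": _random_seq(rng, 9),
            "hla_allele": str(rng.choice(catalogue)),
            "is_negative_control": True,
        })
    panel = pd.DataFrame(panel_rows)
    positives = panel[~panel["is_negative_control"]]

    motifs = {f: (_random_seq(rng, config.motif_length),
                  _random_seq(rng, config.motif_length))
              for f in positives["feature_id"]}
    v_a = [f"TRAV{i}" for i in range(1, 21)]
    j_a = [f"TRAJ{i}" for i in range(1, 11)]
    v_b = [f"TRBV{i}" for i in range(1, 21)]
    j_b = [f"TRBJ{i}" for i in range(1, 11)]

    donors_by_allele = {a: [d for d, hs in haplotypes.items() if a in hs]
                        for a in union}
    ct_rows = []
    for c in range(config.n_clonotypes):
        feat = positives.iloc[int(rng.integers(len(positives)))]
        donor = str(rng.choice(donors_by_allele[feat["hla_allele"]]))
        ma, mb = motifs[feat["feature_id"]]
        size = int(min(rng.zipf(config.size_zipf_a), config.size_max))
        ct_rows.append({
            "sim_ct": f"sim{c:05d}", "donor": donor,
            "true_pmhc": feat["feature_id"],
            "v_a": str(rng.choice(v_a)), "j_a": str(rng.choice(j_a)),
            "cdr3_a": _cdr3(rng, ma),
            "v_b": str(rng.choice(v_b)), "j_b": str(rng.choice(j_b)),
            "cdr3_b": _cdr3(rng, mb),
            "size": size,
        })
    clonotypes = pd.DataFrame(ct_rows)

    n_gems = int(clonotypes["size"].sum())
    cores = set()
    while len(cores) < n_gems:
        cores.update("".join(s) for s in
                     rng.choice(list("ACGT"), size=(n_gems - len(cores), 16)))
    cores = sorted(cores)
    rng.shuffle(cores)

    feature_info = panel.set_index("feature_id").to_dict("index")
    all_features = panel["feature_id"].tolist()
    table_rows, truth_rows = [], []
    g = 0
    for ct in clonotypes.itertuples(index=False):
        for _ in range(ct.size):
            core = cores[g]
            g += 1
            barcode_full = f"{core}-1-{ct.donor}"
            captures = []
            signal_umi = int(_nb_counts(rng, config.signal_umi_mean,
                                        config.signal_umi_shape, 1)[0])
            if signal_umi >= 1:
                info = feature_info[ct.true_pmhc]
                captures.append({"feature_id": ct.true_pmhc,
                                 "peptide": info["peptide"],
                                 "hla_allele": info["hla_allele"],
                                 "umi": signal_umi,
                                 "is_negative_control": False})
            n_noise_draw = int(rng.poisson(config.ambient_rate))
            noise_pool = [f for f in all_features if f != ct.true_pmhc]
            n_noise_draw = min(n_noise_draw, len(noise_pool))
            noise_feats = rng.choice(noise_pool, size=n_noise_draw, replace=False)
            n_noise = 0
            for f in noise_feats:
                u = int(_nb_counts(rng, config.noise_umi_mean,
                                   config.noise_umi_shape, 1)[0])
                if u >= 1:
                    info = feature_info[f]
                    captures.append({"feature_id": str(f),
                                     "peptide": info["peptide"],
                                     "hla_allele": info["hla_allele"],
                                     "umi": u,
                                     "is_negative_control": bool(info["is_negative_control"])})
                    n_noise += 1

            chains = []
            for ctype, v, j, cdr3 in (("alpha", ct.v_a, ct.j_a, ct.cdr3_a),
                                      ("beta", ct.v_b, ct.j_b, ct.cdr3_b)):
                umi = max(1, int(_nb_counts(rng, config.tcr_umi_mean,
                                            config.tcr_umi_shape, 1)[0]))
                chains.append({"chain_type": ctype, "v_gene": v, "j_gene": j,
                               "cdr3_aa": cdr3, "umi": umi,
                               "productive": True, "full_length": True})
            dropped = None
            if rng.random() < config.chain_dropout_prob:
                dropped = "alpha" if rng.random() < 0.5 else "beta"
                chains = [c for c in chains if c["chain_type"] != dropped]
            has_multiplet = False
            if rng.random() < config.chain_multiplet_prob:
                has_multiplet = True
                ctype = "alpha" if rng.random() < 0.5 else "beta"
                chains.append({
                    "chain_type": ctype,
                    "v_gene": str(rng.choice(v_a if ctype == "alpha" else v_b)),
                    "j_gene": str(rng.choice(j_a if ctype == "alpha" else j_b)),
                    "cdr3_aa": _cdr3(rng, _random_seq(rng, config.motif_length)),
                    "umi": 1, "productive": True, "full_length": True,
                })
            is_cell = bool(rng.random() >= config.non_cell_rate)
            emitted = bool(captures)
            truth_rows.append({"barcode_full": barcode_full, "true_ct": ct.sim_ct,
                               "true_pmhc": ct.true_pmhc, "n_noise": n_noise,
                               "dropped_chain": dropped,
                               "has_multiplet": has_multiplet, "emitted": emitted})
            if emitted:
                table_rows.append({"barcode_full": barcode_full,
                                   "barcode_core": core, "donor": ct.donor,
                                   "is_cell": is_cell, "chains": chains,
                                   "captures": captures})
    table = pd.DataFrame(table_rows, columns=[
        "barcode_full", "barcode_core", "donor", "is_cell", "chains", "captures"])
    truth = {"gems": pd.DataFrame(truth_rows), "clonotypes": clonotypes,
             "panel": panel, "haplotypes": haplotypes}
    logger.info("simulated %d GEMs (%d emitted) over %d clonotypes, %d donors",
                n_gems, len(table), config.n_clonotypes, config.n_donors)
    return table, truth


def evaluate_recovery(filtered: pd.DataFrame, truth: dict) -> dict:
    """Precision/recall of a filtered table's pMHC assignments against truth.

    precision: fraction of retained GEMs whose ``assigned_pmhc`` equals the
    true cognate.  recall: fraction of emitted truth GEMs that were retained
    with the correct assignment.  Confusion counts are broken down by the
    corruption flags of the simulator.
    """
    gems = truth["gems"]
    known = set(gems["barcode_full"])
    unknown = set(filtered["barcode_full"]) - known
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} barcodes absent from truth, e.g. {sorted(unknown)[0]}")
    tmap = gems.set_index("barcode_full")
    merged = filtered.join(tmap, on="barcode_full", rsuffix="_truth")
    correct = (merged["assigned_pmhc"] == merged["true_pmhc"])
    n_emitted = int(gems["emitted"].sum())
    confusion = {}
    for flag in ("dropped_chain", "has_multiplet"):
        grp = merged.groupby(merged[flag].notna() if flag == "dropped_chain"
                             else merged[flag].astype(bool))
        confusion[flag] = {bool(k): {"retained": int(len(v)),
                                     "correct": int(correct[v.index].sum())}
                           for k, v in grp}
    return {
        "n_retained": int(len(filtered)),
        "n_correct": int(correct.sum()),
        "precision": float(correct.mean()) if len(merged) else np.nan,
        "recall": float(correct.sum() / n_emitted) if n_emitted else np.nan,
        "confusion": confusion,
    }


# --- raw-dialect writers (for the CLI round trip) ----------------------------

def write_raw_inputs(table: pd.DataFrame, truth: dict, outdir) -> dict:
    """Emit Cellranger-dialect contig CSVs (one per donor), a wide pMHC count
    CSV per donor, plus the panel, HLA and truth CSVs.  Returns the paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"contigs": {}, "pmhc": {}}
    for donor, grp in table.groupby("donor"):
        contig_rows = []
        for _, row in grp.iterrows():
            raw_bc = f"{row['barcode_core']}-1"
            for i, ch in enumerate(row["chains"], start=1):
                contig_rows.append({
                    "barcode": raw_bc, "is_cell": row["is_cell"],
                    "contig_id": f"{raw_bc}_contig_{i}", "high_confidence": True,
                    "chain": "TRA" if ch["chain_type"] == "alpha" else "TRB",
                    "v_gene": ch["v_gene"], "d_gene": "None",
                    "j_gene": ch["j_gene"], "c_gene": "None",
                    "cdr3": ch["cdr3_aa"], "umis": ch["umi"],
                    "productive": ch["productive"],
                    "full_length": ch["full_length"],
                })
        p = outdir / f"contigs_{donor}.csv"
        pd.DataFrame(contig_rows).to_csv(p, index=False)
        paths["contigs"][donor] = p

        features = truth["panel"]["feature_id"].tolist()
        wide = pd.DataFrame(0, index=grp["barcode_core"] + "-1", columns=features)
        for bc, caps in zip(grp["barcode_core"] + "-1", grp["captures"]):
            for cap in caps:
                wide.loc[bc, cap["feature_id"]] = cap["umi"]
        p = outdir / f"pmhc_{donor}.csv"
        wide.to_csv(p)
        paths["pmhc"][donor] = p

    panel_path = outdir / "panel.csv"
    truth["panel"].to_csv(panel_path, index=False)
    hla_rows = [{"donor_id": d, "allele": a}
                for d, alleles in truth["haplotypes"].items()
                for a in sorted(alleles)]
    hla_path = outdir / "hla.csv"
    pd.DataFrame(hla_rows).to_csv(hla_path, index=False)
    truth_path = outdir / "truth.csv"
    truth["gems"].to_csv(truth_path, index=False)
    paths.update({"panel": panel_path, "hla": hla_path, "truth": truth_path})
    return paths
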
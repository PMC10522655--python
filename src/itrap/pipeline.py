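"""End-to-end orchestration: curate -> clonotype -> annotate -> thresholds ->
filters, with staged outputs and a metrics report per stage.

The composite :class:`ItrapDenoiser` is the one-stop sklearn-style surface:
``fit`` learns the clonotype catalogue, the expected binders and the UMI
thresholds from a curated GEM table; ``transform`` applies the configured
filter cascade and returns the denoised table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from . import __version__
from .binders import ExpectedBinderAnnotator
from .clonotyping import ClonotypeAssigner
from .errors import ConfigError
from .filters import (FILTER_ORDER, RECOMMENDED_STEPS, filter_hla_match,
                      filter_is_cell, filter_paired_chains,
                      filter_specificity_singlets, filter_state)
from .io import (assemble_gem_table, concat_runs, curate_gems, read_contig_annotations,
                 read_hla_haplotypes, read_panel, read_pmhc_counts, write_gem_table)
from .metrics import metrics_report
from .thresholds import UmiThresholdFilter

logger = logging.getLogger("itrap")


class ItrapDenoiser(BaseEstimator, TransformerMixin):
    """Learn and apply the full denoising cascade on a curated GEM table.

    Parameters
    ----------
    steps : sequence of {"threshold", "hla", "paired", "singlet", "is_cell"}
        Filters applied by ``transform``, always executed in the canonical
        order.  Default: the recommended minimum (threshold + HLA match).
    haplotypes : mapping donor -> set of canonical alleles
        Required when "hla" is among the steps.
    thresholds : ThresholdSet or tuple, optional
        Fixed UMI thresholds; otherwise ``fit`` grid-searches them.
    min_gems, alpha, zero_fill, exact_limit
        Expected-binder annotation parameters.
    grid, exempt_imputed, impute
        Forwarded to the threshold search / clonotyping.

    Attributes (after ``fit``)
    ----------
    clonotyper_, annotator_, threshold_filter_ : the fitted sub-estimators
    clonotyped_ : the clonotyped (unfiltered) table
    stage_states_ : list of FilterState from the last ``transform``
    """

    def __init__(self, steps=RECOMMENDED_STEPS, haplotypes=None, thresholds=None,
                 grid=None, min_gems: int = 10, alpha: float = 0.05,
                 zero_fill: bool = True, exact_limit: int = 12,
                 exempt_imputed: bool = False, impute: bool = True):
        self.steps = steps
        self.haplotypes = haplotypes
        self.thresholds = thresholds
        self.grid = grid
        self.min_gems = min_gems
        self.alpha = alpha
        self.zero_fill = zero_fill
        self.exact_limit = exact_limit
        self.exempt_imputed = exempt_imputed
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None):
        unknown = set(self.steps) - set(FILTER_ORDER)
        if unknown:
            raise ConfigError(f"unknown filter step(s): {', '.join(sorted(unknown))}")
        if "hla" in self.steps and self.haplotypes is None:
            raise ConfigError("the 'hla' step requires a haplotype table")
        self.clonotyper_ = ClonotypeAssigner(impute=self.impute)
        self.clonotyped_ = self.clonotyper_.fit_transform(X)
        self.annotator_ = ExpectedBinderAnnotator(
            min_gems=self.min_gems, alpha=self.alpha, zero_fill=self.zero_fill,
            exact_limit=self.exact_limit).fit(self.clonotyped_)
        self.threshold_filter_ = UmiThresholdFilter(
            thresholds=self.thresholds, grid=self.grid,
            exempt_imputed=self.exempt_imputed)
        self.threshold_filter_.fit(self.clonotyped_,
                                   annotations=self.annotator_.annotations_)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Apply the filter cascade; with ``X=None`` the table seen at fit time
        is denoised."""
        if not hasattr(self, "threshold_filter_"):
            raise AttributeError("ItrapDenoiser is not fitted")
        table = self.clonotyped_ if X is None else self.clonotyper_.transform(X)
        states = []
        stages = {}
        for step in FILTER_ORDER:
            if step not in self.steps:
                continue
            before = table
            if step == "threshold":
                table = self.threshold_filter_.transform(table)
            elif step == "hla":
                table = filter_hla_match(table, self.haplotypes)
            elif step == "paired":
                table = filter_paired_chains(table)
            elif step == "singlet":
                table = filter_specificity_singlets(table)
            elif step == "is_cell":
                table = filter_is_cell(table)
            states.append(filter_state(step, before, table))
            stages[step] = table
        self.stage_states_ = states
        self.stage_tables_ = stages
        return table

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(None)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (YAML-loadable)."""

    runs: list = field(default_factory=list)   # [{donor, contigs, pmhc}, ...]
    panel: str | None = None
    hla: str | None = None
    steps: tuple = RECOMMENDED_STEPS
    thresholds: tuple | None = None
    grid: dict | None = None
    min_gems: int = 10
    alpha: float = 0.05
    zero_fill: bool = True
    exempt_imputed: bool = False
    seed: int = 0
    outdir: str = "itrap_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        if isinstance(cfg.steps, (list, tuple)):
            cfg.steps = tuple(cfg.steps)
        if cfg.thresholds is not None:
            cfg.thresholds = tuple(cfg.thresholds)
        return cfg


def load_and_curate(config: RunConfig) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Read all per-donor runs, assemble and curate the combined GEM table."""
    if not config.runs or config.panel is None:
        raise ConfigError("config must list runs and a panel file")
    panel = read_panel(config.panel)
    tables = []
    for run in config.runs:
        chains = read_contig_annotations(run["contigs"])
        captures = read_pmhc_counts(run["pmhc"], panel)
        tables.append(assemble_gem_table(chains, captures, donor_id=str(run["donor"])))
    table = concat_runs(tables)
    curated, tally = curate_gems(table)
    haplotypes = read_hla_haplotypes(config.hla) if config.hla else None
    curated.attrs["curation_tally"] = tally
    return curated, haplotypes, panel


STAGE_FILES = {"curated": "01_curated.csv", "threshold": "02_threshold.csv",
               "hla": "03_hla_match.csv", "paired": "04_paired.csv",
               "singlet": "05_singlet.csv", "is_cell": "06_is_cell.csv"}


def run_pipeline(config: RunConfig, curated: pd.DataFrame | None = None,
                 haplotypes: dict | None = None) -> dict:
    """Execute the full cascade and write staged tables, per-stage metrics and
    a reproducibility manifest under ``config.outdir``.

    ``curated``/``haplotypes`` may be passed directly (e.g. from the
    simulator) instead of reading the files listed in the config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if curated is None:
        curated, haplotypes, _ = load_and_curate(config)

    denoiser = ItrapDenoiser(
        steps=config.steps, haplotypes=haplotypes, thresholds=config.thresholds,
        grid=config.grid, min_gems=config.min_gems, alpha=config.alpha,
        zero_fill=config.zero_fill, exempt_imputed=config.exempt_imputed)
    denoiser.fit(curated)
    denoiser.transform(None)

    raw_n = len(curated)
    annotations = denoiser.annotator_.annotations_
    outputs = {}

    def emit(stage: str, table: pd.DataFrame):
        path = outdir / STAGE_FILES[stage]
        write_gem_table(table, path)
        rep = metrics_report(table, raw_n, annotations, seed=config.seed, name=stage)
        mpath = outdir / f"metrics_{stage}.json"
        mpath.write_text(json.dumps(rep.as_dict(), indent=2))
        outputs[stage] = {"table": str(path), "metrics": rep.as_dict()}

    emit("curated", denoiser.clonotyped_)
    for step in FILTER_ORDER:
        if step in denoiser.stage_tables_:
            emit(step, denoiser.stage_tables_[step])

    denoiser.annotator_.binders_.to_csv(outdir / "binders.csv", index=False)
    (outdir / "thresholds.json").write_text(
        json.dumps(denoiser.threshold_filter_.thresholds_.as_dict(), indent=2))
    if denoiser.threshold_filter_.trace_ is not None:
        denoiser.threshold_filter_.trace_.to_csv(
            outdir / "objective_trace.csv", index=False)
    denoiser.clonotyper_.clonotypes_.to_csv(outdir / "clonotypes.csv", index=False)

    cfg_yaml = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "thresholds": denoiser.threshold_filter_.thresholds_.as_dict(),
        "stages": {s: {"n_gems": o["metrics"]["n_gems"],
                       "table_sha256": hashlib.sha256(
                           Path(o["table"]).read_bytes()).hexdigest()}
                   for s, o in outputs.items()},
        "gems_out_sequence": [o["metrics"]["n_gems"] for o in outputs.values()],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"outputs": outputs, "manifest": manifest, "denoiser": denoiser}
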
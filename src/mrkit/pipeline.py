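"""Config-driven orchestration of the exposure x outcome x method grid.

A YAML analysis config names exposure and outcome summary files, the
estimators to run, multivariable adjustment sets, and sensitivity flags; the
pipeline runs instrument selection, harmonization, every requested estimator,
MR-PRESSO, unit scaling, and per-(method, outcome data set) BH-FDR, writing
tidy tab-delimited outputs plus exclusion and outlier audits. Any stage error
is recorded per grid cell and the grid continues. All randomness derives
deterministically from the config seed, independent of execution order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import report
from .errors import ConfigurationError
from .estimators import egger, ivw, mvmr, wald_ratio, weighted_median
from .harmonize import harmonize, merge_multivariable
from .presso import presso
from .summary_io import ClumpSpec, clump, exclude_chromosome, filter_significant, read_summary

logger = logging.getLogger(__name__)

METHODS = ("ivw", "egger", "weighted_median", "mr_presso", "wald")


@dataclass
class ExposureSpec:
    name: str
    path: str
    unit_multiplier: float = 1.0
    unit: str = "SD"
    trait_type: str = "continuous"
    clump_r2: float | None = None
    ld_path: str | None = None
    column_map: dict = field(default_factory=dict)


@dataclass
class OutcomeSpec:
    name: str
    path: str
    column_map: dict = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    seed: int
    output_dir: str
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    methods: list[str] = field(default_factory=lambda: ["ivw"])
    mvmr_groups: dict[str, list[str]] = field(default_factory=dict)
    p_threshold: float = 5e-8
    exclude_chrom_19: bool = False
    second_order_wald: bool = False
    fixed_effect_ivw: bool = False
    reverse_direction: bool = False
    n_boot: int = 1000
    n_sim_presso: int = 2000

    def __post_init__(self):
        if not (self.exposures and self.outcomes and self.methods):
            raise ConfigurationError("need at least one exposure, outcome, and method")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ConfigurationError(f"unknown method(s): {sorted(bad)}")
        names = {e.name for e in self.exposures}
        for g, members in self.mvmr_groups.items():
            missing = set(members) - names
            if missing:
                raise ConfigurationError(
                    f"mvmr group {g!r} references undeclared exposures: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["exposures"] = [ExposureSpec(**e) for e in d.get("exposures", [])]
        d["outcomes"] = [OutcomeSpec(**o) for o in d.get("outcomes", [])]
        return cls(**d)


def _cell_seed(base: int, *names: str) -> int:
    s = base
    for name in names:
        s = (s * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)
    return s


def _select_instruments(table, spec: ExposureSpec, config: AnalysisConfig):
    table = filter_significant(table, config.p_threshold)
    if spec.clump_r2 is not None:
        if spec.ld_path is None:
            raise ConfigurationError(f"exposure {spec.name}: clump_r2 set but no ld_path")
        ld = pd.read_csv(spec.ld_path, sep="\t", index_col=0)
        table = clump(table, ClumpSpec(r2_threshold=spec.clump_r2, ld=ld,
                                       p_threshold=config.p_threshold))
    if config.exclude_chrom_19:
        table = exclude_chromosome(table, "19")
    return table


def _run_methods(hset, config: AnalysisConfig, exposure_name, outcome_name,
                 unit_multiplier, direction, rows, audits, failures):
    seed = _cell_seed(config.seed, exposure_name, outcome_name, direction)
    ivw_model = "fixed" if config.fixed_effect_ivw else "multiplicative_random"
    for method in config.methods:
        try:
            if method == "ivw":
                ests = [ivw(hset, model=ivw_model, second_order=config.second_order_wald)]
            elif method == "egger":
                ests = [egger(hset)]
            elif method == "weighted_median":
                ests = [weighted_median(hset, n_boot=config.n_boot, seed=seed)]
            elif method == "wald":
                ests = [wald_ratio(i, second_order=config.second_order_wald)
                        for i in hset.instruments]
            elif method == "mr_presso":
                res = presso(hset, n_sim=config.n_sim_presso, seed=seed)
                ests = [res.raw_estimate]
                if res.corrected_estimate is not None:
                    ests.append(res.corrected_estimate)
                audit = res.outlier_frame()
                audit.insert(0, "exposure", exposure_name)
                audit.insert(1, "outcome", outcome_name)
                audits.append(audit)
            for est in ests:
                row = report.tidy_row(exposure_name, outcome_name, est, unit_multiplier)
                row["direction"] = direction
                rows.append(row)
        except Exception as exc:  # cell failure: record and continue the grid
            failures.append({"exposure": exposure_name, "outcome": outcome_name,
                             "stage": method, "direction": direction, "error": str(exc)})
            logger.error("%s x %s [%s/%s] failed: %s", exposure_name, outcome_name,
                         method, direction, exc)


def run(config: AnalysisConfig):
    """Execute the whole grid; returns ``(results_df, failures)`` and writes
    ``results.tsv``, ``exclusions.tsv``, ``presso_outliers.tsv`` and
    ``failures.tsv`` under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    audits: list[pd.DataFrame] = []
    exclusions: list[pd.DataFrame] = []
    failures: list[dict] = []

    outcome_tables = {}
    for ospec in config.outcomes:
        outcome_tables[ospec.name] = read_summary(
            ospec.path, ospec.column_map or None, trait_name=ospec.name,
            trait_type="binary", unit="log odds")

    exposure_raw, exposure_instruments = {}, {}
    for espec in config.exposures:
        try:
            raw = read_summary(espec.path, espec.column_map or None,
                               trait_name=espec.name, trait_type=espec.trait_type,
                               unit=espec.unit)
            exposure_raw[espec.name] = raw
            exposure_instruments[espec.name] = _select_instruments(raw, espec, config)
        except Exception as exc:
            failures.append({"exposure": espec.name, "outcome": "*",
                             "stage": "instrument_selection", "direction": "forward",
                             "error": str(exc)})

    for espec in config.exposures:
        if espec.name not in exposure_instruments:
            continue
        for ospec in config.outcomes:
            try:
                hset = harmonize(exposure_instruments[espec.name],
                                 outcome_tables[ospec.name])
                excl = hset.exclusion_frame()
                excl.insert(0, "exposure", espec.name)
                excl.insert(1, "outcome", ospec.name)
                exclusions.append(excl)
            except Exception as exc:
                failures.append({"exposure": espec.name, "outcome": ospec.name,
                                 "stage": "harmonize", "direction": "forward",
                                 "error": str(exc)})
                continue
            _run_methods(hset, config, espec.name, ospec.name, espec.unit_multiplier,
                         "forward", rows, audits, failures)

    for gname, members in config.mvmr_groups.items():
        tables = [exposure_instruments.get(m) for m in members]
        if any(t is None for t in tables):
            continue
        for ospec in config.outcomes:
            try:
                mset = merge_multivariable(tables, outcome_tables[ospec.name],
                                           p_threshold=config.p_threshold)
                res = mvmr(mset)
                mult = {e.name: e.unit_multiplier for e in config.exposures}
                for name, est in zip(members, res.exposures):
                    row = report.tidy_row(name, ospec.name, est, mult.get(name, 1.0))
                    row["method"] = f"mvmr[{gname}]"
                    row["direction"] = "forward"
                    rows.append(row)
            except Exception as exc:
                failures.append({"exposure": gname, "outcome": ospec.name,
                                 "stage": "mvmr", "direction": "forward",
                                 "error": str(exc)})

    if config.reverse_direction:
        # swap roles: outcome-trait instruments against each (behavioral) exposure
        for ospec in config.outcomes:
            try:
                out_instruments = filter_significant(outcome_tables[ospec.name],
                                                     config.p_threshold)
                if config.exclude_chrom_19:
                    out_instruments = exclude_chromosome(out_instruments, "19")
            except Exception as exc:
                failures.append({"exposure": ospec.name, "outcome": "*",
                                 "stage": "reverse_selection", "direction": "reverse",
                                 "error": str(exc)})
                continue
            for espec in config.exposures:
                if espec.name not in exposure_raw:
                    continue
                try:
                    hset = harmonize(out_instruments, exposure_raw[espec.name])
                except Exception as exc:
                    failures.append({"exposure": ospec.name, "outcome": espec.name,
                                     "stage": "harmonize", "direction": "reverse",
                                     "error": str(exc)})
                    continue
                _run_methods(hset, config, ospec.name, espec.name, 1.0,
                             "reverse", rows, audits, failures)

    df = pd.DataFrame(rows, columns=report.RESULT_COLUMNS + ["direction"])
    if len(df):
        df = report.add_fdr(df, by=("method", "outcome", "direction"))
        df = df.sort_values(["direction", "outcome", "method", "exposure"]).reset_index(drop=True)
    df.to_csv(outdir / "results.tsv", sep="\t", index=False)
    (pd.concat(exclusions) if exclusions
     else pd.DataFrame(columns=["exposure", "outcome", "variant_id", "reason"])
     ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    (pd.concat(audits) if audits
     else pd.DataFrame(columns=["exposure", "outcome", "variant_id", "pval",
                                "pval_bonferroni", "pval_display", "flagged"])
     ).to_csv(outdir / "presso_outliers.tsv", sep="\t", index=False)
    pd.DataFrame(failures, columns=["exposure", "outcome", "stage", "direction", "error"]
                 ).to_csv(outdir / "failures.tsv", sep="\t", index=False)
    return df, failures
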
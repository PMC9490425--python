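"""Orchestration of a multi-pair two-sample MR analysis.

A config lists exposure tables (with per-trait instrument p-value thresholds)
and outcome tables; every exposure x outcome pair is harmonized and run
through all estimators and diagnostics. Family-wise inference uses a
Bonferroni threshold alpha / n_tests: p below it is *significant*, p between
it and the nominal alpha is *suggestive*, anything else *null* — the tiering
used when screening several exposures against several outcomes (3 x 3 gives
0.05/9 ≈ 0.0056).

Outputs: one master results table shaped like a published MR table (five
method rows per pair, both IVW variants side by side), per-pair harmonized
instruments, leave-one-out and plot-data TSVs, and a line-delimited JSON run
log carrying seeds, counts and the harmonization audit for every pair. A
failed pair (too few usable instruments, say) is recorded and the run
continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .exceptions import AnalysisError, ConfigurationError
from .diagnostics import (
    cochran_q,
    funnel_data,
    leave_one_out,
    scatter_data,
    single_snp_forest,
)
from .estimators import Method, all_estimates
from .harmonize import (
    DEFAULT_PALINDROMIC_EAF_WINDOW,
    HarmonizationResult,
    harmonize_sets,
    write_harmonized_tsv,
)
from .summary_io import (
    Role,
    StudySet,
    apply_proxy_map,
    read_proxy_map,
    read_summary_table,
    select_instruments,
)

logger = logging.getLogger(__name__)


class Tier(str, Enum):
    SIGNIFICANT = "significant"
    SUGGESTIVE = "suggestive"
    NULL = "null"


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0 < alpha_family < 1):
        raise ConfigurationError(f"alpha_family must be in (0, 1), got {alpha_family}")
    if n_tests < 1:
        raise ConfigurationError(f"n_tests must be >= 1, got {n_tests}")
    return alpha_family / n_tests


def classify_tier(pvalue: float, threshold: float, alpha_nominal: float) -> Tier:
    """Tier a p-value: below threshold, between threshold and nominal, or null.

    With a single-test family the threshold equals the nominal alpha and the
    suggestive band is empty; a threshold *above* the nominal alpha is a
    configuration error.
    """
    if threshold > alpha_nominal:
        raise ConfigurationError(
            f"Bonferroni threshold {threshold} must not exceed the nominal alpha {alpha_nominal}"
        )
    if not (0 < pvalue <= 1):
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    if pvalue < threshold:
        return Tier.SIGNIFICANT
    if pvalue < alpha_nominal:
        return Tier.SUGGESTIVE
    return Tier.NULL


@dataclass
class TraitSpec:
    trait: str
    file: str
    p_threshold: float | None = None  # exposures only
    column_map: dict[str, str] | None = None
    delimiter: str = "\t"


@dataclass
class AnalysisConfig:
    """Full configuration of one pipeline run (see module docstring)."""

    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    output_dir: str = "mrpipe_out"
    proxy_maps: dict[str, str] = field(default_factory=dict)  # "exposure:outcome" -> file
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW
    ivw_model: str = "fixed"
    n_boot: int = 5000
    seed: int = 0
    alpha_family: float = 0.05
    n_tests: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("config needs at least one exposure and one outcome")
        if self.n_tests is None:
            self.n_tests = len(self.exposures) * len(self.outcomes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
        try:
            exposures = [TraitSpec(**e) for e in raw.pop("exposures", [])]
            outcomes = [TraitSpec(**o) for o in raw.pop("outcomes", [])]
            return cls(exposures=exposures, outcomes=outcomes, **raw)
        except TypeError as err:
            raise ConfigurationError(f"{path}: {err}") from None

    def validate_files(self, base: Path | None = None) -> None:
        """Fail fast: every referenced file must exist before any computation."""
        base = base or Path(".")
        for spec in [*self.exposures, *self.outcomes]:
            if not (base / spec.file).exists():
                raise ConfigurationError(f"input table not found: {spec.file}")
        for key, f in self.proxy_maps.items():
            if not (base / f).exists():
                raise ConfigurationError(f"proxy map for {key} not found: {f}")


@dataclass
class PairResult:
    exposure: str
    outcome: str
    harmonization: HarmonizationResult | None
    estimates: dict[Method, Any]
    heterogeneity: Any
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class RunResult:
    table: pd.DataFrame
    pairs: list[PairResult]
    threshold: float
    n_failed: int

    @property
    def exit_code(self) -> int:
        return 1 if self.n_failed else 0


# master-table layout mirrors a published MR results table
_TABLE_COLUMNS = [
    "OUTCOME", "EXPOSURE", "METHOD", "NSNP", "OR", "CI_LOW", "CI_HIGH", "P",
    "Q", "Q_P", "EGGER_INTERCEPT", "EGGER_INTERCEPT_P", "TIER",
]


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Round for publication style: OR/CI to 3 decimals, p to 3 significant figures."""
    out = df.copy()
    for c in ("OR", "CI_LOW", "CI_HIGH", "Q", "EGGER_INTERCEPT"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    for c in ("P", "Q_P", "EGGER_INTERCEPT_P"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.3g}")
    return out


def _load_exposure(spec: TraitSpec, base: Path) -> StudySet:
    study = read_summary_table(
        base / spec.file, spec.trait, Role.EXPOSURE,
        column_map=spec.column_map, delimiter=spec.delimiter,
    )
    if spec.p_threshold is not None:
        study = select_instruments(study, spec.p_threshold)
    return study


def run_analysis(config: AnalysisConfig, base_dir: str | Path = ".") -> RunResult:
    """Run every exposure x outcome pair; see module docstring for outputs."""
    base = Path(base_dir)
    config.validate_files(base)
    out_dir = base / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    log_records: list[dict[str, Any]] = [
        {
            "event": "start",
            "version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "ivw_model": config.ivw_model,
            "n_tests": config.n_tests,
        }
    ]

    threshold = bonferroni_threshold(config.alpha_family, config.n_tests)
    exposures = [_load_exposure(e, base) for e in config.exposures]
    outcomes = [
        read_summary_table(
            base / o.file, o.trait, Role.OUTCOME,
            column_map=o.column_map, delimiter=o.delimiter,
        )
        for o in config.outcomes
    ]

    rows: list[dict[str, Any]] = []
    pairs: list[PairResult] = []
    n_failed = 0
    for exp in exposures:
        for out in outcomes:
            pair_name = f"{exp.trait_name}__{out.trait_name}"
            pair_dir = out_dir / pair_name
            try:
                exp_eff = exp
                key = f"{exp.trait_name}:{out.trait_name}"
                if key in config.proxy_maps:
                    proxies = read_proxy_map(base / config.proxy_maps[key])
                    exp_eff = apply_proxy_map(exp, out, proxies)
                harm = harmonize_sets(exp_eff, out, config.palindromic_eaf_window)
                inst = harm.instruments
                if len(inst) < 3:
                    raise AnalysisError(
                        f"only {len(inst)} usable instrument(s); need >= 3"
                    )
                fits = all_estimates(
                    inst, n_boot=config.n_boot, seed=config.seed,
                    ci_level=config.ci_level,
                )
                het = cochran_q(inst)
            except (AnalysisError, ConfigurationError) as err:
                n_failed += 1
                logger.error("pair %s failed: %s", pair_name, err)
                log_records.append(
                    {"event": "pair_failed", "pair": pair_name, "reason": str(err)}
                )
                pairs.append(
                    PairResult(exp.trait_name, out.trait_name, None, {}, None, str(err))
                )
                continue

            pair_dir.mkdir(parents=True, exist_ok=True)
            write_harmonized_tsv(inst + harm.dropped, pair_dir / "harmonized.tsv")
            loo = leave_one_out(inst, config.ivw_model, config.ci_level)
            loo_df = pd.DataFrame(
                [
                    {"EXCLUDED": r.excluded_id, "NSNP": r.estimate.n_snps,
                     "OR": r.estimate.odds_ratio, "CI_LOW": r.estimate.ci_low,
                     "CI_HIGH": r.estimate.ci_high, "P": r.estimate.pvalue}
                    for r in loo
                ]
            )
            loo_df.to_csv(pair_dir / "leave_one_out.tsv", sep="\t", index=False)
            single_snp_forest(inst, config.ci_level).to_csv(
                pair_dir / "forest.tsv", sep="\t", index=False
            )
            points, lines = scatter_data(inst, list(fits.values()))
            points.to_csv(pair_dir / "scatter_points.tsv", sep="\t", index=False)
            lines.to_csv(pair_dir / "scatter_lines.tsv", sep="\t", index=False)
            funnel_data(inst).to_csv(pair_dir / "funnel.tsv", sep="\t", index=False)

            egger_int = fits[Method.EGGER_INTERCEPT]
            for method in (
                Method.IVW_FIXED, Method.IVW_MRE, Method.WEIGHTED_MEDIAN,
                Method.EGGER_SLOPE, Method.EGGER_INTERCEPT,
            ):
                f = fits[method]
                row: dict[str, Any] = {
                    "OUTCOME": out.trait_name,
                    "EXPOSURE": exp.trait_name,
                    "METHOD": method.value,
                    "NSNP": f.n_snps,
                    "OR": f.odds_ratio,
                    "CI_LOW": f.ci_low,
                    "CI_HIGH": f.ci_high,
                    "P": f.pvalue,
                    "Q": het.q_stat if method is Method.IVW_FIXED else float("nan"),
                    "Q_P": het.pvalue if method is Method.IVW_FIXED else float("nan"),
                    "EGGER_INTERCEPT": egger_int.beta
                    if method is Method.EGGER_SLOPE else float("nan"),
                    "EGGER_INTERCEPT_P": egger_int.pvalue
                    if method is Method.EGGER_SLOPE else float("nan"),
                    "TIER": classify_tier(
                        f.pvalue, threshold, config.alpha_family
                    ).value,
                }
                rows.append(row)
            pairs.append(
                PairResult(exp.trait_name, out.trait_name, harm, fits, het)
            )
            log_records.append(
                {
                    "event": "pair_done",
                    "pair": pair_name,
                    "n_exposure_instruments": harm.n_exposure_instruments,
                    "n_usable": len(inst),
                    "audit": harm.audit,
                }
            )

    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    _format_table(table).to_csv(out_dir / "results.tsv", sep="\t", index=False)
    log_records.append({"event": "end", "n_failed": n_failed})
    with open(log_path, "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return RunResult(table=table, pairs=pairs, threshold=threshold, n_failed=n_failed)


def scenario_from_yaml(path: str | Path) -> "SimScenario":
    """Load a :class:`~mrpipe.synthetic.SimScenario` from a YAML mapping."""
    from .synthetic import SimScenario

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "gamma_range" in raw:
        raw["gamma_range"] = tuple(raw["gamma_range"])
    try:
        return SimScenario(**raw)
    except TypeError as err:
        raise ConfigurationError(f"{path}: {err}") from None


def config_to_dict(config: AnalysisConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)
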
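"""End-to-end orchestration: fit -> exact test -> adjust -> group statistics.

``run_pipeline`` reads an OTU table and treatment map, fits both sampling
formulas per sample, runs the exact neutrality test, applies the
Benjamini-Hochberg adjustment across the sample family, and writes a bundle
of TSV reports: per-sample fits, formula comparison, verdict tables (one per
formula and simulation count), a flip-flop table when two simulation counts
are requested, and treatment-level summaries.  Every output is reproducible
from (inputs, config, seed).
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .etienne import EtienneFit, fit_etienne
from .ewens import EwensFit, fit_ewens
from .groups import passing_rate_table, theta_group_comparison
from .neutrality import (
    NeutralityVerdict,
    apply_adjustment,
    compare_formulae,
    exact_neutrality_test,
)
from .otu_io import (
    AbundanceConfiguration,
    Treatment,
    read_otu_table,
    read_treatment_map,
    to_configurations,
    write_rank_abundance,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config"]

# report formatting widths: theta to 3 decimals, m to 5, p to 4
_FMT = {"theta": 3, "m": 5, "p_value": 4, "p_adjusted": 4}


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    otu_path: str
    treatment_path: str | None = None
    otu_format: Literal["shared", "tsv"] = "shared"
    samples_in: Literal["rows", "cols"] = "rows"
    formula: Literal["ewens", "etienne", "both"] = "both"
    n_sims: int = 100
    n_sims_compare: int | None = None  # second verdict table + flip-flop report
    alpha: float = 0.05
    seed: int = 0
    adjust: Literal["BH", "none"] = "BH"
    refit_sims: bool = False
    outdir: str = "hubbell_out"
    plots: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides (e.g. CLI flags) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


@dataclass
class PipelineResult:
    outdir: Path
    configs: list[AbundanceConfiguration]
    ewens_fits: dict[str, EwensFit] = field(default_factory=dict)
    etienne_fits: dict[str, EtienneFit] = field(default_factory=dict)
    verdicts: dict[tuple[str, int], list[NeutralityVerdict]] = field(default_factory=dict)
    files: dict[str, Path] = field(default_factory=dict)
    failed_samples: list[str] = field(default_factory=list)


def _fit_frame(fits: dict, has_m: bool) -> pd.DataFrame:
    rows = []
    for sid, f in fits.items():
        row = {"sample_id": sid, "J": f.J, "S": f.S,
               "theta": round(f.theta, _FMT["theta"]) if math.isfinite(f.theta) else "NA",
               "logL": f.logL}
        if has_m:
            row["m"] = round(f.m, _FMT["m"])
            row["converged"] = f.converged
        else:
            row["degenerate"] = f.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def _verdict_frame(verdicts: list[NeutralityVerdict],
                   fits_e: dict[str, EwensFit],
                   fits_t: dict[str, EtienneFit]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        J = (fits_t.get(v.sample_id) or fits_e[v.sample_id]).J
        S = (fits_t.get(v.sample_id) or fits_e[v.sample_id]).S
        row = {
            "sample_id": v.sample_id, "J": J, "S": S,
            "theta": round(v.theta, _FMT["theta"]),
        }
        if v.formula == "etienne":
            row["m"] = round(v.m, _FMT["m"])
        row.update({
            "p_value": round(v.p_value, _FMT["p_value"]),
            "p_value_adjusted": round(v.p_adjusted, _FMT["p_adjusted"])
            if v.p_adjusted is not None else "NA",
            "passes": v.passes,
            "rank_p": round(v.rank_p, 4),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``config.outdir``."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_otu_table(config.otu_path, format=config.otu_format,
                           samples_in=config.samples_in)
    treatments = (read_treatment_map(config.treatment_path)
                  if config.treatment_path else {})
    configs = to_configurations(table, treatments)
    result = PipelineResult(outdir=outdir, configs=configs)
    do_ewens = config.formula in ("ewens", "both")
    do_etienne = config.formula in ("etienne", "both")

    # ---- per-sample fits
    for cfg in configs:
        t0 = time.time()
        try:
            if do_ewens:
                result.ewens_fits[cfg.sample_id] = fit_ewens(cfg)
            if do_etienne:
                result.etienne_fits[cfg.sample_id] = fit_etienne(cfg)
            logL = (result.etienne_fits.get(cfg.sample_id)
                    or result.ewens_fits[cfg.sample_id]).logL
            logger.info("sample=%s J=%d S=%d fit=ok logL=%.3f elapsed=%.2fs",
                        cfg.sample_id, cfg.J, cfg.S, logL, time.time() - t0)
        except Exception as exc:
            logger.error("sample=%s fit failed: %s", cfg.sample_id, exc)
            result.failed_samples.append(cfg.sample_id)
    configs_ok = [c for c in configs if c.sample_id not in result.failed_samples]

    if do_ewens:
        f = outdir / "fits_ewens.tsv"
        _fit_frame(result.ewens_fits, has_m=False).to_csv(f, sep="\t", index=False)
        result.files["fits_ewens"] = f
    if do_etienne:
        f = outdir / "fits_etienne.tsv"
        _fit_frame(result.etienne_fits, has_m=True).to_csv(f, sep="\t", index=False)
        result.files["fits_etienne"] = f

    # ---- formula comparison (only meaningful with both fits)
    if do_ewens and do_etienne:
        rows = []
        for cfg in configs_ok:
            ew, et = result.ewens_fits[cfg.sample_id], result.etienne_fits[cfg.sample_id]
            if ew.degenerate:
                continue
            D, p = compare_formulae(cfg, ew, et)
            rows.append({"sample_id": cfg.sample_id,
                         "logL_ewens": ew.logL, "logL_etienne": et.logL,
                         "D": round(D, 4), "p_value": round(p, 4)})
        f = outdir / "formula_comparison.tsv"
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
        result.files["formula_comparison"] = f

    # ---- exact neutrality tests
    sims_grid = [config.n_sims]
    if config.n_sims_compare:
        sims_grid.append(config.n_sims_compare)
    formulas = [f for f, on in (("ewens", do_ewens), ("etienne", do_etienne)) if on]
    for formula in formulas:
        for n_sims in sims_grid:
            if formula == "ewens" and n_sims != config.n_sims:
                continue  # the sensitivity rerun is an Etienne-only report
            verdicts = []
            for cfg in configs_ok:
                fit = (result.etienne_fits if formula == "etienne"
                       else result.ewens_fits)[cfg.sample_id]
                if isinstance(fit, EwensFit) and fit.degenerate:
                    logger.warning("sample %s: degenerate Ewens fit, test skipped",
                                   cfg.sample_id)
                    continue
                verdicts.append(exact_neutrality_test(
                    cfg, fit, n_sims=n_sims, seed=config.seed,
                    alpha=config.alpha, refit_sims=config.refit_sims))
            apply_adjustment(verdicts, method=config.adjust)
            result.verdicts[(formula, n_sims)] = verdicts
            f = outdir / f"verdicts_{formula}_{n_sims}.tsv"
            _verdict_frame(verdicts, result.ewens_fits, result.etienne_fits).to_csv(
                f, sep="\t", index=False)
            result.files[f"verdicts_{formula}_{n_sims}"] = f
            logger.info("formula=%s n_sims=%d passing=%d/%d", formula, n_sims,
                        sum(v.passes for v in verdicts), len(verdicts))

    # ---- flip-flop table between the two simulation counts
    if config.n_sims_compare and do_etienne:
        v1 = {v.sample_id: v for v in result.verdicts[("etienne", config.n_sims)]}
        v2 = {v.sample_id: v for v in result.verdicts[("etienne", config.n_sims_compare)]}
        rows = [
            {
                "sample_id": sid,
                f"p_adj_{config.n_sims}": round(v1[sid].p_adjusted, 4),
                f"p_adj_{config.n_sims_compare}": round(v2[sid].p_adjusted, 4),
                f"passes_{config.n_sims}": v1[sid].passes,
                f"passes_{config.n_sims_compare}": v2[sid].passes,
            }
            for sid in v1
            if sid in v2 and v1[sid].passes != v2[sid].passes
        ]
        f = outdir / "flipflop.tsv"
        cols = ["sample_id",
                f"p_adj_{config.n_sims}", f"p_adj_{config.n_sims_compare}",
                f"passes_{config.n_sims}", f"passes_{config.n_sims_compare}"]
        pd.DataFrame(rows, columns=cols).to_csv(f, sep="\t", index=False)
        result.files["flipflop"] = f

    # ---- group-level statistics
    main_formula = "etienne" if do_etienne else "ewens"
    verdicts = result.verdicts[(main_formula, config.n_sims)]
    trt_map = {c.sample_id: c.treatment for c in configs_ok}
    n_groups = len({t for t in trt_map.values() if t is not Treatment.OTHER})
    if n_groups >= 2 and verdicts:
        summaries, fisher_p = passing_rate_table(verdicts, trt_map)
        f = outdir / "group_summary.tsv"
        pd.DataFrame([
            {"treatment": s.treatment.value, "n_samples": s.n_samples,
             "n_pass": s.n_pass, "pass_rate_pct": f"{100 * s.pass_rate:.2f}",
             "mean_theta": round(s.mean_theta, 3), "sd_theta": round(s.sd_theta, 3)}
            for s in summaries
        ]).to_csv(f, sep="\t", index=False)
        result.files["group_summary"] = f

        rows = [{"treatment_1": t1, "treatment_2": t2, "test": "fisher_pass_rate",
                 "p_value": round(p, 4)} for (t1, t2), p in fisher_p.items()]
        try:
            fits = (result.etienne_fits if main_formula == "etienne"
                    else result.ewens_fits)
            cmp_ = theta_group_comparison(list(fits.values()), trt_map)
            rows.append({"treatment_1": "ALL", "treatment_2": "ALL",
                         "test": "theta_anova_F", "p_value": round(cmp_.anova_p, 4),
                         "statistic": round(cmp_.anova_F, 4)})
            rows += [{"treatment_1": t1, "treatment_2": t2,
                      "test": "theta_t_bonferroni", "p_value": round(p, 4)}
                     for (t1, t2), p in cmp_.pairwise_p.items()]
        except ValueError as exc:
            logger.warning("theta group comparison skipped: %s", exc)
        f = outdir / "pairwise_tests.tsv"
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
        result.files["pairwise_tests"] = f

    # ---- rank-abundance export + optional plots
    f = outdir / "rank_abundance.tsv"
    write_rank_abundance(configs_ok, f)
    result.files["rank_abundance"] = f
    if config.plots:
        _write_plots(result, outdir)

    logger.info("pipeline done: %d samples, %d failed, seed=%d, version=%s, %.1fs",
                len(configs), len(result.failed_samples), config.seed,
                __version__, time.time() - t_start)
    return result


def _write_plots(result: PipelineResult, outdir: Path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .otu_io import rank_abundance

    fig, ax = plt.subplots(figsize=(6, 4))
    for cfg in result.configs[:8]:
        ra = rank_abundance(cfg)
        ax.plot([r for r, _ in ra], [v for _, v in ra], label=cfg.sample_id)
    ax.set_xlabel("species rank")
    ax.set_ylabel("ln abundance")
    ax.legend(fontsize=6)
    fig.savefig(outdir / "rank_abundance.png", dpi=120)
    plt.close(fig)
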
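"""End-to-end orchestration: simulate/load -> impute -> estimate -> intervene
-> bootstrap -> report.

A single master seed deterministically derives the per-stage seeds
(generator, missingness, imputation, bootstrap), so one config reproduces
every output byte-for-byte apart from timestamps.  Human-readable outputs
round to one decimal; machine outputs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_pipeline
from .cohort import PREDICTORS, LEVELS, read_cohort_csv, validate_cohort, write_cohort_csv
from .descriptives import check_positivity, filter_regular_cycle, make_table1
from .generator import GeneratorParams, apply_missingness, default_params, generate_cohort
from .imputation import impute_chained
from .inequality import EXPOSURE, choose_references, fit_adjusted_exposure_model
from .intervention import ROW_COLUMNS, estimate_reduction

log = logging.getLogger(__name__)

_KNOWN_BLOCKS = {"generator", "imputation", "analysis", "bootstrap", "output", "seed", "input_csv"}


class ConfigError(ValueError):
    """The configuration violates the documented schema."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (mirrors the YAML block layout)."""

    seed: int = 0
    input_csv: str | None = None
    generator: dict = field(default_factory=dict)
    imputation: dict = field(default_factory=lambda: {"m": 50, "iterations": 100})
    analysis: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=lambda: {"B": 1000, "alpha": 0.05})
    output: dict = field(default_factory=lambda: {"dir": "results"})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            input_csv=raw.get("input_csv"),
            generator=dict(raw.get("generator", {})),
            imputation={"m": 50, "iterations": 100, **raw.get("imputation", {})},
            analysis=dict(raw.get("analysis", {})),
            bootstrap={"B": 1000, "alpha": 0.05, **raw.get("bootstrap", {})},
            output={"dir": "results", **raw.get("output", {})},
        )
        m = cfg.imputation["m"]
        if not (isinstance(m, int) and m >= 2):
            raise ConfigError("imputation.m must be an integer >= 2")
        if cfg.imputation["iterations"] < 1:
            raise ConfigError("imputation.iterations must be >= 1")
        if cfg.bootstrap["B"] < 2:
            raise ConfigError("bootstrap.B must be >= 2")
        if not (0 < cfg.bootstrap["alpha"] < 0.5):
            raise ConfigError("bootstrap.alpha must be in (0, 0.5)")
        if cfg.analysis.get("counterfactual", "shift") not in ("shift", "predict"):
            raise ConfigError("analysis.counterfactual must be 'shift' or 'predict'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "input_csv": self.input_csv,
            "generator": self.generator,
            "imputation": self.imputation,
            "analysis": self.analysis,
            "bootstrap": self.bootstrap,
            "output": self.output,
        }


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed (below 2^31)."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def build_generator_params(cfg: PipelineConfig) -> GeneratorParams:
    """Generator parameters: published-marginal defaults plus config overrides."""
    overrides = dict(cfg.generator)
    n = int(overrides.pop("n", 4196))
    params = default_params(n=n, seed=derive_seed(cfg.seed, "generator"))
    for key, value in overrides.items():
        if not hasattr(params, key):
            raise ConfigError(f"generator.{key}: unknown parameter")
        current = getattr(params, key)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = {**current, **value}
            setattr(params, key, merged)
        else:
            setattr(params, key, value)
    return params


def table2_estimator(references: dict[str, str], mode: str = "shift"):
    """Estimator mapping one completed table to the flat parameter vector of
    the full without/with/reduction report (keys predictor|level|quantity)."""

    def run(table: pd.DataFrame) -> pd.Series:
        fit = fit_adjusted_exposure_model(table, references)
        values: dict[str, float] = {EXPOSURE: fit.exposure_effect}
        for pred in PREDICTORS:
            rows = estimate_reduction(table, pred, fit, reference=references[pred], mode=mode)
            for _, r in rows.iterrows():
                if r["is_reference"]:
                    continue
                key = f"{pred}|{r['level']}"
                values[f"{key}|without"] = r["beta_without"]
                values[f"{key}|with"] = r["beta_with"]
                values[f"{key}|reduction"] = r["reduction"]
        return pd.Series(values)

    return run


def assemble_table2(point: pd.Series, cis: pd.DataFrame, references: dict[str, str]) -> pd.DataFrame:
    """Tidy report frame with one row per predictor level, reference rows zero."""
    ci_map = cis.set_index("parameter") if len(cis) else None
    rows = []
    for pred in PREDICTORS:
        for lv in LEVELS[pred]:
            row = {c: np.nan for c in ROW_COLUMNS}
            row.update(predictor=pred, level=lv, is_reference=lv == references[pred])
            if lv == references[pred]:
                row.update(beta_without=0.0, beta_with=0.0, reduction=0.0)
            else:
                key = f"{pred}|{lv}"
                for quantity, est_col, lo_col, hi_col in [
                    ("without", "beta_without", "ci_without_lo", "ci_without_hi"),
                    ("with", "beta_with", "ci_with_lo", "ci_with_hi"),
                    ("reduction", "reduction", "ci_reduction_lo", "ci_reduction_hi"),
                ]:
                    pname = f"{key}|{quantity}"
                    if pname in point.index:
                        row[est_col] = point[pname]
                    if ci_map is not None and pname in ci_map.index:
                        row[lo_col] = ci_map.loc[pname, "ci_lo"]
                        row[hi_col] = ci_map.loc[pname, "ci_hi"]
            rows.append(row)
    frame = pd.DataFrame(rows, columns=ROW_COLUMNS)
    # self-consistency: the reduction column is with-minus-without
    est = frame.loc[~frame["is_reference"]].dropna(subset=["reduction"])
    if not np.allclose(est["reduction"], est["beta_with"] - est["beta_without"], atol=1e-8):
        raise RuntimeError("reduction column inconsistent with with-minus-without")
    return frame


def plot_table2(table2: pd.DataFrame, path) -> None:
    """Dot-and-interval chart of inequalities without/with intervention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = table2.reset_index(drop=True)
    labels = [f"{r.predictor}: {r.level}" for r in frame.itertuples()]
    ypos = np.arange(len(frame))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.32 * len(frame) + 1.5))
    for offset, (est, lo, hi, color, lab) in enumerate([
        ("beta_without", "ci_without_lo", "ci_without_hi", "#1f3d7a", "without intervention"),
        ("beta_with", "ci_with_lo", "ci_with_hi", "#7aa6dc", "with intervention"),
    ]):
        y = ypos + (0.18 if offset == 0 else -0.18)
        ax.errorbar(
            frame[est], y,
            xerr=[frame[est] - frame[lo].fillna(frame[est]),
                  frame[hi].fillna(frame[est]) - frame[est]],
            fmt="o", color=color, ecolor=color, elinewidth=1.5, capsize=2,
            markersize=4, label=lab,
        )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("difference in initiation timing (weeks)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Execute the complete analytic sequence and write the report bundle.

    Returns the in-memory results (table1, table2, diagnostics, manifest).
    """
    t0 = time.time()
    outdir = Path(cfg.output["dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    mode = cfg.analysis.get("counterfactual", "shift")

    if cfg.input_csv:
        observed = read_cohort_csv(cfg.input_csv)
        log.info("loaded cohort: %d rows from %s", len(observed), cfg.input_csv)
    else:
        params = build_generator_params(cfg)
        complete = generate_cohort(params, seed=derive_seed(cfg.seed, "generator"))
        observed = apply_missingness(complete, params, seed=derive_seed(cfg.seed, "missingness"))
        log.info("simulated cohort: n=%d (seed %d)", params.n, derive_seed(cfg.seed, "generator"))
    validate_cohort(observed)

    if cfg.analysis.get("regular_cycle_only", False):
        observed = filter_regular_cycle(observed)
        log.info("regular-cycle subset: n=%d", len(observed))

    table1 = make_table1(observed)
    from .descriptives import SeparationError

    try:
        positivity = check_positivity(observed)
        log.info("positivity: min propensity %.3f over %d complete cases",
                 positivity.minimum, positivity.n)
    except SeparationError as exc:
        positivity = None
        log.warning("positivity diagnostic unavailable: %s", exc)

    references = choose_references(observed)

    imputed = impute_chained(
        observed,
        m=cfg.imputation["m"],
        iterations=cfg.imputation["iterations"],
        seed=derive_seed(cfg.seed, "imputation"),
    )
    log.info("imputation: m=%d, %d iterations, visit order %s",
             imputed.m, imputed.iterations, imputed.visit_order)

    estimator = table2_estimator(references, mode=mode)
    from .bootstrap import _pooled

    point = _pooled(imputed.tables, estimator)
    cis = bootstrap_pipeline(
        imputed, estimator,
        B=cfg.bootstrap["B"], alpha=cfg.bootstrap["alpha"],
        seed=derive_seed(cfg.seed, "bootstrap"),
    )
    table2 = assemble_table2(point, cis, references)

    exposure_ci = cis.set_index("parameter").loc[EXPOSURE]
    diagnostics = {
        "n": int(len(observed)),
        "propensity_min": positivity.minimum if positivity else None,
        "propensity_max": positivity.maximum if positivity else None,
        "propensity_n": positivity.n if positivity else None,
        "propensity_warnings": positivity.warnings if positivity
        else ["separation: diagnostic unavailable"],
        "adjusted_exposure_effect": float(point[EXPOSURE]),
        "adjusted_exposure_effect_ci": [float(exposure_ci["ci_lo"]), float(exposure_ci["ci_hi"])],
        "references": references,
    }

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {s: derive_seed(cfg.seed, s)
                  for s in ("generator", "missingness", "imputation", "bootstrap")},
        "visit_order": imputed.visit_order,
        "elapsed_s": round(time.time() - t0, 2),
    }

    table1.to_csv(outdir / "table1.csv", index=False)
    table2.to_csv(outdir / "table2.csv", index=False)
    table2_rounded = table2.copy()
    for c in ROW_COLUMNS[3:]:
        table2_rounded[c] = table2_rounded[c].round(1)
    table2_rounded.to_csv(outdir / "table2_rounded.csv", index=False)
    write_cohort_csv(observed, outdir / "cohort_observed.csv")
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    plot_table2(table2, outdir / "figure1.png")
    log.info("report bundle written to %s (%.1fs)", outdir, time.time() - t0)

    return {
        "table1": table1,
        "table2": table2,
        "diagnostics": diagnostics,
        "manifest": manifest,
        "observed": observed,
        "imputed": imputed,
    }
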
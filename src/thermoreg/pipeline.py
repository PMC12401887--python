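"""End-to-end orchestration: simulate/load → preprocess → coupling →
traits → thermal time constant → statistics, with tidy CSV outputs and a
run manifest. The pipeline is a pure function of (inputs, config, seed)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .biophysics import thermal_time_constant
from .coupling import (
    EPSILON,
    MIN_AIR_RANGE_C,
    MIN_POINTS,
    WINDOW_MINUTES,
    coupling_metrics,
)
from .io import read_logger_csv, read_tables, traits_to_frame
from .preprocess import TRIM_THRESHOLDS_C, WINDOW_END, WINDOW_START, preprocess_series
from .stats import (
    bootstrap_mean_ci,
    contrasts_to_frame,
    pairwise_contrasts,
    two_way_anova,
)
from .synthetic import SyntheticConfig, generate_experiment
from .traits import PCA_TRAITS, derive_traits_frame, pca_traits
from .types import PairedSeries, PlantMeta, TauParams, Treatment

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Provide either ``input_dir`` (a directory with ``metadata.csv``,
    ``traits.csv`` and ``loggers/<plant>_<treatment>.csv``) or
    ``simulate=True`` to generate the inputs with the synthetic module.
    """

    input_dir: Optional[str] = None
    simulate: bool = False
    out_dir: Optional[str] = None
    seed: int = 0
    window_start: str = WINDOW_START
    window_end: str = WINDOW_END
    trim_benign_c: float = 16.0
    trim_high_c: float = 31.0
    beta_window_minutes: int = WINDOW_MINUTES
    beta_min_points: int = MIN_POINTS
    beta_min_air_range_c: float = MIN_AIR_RANGE_C
    beta_epsilon: float = EPSILON
    beta_method: str = "window_mean"
    tau: TauParams = field(default_factory=TauParams)
    n_boot: int = 1000
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("provide input_dir or set simulate=True")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a flat or nested mapping (e.g. parsed YAML).

        Recognised nested sections: ``window.{start,end}``,
        ``trim.{benign_c,high_c}``, ``beta.*``, ``tau.*``.
        """
        d = dict(d)
        kw: dict = {}
        window = d.pop("window", {})
        kw["window_start"] = window.get("start", WINDOW_START)
        kw["window_end"] = window.get("end", WINDOW_END)
        trim = d.pop("trim", {})
        kw["trim_benign_c"] = trim.get("benign_c", 16.0)
        kw["trim_high_c"] = trim.get("high_c", 31.0)
        beta = d.pop("beta", {})
        kw["beta_window_minutes"] = beta.get("window_minutes", WINDOW_MINUTES)
        kw["beta_min_points"] = beta.get("min_points", MIN_POINTS)
        kw["beta_min_air_range_c"] = beta.get("min_air_range_c", MIN_AIR_RANGE_C)
        kw["beta_epsilon"] = beta.get("epsilon", EPSILON)
        kw["beta_method"] = beta.get("method", "window_mean")
        tau = d.pop("tau", {})
        kw["tau"] = TauParams(**tau) if tau else TauParams()
        for key in ("input_dir", "simulate", "out_dir", "seed", "n_boot"):
            if key in d:
                kw[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kw)


@dataclass
class PipelineResult:
    """All tables produced by one run."""

    metrics: pd.DataFrame
    trim_reports: pd.DataFrame
    traits: pd.DataFrame
    group_summaries: pd.DataFrame
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    pca_loadings: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_variance: pd.DataFrame
    manifest: dict


def _jsonable(obj):
    """Recursively convert a config tree to JSON-safe types (keys to str)."""
    if isinstance(obj, dict):
        return {str(getattr(k, "value", k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        exp = generate_experiment(cfg.synthetic, seed=cfg.seed)
        return exp.meta, traits_to_frame(exp.traits), exp.series
    root = Path(cfg.input_dir)
    meta, traits = read_tables(root / "metadata.csv", root / "traits.csv")
    series = {}
    for path in sorted((root / "loggers").glob("*.csv")):
        s = read_logger_csv(path)
        series[(s.plant_id, s.treatment)] = s
    if not series:
        raise FileNotFoundError(f"no logger CSVs under {root / 'loggers'}")
    return meta, traits_to_frame(traits), series


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every analysis stage and (optionally) write tidy CSV outputs."""
    cfg = config
    meta, traits_raw, series = _load_inputs(cfg)
    biome_of = {m.plant_id: m.biome.value for m in meta}
    thresholds = {Treatment.BENIGN: cfg.trim_benign_c, Treatment.HIGH: cfg.trim_high_c}

    metric_rows, trim_rows = [], []
    for (pid, trt), s in sorted(series.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        try:
            clean, report = preprocess_series(
                s, cfg.window_start, cfg.window_end, thresholds
            )
            cm = coupling_metrics(
                clean,
                window_minutes=cfg.beta_window_minutes,
                min_points=cfg.beta_min_points,
                min_air_range=cfg.beta_min_air_range_c,
                epsilon=cfg.beta_epsilon,
                anchor=cfg.window_start,
                method=cfg.beta_method,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage coupling failed for plant {pid} ({trt.value}): {exc}"
            ) from exc
        metric_rows.append(
            {
                "plant_id": pid,
                "treatment": trt.value,
                "biome": biome_of.get(pid, ""),
                "delta_t_mean": cm.delta_t_mean,
                "beta": cm.beta,
                "n_windows": cm.n_windows,
                "thermo_class": cm.thermo_class.value,
            }
        )
        trim_rows.append(
            {
                "plant_id": pid,
                "treatment": trt.value,
                "n_input": report.n_input,
                "n_after_window": report.n_after_window,
                "n_after_threshold": report.n_after_threshold,
                "fraction_trimmed_by_threshold": report.fraction_trimmed_by_threshold,
            }
        )
    metrics = pd.DataFrame(metric_rows)
    trim_reports = pd.DataFrame(trim_rows)
    log.info("coupling metrics computed for %d plant×treatment series", len(metrics))

    # Derived traits and the thermal time constant per plant.
    traits = derive_traits_frame(traits_raw)
    traits["tau_s"] = thermal_time_constant(
        traits["lma_kg_m2"].to_numpy(),
        traits["ldmc"].to_numpy(),
        traits["width_mm"].to_numpy() / 1000.0,
        cfg.tau,
    )

    # Biome×treatment summaries with bootstrap CIs (seeded).
    rng = np.random.default_rng(cfg.seed + 1)
    summary_rows = []
    for (biome, trt), grp in metrics.groupby(["biome", "treatment"], sort=True):
        for var in ("delta_t_mean", "beta"):
            vals = grp[var].to_numpy()
            if vals.size >= 2:
                mean, lo, hi = bootstrap_mean_ci(vals, n_boot=cfg.n_boot, seed=rng)
            else:  # single plant: no resampling distribution
                mean, lo, hi = float(vals.mean()), np.nan, np.nan
            summary_rows.append(
                {
                    "biome": biome,
                    "treatment": trt,
                    "variable": var,
                    "mean": mean,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n": len(grp),
                }
            )
    group_summaries = pd.DataFrame(summary_rows)

    # Fixed-effects Type III ANOVA and Tukey contrasts for ΔT and β.
    anova_frames, contrast_frames = [], []
    group_label = metrics["biome"] + ":" + metrics["treatment"]
    for var in ("delta_t_mean", "beta"):
        try:
            tab = two_way_anova(
                metrics[var].to_numpy(),
                metrics["treatment"].to_numpy(),
                metrics["biome"].to_numpy(),
            )
        except ValueError as exc:
            log.warning("ANOVA skipped for %s: %s", var, exc)
        else:
            frame = tab.to_frame()
            frame.insert(0, "response", var)
            frame["r_squared"] = tab.r_squared
            anova_frames.append(frame)
        try:
            cframe = contrasts_to_frame(
                pairwise_contrasts(metrics[var].to_numpy(), group_label.to_numpy())
            )
        except ValueError as exc:
            log.warning("contrasts skipped for %s: %s", var, exc)
        else:
            cframe.insert(0, "response", var)
            contrast_frames.append(cframe)
    anova = (
        pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()
    )
    contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )

    # Six-trait PCA on plants with a complete trait set.
    try:
        pca = pca_traits(traits, PCA_TRAITS)
    except ValueError as exc:
        log.warning("PCA skipped: %s", exc)
        pca = None
    if pca is not None:
        pca_variance = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.variance_explained))],
                "variance_explained_pct": pca.variance_explained,
            }
        )
    else:
        pca_variance = pd.DataFrame()

    config_dict = _jsonable(asdict(cfg))
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_plants": len({pid for pid, _ in series}),
        "n_series": len(series),
        "n_metric_rows": len(metrics),
        "n_pca_plants": 0 if pca is None else len(pca.scores),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    result = PipelineResult(
        metrics=metrics,
        trim_reports=trim_reports,
        traits=traits,
        group_summaries=group_summaries,
        anova=anova,
        contrasts=contrasts,
        pca_loadings=(
            pd.DataFrame() if pca is None else pca.loadings.reset_index(names="trait")
        ),
        pca_scores=pd.DataFrame() if pca is None else pca.scores.reset_index(drop=True),
        pca_variance=pca_variance,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.trim_reports.to_csv(out / "trim_reports.csv", index=False)
    result.traits.to_csv(out / "traits_derived.csv", index=False)
    result.group_summaries.to_csv(out / "group_summaries.csv", index=False)
    result.anova.to_csv(out / "anova.csv", index=False)
    result.contrasts.to_csv(out / "contrasts.csv", index=False)
    result.pca_loadings.to_csv(out / "pca_loadings.csv", index=False)
    result.pca_scores.to_csv(out / "pca_scores.csv", index=False)
    result.pca_variance.to_csv(out / "pca_variance.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    log.info("outputs written to %s", out)
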
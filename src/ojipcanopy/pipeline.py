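"""End-to-end orchestration: transients + leaf samples -> analysis tables.

`run_pipeline` reproduces the full analysis chain on either measured CSV
inputs or a synthetic canopy design: per-sample landmarks and JIP parameters,
per-stage vertical chlorophyll profiles with SE and LSD letters, JI-phase
classification per nitrogen x stage, vertical-pattern categories,
reversal-stage detection per nitrogen level, and per-layer boosted-tree
importance of the JIP parameters for chlorophyll content.  Every output is a
CSV in the configured output directory plus a JSON run log recording the
configuration, seeds and software versions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .canopy import (
    VerticalProfile,
    anova_lsd,
    classify_stage_category,
    detect_reversal_stage,
    layer_relative_ratios,
    within_leaf_gradient,
)
from .errors import OjipError, ValidationError
from .importance import (
    DEFAULT_PARAM_GRID,
    cumulative_importance,
    fit_chl_model,
    rank_features,
)
from .jip import JIP_PARAMETER_NAMES, classify_ji_phase, jip_panel
from .simulate import CanopyDesign, generate_canopy_dataset
from .transients import LAYERS, STAGES, Transient, read_transients

OUTPUT_TABLES = (
    "jip_parameters.csv",
    "vertical_profiles.csv",
    "ji_phase_summary.csv",
    "stage_categories.csv",
    "reversal_stages.csv",
    "importance.csv",
    "model_quality.csv",
)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: CSV paths (``transients_csv`` + ``samples_csv``)
    or a synthetic ``design``.
    """

    transients_csv: str | None = None
    samples_csv: str | None = None
    design: CanopyDesign | None = None
    variant: str = "as_printed"
    ji_delta: float = 0.01
    peak_delta: float = 0.05
    gradient_delta: float = 0.01
    alpha: float = 0.05
    importance_grid: Mapping[str, list] = field(default_factory=lambda: dict(DEFAULT_PARAM_GRID))
    split_seed: int = 0
    top_k: int = 7
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        has_files = self.transients_csv is not None and self.samples_csv is not None
        if not has_files and self.design is None:
            raise ValidationError("config needs input CSV paths or a synthetic design")


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, list[Transient]]:
    if config.design is not None:
        samples, transients, _ = generate_canopy_dataset(config.design)
        return samples, transients
    transients = read_transients(config.transients_csv)
    samples = pd.read_csv(config.samples_csv)
    required = {"sample_id", "nitrogen", "stage", "layer", "portion", "replicate", "chl_ug_cm2"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"samples table missing column(s) {sorted(missing)}")
    return samples, transients


def jip_table(
    transients: list[Transient], variant: str = "as_printed", ji_delta: float = 0.01
) -> pd.DataFrame:
    """One row per transient: landmarks, derived panel, JI-phase class."""
    rows = []
    for tr in transients:
        lm, params = jip_panel(tr, variant=variant)
        row = {
            "sample_id": tr.sample_id,
            "nitrogen": tr.nitrogen,
            "stage": tr.stage,
            "layer": tr.layer,
            "F0": lm.F0,
            "F300": lm.F300,
            "FJ": lm.FJ,
            "FI": lm.FI,
            "FM": lm.FM,
            "t_fm": lm.t_fm,
            "area": lm.area,
        }
        row.update(params.as_dict())
        row["variant"] = variant
        row["ji_phase"] = classify_ji_phase(lm, delta=ji_delta)
        rows.append(row)
    return pd.DataFrame(rows)


def leaf_chl_table(samples: pd.DataFrame, gradient_delta: float = 0.01) -> pd.DataFrame:
    """Per-leaf chlorophyll: mean over portions plus the within-leaf gradient."""
    rows = []
    keys = ["sample_id", "nitrogen", "stage", "layer", "replicate"]
    for key_vals, grp in samples.groupby(keys, sort=False):
        by_portion = grp.set_index("portion")["chl_ug_cm2"]
        row = dict(zip(keys, key_vals))
        row["chl_ug_cm2"] = float(grp["chl_ug_cm2"].mean())
        if {"basal", "central", "top"} <= set(by_portion.index):
            row["gradient"] = within_leaf_gradient(
                float(by_portion["basal"]), float(by_portion["central"]),
                float(by_portion["top"]), delta=gradient_delta,
            )
        else:
            row["gradient"] = "unknown"
        rows.append(row)
    return pd.DataFrame(rows)


def chl_profiles(leaf_chl: pd.DataFrame) -> dict[tuple[str, str], VerticalProfile]:
    """Vertical chlorophyll profile per (nitrogen, stage)."""
    profiles = {}
    for (nitrogen, stage), grp in leaf_chl.groupby(["nitrogen", "stage"], sort=False):
        profiles[(nitrogen, stage)] = VerticalProfile.from_samples(
            grp, "chl_ug_cm2", nitrogen, stage
        )
    return profiles


def _profiles_table(
    profiles: dict[tuple[str, str], VerticalProfile],
    leaf_chl: pd.DataFrame,
    alpha: float,
) -> pd.DataFrame:
    rows = []
    for (nitrogen, stage), profile in profiles.items():
        grp = leaf_chl[(leaf_chl["nitrogen"] == nitrogen) & (leaf_chl["stage"] == stage)]
        groups = [
            grp.loc[grp["layer"] == layer, "chl_ug_cm2"].to_numpy()
            for layer in profile.layers
        ]
        if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
            res = anova_lsd(groups, alpha=alpha)
            letters = res.letters
            f_stat, p_val = res.f_statistic, res.p_value
        else:
            letters = tuple("" for _ in profile.layers)
            f_stat = p_val = float("nan")
        for layer, mean, se, n, letter in zip(
            profile.layers, profile.means, profile.ses, profile.ns, letters
        ):
            rows.append(
                {
                    "nitrogen": nitrogen, "stage": stage, "layer": layer,
                    "mean_chl_ug_cm2": mean, "se": se, "n": n,
                    "lsd_letter": letter, "anova_F": f_stat, "anova_p": p_val,
                }
            )
    return pd.DataFrame(rows)


def _ji_phase_summary(jip: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (nitrogen, stage), grp in jip.groupby(["nitrogen", "stage"], sort=False):
        counts = grp["ji_phase"].value_counts()
        n = len(grp)
        rows.append(
            {
                "nitrogen": nitrogen, "stage": stage, "n": n,
                "frac_JI_fall": counts.get("JI_fall", 0) / n,
                "frac_JI_rise": counts.get("JI_rise", 0) / n,
                "frac_flat": counts.get("flat", 0) / n,
                "dominant_phase": counts.idxmax(),
            }
        )
    return pd.DataFrame(rows)


def _stage_categories(jip: pd.DataFrame, peak_delta: float) -> pd.DataFrame:
    rows = []
    for (nitrogen, stage), grp in jip.groupby(["nitrogen", "stage"], sort=False):
        layer_means = grp.groupby("layer")[list(JIP_PARAMETER_NAMES)].mean()
        if len(layer_means) < 3 or "L1" not in layer_means.index:
            continue
        panel = {
            name: dict(layer_means[name] / layer_means.loc["L1", name])
            for name in JIP_PARAMETER_NAMES
        }
        try:
            match = classify_stage_category(panel, delta=peak_delta)
        except ValidationError:
            continue
        rows.append(
            {
                "nitrogen": nitrogen, "stage": stage,
                "category": match.category, "score": match.score, "tie": match.tie,
                "peaks": ";".join(sorted(match.peaks)),
                "valleys": ";".join(sorted(match.valleys)),
            }
        )
    return pd.DataFrame(rows)


def _reversal_table(profiles: dict[tuple[str, str], VerticalProfile]) -> pd.DataFrame:
    rows = []
    for nitrogen in sorted({n for n, _ in profiles}):
        per_stage = {s: p for (n, s), p in profiles.items() if n == nitrogen}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stage = detect_reversal_stage(per_stage, STAGES)
        rows.append({"nitrogen": nitrogen, "reversal_stage": stage or "none"})
    return pd.DataFrame(rows)


def _importance_tables(
    jip: pd.DataFrame, leaf_chl: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    merged = jip.merge(
        leaf_chl[["sample_id", "chl_ug_cm2"]], on="sample_id", validate="one_to_one"
    )
    imp_rows, quality_rows = [], []
    importance_by_layer: dict[str, dict[str, float]] = {}
    for layer in LAYERS:
        grp = merged[merged["layer"] == layer]
        if len(grp) < 20:
            continue
        features = grp[list(JIP_PARAMETER_NAMES)].reset_index(drop=True)
        model, rmse_test = fit_chl_model(
            features,
            grp["chl_ug_cm2"].to_numpy(),
            split_seed=config.split_seed,
            grid=config.importance_grid,
            stratify=grp["nitrogen"].tolist(),
        )
        importance, top_k = rank_features(model, k=config.top_k)
        importance_by_layer[layer] = importance
        ordered = sorted(importance, key=lambda nm: (-importance[nm], nm))
        for rank, name in enumerate(ordered, start=1):
            imp_rows.append(
                {"layer": layer, "parameter": name,
                 "importance": importance[name], "rank": rank,
                 "in_top_k": name in top_k}
            )
        quality_rows.append(
            {"layer": layer, "n": len(grp), "rmse_test": rmse_test,
             **{f"best_{k}": v for k, v in model.best_params_.items()}}
        )
    imp = pd.DataFrame(imp_rows)
    if importance_by_layer and all(l in importance_by_layer for l in LAYERS):
        lower, upper = cumulative_importance(importance_by_layer)
        cum = pd.DataFrame(
            {
                "parameter": sorted(lower),
                "cumulative_lower": [lower[p] for p in sorted(lower)],
                "cumulative_upper": [upper[p] for p in sorted(lower)],
            }
        )
    else:
        cum = pd.DataFrame(columns=["parameter", "cumulative_lower", "cumulative_upper"])
    return imp, cum, pd.DataFrame(quality_rows)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the output tables and writes them as
    CSV under ``config.out_dir`` together with ``run_log.json``."""
    samples, transients = _load_inputs(config)  # I/O errors surface before any output

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}
    log: dict = {
        "config": {
            k: (asdict(v) if isinstance(v, CanopyDesign) else v)
            for k, v in asdict(config).items()
        },
        "variant": config.variant,
        "versions": {
            "ojipcanopy": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages_completed": [],
        "failures": {},
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except OjipError as exc:
            log["failures"][name] = str(exc)
            return None
        log["stages_completed"].append(name)
        return result

    jip = stage("jip_parameters", lambda: jip_table(transients, config.variant, config.ji_delta))
    leaf_chl = stage("leaf_chl", lambda: leaf_chl_table(samples, config.gradient_delta))
    profiles = chl_profiles(leaf_chl) if leaf_chl is not None else {}
    if jip is not None:
        outputs["jip_parameters"] = jip
    if leaf_chl is not None:
        prof_tab = stage("vertical_profiles", lambda: _profiles_table(profiles, leaf_chl, config.alpha))
        if prof_tab is not None:
            outputs["vertical_profiles"] = prof_tab
        rev = stage("reversal_stages", lambda: _reversal_table(profiles))
        if rev is not None:
            outputs["reversal_stages"] = rev
    if jip is not None:
        phase = stage("ji_phase_summary", lambda: _ji_phase_summary(jip))
        if phase is not None:
            outputs["ji_phase_summary"] = phase
        cats = stage("stage_categories", lambda: _stage_categories(jip, config.peak_delta))
        if cats is not None:
            outputs["stage_categories"] = cats
    if jip is not None and leaf_chl is not None:
        result = stage("importance", lambda: _importance_tables(jip, leaf_chl, config))
        if result is not None:
            imp, cum, quality = result
            outputs["importance"] = imp
            outputs["cumulative_importance"] = cum
            outputs["model_quality"] = quality

    for name, table in outputs.items():
        table.to_csv(out_dir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outputs
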
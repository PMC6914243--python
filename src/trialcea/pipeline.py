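"""End-to-end orchestration: generate → outcomes → costs → models → CEA.

A run is fully described by a :class:`RunConfig`; identical config + seed
reproduce byte-identical artifacts. All randomness flows from the run seed
through named substreams (generation/missingness inside the generator, one
bootstrap stream per analysis). Stage outputs are cached by content hash of
their inputs, so re-running with ``reuse=True`` skips stages whose inputs
did not change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from trialcea import __version__
from trialcea import cea as cea_mod
from trialcea.constants import ARM_STANDARD, RESOURCE_PREFIX
from trialcea.costing import UnitCostTable, build_cost_panel, default_unit_cost_table
from trialcea.errors import ConfigurationError, PipelineError
from trialcea.models import ModelSpec, fit_lmm, fit_logistic_mixed
from trialcea.outcomes import RciParams, derive_outcomes
from trialcea.synthetic import (
    GeneratorConfig,
    apply_missingness,
    generate_trial,
    read_dataset,
    write_dataset,
)

DEFAULT_ANALYSES = tuple(
    (p, e) for p in ("societal", "provider") for e in ("response", "episode", "qaly")
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    generator: GeneratorConfig | None = None
    dataset_path: str | None = None
    unit_costs_path: str | None = None
    analyses: tuple[tuple[str, str], ...] = DEFAULT_ANALYSES
    n_draws: int = 1000
    seed: int = 0
    method: str = "cluster_bootstrap"
    wtp_max: float = 80000.0
    wtp_step: float = 1000.0
    sensitivity: tuple[str, ...] = ()
    output_dir: str = "trialcea_run"
    apply_dropout: bool = True
    cumulative_method: str = "rate_trapezoid"
    baseline_window: str = "include"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.dataset_path is None):
            raise ConfigurationError(
                "generator/dataset_path", "exactly one input source must be given"
            )
        for p, e in self.analyses:
            if p not in cea_mod.PERSPECTIVES or e not in cea_mod.EFFECT_KINDS:
                raise ConfigurationError("analyses", f"unknown analysis ({p}, {e})")
        if self.n_draws < 1:
            raise ConfigurationError("n_draws", "must be >= 1")
        if self.wtp_step <= 0 or self.wtp_max < self.wtp_step:
            raise ConfigurationError("wtp", "need wtp_max >= wtp_step > 0")

    @property
    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigurationError("run_config", f"{path} does not contain a mapping")
        data = dict(data)
        if "generator" in data and isinstance(data["generator"], Mapping):
            data["generator"] = GeneratorConfig.from_dict(data["generator"])
        if "analyses" in data:
            data["analyses"] = tuple(tuple(a) for a in data["analyses"])
        if "sensitivity" in data:
            data["sensitivity"] = tuple(data["sensitivity"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError("run_config", str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_dataset(data: pd.DataFrame | str | Path) -> list[str]:
    """Check trial-dataset invariants; returns ALL violations found.

    Checks: exactly one row per patient × week, non-missing baseline scores,
    score and utility ranges, non-negative resource-use counts, and zero
    online sessions / feedback messages in the standard arm.
    """
    if not isinstance(data, pd.DataFrame):
        data = read_dataset(data)
    v: list[str] = []
    dup = data.duplicated(subset=["patient_id", "week"])
    for _, row in data.loc[dup].iterrows():
        v.append(
            f"duplicate row for patient {row['patient_id']} week {row['week']}"
        )
    for pid, grp in data.groupby("patient_id"):
        if 0 not in set(grp["week"]):
            v.append(f"patient {pid}: no baseline (week 0) row")
        else:
            base = grp.loc[grp["week"] == 0].iloc[0]
            if pd.isna(base["ids_sr"]):
                v.append(f"patient {pid}: missing baseline ids_sr")
            if "utility" in grp.columns and pd.isna(base["utility"]):
                v.append(f"patient {pid}: missing baseline utility")
    bad = data.loc[(data["ids_sr"] < 0) | (data["ids_sr"] > 84)]
    for _, row in bad.iterrows():
        v.append(
            f"patient {row['patient_id']} week {row['week']}: ids_sr "
            f"{row['ids_sr']} outside [0, 84]"
        )
    if "utility" in data.columns:
        bad = data.loc[(data["utility"] < -0.33) | (data["utility"] > 1.0)]
        for _, row in bad.iterrows():
            v.append(
                f"patient {row['patient_id']} week {row['week']}: utility "
                f"{row['utility']} outside [-0.33, 1]"
            )
    for col in data.columns:
        if col.startswith(RESOURCE_PREFIX) or col.startswith("n_"):
            bad = data.loc[data[col] < 0]
            for _, row in bad.iterrows():
                v.append(
                    f"patient {row['patient_id']} week {row['week']}: negative {col}"
                )
    if {"arm", "n_online_sessions"} <= set(data.columns):
        std = data.loc[data["arm"] == ARM_STANDARD]
        for col in ("n_online_sessions", "n_feedback_messages"):
            if col in std.columns:
                bad = std.loc[std[col] != 0]
                for pid in bad["patient_id"].unique():
                    v.append(f"patient {pid}: standard arm has nonzero {col}")
    return v


@dataclass
class RunResult:
    """Artifacts and manifest of a completed pipeline run."""

    output_dir: Path
    manifest: dict
    dataset: pd.DataFrame
    outcome_panel: pd.DataFrame
    cost_panel: pd.DataFrame
    summary: pd.DataFrame
    ceac_table: pd.DataFrame


def run_pipeline(config: RunConfig, reuse: bool = False) -> RunResult:
    """Execute the full analysis pipeline and write all artifacts.

    Writes: dataset.csv (if generated), outcomes.csv, costs.csv, models.csv,
    cea_summary.csv, ceac.csv, sensitivity.csv (if requested), and
    manifest.json. Stage failures abort with a stage-named error; the
    manifest flags partially written output.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "complete": False,
    }
    old_manifest = {}
    manifest_path = out / "manifest.json"
    if reuse and manifest_path.exists():
        old_manifest = json.loads(manifest_path.read_text())

    def _cached(stage: str, input_hash: str, path: Path) -> bool:
        prev = old_manifest.get("stages", {}).get(stage, {})
        return (
            reuse
            and prev.get("input_hash") == input_hash
            and path.exists()
            and prev.get("file_hash") == _file_hash(path)
        )

    root = np.random.SeedSequence(config.seed)
    gen_seed = int(root.generate_state(1, dtype=np.uint32)[0])
    analysis_children = root.spawn(len(config.analyses) + len(config.sensitivity))

    # --- stage: dataset -----------------------------------------------------
    stage = "dataset"
    try:
        ds_path = out / "dataset.csv"
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=gen_seed)
            h = _hash({"generator": gen.to_dict(), "dropout": config.apply_dropout})
            if _cached(stage, h, ds_path):
                dataset = read_dataset(ds_path)
            else:
                dataset = generate_trial(gen)
                if config.apply_dropout:
                    dataset = apply_missingness(dataset, gen)
                write_dataset(dataset, ds_path, seed=config.seed)
            manifest["stages"][stage] = {
                "input_hash": h,
                "file_hash": _file_hash(ds_path),
                "n_rows": len(dataset),
            }
        else:
            dataset = read_dataset(config.dataset_path)
            manifest["stages"][stage] = {
                "input_hash": _file_hash(Path(config.dataset_path)),
                "n_rows": len(dataset),
            }
        violations = validate_dataset(dataset)
        if violations:
            raise PipelineError(
                stage, f"{len(violations)} invariant violations; first: {violations[0]}"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: outcomes ----------------------------------------------------
    stage = "outcomes"
    try:
        outcome_panel = derive_outcomes(dataset, RciParams())
        oc_path = out / "outcomes.csv"
        outcome_panel.to_csv(oc_path, index=False)
        manifest["stages"][stage] = {
            "file_hash": _file_hash(oc_path),
            "n_rows": len(outcome_panel),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: costs -------------------------------------------------------
    stage = "costs"
    try:
        table = (
            UnitCostTable.from_file(config.unit_costs_path)
            if config.unit_costs_path
            else default_unit_cost_table()
        )
        cost_panel = build_cost_panel(
            dataset,
            table,
            method=config.cumulative_method,
            baseline_window=config.baseline_window,
        )
        cost_path = out / "costs.csv"
        cost_panel.to_csv(cost_path, index=False)
        manifest["stages"][stage] = {
            "file_hash": _file_hash(cost_path),
            "n_rows": len(cost_panel),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: descriptive mixed models ------------------------------------
    stage = "models"
    try:
        fu = dataset[dataset["week"] != 0].copy()
        base = dataset.loc[dataset["week"] == 0, ["patient_id", "ids_sr"]].rename(
            columns={"ids_sr": "baseline_ids"}
        )
        fu = fu.merge(base, on="patient_id")
        tidy = []
        est = fit_lmm(
            fu, ModelSpec(outcome="ids_sr", baseline_covariate="baseline_ids")
        )
        tidy.append(est.tidy("ids_sr~treat+C(week)+baseline"))
        est = fit_lmm(fu, ModelSpec(outcome="utility"))
        tidy.append(est.tidy("utility~treat+C(week)"))
        model_notes = []
        if fu["episode"].dropna().nunique() > 1:
            from trialcea.errors import ModelError

            try:
                est = fit_logistic_mixed(
                    fu,
                    ModelSpec(
                        outcome="episode", family="binomial", random_intercept=False
                    ),
                )
                tidy.append(est.tidy("episode~treat+C(week)"))
            except ModelError as exc:
                # descriptive model only; flag and carry on with the CEA
                model_notes.append(f"episode model skipped: {exc}")
        models_df = pd.concat(tidy, ignore_index=True)
        models_path = out / "models.csv"
        models_df.to_csv(models_path, index=False)
        manifest["stages"][stage] = {
            "file_hash": _file_hash(models_path),
            "notes": model_notes,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: cost-effectiveness analyses ---------------------------------
    stage = "cea"
    try:
        summary_rows = []
        ceac_rows = []
        for (perspective, effect_kind), child in zip(
            config.analyses, analysis_children
        ):
            frame = cea_mod.build_cea_frame(
                outcome_panel, cost_panel, perspective, effect_kind
            )
            pairs = cea_mod.draw_ce_pairs(
                frame,
                n_draws=config.n_draws,
                seed=int(child.generate_state(1, dtype=np.uint32)[0]),
                method=config.method,
            )
            summary_rows.append(cea_mod.summarize(pairs, config.wtp_grid))
            curve = cea_mod.ceac(pairs, config.wtp_grid)
            cdf = curve.to_frame()
            cdf.insert(0, "effect_kind", effect_kind)
            cdf.insert(0, "perspective", perspective)
            ceac_rows.append(cdf)
            if config.make_plots:
                tag = f"{perspective}_{effect_kind}"
                cea_mod.plot_plane(pairs, out / f"plane_{tag}.png")
                cea_mod.plot_ceac({tag: curve}, out / f"ceac_{tag}.png")
        summary = pd.DataFrame(summary_rows)
        ceac_table = pd.concat(ceac_rows, ignore_index=True)
        summary.to_csv(out / "cea_summary.csv", index=False)
        ceac_table.to_csv(out / "ceac.csv", index=False)
        manifest["stages"][stage] = {
            "file_hash": _file_hash(out / "cea_summary.csv"),
            "n_analyses": len(config.analyses),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: sensitivity -------------------------------------------------
    if config.sensitivity:
        stage = "sensitivity"
        try:
            sens_children = analysis_children[len(config.analyses) :]
            rows = []
            for variant, child in zip(config.sensitivity, sens_children):
                res = cea_mod.sensitivity_suite(
                    outcome_panel,
                    cost_panel,
                    [variant],
                    n_draws=config.n_draws,
                    seed=int(child.generate_state(1, dtype=np.uint32)[0]),
                    method=config.method,
                    wtp_grid=config.wtp_grid,
                )
                rows.append(res[variant])
            sens = pd.DataFrame(rows)
            sens.to_csv(out / "sensitivity.csv", index=False)
            manifest["stages"][stage] = {"file_hash": _file_hash(out / "sensitivity.csv")}
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return RunResult(
        output_dir=out,
        manifest=manifest,
        dataset=dataset,
        outcome_panel=outcome_panel,
        cost_panel=cost_panel,
        summary=summary,
        ceac_table=ceac_table,
    )
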
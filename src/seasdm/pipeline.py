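"""End-to-end orchestration: simulate → prep → stack → fit → evaluate →
ensemble → exposure, from a single validated configuration.

A run is driven by a :class:`RunConfig` (YAML-loadable) and a master
seed; every stage derives its own substream seed from the master seed
and a stable stage label, so outputs are reproducible and adding a
stage never perturbs another.  Artifacts are written under the run's
output directory with a JSON manifest and a line-delimited JSON log.
"""

from __future__ import annotations

import csv
import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import Point, binarize, ensemble, exposure_summary, extract_at_points
from .evaluation import (
    minimum_training_presence_threshold,
    permutation_importance,
    rank_importance,
)
from .grids import GridSpec, RasterLayer, read_ascii_grid, write_ascii_grid
from .models import MODEL_FORM_NAMES, cross_validate, fit_model, predict_surface
from .occurrences import (
    SUBSET_KEYS,
    SubsetKey,
    filter_records,
    make_subsets,
    parse_occurrences,
    rasterize_occurrences,
    write_occurrence_csv,
)
from .predictors import (
    PredictorStack,
    adjacent_season_temperature,
    assemble_training_table,
    correlation_screen,
    sample_background,
    seasonal_mean_temperature,
    seasonal_temperature_range,
)
from .synthetic import default_scenario, seed_for, write_fixture_bundle

STAGES = ("simulate", "prep", "stack", "fit", "evaluate", "ensemble", "exposure")


class PipelineError(RuntimeError):
    """A stage failed; partial results were recorded in the manifest."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults mirror the method's
    standard constants (50-km error cap, r > 0.70 screen, 10,000
    background pixels, 10-fold cross-validation)."""

    out_dir: str = "run_output"
    synthetic: bool = True
    input_manifest: str | None = None  # fixture-bundle manifest for file mode
    grid_rows: int = 100
    grid_cols: int = 100
    subsets: list[str] = field(default_factory=lambda: [k.label for k in SUBSET_KEYS])
    forms: list[str] = field(default_factory=lambda: list(MODEL_FORM_NAMES))
    hyperparameters: dict = field(default_factory=dict)  # form -> overrides
    seed: int = 0
    max_error_km: float = 50.0
    correlation_threshold: float = 0.70
    background_n: int = 10_000
    cv_folds: int = 10
    importance_repeats: int = 10
    exposure_bins: int = 10
    n_turbines: int = 5000
    quicklooks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                data = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"unparseable config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every violation (not fail-fast); empty list means valid."""
    v: list[str] = []
    valid_subsets = {k.label for k in SUBSET_KEYS}
    for s in config.subsets:
        if s not in valid_subsets:
            v.append(f"unknown subset {s!r}")
    for f in config.forms:
        if f not in MODEL_FORM_NAMES:
            v.append(f"unknown model form {f!r}")
    for f in config.hyperparameters:
        if f not in MODEL_FORM_NAMES:
            v.append(f"hyperparameters given for unknown form {f!r}")
    if config.cv_folds < 2:
        v.append(f"cv_folds must be >= 2, got {config.cv_folds}")
    if config.max_error_km <= 0:
        v.append("max_error_km must be positive")
    if not (0 < config.correlation_threshold <= 1):
        v.append("correlation_threshold must be in (0, 1]")
    if config.background_n < 1:
        v.append("background_n must be >= 1")
    if config.importance_repeats < 1:
        v.append("importance_repeats must be >= 1")
    if config.grid_rows < 1 or config.grid_cols < 1:
        v.append("grid must have positive dimensions")
    if not config.synthetic:
        if config.input_manifest is None:
            v.append("file mode requires input_manifest")
        elif not Path(config.input_manifest).exists():
            v.append(f"input_manifest path does not exist: {config.input_manifest}")
    return v


# --------------------------------------------------------------------------
# Stack construction

#: Canonical per-season covariate names after stack assembly.
def season_variable_names(season: str) -> list[str]:
    adjacent = "next_season_temp" if season == "autumn" else "prior_season_temp"
    return ["mean_temp", adjacent, "temp_range",
            "precip_seasonality", "season_length", "tree_cover"]


def build_candidate_stack(
    landscape: dict[str, RasterLayer],
    season: str,
    include_elevation: bool = True,
    trange_scale: float = 0.1,
) -> PredictorStack:
    """Assemble one season's candidate covariates from landscape layers.

    ``landscape`` maps layer names to rasters and must contain monthly
    ``tmean_01..12`` and ``trange_01..12`` plus ``precip_seasonality``,
    ``season_length``, ``tree_cover`` (and ``elevation`` when included
    as a screening candidate).
    """
    tmean = [landscape[f"tmean_{m:02d}"] for m in range(1, 13)]
    trange = [landscape[f"trange_{m:02d}"] for m in range(1, 13)]
    layers: dict[str, RasterLayer] = {}
    provenance: dict[str, str] = {}
    mt = seasonal_mean_temperature(tmean, season)
    layers["mean_temp"] = mt.with_values(mt.values, "mean_temp")
    provenance["mean_temp"] = f"mean of monthly tmean over {season} months"
    if season == "autumn":
        adj = adjacent_season_temperature(tmean, season, "next")
        layers["next_season_temp"] = adj.with_values(adj.values, "next_season_temp")
        provenance["next_season_temp"] = "mean winter temperature (next season)"
    else:
        adj = adjacent_season_temperature(tmean, season, "prior")
        layers["prior_season_temp"] = adj.with_values(adj.values, "prior_season_temp")
        provenance["prior_season_temp"] = "mean temperature of the prior season"
    tr = seasonal_temperature_range(trange, season, input_scale=trange_scale)
    layers["temp_range"] = tr.with_values(tr.values, "temp_range")
    provenance["temp_range"] = "mean monthly temperature range (rescaled from degC x10)"
    for name in ("precip_seasonality", "season_length", "tree_cover"):
        layers[name] = landscape[name]
        provenance[name] = "direct input layer"
    if include_elevation and "elevation" in landscape:
        layers["elevation"] = landscape["elevation"]
        provenance["elevation"] = "screening candidate only"
    return PredictorStack(season, layers, provenance)


# --------------------------------------------------------------------------
# Runner

def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Log:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.lines: list[dict] = []

    def event(self, stage: str, **payload) -> None:
        line = {"stage": stage, **payload}
        self.lines.append(line)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(line, sort_keys=True, default=str) + "\n")


def _load_inputs(config: RunConfig, out_dir: Path, log: _Log):
    """Simulate stage (or load a pre-built fixture bundle)."""
    if config.synthetic:
        scenario = default_scenario(
            seed=seed_for(config.seed, "stage:simulate"),
            n_rows=config.grid_rows,
            n_cols=config.grid_cols,
        )
        scenario.n_turbines = config.n_turbines
        bundle_dir = out_dir / "inputs"
        manifest = write_fixture_bundle(scenario, bundle_dir)
    else:
        bundle_dir = Path(config.input_manifest).parent
        with open(config.input_manifest) as fh:
            manifest = json.load(fh)
    landscape = {
        name: read_ascii_grid(bundle_dir / rel, name=name)
        for name, rel in manifest["files"]["rasters"].items()
    }
    occ_path = bundle_dir / manifest["files"]["occurrences"]
    turb_path = bundle_dir / manifest["files"]["turbines"]
    log.event("simulate", n_rasters=len(landscape),
              occurrences=str(occ_path), turbines=str(turb_path))
    return landscape, occ_path, turb_path


def _read_turbines(path: Path) -> list[Point]:
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(Point(row["id"], float(row["x_km"]), float(row["y_km"])))
    return points


def run_pipeline(config: RunConfig, through: str = "exposure") -> dict:
    """Execute the pipeline up to (and including) stage ``through``.

    Returns the run manifest.  A stage failure writes a partial-results
    manifest with the failure record and raises :class:`PipelineError`.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(out_dir / "log.jsonl")
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages_completed": [],
        "artifacts": {},
    }

    def finish(stage: str, error: str | None = None) -> None:
        if error is None:
            manifest["stages_completed"].append(stage)
        else:
            manifest["failure"] = {"stage": stage, "error": error}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    stage = "simulate"
    try:
        t0 = time.time()
        landscape, occ_path, turb_path = _load_inputs(config, out_dir, log)
        manifest["input_hashes"] = {
            "occurrences": _hash_file(occ_path),
            "turbines": _hash_file(turb_path),
        }
        finish(stage)
        if last == 0:
            return manifest

        # ---------------- prep
        stage = "prep"
        grid = next(iter(landscape.values())).grid
        parsed = parse_occurrences(occ_path)
        kept, dropped = filter_records(parsed.records, config.max_error_km)
        subset_result = make_subsets(kept)
        reasons: dict[str, int] = {}
        for _, reason in dropped:
            key = reason.split("=")[0]
            reasons[key] = reasons.get(key, 0) + 1
        subset_dir = out_dir / "subsets"
        subset_dir.mkdir(exist_ok=True)
        occupied = {}
        qc = {
            "n_parsed": len(parsed.records),
            "n_parse_rejects": len(parsed.rejects),
            "n_kept": len(kept),
            "n_dropped": len(dropped),
            "dropped_by_reason": reasons,
            "n_unknown_sex_excluded": subset_result.n_unknown_sex_excluded,
            "subsets": {},
        }
        for key in SUBSET_KEYS:
            if key.label not in config.subsets:
                continue
            recs = subset_result.subsets[key]
            occupied[key] = rasterize_occurrences(recs, grid, key)
            write_occurrence_csv(recs, subset_dir / f"{key.label}.csv")
            qc["subsets"][key.label] = {
                "n_records": len(recs),
                "n_locations": occupied[key].n_locations,
            }
        with open(out_dir / "qc_report.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        log.event("prep", n_kept=len(kept), n_dropped=len(dropped),
                  subsets={k.label: v["n_records"] for k, v in
                           zip(occupied, qc["subsets"].values())})
        finish(stage)
        if last == 1:
            return manifest

        # ---------------- stack
        stage = "stack"
        stacks: dict[SubsetKey, PredictorStack] = {}
        screen_rows = []
        seasons_needed = {k.season for k in occupied}
        season_stacks: dict[str, PredictorStack] = {}
        for season in sorted(seasons_needed):
            candidate = build_candidate_stack(landscape, season)
            retained, report = correlation_screen(
                candidate.layers,
                threshold=config.correlation_threshold,
                seed=seed_for(config.seed, f"stage:stack:{season}"),
            )
            season_stacks[season] = candidate.subset(retained)
            for pair in report.flagged_pairs:
                screen_rows.append({"season": season, **pair})
            log.event("stack", season=season, retained=retained,
                      dropped=report.dropped)
        for key in occupied:
            stacks[key] = season_stacks[key.season]
        pd.DataFrame(
            screen_rows,
            columns=["season", "name_a", "name_b", "pearson_r", "spearman_r", "dropped"],
        ).to_csv(out_dir / "screening_report.csv", index=False)
        stack_manifest = {
            season: {
                name: {
                    "units": stk.layers[name].units,
                    "provenance": stk.provenance.get(name, ""),
                }
                for name in stk.names
            }
            for season, stk in season_stacks.items()
        }
        with open(out_dir / "stack_manifest.json", "w") as fh:
            json.dump(stack_manifest, fh, indent=2, sort_keys=True)
        finish(stage)
        if last == 2:
            return manifest

        # ---------------- fit
        stage = "fit"
        model_dir = out_dir / "models"
        model_dir.mkdir(exist_ok=True)
        tables = {}
        fits = {}
        model_files = []
        for key in occupied:
            background = sample_background(
                grid, config.background_n,
                seed=seed_for(config.seed, f"stage:fit:background:{key.label}"),
            )
            tables[key] = assemble_training_table(occupied[key], background, stacks[key])
            for form in config.forms:
                model = fit_model(
                    form, tables[key],
                    hp=config.hyperparameters.get(form),
                    seed=seed_for(config.seed, f"stage:fit:{key.label}:{form}"),
                )
                fits[(key, form)] = model
                path = model_dir / f"{key.label}_{form}.pkl"
                with open(path, "wb") as fh:
                    pickle.dump({"version": __version__, "form": form,
                                 "subset": key.label, "model": model}, fh)
                model_files.append(str(path.relative_to(out_dir)))
                log.event("fit", subset=key.label, form=form,
                          n_rows=len(tables[key].frame),
                          n_presence=tables[key].n_presence)
        manifest["artifacts"]["models"] = model_files
        finish(stage)
        if last == 3:
            return manifest

        # ---------------- evaluate
        stage = "evaluate"
        auc_tbl: dict[str, dict[str, float]] = {f: {} for f in config.forms}
        ss_tbl: dict[str, dict[str, str]] = {f: {} for f in config.forms}
        importance_rows = []
        for key in occupied:
            table = tables[key]
            deltas = pd.DataFrame(
                index=table.covariate_names, columns=config.forms, dtype=float
            )
            for form in config.forms:
                cv = cross_validate(
                    form, table, k=config.cv_folds,
                    seed=seed_for(config.seed, f"stage:evaluate:cv:{key.label}:{form}"),
                    hp=config.hyperparameters.get(form),
                )
                auc_tbl[form][key.label] = round(cv.mean_auc, 3)
                ss_tbl[form][key.label] = (
                    f"{cv.mean_sensitivity:.3f}/{cv.mean_specificity:.3f}"
                )
                model = fits[(key, form)]
                for var in table.covariate_names:
                    deltas.loc[var, form] = permutation_importance(
                        model, table.X, table.y, table.covariate_names, var,
                        n_repeats=config.importance_repeats,
                        seed=seed_for(
                            config.seed,
                            f"stage:evaluate:perm:{key.label}:{form}:{var}",
                        ),
                    )
            for vi in rank_importance(deltas):
                importance_rows.append({
                    "subset": key.label, "variable": vi.variable,
                    **{f: round(vi.per_form[f], 3) for f in config.forms},
                    "mean_delta_auc": round(vi.mean_delta_auc, 3),
                    "rank": vi.rank,
                })
            log.event("evaluate", subset=key.label,
                      auc={f: auc_tbl[f][key.label] for f in config.forms})
        labels = [k.label for k in occupied]
        pd.DataFrame(auc_tbl).T.loc[config.forms, labels].to_csv(
            out_dir / "metrics_auc.csv", index_label="form"
        )
        pd.DataFrame(ss_tbl).T.loc[config.forms, labels].to_csv(
            out_dir / "metrics_sensitivity_specificity.csv", index_label="form"
        )
        pd.DataFrame(importance_rows).to_csv(
            out_dir / "importance.csv", index=False
        )
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump({"auc": auc_tbl, "sensitivity_specificity": ss_tbl,
                       "importance": importance_rows}, fh, indent=2, sort_keys=True)
        finish(stage)
        if last == 4:
            return manifest

        # ---------------- ensemble
        stage = "ensemble"
        map_dir = out_dir / "maps"
        map_dir.mkdir(exist_ok=True)
        ensembles = {}
        map_files = []
        for key in occupied:
            binaries = []
            for form in config.forms:
                model = fits[(key, form)]
                thr = minimum_training_presence_threshold(
                    model, tables[key].presence_X()
                )
                surface = predict_surface(model, stacks[key])
                binaries.append(binarize(surface, thr))
            emap = ensemble(binaries, subset=key, forms=list(config.forms))
            ensembles[key] = emap
            path = map_dir / f"ensemble_{key.label}.asc"
            write_ascii_grid(emap.layer, path)
            map_files.append(str(path.relative_to(out_dir)))
            if config.quicklooks:
                _quicklook(emap.layer, map_dir / f"ensemble_{key.label}.png")
            log.event("ensemble", subset=key.label,
                      mean_value=float(np.nanmean(emap.values)))
        manifest["artifacts"]["ensemble_maps"] = map_files
        finish(stage)
        if last == 5:
            return manifest

        # ---------------- exposure
        stage = "exposure"
        turbines = _read_turbines(turb_path)
        summary_rows = []
        for key in occupied:
            values, n_excluded = extract_at_points(ensembles[key], turbines)
            summ = exposure_summary(values, n_bins=config.exposure_bins, subset=key)
            summary_rows.append({
                "subset": key.label, "n_points": summ.n_points,
                "n_excluded": n_excluded,
                "mean": round(summ.mean, 3), "min": round(summ.min, 3),
                "max": round(summ.max, 3),
                "skewness": None if summ.skewness is None else round(summ.skewness, 3),
            })
            hist = pd.DataFrame({
                "bin_low": summ.bin_edges[:-1], "bin_high": summ.bin_edges[1:],
                "count": summ.counts,
            })
            hist.to_csv(out_dir / f"exposure_hist_{key.label}.csv", index=False)
            log.event("exposure", subset=key.label, mean=summary_rows[-1]["mean"],
                      n_points=summ.n_points)
        pd.DataFrame(summary_rows).to_csv(out_dir / "exposure_summary.csv", index=False)
        finish(stage)
        return manifest
    except Exception as exc:  # record the failing stage, then re-raise
        finish(stage, error=str(exc))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _quicklook(layer: RasterLayer, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(layer.values, origin="lower", vmin=0, vmax=1, cmap="Blues")
    ax.set_title(layer.name, fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
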
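"""End-to-end orchestration: simulate / extract -> weekly deltas -> filter ->
rank -> incremental-K models -> stability, with deterministic seeding,
structured exclusion logging and a reproducibility manifest.

Every stage output is a pure function of (inputs, config, master seed): stage
seeds are spawned from the master seed in a fixed order, and reports are
written with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delta import WindowSpec, baseline_values, delta_grouped, delta_single_week, weekly_mean
from .features import ExtractionConfig, extract_all
from .modeling import ModelConfig, k_sweep, threshold_metrics
from .preprocess import ParameterError, read_nifti, read_nifti_mask
from .selection import SelectionConfig, rf_rank, spearman_filter
from .stability import compute_stability
from .synthetic import SyntheticCohortSpec, generate_feature_cohort
from .voladjust import apply_volume_adjustment, default_rules

DEFAULT_WINDOWS = ("2", "1-4", "1-6")


@dataclass(frozen=True)
class PipelineConfig:
    windows: tuple[str, ...] = DEFAULT_WINDOWS
    seed: int = 0
    # input: exactly one of cohort (simulate), features_csv, images_dir
    cohort: SyntheticCohortSpec | None = None
    features_csv: str | None = None
    outcomes_csv: str | None = None
    images_dir: str | None = None
    fractions_per_week: int = 5
    min_fractions: int = 3
    rho_threshold: float = 0.8
    n_trees: int = 500
    k_max: int = 7
    n_iterations: int = 1000
    train_fraction: float = 2 / 3
    eval_population: str = "all_patients"
    threshold: float = 0.5
    iso_mm: float = 1.0
    n_gray_levels: int = 32
    run_stability: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"] = asdict(self.cohort)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = raw.pop("cohort", None)
    if cohort is not None:
        for key in ("drift_features", "feature_names", "grid_shape", "spacing",
                    "roi_shape", "skew_shape_drift"):
            if key in cohort:
                cohort[key] = tuple(tuple(v) if isinstance(v, list) else v
                                    for v in cohort[key]) if key == "drift_features" \
                    else tuple(cohort[key])
        cohort = SyntheticCohortSpec(**cohort)
    if "windows" in raw:
        raw["windows"] = tuple(str(w) for w in raw["windows"])
    return PipelineConfig(cohort=cohort, **raw)


# ---------------------------------------------------------------------------
# image-directory extraction

_IMG_RE = re.compile(r"^(?P<pid>.+)_f(?P<frac>\d+)_img\.nii(\.gz)?$")


def extract_feature_table(images_dir: str | Path, extraction: ExtractionConfig,
                          fractions_per_week: int = 5) -> pd.DataFrame:
    """Extract the volume-adjusted feature table from a directory of
    ``<pid>_f<NN>_img.nii.gz`` / ``<pid>_f<NN>_mask.nii.gz`` pairs."""
    images_dir = Path(images_dir)
    rules = default_rules()
    records = []
    entries = []
    for p in sorted(images_dir.iterdir()):
        m = _IMG_RE.match(p.name)
        if m:
            entries.append((m["pid"], int(m["frac"]), p))
    if not entries:
        raise ParameterError(f"images_dir: no image/mask pairs found in {images_dir}")
    for pid, frac, img_path in sorted(entries):
        mask_path = Path(str(img_path).replace("_img.nii", "_mask.nii"))
        img = read_nifti(img_path)
        mask = read_nifti_mask(mask_path)
        week = 1 + (frac - 1) // fractions_per_week
        fv = extract_all(img, mask, extraction, patient_id=pid,
                         fraction=frac, week=week)
        fv = apply_volume_adjustment(fv, rules)
        for name, value in fv.values.items():
            records.append({"patient_id": pid, "fraction": frac, "week": week,
                            "feature_name": name, "value": value})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# run

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and persist results; returns the summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows = [WindowSpec.parse(w) for w in cfg.windows]

    ss = np.random.SeedSequence(cfg.seed)
    cohort_child, *window_children = ss.spawn(1 + 2 * len(windows))

    def child_seed(child) -> int:
        return int(child.generate_state(1)[0] % (2 ** 31))

    # ---- inputs
    exclusions: list[dict] = []
    if cfg.cohort is not None:
        spec = replace(cfg.cohort, seed=child_seed(cohort_child))
        cohort = generate_feature_cohort(spec)
        table, outcomes = cohort.features, cohort.outcomes
    elif cfg.features_csv is not None:
        table = pd.read_csv(cfg.features_csv)
        outcomes = pd.read_csv(cfg.outcomes_csv).set_index("patient_id")["label"]
    elif cfg.images_dir is not None:
        extraction = ExtractionConfig(iso_mm=cfg.iso_mm,
                                      discretization_param=cfg.n_gray_levels)
        table = extract_feature_table(cfg.images_dir, extraction,
                                      cfg.fractions_per_week)
        outcomes = pd.read_csv(Path(cfg.images_dir) / "outcomes.csv"
                               ).set_index("patient_id")["label"]
    else:
        raise ParameterError("input: set one of cohort, features_csv, images_dir")
    table.to_csv(out / "fraction_features.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv")

    # ---- aggregation
    weekly = weekly_mean(table, min_fractions=cfg.min_fractions)
    baseline = baseline_values(table)

    sel_base = SelectionConfig(rho_threshold=cfg.rho_threshold, n_trees=cfg.n_trees)
    model_base = ModelConfig(k_max=cfg.k_max, n_iterations=cfg.n_iterations,
                             train_fraction=cfg.train_fraction,
                             eval_population=cfg.eval_population,
                             threshold=cfg.threshold)

    summary: dict = {"windows": {}}
    for wi, window in enumerate(windows):
        dt = delta_grouped(weekly, baseline, window)
        exclusions.extend(dt.exclusions)
        slug = window.label.lower().replace(" ", "_")
        dt.data.to_csv(out / f"delta_{slug}.csv")

        sel_cfg = replace(sel_base, rf_seed=child_seed(window_children[2 * wi]))
        filt = spearman_filter(dt.data, sel_cfg)
        filt.correlation.to_csv(out / f"correlation_{slug}.csv")
        ranking = rf_rank(dt.data[filt.retained_features], outcomes, sel_cfg,
                          prior=filt)
        pd.DataFrame({"feature_name": list(ranking.importances),
                      "importance": list(ranking.importances.values())}
                     ).to_csv(out / f"importance_{slug}.csv", index=False)

        model_cfg = replace(model_base,
                            seed=child_seed(window_children[2 * wi + 1]))
        sweep = k_sweep(dt.data, outcomes, ranking, model_cfg,
                        window_label=window.label)
        best = sweep.optimal
        pd.DataFrame({"iteration": np.arange(1, len(best.aucs) + 1),
                      "auc": best.aucs}).to_csv(
            out / f"iteration_aucs_{slug}.csv", index=False)
        thr = threshold_metrics(best, cfg.threshold)

        report = {
            "window": window.label,
            "weeks": list(window.weeks),
            "n_features_input": int(dt.data.shape[1]),
            "n_features_retained": len(ranking.retained_features),
            "removed_pairs": [
                {"kept": k, "dropped": d, "rho": float(r)}
                for k, d, r in ranking.removed_pairs],
            "importances": {f: float(v) for f, v in ranking.importances.items()},
            "positive_set": ranking.positive_set,
            "optimal_k": sweep.optimal_k,
            "selected_features": best.features,
            "mean_auc": best.mean_auc,
            "ci": [best.ci_low, best.ci_high],
            "auc_by_k": {str(k): {"mean_auc": r.mean_auc,
                                  "ci": [r.ci_low, r.ci_high],
                                  "features": r.features}
                         for k, r in sweep.results.items()},
            "threshold_metrics": thr.summary(),
            "n_redrawn_subsets": best.n_redrawn,
            "n_unconverged_fits": best.n_unconverged,
        }
        _write_json(out / f"report_{slug}.json", report)
        top_feature = next(iter(ranking.importances))
        summary["windows"][window.label] = {
            "mean_auc": best.mean_auc, "ci": [best.ci_low, best.ci_high],
            "optimal_k": sweep.optimal_k,
            "n_features_retained": len(ranking.retained_features),
            "selected_features": best.features,
            "top_feature": top_feature,
            "top_importance": ranking.importances[top_feature],
        }

    # ---- stability (diagnostic only)
    if cfg.run_stability:
        all_weeks = sorted(weekly["week"].unique())
        weekly_tables = [delta_single_week(weekly, baseline, w) for w in all_weeks]
        stab = compute_stability(weekly_tables)
        stab.to_csv(out / "stability.csv", index=False)

    with open(out / "exclusions.jsonl", "w") as fh:
        for rec in exclusions:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=_jsonable)
    manifest = {
        "deltarad_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg_dict,
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "summary.json", summary)
    return summary
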
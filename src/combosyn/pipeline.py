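"""Experiment orchestration: the exploratory ladder, single experiments,
and the screening-center comparison.

These functions tie the lower-level modules together the way the study's
experiments are structured: per-cell-line models, shared partitions where
designs are compared, reliability strata for forests, and summary tables
per step or per center.  Each entry point is a pure function of an
:class:`ExperimentConfig` plus the data, so runs are reproducible from the
config and seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .chem_features import FeatureConfig, featurize_library
from .dataset import (
    PairSample,
    build_table,
    kfold,
    lodo_folds,
    permute_targets,
    random_split,
)
from .evaluation import compute_metrics, lodo_summary, replicate_variability, stratified_report
from .models import (
    ModelSpec,
    RF_BASELINE,
    reliability_strata,
    predict,
    train,
    tune_xgb,
)
from .simulate import SynthConfig, emit_grids, generate_drug_library, plant_synergy, synthetic_labels

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One experiment: data source, features, model, validation scheme."""

    synth: SynthConfig | None = None
    structures_path: str | None = None
    screen_csv_path: str | None = None
    feature_cfg: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    scheme: str = "split"  # split | kfold | lodo | yrand
    test_fraction: float = 0.1
    k: int = 5
    yrand_seeds: int = 11
    reliability_quantile: float = 0.25
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_synth = self.synth is not None
        has_files = self.structures_path is not None and self.screen_csv_path is not None
        if has_synth == has_files:
            raise ValueError("configure exactly one data source (synthetic or files)")
        if self.scheme not in ("split", "kfold", "lodo", "yrand"):
            raise ValueError(f"unknown validation scheme {self.scheme!r}")


def config_hash(cfg: ExperimentConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def assemble_synthetic(
    cfg: SynthConfig,
    feature_cfg: FeatureConfig | None = None,
    center_code: str | None = None,
) -> dict[str, list[PairSample]]:
    """Generate a synthetic screen and return per-cell-line sample tables."""
    feature_cfg = feature_cfg or FeatureConfig()
    library = generate_drug_library(cfg)
    truth, features = plant_synergy(library, cfg, feature_cfg)
    labels = synthetic_labels(truth, cfg, center_code)
    return {
        cell: build_table(features, cell_labels, cell)
        for cell, cell_labels in sorted(labels.items())
    }


def _fit_eval(
    samples: list[PairSample],
    fold,
    spec: ModelSpec,
    augment: bool,
    quantile: float | None = None,
    context: dict | None = None,
) -> dict:
    """Train on a fold's training rows, evaluate on its test rows."""
    tr = [samples[i] for i in fold.train_idx]
    te = [samples[i] for i in fold.test_idx]
    model = train(tr, spec, augment=augment)
    preds = predict(model, te)
    y_obs = np.array([s.target for s in te])
    y_pred = np.array([p.y_pred for p in preds])
    ctx = {**(context or {}), "fold": fold.name, "algorithm": spec.algorithm}
    report = compute_metrics(y_obs, y_pred, context=ctx)
    out = {"report": report, "predictions": preds, "y_obs": y_obs}
    if spec.algorithm == "rf" and quantile is not None and len(te) >= 4:
        strata = reliability_strata(preds, q=quantile)
        out["strata"] = strata
        out["stratified"] = stratified_report(preds, y_obs, strata, context=ctx)
    return out


LADDER_STEPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def run_ladder(
    cfg: SynthConfig,
    steps: tuple[str, ...] = LADDER_STEPS,
    seed: int = 0,
    fp_length: int = 256,
) -> dict:
    """The eight-step exploratory modeling ladder on synthetic data.

    Steps are cumulative modeling choices, evaluated per cell line:

    I    RF baseline (1000 trees, all features), 80/20 split, MACCS keys
    II   counted Morgan fingerprints instead of MACCS
    III  physico-chemical features added
    IV   training rows duplicated in reverse drug order (augmentation)
    V    90/10 split instead of 80/20
    VI   RF tuned: 250 trees, a third of features per split
    VII  XGBoost with recommended settings
    VIII XGBoost with a tuned grid

    Returns per-step, per-cell-line Pearson r plus per-step medians.
    """
    unknown = [s for s in steps if s not in LADDER_STEPS]
    if unknown:
        raise ValueError(f"unknown ladder steps: {unknown}")

    library = generate_drug_library(cfg)
    feature_sets = {
        "maccs": FeatureConfig(blocks=("maccs",), fp_length=fp_length),
        "mfpc": FeatureConfig(blocks=("mfpc",), fp_length=fp_length),
        "mfpc+physchem": FeatureConfig(blocks=("mfpc", "physchem"), fp_length=fp_length),
    }
    truth, _ = plant_synergy(library, cfg)
    labels = synthetic_labels(truth, cfg)
    features_by_set = {
        name: featurize_library(library, fc)[0] for name, fc in feature_sets.items()
    }

    presets = {
        "I": ("maccs", False, 0.2, ModelSpec("rf", dict(RF_BASELINE), seed)),
        "II": ("mfpc", False, 0.2, ModelSpec("rf", dict(RF_BASELINE), seed)),
        "III": ("mfpc+physchem", False, 0.2, ModelSpec("rf", dict(RF_BASELINE), seed)),
        "IV": ("mfpc+physchem", True, 0.2, ModelSpec("rf", dict(RF_BASELINE), seed)),
        "V": ("mfpc+physchem", True, 0.1, ModelSpec("rf", dict(RF_BASELINE), seed)),
        "VI": ("mfpc+physchem", True, 0.1, ModelSpec("rf", seed=seed)),
        "VII": ("mfpc+physchem", True, 0.1, ModelSpec("xgb", seed=seed)),
        "VIII": ("mfpc+physchem", True, 0.1, None),  # tuned per cell line
    }

    rows = []
    train_counts: dict[tuple[str, str], int] = {}
    for cell, cell_labels in sorted(labels.items()):
        for step in steps:
            feat_name, augment, test_frac, spec = presets[step]
            samples = build_table(features_by_set[feat_name], cell_labels, cell)
            fold = random_split(samples, test_fraction=test_frac, seed=seed)
            if spec is None:  # tuned XGB
                tr = [samples[i] for i in fold.train_idx]
                spec = tune_xgb(tr, seed=seed)
            result = _fit_eval(samples, fold, spec, augment, context={"cell_line": cell, "step": step})
            n_train = len(fold.train_idx) * (2 if augment else 1)
            train_counts[(cell, step)] = n_train
            rows.append(
                {
                    "step": step,
                    "cell_line": cell,
                    "r_p": result["report"].r_p,
                    "rmse": result["report"].rmse,
                    "n_train_rows": n_train,
                    "n_test": result["report"].n,
                }
            )
    medians = {
        step: float(np.median([r["r_p"] for r in rows if r["step"] == step]))
        for step in steps
    }
    return {"rows": rows, "median_r_p_by_step": medians, "train_counts": train_counts}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one validation experiment per the configured scheme.

    ``split``: one random split per cell line, with reliability strata for
    forests.  ``kfold``/``lodo``: per-fold reports and a summary.
    ``yrand``: Y-randomized retraining over ``yrand_seeds`` permutation
    seeds, reporting the per-seed test Pearson r and its median.
    """
    if config.scheme == "yrand" and config.yrand_seeds < 1:
        raise ValueError("yrand requires at least one permutation seed")
    if config.reliability_quantile is not None and config.model.algorithm != "rf" and config.scheme == "split":
        if config.model.algorithm in ("xgb", "en") and config.reliability_quantile != 0.25:
            raise ValueError("reliability strata require a random forest model")
    tables = assemble_synthetic(config.synth, config.feature_cfg)

    out: dict = {"config_hash": config_hash(config), "scheme": config.scheme, "cell_lines": {}}
    for cell, samples in tables.items():
        ctx = {"cell_line": cell}
        if config.scheme == "split":
            fold = random_split(samples, config.test_fraction, config.seed)
            res = _fit_eval(
                samples, fold, config.model, config.augment,
                quantile=config.reliability_quantile if config.model.algorithm == "rf" else None,
                context=ctx,
            )
            entry = {"report": res["report"]}
            if "stratified" in res:
                entry["stratified"] = res["stratified"]
            out["cell_lines"][cell] = entry
        elif config.scheme == "kfold":
            reports = []
            for fold in kfold(samples, config.k, config.seed):
                res = _fit_eval(samples, fold, config.model, config.augment, context=ctx)
                reports.append(res["report"])
            out["cell_lines"][cell] = {"fold_reports": reports}
        elif config.scheme == "lodo":
            reports = []
            for fold in lodo_folds(samples):
                res = _fit_eval(
                    samples, fold, config.model, config.augment,
                    context={**ctx, "left_out_drug": fold.left_out_drug},
                )
                r = res["report"]
                r.context["left_out_drug"] = fold.left_out_drug
                reports.append(r)
            out["cell_lines"][cell] = {"fold_reports": reports}
        else:  # yrand
            fold = random_split(samples, config.test_fraction, config.seed)
            r_ps = []
            for ps in range(config.yrand_seeds):
                shuffled = permute_targets(samples, seed=ps)
                res = _fit_eval(shuffled, fold, config.model, config.augment, context=ctx)
                r_ps.append(res["report"].r_p)
            out["cell_lines"][cell] = {
                "r_p_per_seed": r_ps,
                "median_r_p": float(np.median(r_ps)),
            }
    if config.scheme == "lodo":
        all_reports = [
            r for entry in out["cell_lines"].values() for r in entry["fold_reports"]
        ]
        out["lodo_summary"] = lodo_summary(all_reports)
    if config.scheme == "yrand":
        all_rp = [v for entry in out["cell_lines"].values() for v in entry["r_p_per_seed"]]
        out["median_r_p"] = float(np.median(all_rp))
    return out


def run_center_compare(
    cfg: SynthConfig,
    feature_cfg: FeatureConfig | None = None,
    model: ModelSpec | None = None,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Paired per-center modeling plus replicate-variability comparison.

    Each configured center's labels are modeled separately on shared
    partitions (identical pair keys in train/test across centers, since
    the synthetic centers measure the same tuples), yielding a paired
    per-cell-line table of test Pearson r and RMSE.  Single-agent
    replicate sets matched across centers are compared by their growth SD.
    """
    if len(cfg.centers) < 2:
        raise ValueError("center comparison requires at least 2 centers")
    feature_cfg = feature_cfg or FeatureConfig()
    model = model or ModelSpec("rf")
    library = generate_drug_library(cfg)
    truth, features = plant_synergy(library, cfg, feature_cfg)
    _, singles = emit_grids(truth, cfg)

    per_center_tables = {}
    for center in cfg.centers:
        labels = synthetic_labels(truth, cfg, center.code)
        per_center_tables[center.code] = {
            cell: build_table(features, cl, cell) for cell, cl in sorted(labels.items())
        }

    codes = [c.code for c in cfg.centers]
    cells = sorted(per_center_tables[codes[0]])
    rows = []
    for cell in cells:
        row = {"cell_line": cell}
        # shared partition: split on the first center's table; tuples match
        ref = per_center_tables[codes[0]][cell]
        fold = random_split(ref, test_fraction, seed)
        ref_keys = [ref[i].key for i in fold.test_idx]
        for code in codes:
            samples = per_center_tables[code][cell]
            keymap = {s.key: i for i, s in enumerate(samples)}
            test_idx = np.array([keymap[k] for k in ref_keys])
            train_idx = np.array(sorted(set(range(len(samples))) - set(test_idx)))
            from .dataset import FoldSpec

            cfold = FoldSpec(name=fold.name, train_idx=train_idx, test_idx=test_idx)
            res = _fit_eval(samples, cfold, model, augment=True, context={"cell_line": cell, "center": code})
            row[code] = {"r_p": res["report"].r_p, "rmse": res["report"].rmse}
        rows.append(row)

    median_r_p = {
        code: float(np.median([row[code]["r_p"] for row in rows])) for code in codes
    }
    noisier = max(cfg.centers, key=lambda c: c.replicate_noise_sd).code

    rep = replicate_variability(singles)
    pair_codes = codes[:2]
    n_larger = 0
    n_matched = 0
    for p in rep["paired_sets"]:
        sds = p["sd_by_center"]
        if pair_codes[0] in sds and pair_codes[1] in sds:
            n_matched += 1
            hi = max(sds, key=sds.get)
            if hi == noisier:
                n_larger += 1
    return {
        "per_cell_line": rows,
        "median_r_p": median_r_p,
        "noisier_center": noisier,
        "noisier_center_flagged_worse": median_r_p[noisier] == min(median_r_p.values()),
        "replicates": {
            "avg_tests_per_drug_cell_line": rep["avg_tests_per_drug_cell_line"],
            "n_matched_sets": n_matched,
            "n_noisier_center_larger_sd": n_larger,
            "fraction_noisier_larger": (n_larger / n_matched) if n_matched else float("nan"),
        },
    }
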
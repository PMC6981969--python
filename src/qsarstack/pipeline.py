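"""Config-driven end-to-end runs of the screening workflow.

A pipeline run executes, in a fixed order: curation -> preprocessing ->
feature selection -> nested-CV modeling -> gating -> vote stacking over a
screening library -> applicability-domain masking -> docking-cutoff
calibration. Every run directory receives the resolved configuration, a
config hash and the seed, so reruns with identical config + seed are
byte-identical on all metric tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from qsarstack import adomain, curation, dockpost, ensemble, modeling
from qsarstack import feature_select as fs
from qsarstack import preprocess, synthetic
from qsarstack.synthetic import LabeledDataset, SyntheticSpec

ALL_STAGES = (
    "curate",
    "preprocess",
    "select",
    "train",
    "gate",
    "screen",
    "ad",
    "dockcal",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "synthetic": {
        "enabled": True,
        "n_active": 60,
        "n_inactive": 140,
        "n_informative": 10,
        "n_noise": 30,
        "n_quasi_constant": 5,
        "n_correlated_pairs": 3,
        "effect_size": 1.2,
        "duplicate_fraction": 0.1,
        "n_activity_records": 200,
        "n_screen": 100,
    },
    "thresholds": {
        "activity_nM": 1000.0,
        "ba_gate": 70.0,
        "ppv_gate": 70.0,
        "vote_tier": 75.0,
        "sahigara_k": 5,
    },
    "preprocess": {
        "quasi_constant_fraction": 0.01,
        "correlation_cutoff": 0.9,
        "clip_limit": 2.0,
    },
    "models": [
        {"classifier": "logistic", "fs_method": "anova", "k": 5},
        {"classifier": "rf", "fs_method": "anova", "k": 10},
        {"classifier": "rf", "fs_method": "auc", "k": 10},
    ],
    "docking": {"mean_active": -8.02, "mean_inactive": -7.29, "sd": 0.8},
    "inputs": {},  # file paths when synthetic mode is off
    "model_registry": None,  # path to a saved registry (skips training)
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and override dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def update(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                update(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        update(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _dataset_from_config(cfg: dict) -> LabeledDataset:
    syn = cfg["synthetic"]
    if syn["enabled"]:
        spec = SyntheticSpec(
            n_active=syn["n_active"],
            n_inactive=syn["n_inactive"],
            n_informative=syn["n_informative"],
            n_noise=syn["n_noise"],
            n_quasi_constant=syn["n_quasi_constant"],
            n_correlated_pairs=syn["n_correlated_pairs"],
            effect_size=syn["effect_size"],
            duplicate_fraction=syn["duplicate_fraction"],
            seed=cfg["seed"],
        )
        return synthetic.generate_labeled_dataset(spec)
    path = cfg["inputs"].get("descriptor_csv")
    if not path:
        raise FileNotFoundError(
            "stage 'preprocess' needs inputs.descriptor_csv or synthetic mode"
        )
    df = pd.read_csv(path, index_col=0)
    y = (df.pop("activity") == "active").astype(int).to_numpy()
    return LabeledDataset(X=df, y=y, ids=list(df.index))


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the configured stages; returns {artifact name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = copy.deepcopy(cfg)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    artifacts: dict[str, Path] = {}

    resolved = out / "run_config.yaml"
    with open(resolved, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    artifacts["run_config"] = resolved

    syn = cfg["synthetic"]
    thr = cfg["thresholds"]

    # ---- curate ---------------------------------------------------------
    if "curate" in stages:
        if syn["enabled"]:
            records = synthetic.generate_activity_records(
                syn["n_activity_records"],
                duplicate_fraction=syn["duplicate_fraction"],
                seed=seed,
            )
        else:
            path = cfg["inputs"].get("activity_csv")
            if not path:
                raise FileNotFoundError(
                    "stage 'curate' needs inputs.activity_csv or synthetic mode"
                )
            records = curation.read_activity_csv(path)
        curated = curation.curate(records, threshold_nM=thr["activity_nM"])
        curated.to_csv(out / "curated.csv")
        artifacts["curated"] = out / "curated.csv"

    # ---- preprocess -----------------------------------------------------
    dataset = _dataset_from_config(cfg)
    pp = cfg["preprocess"]
    recipe = preprocess.fit_scaler(
        dataset.X,
        min_variant_fraction=pp["quasi_constant_fraction"],
        r_cutoff=pp["correlation_cutoff"],
        clip_limit=pp["clip_limit"],
    )
    clean = LabeledDataset(
        X=recipe.apply(dataset.X), y=dataset.y, ids=dataset.ids,
        column_roles=dataset.column_roles,
    )
    if "preprocess" in stages:
        recipe.to_yaml(out / "preprocess_recipe.yaml")
        clean.X.to_csv(out / "descriptors_clean.csv")
        artifacts["recipe"] = out / "preprocess_recipe.yaml"
        artifacts["descriptors_clean"] = out / "descriptors_clean.csv"

    # ---- select ---------------------------------------------------------
    if "select" in stages:
        methods = ("anova", "kruskal", "auc", "rf_impurity")
        rankings = fs.rank_all_methods(clean, methods=methods, seed=seed)
        pd.concat([r.to_frame() for r in rankings]).to_csv(
            out / "feature_rankings.csv", index=False
        )
        fs.top_k_frequency(rankings, k=5).to_csv(
            out / "top5_frequency.csv", index=False
        )
        artifacts["feature_rankings"] = out / "feature_rankings.csv"
        artifacts["top5_frequency"] = out / "top5_frequency.csv"

    # ---- train / gate ---------------------------------------------------
    registry: dict | None = None
    perfs: list[modeling.CVPerformance] = []
    if "train" in stages:
        specs = [
            modeling.ModelSpec(
                classifier=m["classifier"],
                fs_method=m["fs_method"],
                k=m["k"],
                seed=seed,
            )
            for m in cfg["models"]
        ]
        perfs = [modeling.nested_cv(clean, s, seed=seed) for s in specs]
        modeling.results_table(perfs).to_csv(out / "cv_results.csv", index=False)
        artifacts["cv_results"] = out / "cv_results.csv"

        gated = modeling.gate_models(
            perfs, ba_min=thr["ba_gate"], ppv_min=thr["ppv_gate"]
        )
        gated_names = {p.model_name for p in gated}
        if "gate" in stages:
            modeling.results_table(gated).to_csv(
                out / "gated_models.csv", index=False
            )
            artifacts["gated_models"] = out / "gated_models.csv"
        # refit gated configurations on the full dataset for screening
        fitted = {}
        for s in specs:
            if s.name in gated_names:
                est = modeling.QSARModel(
                    classifier=s.classifier, fs_method=s.fs_method,
                    k=s.k, seed=seed,
                ).fit(clean.X, clean.y)
                fitted[s.name] = est
        registry = {
            "models": fitted,
            "features": {n: e.selected_features_ for n, e in fitted.items()},
            "recipe": recipe.to_dict(),
            "train_X": clean.X,
        }
        joblib.dump(registry, out / "model_registry.joblib")
        artifacts["model_registry"] = out / "model_registry.joblib"
    elif cfg.get("model_registry"):
        registry = joblib.load(cfg["model_registry"])

    # ---- screen / ad ----------------------------------------------------
    if "screen" in stages:
        if registry is None or not registry["models"]:
            raise FileNotFoundError(
                "stage 'screen' needs a model registry produced by stage "
                "'train' (or cfg['model_registry']); no gated model available"
            )
        screen_spec = SyntheticSpec(
            n_active=max(syn["n_screen"] // 4, 1),
            n_inactive=syn["n_screen"] - max(syn["n_screen"] // 4, 1),
            n_informative=syn["n_informative"],
            n_noise=syn["n_noise"],
            n_quasi_constant=syn["n_quasi_constant"],
            n_correlated_pairs=syn["n_correlated_pairs"],
            effect_size=syn["effect_size"],
            seed=seed + 1,
        )
        screen_raw = synthetic.generate_labeled_dataset(screen_spec)
        screen_raw.X.index = pd.Index(
            [f"SCR{i:06d}" for i in range(len(screen_raw.X))], name="compound_id"
        )
        rec = preprocess.PreprocessRecipe.from_dict(registry["recipe"])
        screen_X = rec.apply(screen_raw.X)
        preds = pd.DataFrame(
            {name: est.predict(screen_X) for name, est in registry["models"].items()},
            index=screen_X.index,
        )
        report = ensemble.tier_report(preds)
        report.to_csv(out / "screen_votes.csv")
        artifacts["screen_votes"] = out / "screen_votes.csv"

        if "ad" in stages:
            mask = adomain.sahigara_mask(
                registry["features"], registry["train_X"], screen_X,
                k=thr["sahigara_k"],
            )
            masked = ensemble.tier_report(preds, ad_mask=mask)
            masked.to_csv(out / "screen_votes_ad.csv")
            adomain.outlier_fraction_summary(mask).to_csv(
                out / "ad_outlier_fractions.csv"
            )
            artifacts["screen_votes_ad"] = out / "screen_votes_ad.csv"
            artifacts["ad_outlier_fractions"] = out / "ad_outlier_fractions.csv"

    # ---- dockcal --------------------------------------------------------
    if "dockcal" in stages:
        dock_cfg = cfg["docking"]
        if syn["enabled"]:
            table = synthetic.generate_docking_scores(
                dataset.y,
                mean_active=dock_cfg["mean_active"],
                mean_inactive=dock_cfg["mean_inactive"],
                sd=dock_cfg["sd"],
                seed=seed,
            )
        else:
            table = dockpost.read_docking_csv(cfg["inputs"]["docking_csv"])
        labels = (table["label"] == "active").astype(int).to_numpy()
        cal = {
            "optimal": dockpost.optimal_cutpoint(table["energy"], labels).as_dict(),
            "max_specificity": dockpost.max_specificity_cutpoint(
                table["energy"], labels
            ).as_dict(),
        }
        with open(out / "docking_calibration.json", "w") as fh:
            json.dump(cal, fh, indent=2)
        artifacts["docking_calibration"] = out / "docking_calibration.json"

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
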
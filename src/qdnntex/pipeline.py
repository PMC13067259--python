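"""End-to-end orchestration: simulate -> extract -> train -> evaluate.

This module carries the library-level plumbing behind the command-line
interface: a meta-estimator chaining annealed feature weighting into the
quantum-classical classifier, nested configuration handling with strict
key checking, deterministic per-stage seed derivation from one global
seed, and the with/without-feature-weighting comparison protocol.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import platform

import numpy as np
import pandas as pd
import yaml

from .classifier import QDNNClassifier
from .evaluation import run_cv
from .fssa import FSSAWeighter, weights_to_csv
from .preprocess import load_image
from .texture import DEFAULT_ANGLES, DEFAULT_DISTANCES, HaralickExtractor
from .synthetic import SyntheticConfig, write_dataset

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_classes": 4,
        "n_per_class": 100,
        "size": 128,
        "missing_fraction": 0.0,
        "mask": False,
    },
    "preprocess": {
        "smooth_sigma": 1.0,
        "levels": 32,
        "icv": None,
    },
    "texture": {
        "distances": list(DEFAULT_DISTANCES),
        "angles": [float(a) for a in DEFAULT_ANGLES],
        "levels": 32,
        "window": None,
        "symmetric": True,
    },
    "fssa": {
        "a": 1.0,
        "b": 0.5,
        "sigma_perturb": 0.05,
        "T0": 1.0,
        "gamma": 0.95,
        "max_iter": 500,
        "T_min": 1e-6,
        "val_fraction": 0.25,
    },
    "qdnn": {
        "n_input_qubits": 4,
        "n_hidden_qubits": 2,
        "n_output_qubits": 1,
    },
    "train": {
        "mode": "sa",
        "T0": 1.0,
        "gamma": 0.95,
        "max_iter": 500,
        "T_min": 1e-6,
        "sigma_param": 0.1,
        "lr": 0.01,
        "epochs": 200,
        "batch_size": 32,
    },
    "eval": {
        "k": 5,
        "stratified": True,
    },
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by hashing the
    stage name together with the global seed."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise KeyError(f"config section {where} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override
    mapping.  Unknown keys raise ``KeyError`` naming the key."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def write_provenance(outdir, config: dict, extra: dict | None = None) -> None:
    payload = {
        "config": config,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        payload.update(extra)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


class FSSAQDNNClassifier:
    """Meta-estimator: annealed feature weighting feeding the quantum
    classifier.

    When ``use_fssa`` is true, per-feature weights are annealed on the
    training data and passed to the classifier as the relevance ranking
    for its top-``N`` input-qubit feature selection; otherwise unit
    weights are used (selection falls back to column order).
    """

    def __init__(self, use_fssa: bool = True, fssa_params: dict | None = None,
                 qdnn_params: dict | None = None, random_state: int = 0):
        self.use_fssa = use_fssa
        self.fssa_params = fssa_params
        self.qdnn_params = qdnn_params
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"use_fssa": self.use_fssa, "fssa_params": self.fssa_params,
                "qdnn_params": self.qdnn_params, "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.use_fssa:
            weighter = FSSAWeighter(random_state=derive_seed(self.random_state, "fssa"),
                                    **(self.fssa_params or {}))
            weighter.fit(X, y)
            self.weighter_ = weighter
            weights = weighter.weights_
        else:
            self.weighter_ = None
            weights = None
        self.qdnn_ = QDNNClassifier(random_state=derive_seed(self.random_state, "train"),
                                    **(self.qdnn_params or {}))
        self.qdnn_.fit(X, y, feature_weights=weights)
        self.classes_ = self.qdnn_.classes_
        return self

    def predict(self, X):
        return self.qdnn_.predict(X)

    def predict_proba(self, X):
        return self.qdnn_.predict_proba(X)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


# ----------------------------------------------------------------------
# pipeline stages


def simulate(config: dict, outdir) -> pd.DataFrame:
    """Generate the synthetic image tree plus manifest CSV."""
    sim = config["simulate"]
    n_classes = sim["n_classes"]
    base = SyntheticConfig()
    syn = SyntheticConfig(
        n_classes=n_classes,
        n_per_class=sim["n_per_class"],
        size=sim["size"],
        class_smoothness=base.class_smoothness[:n_classes],
        class_contrast=base.class_contrast[:n_classes],
        missing_fraction=sim["missing_fraction"],
        mask=sim["mask"],
        seed=derive_seed(config["seed"], "simulate"),
    )
    return write_dataset(syn, outdir)


def _extractor(config: dict) -> HaralickExtractor:
    tex, pre = config["texture"], config["preprocess"]
    return HaralickExtractor(
        distances=tuple(tex["distances"]), angles=tuple(tex["angles"]),
        levels=tex["levels"], window=tex["window"], symmetric=tex["symmetric"],
        smooth_sigma=pre["smooth_sigma"])


def extract(manifest: pd.DataFrame | str, config: dict) -> pd.DataFrame:
    """Haralick feature table for every image in the manifest.

    Images that fail to load or process are skipped with a warning; the
    returned frame holds ``image_id``, ``label`` and one column per
    feature.
    """
    if isinstance(manifest, (str, os.PathLike)):
        manifest = pd.read_csv(manifest)
    extractor = _extractor(config).fit([])
    rows, skipped = [], 0
    for _, rec in manifest.iterrows():
        try:
            img = load_image(rec["path"])
            feats = extractor.transform([img])[0]
        except (OSError, ValueError) as exc:
            skipped += 1
            print(f"warning: skipping {rec['path']}: {exc}")
            continue
        row = {"image_id": os.path.basename(str(rec["path"])), "label": int(rec["label"])}
        row.update(dict(zip(extractor.feature_names_, feats)))
        rows.append(row)
    if skipped:
        print(f"skipped {skipped} image(s)")
    return pd.DataFrame(rows)


def split_features(features: pd.DataFrame):
    feat_cols = [c for c in features.columns if c not in ("image_id", "label")]
    return features[feat_cols].to_numpy(dtype=float), \
        features["label"].to_numpy(), feat_cols


def _model_factory(config: dict, use_fssa: bool):
    f, q, t = config["fssa"], config["qdnn"], config["train"]
    fssa_params = {k: f[k] for k in ("a", "b", "sigma_perturb", "T0", "gamma",
                                     "max_iter", "T_min", "val_fraction")}
    qdnn_params = dict(
        n_input_qubits=q["n_input_qubits"], n_hidden_qubits=q["n_hidden_qubits"],
        n_output_qubits=q["n_output_qubits"], mode=t["mode"], T0=t["T0"],
        gamma=t["gamma"], max_iter=t["max_iter"], T_min=t["T_min"],
        sigma_param=t["sigma_param"], lr=t["lr"], epochs=t["epochs"],
        batch_size=t["batch_size"])

    def factory(fold_idx: int) -> FSSAQDNNClassifier:
        return FSSAQDNNClassifier(
            use_fssa=use_fssa, fssa_params=fssa_params, qdnn_params=qdnn_params,
            random_state=derive_seed(config["seed"], f"fold{fold_idx}"))

    return factory


def train_model(features: pd.DataFrame, config: dict, use_fssa: bool = True,
                outdir=None) -> FSSAQDNNClassifier:
    """Fit the (optionally feature-weighted) classifier on a full
    feature table; write model JSON / weights CSV / training log when
    ``outdir`` is given."""
    X, y, feat_cols = split_features(features)
    model = _model_factory(config, use_fssa)(-1)
    model.fit(X, y)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        model.qdnn_.save_json(os.path.join(outdir, "model.json"))
        if model.weighter_ is not None:
            weights_to_csv(model.weighter_.weights_, feat_cols,
                           os.path.join(outdir, "fssa_weights.csv"))
            model.weighter_.trace_.to_csv(os.path.join(outdir, "fssa_trace.csv"))
        for i, trace in enumerate(model.qdnn_.traces_):
            if trace is not None:
                trace.to_csv(os.path.join(outdir, f"train_trace_head{i}.csv"))
    return model


def evaluate_cv(features: pd.DataFrame, config: dict, use_fssa: bool = True,
                compare_fssa: bool = False) -> dict:
    """k-fold cross-validation; optionally the paired with/without
    feature-weighting comparison."""
    X, y, _ = split_features(features)
    k = config["eval"]["k"]
    seed = derive_seed(config["seed"], "cv")
    stratified = config["eval"]["stratified"]

    def one(use: bool) -> dict:
        reports, mean = run_cv(X, y, _model_factory(config, use), k=k,
                               seed=seed, stratified=stratified)
        return {"folds": [r.to_dict() for r in reports], "mean": mean.to_dict()}

    result = {"k": k, "with_fssa" if use_fssa else "without_fssa": one(use_fssa)}
    if compare_fssa:
        other = not use_fssa
        result["with_fssa" if other else "without_fssa"] = one(other)
    return result


def run_all(config: dict, outdir) -> dict:
    """Full chain with one global seed: simulate, extract, train on the
    full table, cross-validate.  Returns the metrics payload and leaves
    all artifacts (manifest, features.csv, model.json, metrics.json,
    provenance.json) under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    manifest = simulate(config, os.path.join(outdir, "images"))
    features = extract(manifest, config)
    features.to_csv(os.path.join(outdir, "features.csv"), index=False)
    train_model(features, config, use_fssa=True, outdir=outdir)
    metrics = evaluate_cv(features, config, use_fssa=True)
    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    write_provenance(outdir, config)
    return metrics
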
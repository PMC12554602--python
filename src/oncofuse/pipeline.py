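"""End-to-end orchestration: evaluation metrics, EMA, ablations, reports.

Metric conventions: accuracy, macro (unweighted) recall and F1, and macro
one-vs-rest AUC.  A class absent from the evaluation cohort is excluded from
the macro averages with a logged warning.  Ablation variants mirror the
component structure of the full model: attention fusion replaced by a
uniform mean, tailored encoders replaced by a shared MLP on flattened
inputs, the adversarial domain-adaptation terms disabled, or the
treatment-policy stage skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import f1_score, recall_score, roc_auc_score

from ._autodiff import Tensor
from .fusion import MultimodalFusionClassifier
from .synthetic import (
    CohortConfig,
    cohort_arrays,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    read_cohort,
)
from .uncertainty import (
    inverse_variance_weights,
    mc_dropout_predict,
    modality_variance,
    prediction_entropy,
)

logger = logging.getLogger("oncofuse")

MODALITY_NAMES = ("image", "genomic", "clinical")

ABLATION_VARIANTS = {
    "full": {},
    "no_fusion_attention": {"uniform_fusion": True},
    "no_tailored_encoders": {"architecture": "shared_mlp"},
    "no_policy": {},  # the RL stage is orthogonal to the classifier
    "no_domain_adaptation": {"use_domain_adaptation": False,
                             "use_consistency": False},
    "cnn_mlp_baseline": {"architecture": "shared_mlp", "uniform_fusion": True,
                         "use_domain_adaptation": False,
                         "weight_contrastive": 0.0, "weight_calibration": 0.0},
}

__all__ = [
    "MetricsReport",
    "ABLATION_VARIANTS",
    "evaluate",
    "ema_update",
    "run_ablation",
    "attention_report",
    "run_training",
    "split_cohort",
]


@dataclass
class MetricsReport:
    accuracy: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    per_class: dict
    n_samples: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate(model, cohort, mode: str = "deterministic", T: int = 20,
             seed: int = 0) -> MetricsReport:
    """Score a fitted classifier on a cohort.

    ``mode='deterministic'`` runs with dropout off; ``mode='mc'`` scores the
    seeded MC-dropout mean prediction instead.
    """
    samples = list(cohort)
    if not samples:
        raise ValueError("cannot evaluate on an empty cohort")
    arrays = cohort_arrays(samples)
    y = arrays["label"]
    if mode == "deterministic":
        probs = model.predict_proba(arrays)
    elif mode == "mc":
        probs = np.atleast_2d(mc_dropout_predict(model, arrays, T=T, seed=seed).mean)
    else:
        raise ValueError(f"mode must be 'deterministic' or 'mc', got {mode!r}")
    pred = model.classes_[probs.argmax(axis=1)]

    present_classes = [c for c in model.classes_ if (y == c).any()]
    missing = [c for c in model.classes_ if c not in present_classes]
    if missing:
        logger.warning("classes %s absent from cohort; excluded from macro metrics",
                       missing)

    accuracy = float(np.mean(pred == y))
    macro_recall = float(recall_score(y, pred, labels=present_classes,
                                      average="macro", zero_division=0))
    macro_f1 = float(f1_score(y, pred, labels=present_classes,
                              average="macro", zero_division=0))

    per_class, aucs = {}, []
    for i, c in enumerate(model.classes_):
        if c not in present_classes:
            per_class[int(c)] = {"recall": None, "f1": None, "auc": None}
            continue
        rec = float(recall_score(y, pred, labels=[c], average="macro",
                                 zero_division=0))
        f1c = float(f1_score(y, pred, labels=[c], average="macro", zero_division=0))
        binary = (y == c).astype(int)
        auc = float(roc_auc_score(binary, probs[:, i])) if 0 < binary.sum() < len(y) \
            else None
        per_class[int(c)] = {"recall": rec, "f1": f1c, "auc": auc}
        if auc is not None:
            aucs.append(auc)
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricsReport(accuracy=accuracy, macro_recall=macro_recall,
                         macro_f1=macro_f1, macro_auc=macro_auc,
                         per_class=per_class, n_samples=len(samples))


def ema_update(ema_weights, current_weights, decay: float):
    """``ema <- decay * ema + (1 - decay) * current`` elementwise.

    Accepts arrays, dicts of arrays, or (nested) lists; decay 0 copies the
    current weights, decay 1 leaves the average unchanged.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must be in [0, 1], got {decay}")
    if isinstance(ema_weights, dict):
        if set(ema_weights) != set(current_weights):
            raise ValueError("EMA and current weight dictionaries have different keys")
        return {k: ema_update(ema_weights[k], current_weights[k], decay)
                for k in ema_weights}
    if isinstance(ema_weights, (list, tuple)):
        if len(ema_weights) != len(current_weights):
            raise ValueError("EMA and current weight lists have different lengths")
        return type(ema_weights)(
            ema_update(e, c, decay) for e, c in zip(ema_weights, current_weights)
        )
    ema = np.asarray(ema_weights, dtype=np.float64)
    cur = np.asarray(current_weights, dtype=np.float64)
    if ema.shape != cur.shape:
        raise ValueError(f"shape mismatch: {ema.shape} vs {cur.shape}")
    return decay * ema + (1.0 - decay) * cur


def split_cohort(samples, seed: int, fractions=(0.70, 0.15, 0.15)):
    """Seeded patient-level shuffle into train/validation/test lists."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(fractions[0] * len(samples)))
    n_val = int(round(fractions[1] * len(samples)))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def run_ablation(base_params: dict, variants, seeds, cohort_config: CohortConfig,
                 eval_fraction: float = 0.3) -> pd.DataFrame:
    """Train and evaluate every (variant, seed) pair on the same cohort split.

    Returns a table of mean +/- sd metrics per variant; a failing run is
    recorded in the table rather than aborting the sweep.
    """
    if not variants or not len(seeds):
        raise ValueError("need at least one variant and one seed")
    rows = []
    for variant in variants:
        if variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {variant!r}; "
                             f"choose from {sorted(ABLATION_VARIANTS)}")
        metrics_per_seed = []
        failure = None
        for seed in seeds:
            try:
                cohort = generate_cohort(
                    dataclasses.replace(cohort_config, seed=cohort_config.seed + seed)
                )
                train, _, test = split_cohort(cohort, seed=seed,
                                              fractions=(1 - eval_fraction, 0.0,
                                                         eval_fraction))
                params = dict(base_params)
                params.update(ABLATION_VARIANTS[variant])
                params["random_state"] = seed
                params.setdefault("vocab_size", cohort_config.vocab_size)
                clf = MultimodalFusionClassifier(**params).fit(train)
                metrics_per_seed.append(evaluate(clf, test))
            except Exception as exc:  # record, keep sweeping
                failure = f"{type(exc).__name__}: {exc}"
                logger.warning("variant %s seed %s failed: %s", variant, seed, failure)
        row = {"variant": variant, "n_seeds": len(metrics_per_seed),
               "failure": failure}
        for metric in ("accuracy", "macro_recall", "macro_f1", "macro_auc"):
            vals = [getattr(m, metric) for m in metrics_per_seed]
            row[f"{metric}_mean"] = float(np.mean(vals)) if vals else float("nan")
            row[f"{metric}_sd"] = float(np.std(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def attention_report(model, sample, T: int = 20, seed: int = 0) -> dict:
    """Machine-readable case report for one patient.

    Contains attention weights, per-modality MC variances and their
    inverse-variance weights, predicted class probabilities, normalized
    predictive entropy, and a gradient-x-input saliency vector per modality
    (``None`` for absent modalities).
    """
    if not hasattr(model, "net_"):
        raise ValueError("attention_report requires a fitted model")
    arrays = cohort_arrays([sample])
    out = model.net_.forward(arrays, dropout_active=False)
    probs = out["probs"].data[0]
    alpha = out["alpha"].data[0]
    mask = arrays["mask"][0]

    sigma2 = modality_variance(model, [sample], T=T, seed=seed)[0]
    iv_weights = inverse_variance_weights(sigma2)
    saliency = _input_saliency(model, arrays, mask)

    return {
        "patient_id": sample.patient_id,
        "modalities": list(MODALITY_NAMES),
        "present": [bool(m) for m in mask],
        "attention_weights": [float(a) for a in alpha],
        "modality_variance": [None if not np.isfinite(v) else float(v)
                              for v in sigma2],
        "inverse_variance_weights": [float(w) for w in iv_weights],
        "class_labels": [int(c) for c in model.classes_],
        "probabilities": [float(p) for p in probs],
        "predicted_class": int(model.classes_[int(np.argmax(probs))]),
        "normalized_entropy": float(prediction_entropy(probs, normalized=True)),
        "saliency": saliency,
        "mc_passes": T,
        "seed": seed,
    }


def _input_saliency(model, arrays, mask) -> dict:
    """Gradient-x-input attribution of the predicted-class logit."""
    net = model.net_
    image_t = Tensor(arrays["image"], requires_grad=True)
    clinical_t = Tensor(arrays["clinical"], requires_grad=True)
    saliency = {"image": None, "genomic": None, "clinical": None}
    if net.architecture == "tailored":
        emb = net.genomic_encoder.embedding(arrays["genomic"])
        genomic_leaf = Tensor(emb.data, requires_grad=True)
        out = net.forward(arrays, dropout_active=False, image_t=image_t,
                          clinical_t=clinical_t, genomic_leaf=genomic_leaf)
    else:
        genomic_leaf = None
        out = net.forward(arrays, dropout_active=False, image_t=image_t,
                          clinical_t=clinical_t)
    logits = out["logits"]
    k = int(np.argmax(out["probs"].data[0]))
    chosen = logits[(np.array([0]), np.array([k]))]
    chosen.backward()
    if mask[0] and image_t.grad is not None:
        saliency["image"] = (image_t.grad[0] * arrays["image"][0]).tolist()
    if mask[1] and genomic_leaf is not None and genomic_leaf.grad is not None:
        # per-token attribution: grad . embedding, summed over embedding dims
        saliency["genomic"] = (
            (genomic_leaf.grad[0] * genomic_leaf.data[0]).sum(axis=1).tolist()
        )
    if mask[2] and clinical_t.grad is not None:
        saliency["clinical"] = (clinical_t.grad[0] * arrays["clinical"][0]).tolist()
    return saliency


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_training(config, out_dir: str) -> str:
    """Config-driven training run producing a self-describing artifact dir.

    ``config`` is a path to a YAML/JSON file or an equivalent dict with keys
    ``cohort`` (generator parameters or ``{"path": DIR}``), ``model``
    (estimator parameters), ``seed``, and optional ``split`` fractions.
    Writes checkpoint, metrics JSON, JSON-lines training log, a copy of the
    config, and a seed/environment record.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to one")
    unknown = set(config) - {"cohort", "model", "seed", "split", "mc_passes"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    seed = int(config.get("seed", 0))
    cohort_spec = dict(config.get("cohort", {}))
    if "path" in cohort_spec:
        samples = read_cohort(cohort_spec["path"])
        cohort_cfg = None
    else:
        cohort_spec.setdefault("seed", seed)
        cohort_cfg = config_from_dict(cohort_spec)
        samples = generate_cohort(cohort_cfg)

    fractions = tuple(config.get("split", (0.70, 0.15, 0.15)))
    train, val, test = split_cohort(samples, seed=seed, fractions=fractions)

    model_params = dict(config.get("model", {}))
    model_params.setdefault("random_state", seed)
    if cohort_cfg is not None:
        model_params.setdefault("vocab_size", cohort_cfg.vocab_size)
    clf = MultimodalFusionClassifier(**model_params).fit(train)

    os.makedirs(out_dir, exist_ok=True)
    resolved = {
        "cohort": config_to_dict(cohort_cfg) if cohort_cfg else cohort_spec,
        "model": model_params,
        "seed": seed,
        "split": list(fractions),
    }
    cfg_hash = _config_hash(resolved)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(resolved, fh, indent=2, default=str)

    np.savez(os.path.join(out_dir, "checkpoint.npz"),
             __version__="1", __config_hash__=cfg_hash,
             **clf.net_.state_dict())

    metrics = {
        "train": evaluate(clf, train).to_dict(),
        "test": evaluate(clf, test).to_dict() if test else None,
        "validation": evaluate(clf, val).to_dict() if val else None,
        "config_hash": cfg_hash,
    }
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2)

    with open(os.path.join(out_dir, "train_log.jsonl"), "w") as fh:
        for record in clf.history_:
            fh.write(json.dumps({"level": "info", "seed": seed,
                                 "config_hash": cfg_hash, **record}) + "\n")
    with open(os.path.join(out_dir, "run_record.json"), "w") as fh:
        json.dump({"seed": seed, "config_hash": cfg_hash,
                   "n_train": len(train), "n_val": len(val), "n_test": len(test),
                   "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}, fh, indent=2)
    return out_dir
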
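"""Desk-scale reference experiments on phantom data.

Each function runs one self-contained experiment at sizes a single CPU
handles in minutes — training the tiny backbones on phantom slices,
cross-validating the outcome models on generated cohorts, or running
statistical diagnostics against their known truths — and returns plain
dictionaries of measured quantities.  They are the package's
reproducibility surface: the test suite asserts on their outputs and
the acceptance script re-runs them from scratch.

All randomness descends from one integer seed per experiment.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .classify import (
    ClsTrainConfig,
    build_fusion_input,
    predict_subtypes,
    train_binary_filter,
    train_multilabel,
)
from .image_io import SUBTYPE_NAMES
from .metrics import dice_score, hematoma_volume_ml
from .outcome import box_cox, box_tidwell, fit_predict_cv, recover_coefficients
from .pipeline import PipelineConfig, run_pipeline
from .roi import compute_roi
from .segmentation import (
    SegTrainConfig,
    cascade_predict,
    make_stage2_dataset,
    train_stage,
)
from .synthetic import (
    DEFAULT_COEF_A,
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom_series,
)

# desk-scale training preset for the from-scratch tiny backbones
TINY_LR = 1e-2
IMAGE_SIDE = 64


def filter_experiment(seed: int = 1, n_train: int = 200, n_test: int = 50,
                      epochs: int = 20) -> Dict:
    """Train the hemorrhage gate on half-empty slices; held-out accuracy."""
    spec = PhantomSpec(
        image_side=IMAGE_SIDE,
        n_slices=n_train + n_test,
        fraction_empty_slices=0.5,
        seed=seed,
    )
    series, masks, _ = generate_phantom_series(spec)
    pairs = [(s, not m.is_empty()) for s, m in zip(series.slices, masks)]
    model = train_binary_filter(
        pairs[:n_train],
        ClsTrainConfig(task="binary", epochs=epochs, lr=TINY_LR, seed=seed),
    )
    correct = [model.predict(s) == y for s, y in pairs[n_train:]]
    return {"model": model, "held_out_accuracy": float(np.mean(correct))}


def cascade_experiment(seed: int = 1, n_train: int = 200, n_test: int = 50,
                       epochs: int = 30, n_boot: int = 2000) -> Dict:
    """Train Stage I/II and compare held-out Dice, with a paired bootstrap.

    Returns per-slice Dice for Stage I alone and for the full cascade,
    plus a bootstrap confidence interval of their paired difference.
    """
    spec = PhantomSpec(
        image_side=IMAGE_SIDE,
        n_slices=n_train + n_test,
        fraction_empty_slices=0.3,
        seed=seed,
    )
    series, masks, _ = generate_phantom_series(spec)
    tr_s, tr_m = series.slices[:n_train], masks[:n_train]
    te_s, te_m = series.slices[n_train:], masks[n_train:]

    stage1 = train_stage(
        list(zip(tr_s, tr_m)),
        SegTrainConfig(stage="I", epochs=epochs, lr=TINY_LR, seed=seed),
    )
    stage2 = train_stage(
        make_stage2_dataset(tr_s, tr_m),
        SegTrainConfig(stage="II", epochs=epochs, lr=TINY_LR, seed=seed + 1),
    )

    dice1, dice_cascade = [], []
    for s, m in zip(te_s, te_m):
        p1 = (stage1.predict(s) >= 0.5).astype(np.uint8)
        dice1.append(dice_score(p1, m))
        fused, _ = cascade_predict(stage1, stage2, s)
        dice_cascade.append(dice_score(fused, m))
    diff = np.asarray(dice_cascade) - np.asarray(dice1)
    rng = np.random.default_rng(seed)
    boots = [
        float(diff[rng.integers(0, len(diff), len(diff))].mean())
        for _ in range(n_boot)
    ]
    return {
        "stage1": stage1,
        "stage2": stage2,
        "dice_stage1": float(np.mean(dice1)),
        "dice_cascade": float(np.mean(dice_cascade)),
        "diff_ci_low": float(np.percentile(boots, 2.5)),
        "diff_ci_high": float(np.percentile(boots, 97.5)),
    }


def _fusion_dataset(seed: int, n: int):
    spec = PhantomSpec(
        image_side=IMAGE_SIDE, n_slices=n, fraction_empty_slices=0.25, seed=seed
    )
    series, masks, labels = generate_phantom_series(spec)
    data = []
    for s, m, lab in zip(series.slices, masks, labels):
        roi = None if m.is_empty() else compute_roi(m.binary())
        data.append((build_fusion_input(s, m, roi), lab))
    return data


def _per_label_accuracy(model, data) -> float:
    hits = []
    for fi, lab in data:
        pred, _ = predict_subtypes(model, fi)
        hits.append(pred.to_array() == lab.to_array())
    return float(np.mean(hits))


def fusion_experiment(seed: int = 1, n_train: int = 300, n_test: int = 60,
                      epochs: int = 30, n_seeds: int = 3) -> Dict:
    """Fusion classifier vs. global-only ablation on shape-coded subtypes.

    Mask and ROI come from ground truth so subtype is recoverable from
    lesion geometry alone; accuracies are averaged over training seeds.
    """
    data = _fusion_dataset(seed, n_train + n_test)
    train, test = data[:n_train], data[n_train:]
    fusion_accs, global_accs = [], []
    last_fusion = None
    for k in range(n_seeds):
        cfg = ClsTrainConfig(
            task="multilabel", epochs=epochs, lr=TINY_LR, seed=seed + k
        )
        fusion = train_multilabel(train, cfg)
        global_only = train_multilabel(train, cfg, global_only=True)
        fusion_accs.append(_per_label_accuracy(fusion, test))
        global_accs.append(_per_label_accuracy(global_only, test))
        last_fusion = fusion
    return {
        "model": last_fusion,
        "fusion_accuracy": float(np.mean(fusion_accs)),
        "global_only_accuracy": float(np.mean(global_accs)),
    }


def outcome_experiment(seed: int = 1, n_patients: int = 2000) -> Dict:
    """Nested CRASH models on an informative and a null cohort."""
    df = generate_cohort(CohortSpec(n_patients=n_patients, seed=seed))
    aucs = {
        name: fit_predict_cv(df, name, "logistic", "A", seed=seed).mean("auc")
        for name in ("CRASH_BASIC", "CRASH_CT", "CRASH_CT_VOL", "CRASH_CT_VOL_SUB")
    }
    null_df = generate_cohort(CohortSpec.null(n_patients=n_patients, seed=seed + 1))
    null_auc = fit_predict_cv(
        null_df, "CRASH_CT_VOL_SUB", "logistic", "A", seed=seed
    ).mean("auc")
    rf = fit_predict_cv(df, "CRASH_CT_VOL_SUB", "random_forest", "A", seed=seed,
                        rf_trees=200)
    top_feature = rf.feature_names[int(np.argmax(rf.importances))]
    return {"auc": aucs, "null_auc": float(null_auc), "rf_top_feature": top_feature,
            "rf_auc": rf.mean("auc")}


def volumetry_experiment(models: Dict, seed: int = 1, n_slices: int = 20) -> Dict:
    """End-to-end pipeline volume against phantom ground truth."""
    cfg = PipelineConfig(
        binary_filter=models["filter"],
        stage1=models["stage1"],
        stage2=models["stage2"],
        multilabel=models["multilabel"],
    )
    spec = PhantomSpec(
        image_side=IMAGE_SIDE, n_slices=n_slices, fraction_empty_slices=0.3,
        seed=seed + 100,
    )
    series, gt_masks, _ = generate_phantom_series(spec)
    _, report = run_pipeline(series, cfg)
    gt_volume = hematoma_volume_ml(gt_masks, series)
    return {
        "predicted_volume_ml": report.volume_ml,
        "gt_volume_ml": gt_volume,
        "relative_error": abs(report.volume_ml - gt_volume) / gt_volume,
    }


def boxcox_diagnostic(seed: int = 7, n: int = 5000) -> float:
    """Profile-ML lambda on lognormal data (truth: 0)."""
    x = np.random.default_rng(seed).lognormal(0.0, 1.0, n)
    return box_cox(x)[1]


def boxtidwell_diagnostic(seed: int = 1, n: int = 2000, n_rep: int = 200) -> Dict:
    """Type-I error under a linear-logit truth; power under a log truth."""
    rng = np.random.default_rng(seed)
    rej_null = rej_alt = 0
    for _ in range(n_rep):
        x = rng.lognormal(3.0, 0.5, n)
        p_lin = 1 / (1 + np.exp(-(-2.0 + 0.08 * x)))
        y = (rng.random(n) < p_lin).astype(float)
        rej_null += box_tidwell(x, None, y) < 0.05
        x2 = rng.lognormal(3.0, 0.5, n)
        p_log = 1 / (1 + np.exp(-(-6.0 + 2.0 * np.log(x2))))
        y2 = (rng.random(n) < p_log).astype(float)
        rej_alt += box_tidwell(x2, None, y2) < 0.05
    return {"type1_error": rej_null / n_rep, "power": rej_alt / n_rep}


def coverage_diagnostic(seed: int = 1, n: int = 5000, n_seeds: int = 20) -> float:
    """Share of true coefficients inside their 95% Wald interval."""
    inside = total = 0
    for k in range(n_seeds):
        df = generate_cohort(CohortSpec(n_patients=n, seed=seed + k))
        est = recover_coefficients(df, "CRASH_CT_VOL_SUB", "A", boxcox_lambda=0.0)
        for name in est.index:
            true = DEFAULT_COEF_A["intercept" if name == "intercept" else name]
            inside += est.loc[name, "ci_low"] <= true <= est.loc[name, "ci_high"]
            total += 1
    return inside / total
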
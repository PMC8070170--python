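"""End-to-end orchestration: simulate, build samples, augment, train, fuse, evaluate.

``run_pipeline`` executes the whole workflow on phantom data and returns a
JSON-serializable report with the per-branch and fused test metrics. Every
stage draws its randomness from one seed, so a report is reproducible from
the config alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import sample_builder
from .augmentation import AugmentConfig, offline_expand
from .core_io import NoduleCase
from .estimators import HybridNoduleClassifier
from .evaluation import confusion, metrics_from_confusion, roc_auc
from .synthetic import PhantomConfig, generate_dataset

logger = logging.getLogger("nodulefusion")

__all__ = ["PipelineConfig", "run_pipeline", "cases_to_arrays"]


@dataclass
class PipelineConfig:
    """One document holding every stage's knobs for a miniature run.

    Defaults are the miniature study conditions: a 72+122 / 25+25 phantom
    split, channel widths (16, 32, 256) (feature length stays 256), and the
    published optimizer settings.
    """

    n_pos: int = 97
    n_neg: int = 147
    n_test_per_class: int = 25
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    offline_factor_pos: int = 1
    offline_factor_neg: int = 1
    channels: tuple[int, int, int] = (16, 32, 256)
    kernel_size: int = 3
    lr_2d: float = 0.004
    lr_3d: float = 0.02
    epochs_2d: int = 12
    epochs_3d: int = 8
    batch_size: int = 16
    cutmix_prob: float = 0.5
    gbt_max_depth: int = 8
    gbt_learning_rate: float = 0.02
    gbt_rounds: int = 60
    seed: int = 0


def cases_to_arrays(cases: list[NoduleCase]):
    """Build per-case 2D and 3D sample arrays (network-ready) plus labels."""
    s2d = [sample_builder.build_sample_2d(c) for c in cases]
    s3d = [sample_builder.build_sample_3d(c) for c in cases]
    x2d = np.stack([s.channels for s in s2d]) if s2d else np.zeros((0, 3, 32, 32))
    x3d_samples = np.stack([s.volume for s in s3d]) if s3d else np.zeros((0, 32, 32, 7))
    y = np.array([c.label for c in cases], dtype=np.float64)
    return x2d, x3d_samples, y, s2d, s3d


def _augmented_arrays(s2d, s3d, y, cfg: PipelineConfig, rng):
    """Offline-expand the training samples per class and re-stack arrays."""
    if cfg.offline_factor_pos == 1 and cfg.offline_factor_neg == 1:
        x2d = np.stack([s.channels for s in s2d])
        x3d = np.stack([s.volume for s in s3d])
        return x2d, x3d, y, y
    aug_cfg = AugmentConfig(
        offline_factor_pos=cfg.offline_factor_pos,
        offline_factor_neg=cfg.offline_factor_neg,
    )
    out2d, out3d = [], []
    for samples, out in ((s2d, out2d), (s3d, out3d)):
        pos = [s for s in samples if s.label >= 0.5]
        neg = [s for s in samples if s.label < 0.5]
        out.extend(offline_expand(pos, cfg.offline_factor_pos, rng, aug_cfg))
        out.extend(offline_expand(neg, cfg.offline_factor_neg, rng, aug_cfg))
    x2d = np.stack([s.channels for s in out2d])
    x3d = np.stack([s.volume for s in out3d])
    y2d = np.array([s.label for s in out2d])
    y3d = np.array([s.label for s in out3d])
    return x2d, x3d, y2d, y3d


def _branch_report(probs, y_test):
    cm = confusion(y_test, probs, threshold=0.5)
    rep = metrics_from_confusion(cm)
    rep.roc_points, rep.auc = roc_auc(y_test, probs)
    d = rep.as_dict()
    d["confusion"] = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
    return d


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run simulate -> build-samples -> augment -> train 2D/3D -> fuse -> evaluate."""
    cfg = config or PipelineConfig()
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)

    logger.info("stage=simulate n_pos=%d n_neg=%d seed=%d", cfg.n_pos, cfg.n_neg, cfg.seed)
    cases, split = generate_dataset(cfg.n_pos, cfg.n_neg, cfg.phantom, rng,
                                    cfg.n_test_per_class)
    by_id = {c.case_id: c for c in cases}
    train_cases = [by_id[i] for i in split.train_cases]
    test_cases = [by_id[i] for i in split.test_cases]

    logger.info("stage=build-samples train=%d test=%d", len(train_cases), len(test_cases))
    x2d_tr, x3d_tr, y_tr, s2d_tr, s3d_tr = cases_to_arrays(train_cases)
    x2d_te, x3d_te, y_te, _, _ = cases_to_arrays(test_cases)

    logger.info("stage=augment factors=(%d, %d)", cfg.offline_factor_pos, cfg.offline_factor_neg)
    ax2d, ax3d, ay2d, ay3d = _augmented_arrays(s2d_tr, s3d_tr, y_tr, cfg, rng)

    model = HybridNoduleClassifier(
        channels=cfg.channels, kernel_size=cfg.kernel_size,
        lr_2d=cfg.lr_2d, lr_3d=cfg.lr_3d,
        epochs_2d=cfg.epochs_2d, epochs_3d=cfg.epochs_3d,
        batch_size=cfg.batch_size, cutmix_prob=cfg.cutmix_prob,
        gbt_max_depth=cfg.gbt_max_depth, gbt_learning_rate=cfg.gbt_learning_rate,
        gbt_rounds=cfg.gbt_rounds, random_state=cfg.seed,
    )
    logger.info("stage=train-2d epochs=%d lr=%g", cfg.epochs_2d, cfg.lr_2d)
    model.cnn2d_ = model._branch(2, cfg.lr_2d, cfg.epochs_2d, cfg.seed).fit(ax2d, ay2d)
    logger.info("stage=train-3d epochs=%d lr=%g", cfg.epochs_3d, cfg.lr_3d)
    model.cnn3d_ = model._branch(3, cfg.lr_3d, cfg.epochs_3d, cfg.seed + 1).fit(ax3d, ay3d)

    logger.info("stage=fuse gbt=(depth=%d, lr=%g, rounds=%d)",
                cfg.gbt_max_depth, cfg.gbt_learning_rate, cfg.gbt_rounds)
    from .fusion import GBTConfig, fuse_vectors, predict_fused, train_gbt

    fused_tr = fuse_vectors(model.cnn3d_.transform(x3d_tr), model.cnn2d_.transform(x2d_tr))
    model.gbt_ = train_gbt(
        fused_tr, y_tr.astype(int),
        GBTConfig(max_depth=cfg.gbt_max_depth, learning_rate=cfg.gbt_learning_rate,
                  n_rounds=cfg.gbt_rounds, seed=cfg.seed),
    )
    model.classes_ = np.array([0, 1])

    logger.info("stage=evaluate n_test=%d", len(test_cases))
    p2d = model.cnn2d_.predict_proba(x2d_te)[:, 1]
    p3d = model.cnn3d_.predict_proba(x3d_te)[:, 1]
    fused_te = fuse_vectors(model.cnn3d_.transform(x3d_te), model.cnn2d_.transform(x2d_te))
    p_fused = predict_fused(model.gbt_, fused_te)

    report = {
        "config": {
            "seed": cfg.seed,
            "n_train": len(train_cases),
            "n_test": len(test_cases),
            "channels": list(cfg.channels),
            "epochs_2d": cfg.epochs_2d,
            "epochs_3d": cfg.epochs_3d,
        },
        "network_2d": _branch_report(p2d, y_te),
        "network_3d": _branch_report(p3d, y_te),
        "fused": _branch_report(p_fused, y_te),
        "runtime_s": round(time.time() - t0, 2),
    }
    report["_model"] = model  # stripped before JSON serialization
    report["_test_labels"] = y_te
    return report
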
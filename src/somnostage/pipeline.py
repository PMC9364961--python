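"""End-to-end pipeline: simulate -> split -> resample -> train -> evaluate.

Each stage is logged with its wall time and the governing seed; artifacts
(EDF nights, checkpoint, per-epoch curves, metric tables) land under the
configured output directory.  When ``reuse_existing`` is set and a stage's
outputs are already on disk, the stage is skipped and the files are read
back instead.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluation import confusion, report
from .io import export_dataset, load_dataset
from .model import build_model, load_checkpoint, predict, save_checkpoint
from .synth import generate_dataset
from .training import (SplitPlan, resample, split_by_subject, train,
                       validation_folds)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.1f s", stage, dt)
                return False
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    return _Timer()


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the full pipeline; returns artifact paths and headline metrics."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = out_dir / "data"
    ckpt_path = out_dir / "model.npz"
    logger.info("pipeline seed = %d, output -> %s", config.seed, out_dir)

    with _timed("simulate"):
        if config.reuse_existing and data_dir.exists() and any(
            data_dir.glob("*.edf")
        ):
            logger.info("reusing existing EDF nights in %s", data_dir)
            records = load_dataset(data_dir)
        else:
            gen = config.generator
            records = generate_dataset(
                gen.subjects, gen.nights_per_subject, gen.epochs_per_night,
                fs_hz=gen.fs_hz, seed=config.seed,
            )
            export_dataset(records, data_dir)

    with _timed("split"):
        subjects = sorted({r.subject_id for r in records})
        if config.split.test_subjects:
            test_subjects = tuple(config.split.test_subjects)
        else:
            k = min(config.split.n_test_subjects, max(len(subjects) - 1, 0))
            test_subjects = tuple(subjects[len(subjects) - k:])
        plan = SplitPlan(
            train_subjects=tuple(s for s in subjects if s not in test_subjects),
            test_subjects=test_subjects,
        )
        train_records, test_records = split_by_subject(records, plan)
        logger.info("%d train / %d test epochs (%d/%d subjects)",
                    len(train_records), len(test_records),
                    len(plan.train_subjects), len(plan.test_subjects))

    with _timed("resample"):
        if config.resample.enabled:
            rng = np.random.default_rng(config.seed)
            balanced = resample(train_records, config.resample.to_policy(), rng)
        else:
            balanced = train_records
        logger.info("training epochs after resampling: %d", len(balanced))

    with _timed("train"):
        model_config = config.model.to_model_config()
        if config.reuse_existing and ckpt_path.exists():
            logger.info("reusing existing checkpoint %s", ckpt_path)
            model = load_checkpoint(ckpt_path)
            curves_path = out_dir / "curves.csv"
        else:
            model = build_model(model_config, seed=config.seed)
            n_nights = len({(r.subject_id, r.night_id) for r in train_records})
            validation = None
            fit_records = balanced
            if n_nights >= 2:
                n_folds = min(config.split.validation_folds, n_nights)
                if n_folds >= 2:
                    _, validation = validation_folds(train_records, n_folds)[-1]
            result = train(
                model, fit_records,
                config.schedule.to_schedule(config.seed),
                validation=validation,
            )
            save_checkpoint(model, ckpt_path)
            curves_path = out_dir / "curves.csv"
            curves = result.curves()
            with open(curves_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                keys = ["epoch", "lr", "train_loss", "train_acc",
                        "val_loss", "val_acc"]
                writer.writerow(keys)
                for i in range(len(curves["epoch"])):
                    writer.writerow([curves[k][i] for k in keys])

    metrics: dict[str, float] = {}
    if test_records:
        with _timed("evaluate"):
            y_pred, _ = predict(model, test_records)
            y_true = [r.stage for r in test_records]
            cm = confusion(y_true, y_pred)
            metrics = report(cm, out_dir, stem="test")
            logger.info("test accuracy %.3f, macro F1 %.3f",
                        metrics["accuracy"], metrics["macro_f1"])

    return {
        "data_dir": data_dir,
        "checkpoint": ckpt_path,
        "curves": curves_path,
        "metrics": metrics,
    }
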
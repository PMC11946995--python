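"""Leave-one-specimen-out cross-validation and reporting.

The data are split at the specimen level: each fold holds out every
recording of one specimen (both sensors, both conditions) and trains a fresh
model on the remaining specimens.  Per-fold sensitivity (loose correctly
called loose), specificity, and accuracy are aggregated as
mean +/- population standard deviation (ddof=0) over folds — the convention
that reproduces the published per-fold table's summary values.

Normalization statistics and waveform augmentation are by default re-derived
inside each training fold (no leakage into the held-out specimen); the
``paper_faithful`` flag instead computes normalization statistics over the
entire dataset, matching the published protocol.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .excitation import DatasetManifest, Recording, read_recording
from .features import (
    FeatureConfig,
    Spectrogram,
    augment,
    compute_norm_stats,
    logmel,
    normalize,
)
from .model import ModelConfig, build_model, predict_batch, train

__all__ = [
    "FoldResult",
    "CVSummary",
    "Fold",
    "loso_folds",
    "confusion_metrics",
    "summarize",
    "cross_validate",
]


@dataclass
class FoldResult:
    """Confusion counts and derived metrics for one held-out specimen.

    Loose is the positive class; metrics are percentages.
    """

    test_specimen_id: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total


@dataclass
class CVSummary:
    """Per-metric mean and population-std spread over folds (percent)."""

    folds: list[FoldResult]
    mean: dict[str, float]
    spread: dict[str, float]

    def report(self) -> str:
        lines = ["fold,specimen_id,tp,fp,tn,fn,sensitivity,specificity,accuracy"]
        for i, f in enumerate(self.folds):
            lines.append(
                f"{i},{f.test_specimen_id},{f.tp},{f.fp},{f.tn},{f.fn},"
                f"{f.sensitivity:.2f},{f.specificity:.2f},{f.accuracy:.2f}"
            )
        return "\n".join(lines)

    def text_summary(self) -> str:
        return "\n".join(
            f"{m}: {self.mean[m]:.2f} +/- {self.spread[m]:.2f} %"
            for m in ("sensitivity", "specificity", "accuracy")
        )


class Fold(NamedTuple):
    specimen_id: int
    train: pd.DataFrame
    test: pd.DataFrame


def _rows(manifest: DatasetManifest | pd.DataFrame) -> pd.DataFrame:
    return manifest.rows if isinstance(manifest, DatasetManifest) else manifest


def loso_folds(manifest: DatasetManifest | pd.DataFrame) -> list[Fold]:
    """One fold per specimen: its rows are the test set, the rest train.

    The folds partition the manifest; at least two specimens are required.
    """
    rows = _rows(manifest)
    specimens = sorted(rows["specimen_id"].unique())
    if len(specimens) < 2:
        raise ValueError(
            f"leave-one-specimen-out needs >= 2 specimens, got {len(specimens)}"
        )
    folds = []
    for sid in specimens:
        mask = rows["specimen_id"] == sid
        folds.append(Fold(int(sid), rows[~mask].copy(), rows[mask].copy()))
    return folds


def _to01(labels) -> np.ndarray:
    out = []
    for lbl in labels:
        if isinstance(lbl, str):
            if lbl not in ("fixed", "loose"):
                raise ValueError(f"unknown label {lbl!r}")
            out.append(1 if lbl == "loose" else 0)
        else:
            out.append(int(lbl))
    return np.array(out)


def confusion_metrics(
    predictions: Sequence, labels: Sequence, test_specimen_id: int = -1
) -> FoldResult:
    """Confusion counts with loose as the positive class.

    Accepts "fixed"/"loose" strings or 0/1 integers; labels must contain both
    classes, otherwise sensitivity or specificity is undefined.
    """
    pred = _to01(predictions)
    true = _to01(labels)
    if pred.size != true.size:
        raise ValueError(f"length mismatch: {pred.size} predictions, {true.size} labels")
    if len(np.unique(true)) < 2:
        raise ValueError("labels must contain both classes; a metric is undefined")
    return FoldResult(
        test_specimen_id=test_specimen_id,
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def summarize(folds: Sequence[FoldResult] | Mapping[str, Sequence[float]]) -> CVSummary:
    """Aggregate folds as mean +/- population standard deviation (ddof=0).

    Also accepts a mapping of metric name -> per-fold percentages, for
    aggregating externally reported fold tables.
    """
    if isinstance(folds, Mapping):
        metric_values = {k: np.asarray(v, dtype=np.float64) for k, v in folds.items()}
        fold_list: list[FoldResult] = []
        if any(v.size == 0 for v in metric_values.values()) or not metric_values:
            raise ValueError("empty fold list")
    else:
        fold_list = list(folds)
        if not fold_list:
            raise ValueError("empty fold list")
        metric_values = {
            m: np.array([getattr(f, m) for f in fold_list])
            for m in ("sensitivity", "specificity", "accuracy")
        }
    mean = {m: float(v.mean()) for m, v in metric_values.items()}
    spread = {m: float(v.std(ddof=0)) for m, v in metric_values.items()}
    return CVSummary(folds=fold_list, mean=mean, spread=spread)


def _featurize_rows(
    rows: pd.DataFrame,
    feature_config: FeatureConfig,
    recordings: Mapping[str, Recording] | None,
    cache: dict[str, Spectrogram],
) -> list[tuple[Spectrogram, int]]:
    out = []
    for _, r in rows.iterrows():
        path = r["path"]
        if path not in cache:
            rec = recordings[path] if recordings is not None else read_recording(path)
            cache[path] = logmel(rec, feature_config)
        out.append((cache[path], 1 if r["condition"] == "loose" else 0))
    return out


def cross_validate(
    manifest: DatasetManifest | pd.DataFrame,
    feature_config: FeatureConfig | None = None,
    model_config: ModelConfig | None = None,
    *,
    n_augment: int = 1,
    paper_faithful: bool = False,
    seed: int = 0,
    recordings: Mapping[str, Recording] | None = None,
    log: list[str] | None = None,
) -> CVSummary:
    """Run the full leave-one-specimen-out experiment.

    For each fold: featurize, fit normalization statistics (training rows
    only, or the entire dataset under ``paper_faithful``), extend the training
    set with ``n_augment`` augmented copies per recording, train a fresh
    model, and score the held-out specimen.  All randomness derives from
    ``seed``; pass ``recordings`` (path -> Recording) to evaluate in-memory
    data without touching disk.
    """
    feature_config = feature_config or FeatureConfig()
    model_config = model_config or ModelConfig()
    rows = _rows(manifest)
    cache: dict[str, Spectrogram] = {}
    folds = loso_folds(rows)
    fold_results = []
    all_base = None
    if paper_faithful:
        all_specs = _featurize_rows(rows, feature_config, recordings, cache)
        all_base = compute_norm_stats([s for s, _ in all_specs], scope="entire_dataset")
    for k, fold in enumerate(folds):
        train_specs = _featurize_rows(fold.train, feature_config, recordings, cache)
        test_specs = _featurize_rows(fold.test, feature_config, recordings, cache)
        aug_specs: list[tuple[Spectrogram, int]] = []
        if n_augment > 0:
            for _, r in fold.train.iterrows():
                path = r["path"]
                for a in range(n_augment):
                    key = f"{path}#aug{a}"
                    if key not in cache:
                        rec = (recordings[path] if recordings is not None
                               else read_recording(path))
                        # seeded by row identity so the same augmented copy is
                        # shared by every fold that trains on this row
                        tag = zlib.crc32(path.encode()) & 0x7FFFFFFF
                        rng = np.random.default_rng(
                            np.random.SeedSequence([seed, 404, tag, a])
                        )
                        wav = augment(rec.samples, rng, sample_rate=rec.sample_rate)
                        aug_rec = Recording(
                            samples=wav, sample_rate=rec.sample_rate, meta=rec.meta
                        )
                        cache[key] = logmel(aug_rec, feature_config)
                    aug_specs.append(
                        (cache[key], 1 if r["condition"] == "loose" else 0)
                    )
        train_all = train_specs + aug_specs
        if paper_faithful:
            stats = all_base
        else:
            stats = compute_norm_stats([s for s, _ in train_all], scope="train_only")
        train_norm = [(normalize(s, stats), y) for s, y in train_all]
        test_norm = [(normalize(s, stats), y) for s, y in test_specs]
        cfg = replace(model_config, rng_seed=model_config.rng_seed + 1000 * (k + 1) + seed)
        net = build_model(cfg)
        if log is not None:
            log.append(f"fold {k} (test specimen {fold.specimen_id}): "
                       f"{len(train_norm)} train / {len(test_norm)} test")
        trained = train(net, train_norm, cfg, log=log)
        probs = predict_batch(trained, [s for s, _ in test_norm],
                              batch_size=cfg.batch_size)
        preds = (probs > cfg.threshold).astype(int)
        fold_results.append(
            confusion_metrics(preds, [y for _, y in test_norm],
                              test_specimen_id=fold.specimen_id)
        )
        if log is not None:
            f = fold_results[-1]
            log.append(
                f"fold {k}: sens={f.sensitivity:.2f}% spec={f.specificity:.2f}% "
                f"acc={f.accuracy:.2f}%"
            )
    return summarize(fold_results)
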
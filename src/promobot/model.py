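"""Feature combining, sequence vectorization, SVM training and k-fold CV.

The classifier is an RBF-kernel support vector machine (LIBSVM via
scikit-learn) on min-max scaled count features: one count per selected
hexamer plus one min-frequency value per selected triplet pair.  Feature
selection runs on the training folds only; the held-out fold is scored with
promoter as the positive class, and sensitivity/specificity are reported as
round-half-up integer percentages, averaged the same way across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from ._kmers import count_matrix, kmer_index
from .fdafsa import compute_hexamer_scores, select_top_fraction
from .rtpfsga import GAConfig, TripletPair, run_ga
from .seqio import LabeledDataset, Sequence

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
PROMOTER, NONPROMOTER = "promoter", "nonpromoter"


class ModelFormatError(ValueError):
    """Raised when a persisted model artifact cannot be used."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FeatureSet:
    """Merged, duplicate-free hexamer + RTP feature list.

    No retained hexamer may equal either concatenation of a retained pair's
    triplets — such hexamers carry the same information as the pair and are
    excluded when the sets are combined.
    """

    hexamers: tuple[str, ...]
    rtps: tuple[TripletPair, ...]

    def __post_init__(self) -> None:
        if len(set(self.hexamers)) != len(self.hexamers):
            raise ValueError("duplicate hexamers in feature set")
        if len(set(self.rtps)) != len(self.rtps):
            raise ValueError("duplicate triplet pairs in feature set")
        banned = _concatenation_hexamers(self.rtps)
        overlap = banned & set(self.hexamers)
        if overlap:
            raise ValueError(
                f"hexamers {sorted(overlap)} duplicate RTP concatenations"
            )

    def __len__(self) -> int:
        return len(self.hexamers) + len(self.rtps)


def _concatenation_hexamers(rtps) -> set[str]:
    out: set[str] = set()
    for r in rtps:
        out.add(r.t1 + r.t2)
        out.add(r.t2 + r.t1)
    return out


def combine_features(
    hexamers: list[str], rtps: list[TripletPair]
) -> FeatureSet:
    """Merge the two feature sets, keeping only distinct information.

    Every hexamer equal to t1+t2 or t2+t1 of a selected pair is dropped
    (order of the survivors preserved); the pairs are kept as-is.
    """
    banned = _concatenation_hexamers(rtps)
    kept = [h for h in hexamers if h not in banned]
    return FeatureSet(hexamers=tuple(kept), rtps=tuple(rtps))


def vectorize(
    seq: Sequence, features: FeatureSet, both_strands: bool = True
) -> np.ndarray:
    """Count vector for one sequence: hexamer counts then RTP min-frequencies."""
    return vectorize_many([seq], features, both_strands)[0]


def vectorize_many(
    seqs: list[Sequence], features: FeatureSet, both_strands: bool = True
) -> np.ndarray:
    """Feature matrix, one row per sequence (vectorized batch path)."""
    n = len(seqs)
    if len(features) == 0:
        return np.empty((n, 0), dtype=float)
    blocks = []
    if features.hexamers:
        hex_counts = count_matrix(seqs, 6, both_strands)
        cols = [kmer_index(h) for h in features.hexamers]
        blocks.append(hex_counts[:, cols])
    if features.rtps:
        tri_counts = count_matrix(seqs, 3, both_strands)
        rtp_cols = [
            np.minimum(
                tri_counts[:, kmer_index(r.t1)], tri_counts[:, kmer_index(r.t2)]
            )
            for r in features.rtps
        ]
        blocks.append(np.column_stack(rtp_cols))
    return np.hstack(blocks).astype(float)


@dataclass(frozen=True)
class SvmParams:
    """RBF SVM hyperparameters; LIBSVM defaults (C=1, gamma=1/n_features)."""

    C: float = 1.0
    gamma: float | str = "auto"
    kernel: str = "rbf"


@dataclass
class PromoterModel:
    """Trained artifact: feature set, fitted scaler and fitted SVM."""

    features: FeatureSet
    scaler: MinMaxScaler
    svm: SVC
    both_strands: bool = True


def train_classifier(
    train: LabeledDataset,
    features: FeatureSet,
    svm_params: SvmParams = SvmParams(),
    both_strands: bool = True,
) -> PromoterModel:
    """Fit per-feature min-max scaling on the training vectors, then the SVM.

    Labels are promoter=+1, non-promoter=-1.  A feature constant across the
    training data is kept and scales to 0 (logged).
    """
    seqs = train.promoters + train.nonpromoters
    X = vectorize_many(seqs, features, both_strands)
    y = np.concatenate(
        [np.ones(len(train.promoters)), -np.ones(len(train.nonpromoters))]
    )
    scaler = MinMaxScaler().fit(X)
    constant = int((scaler.data_range_ == 0).sum())
    if constant:
        logger.info("%d constant feature(s) in training data, scaled to 0", constant)
    svm = SVC(C=svm_params.C, gamma=svm_params.gamma, kernel=svm_params.kernel)
    svm.fit(scaler.transform(X), y)
    return PromoterModel(
        features=features, scaler=scaler, svm=svm, both_strands=both_strands
    )


def predict(model: PromoterModel, seqs: list[Sequence]) -> list[str]:
    """Class labels ('promoter'/'nonpromoter'), one per sequence, in order."""
    if not seqs:
        return []
    X = model.scaler.transform(
        vectorize_many(seqs, model.features, model.both_strands)
    )
    return [PROMOTER if y > 0 else NONPROMOTER for y in model.svm.predict(X)]


@dataclass(frozen=True)
class FoldResult:
    """Confusion counts and integer-percent metrics for one CV fold."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if self.tp + self.fn == 0:
            raise ValueError("no positive test sequences: sensitivity undefined")
        if self.tn + self.fp == 0:
            raise ValueError("no negative test sequences: specificity undefined")

    @property
    def sensitivity(self) -> int:
        return round_half_up(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity(self) -> int:
        return round_half_up(100.0 * self.tn / (self.tn + self.fp))


def evaluate_fold(model: PromoterModel, test: LabeledDataset) -> FoldResult:
    """Confusion counts on a held-out fold, promoter as positive class."""
    pred_pos = predict(model, test.promoters)
    pred_neg = predict(model, test.nonpromoters)
    tp = sum(p == PROMOTER for p in pred_pos)
    tn = sum(p == NONPROMOTER for p in pred_neg)
    return FoldResult(
        tp=tp, fn=len(pred_pos) - tp, tn=tn, fp=len(pred_neg) - tn
    )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration for feature selection + SVM training."""

    fraction: float = 0.25
    ga: GAConfig = field(default_factory=GAConfig)
    svm: SvmParams = field(default_factory=SvmParams)
    both_strands: bool = True


@dataclass
class CVReport:
    folds: list[FoldResult]
    feature_counts: list[int]

    @property
    def avg_sensitivity(self) -> int:
        return round_half_up(np.mean([f.sensitivity for f in self.folds]))

    @property
    def avg_specificity(self) -> int:
        return round_half_up(np.mean([f.specificity for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": i,
                "TP": f.tp,
                "FN": f.fn,
                "TN": f.tn,
                "FP": f.fp,
                "sensitivity": f.sensitivity,
                "specificity": f.specificity,
            }
            for i, f in enumerate(self.folds)
        ]
        rows.append(
            {
                "fold": "average",
                "TP": "",
                "FN": "",
                "TN": "",
                "FP": "",
                "sensitivity": self.avg_sensitivity,
                "specificity": self.avg_specificity,
            }
        )
        return pd.DataFrame(rows)


def average_percent(values: list[int]) -> int:
    """Round-half-up average of per-fold integer percentages."""
    return round_half_up(float(np.mean(values)))


def select_features(
    train: LabeledDataset, config: PipelineConfig
) -> FeatureSet:
    """FDAFSA top fraction + RTPFSGA significant pairs, combined."""
    hexamers = select_top_fraction(
        compute_hexamer_scores(train, both_strands=config.both_strands),
        config.fraction,
    )
    rtps = run_ga(
        train,
        replace(config.ga, both_strands=config.both_strands),
    )
    return combine_features(hexamers, rtps)


def cross_validate(data: LabeledDataset, config: PipelineConfig) -> CVReport:
    """Per-fold pipeline: select features on training folds, train, evaluate.

    Feature selection never sees the held-out fold.  Each fold's GA is
    seeded with config.ga.seed + fold index so folds are independent yet
    reproducible.
    """
    if data.n_folds < 2:
        raise ValueError("dataset needs a fold assignment with k >= 2")
    folds: list[FoldResult] = []
    feature_counts: list[int] = []
    for fold in range(data.n_folds):
        train = data.training_split(fold)
        test = data.test_split(fold)
        fold_config = replace(
            config, ga=replace(config.ga, seed=config.ga.seed + fold)
        )
        features = select_features(train, fold_config)
        feature_counts.append(len(features))
        logger.info(
            "fold %d: %d hexamers + %d RTPs = %d features",
            fold,
            len(features.hexamers),
            len(features.rtps),
            len(features),
        )
        model = train_classifier(
            train, features, config.svm, config.both_strands
        )
        folds.append(evaluate_fold(model, test))
    return CVReport(folds=folds, feature_counts=feature_counts)


def save_model(model: PromoterModel, path) -> None:
    """Persist the trained artifact (scaler + SVM + features, versioned)."""
    joblib.dump(
        {
            "format": "promobot-model",
            "version": MODEL_FORMAT_VERSION,
            "features": model.features,
            "scaler": model.scaler,
            "svm": model.svm,
            "both_strands": model.both_strands,
        },
        path,
    )


def load_model(path) -> PromoterModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if (
        not isinstance(payload, dict)
        or payload.get("format") != "promobot-model"
    ):
        raise ModelFormatError(f"{path} is not a promobot model artifact")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model version {payload.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return PromoterModel(
        features=payload["features"],
        scaler=payload["scaler"],
        svm=payload["svm"],
        both_strands=payload["both_strands"],
    )
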
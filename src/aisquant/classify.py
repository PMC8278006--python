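"""Per-neuron feature extraction and repeated 70/30 SVM classification.

Each neuron contributes a 5-element feature vector: interquartile range,
excess kurtosis, skewness and root-mean-square of its denoised
first-25-micrometer AIS intensity profile, with the axo:dendritic ratio
appended. A support-vector classifier is trained on a random 70% of the
cohort and scored on the remaining 30%; the experiment is repeated (100
times by default) with a fresh split each time and accuracies are averaged.

Conventions: quantiles use linear interpolation; skewness and kurtosis use
uncorrected central-moment estimators (``m3 / m2**1.5`` and
``m4 / m2**2 - 3``), matching common time-series feature-library defaults;
features are z-scored with training-set statistics only; the train size is
``floor(0.7 n)``, which reproduces the 56/24, 47/21 and 50/22 splits of
cohorts of 80, 68 and 72 neurons.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .errors import FeatureError
from .profiles import IntensityProfile
from .quant import smooth_profile

FEATURE_NAMES = ("iqr", "kurtosis", "skewness", "rms", "adr")
DEFAULT_WINDOW_UM = 25.0
DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_N_REPEATS = 100


@dataclass(frozen=True)
class FeatureVector:
    """The 5 per-neuron classifier inputs."""

    iqr: float
    kurtosis: float
    skewness: float
    rms: float
    adr: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise FeatureError(f"non-finite feature in {arr}")
        if self.iqr < 0 or self.rms < 0:
            raise FeatureError("iqr and rms must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.iqr, self.kurtosis, self.skewness, self.rms, self.adr])

    def __len__(self) -> int:
        return 5


@dataclass
class ClassificationResult:
    """Aggregate of the repeated random-split experiments."""

    per_repeat_accuracy: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    n_repeats: int
    train_size: int
    test_size: int
    confusion_totals: Dict[str, int]
    seed: int
    positive_label: str


def denoise_profile(profile: IntensityProfile, window_um: float = DEFAULT_WINDOW_UM,
                    window: int = 3) -> IntensityProfile:
    """Crop to the first ``window_um`` micrometers, then 3-point average.

    The crop keeps ``floor(window_um / pixel) + 1`` samples (positions 0
    through the last one at or below 25 um); profiles that do not span the
    window exclude the neuron with an explicit error.
    """
    p = profile.pixel_size_um
    n_keep = int(math.floor(window_um / p)) + 1
    if profile.n < n_keep:
        raise FeatureError(
            f"profile spans {profile.span_um:.2f} um < {window_um} um; neuron excluded")
    cropped = profile.replace(positions_um=profile.positions_um[:n_keep],
                              intensities=profile.intensities[:n_keep])
    return smooth_profile(cropped, window)


def compute_features(denoised: IntensityProfile, adr: float) -> FeatureVector:
    """IQR, excess kurtosis, skewness, RMS of a denoised profile, plus adr."""
    x = denoised.intensities
    if x.size < 4:
        raise FeatureError(f"need >= 4 samples for moment features, got {x.size}")
    if not np.isfinite(adr):
        raise FeatureError(f"axo:dendritic ratio is not finite ({adr})")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise FeatureError("zero-variance profile: skewness/kurtosis undefined")
    q25, q75 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return FeatureVector(
        iqr=float(q75 - q25),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
        skewness=float(stats.skew(x, bias=True)),
        rms=float(np.sqrt(np.mean(x ** 2))),
        adr=float(adr),
    )


def features_from_cohort(
    records,
    threshold_fraction: float = 0.15,
    smooth_window: int = 3,
) -> Tuple[List[FeatureVector], List[str]]:
    """Quantify each neuron record and build its 5-feature vector.

    Convenience path used when the cohort is held in memory; the file-based
    pipeline stages produce the same numbers via the serialized tables.
    """
    from .quant import quantify_neuron, subtract_background

    feats: List[FeatureVector] = []
    labels: List[str] = []
    for rec in records:
        bg = rec.ground_truth.background_level if rec.ground_truth else 0.0
        q = quantify_neuron(rec, bg, bg, threshold_fraction, smooth_window)
        profile = subtract_background(rec.ais_profile, bg)
        feats.append(compute_features(denoise_profile(profile), q.adr))
        labels.append(rec.treatment)
    return feats, labels


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    for c in (tp, tn, fp, fn):
        if c < 0:
            raise FeatureError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise FeatureError("accuracy undefined for an empty test set")
    return (tp + tn) / total


def split_cohort(
    n: int,
    rng: np.random.Generator,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform random unstratified split: floor(f*n) train, the rest test."""
    if n < 4:
        raise FeatureError(f"cohort of {n} too small to split")
    if not 0 < train_fraction < 1:
        raise FeatureError(f"train_fraction must be in (0, 1), got {train_fraction}")
    perm = rng.permutation(n)
    k = int(math.floor(train_fraction * n))
    return perm[:k], perm[k:]


def _stratified_split(labels: np.ndarray, rng: np.random.Generator,
                      train_fraction: float) -> Tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        perm = rng.permutation(idx)
        k = int(math.floor(train_fraction * idx.size))
        train.append(perm[:k])
        test.append(perm[k:])
    return np.concatenate(train), np.concatenate(test)


def run_repeated_classification(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[str],
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    kernel: str = "rbf",
    c: float = 1.0,
    gamma: str | float = "scale",
    stratified: bool = False,
) -> ClassificationResult:
    """Repeated random-split SVM experiment.

    Each repeat draws a fresh 70/30 split, z-scores the features with the
    training-set mean and standard deviation (degenerate zero-sd columns fall
    back to unit scale with a warning), fits a support-vector classifier and
    scores the held-out neurons. The per-repeat accuracies are aggregated as
    mean and standard deviation, and confusion counts are summed over
    repeats with the lexicographically larger label as the positive class.
    """
    X = np.array([f.as_array() if isinstance(f, FeatureVector) else np.asarray(f, float)
                  for f in features])
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise FeatureError("features and labels must have equal length")
    classes = np.unique(y)
    if classes.size != 2:
        raise FeatureError(f"need exactly two classes, got {list(classes)}")
    for lab in classes:
        if (y == lab).sum() < 2:
            raise FeatureError(f"class {lab!r} has fewer than 2 members")
    positive = str(classes[-1])

    n = X.shape[0]
    accuracies = np.empty(n_repeats)
    totals = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    train_size = test_size = 0
    for i in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        if stratified:
            train_idx, test_idx = _stratified_split(y, rng, train_fraction)
        else:
            train_idx, test_idx = split_cohort(n, rng, train_fraction)
        train_size, test_size = train_idx.size, test_idx.size
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if np.unique(y_tr).size < 2:
            # an unstratified draw can miss a class; score the repeat at the
            # majority-vote level rather than aborting the experiment
            warnings.warn("single-class training split; predicting majority class")
            pred = np.full(y_te.shape, y_tr[0])
        else:
            mean = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            if np.any(sd == 0):
                warnings.warn("zero-variance feature column; unit-scale fallback")
                sd = np.where(sd == 0, 1.0, sd)
            clf = SVC(kernel=kernel, C=c, gamma=gamma)
            clf.fit((X_tr - mean) / sd, y_tr)
            pred = clf.predict((X_te - mean) / sd)
        tp = int(np.sum((pred == positive) & (y_te == positive)))
        tn = int(np.sum((pred != positive) & (y_te != positive)))
        fp = int(np.sum((pred == positive) & (y_te != positive)))
        fn = int(np.sum((pred != positive) & (y_te == positive)))
        totals["tp"] += tp
        totals["tn"] += tn
        totals["fp"] += fp
        totals["fn"] += fn
        accuracies[i] = accuracy(tp, tn, fp, fn)
    return ClassificationResult(
        per_repeat_accuracy=accuracies,
        mean_accuracy=float(accuracies.mean()),
        sd_accuracy=float(accuracies.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
        train_size=train_size,
        test_size=test_size,
        confusion_totals=totals,
        seed=seed,
        positive_label=positive,
    )
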
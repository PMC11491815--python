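"""Window-level behaviour classification with gradient-boosted trees.

The trace is cut into consecutive non-overlapping 16-sample windows
(~0.7 s at 23 Hz — long enough for ~14 wingbeat cycles of a 20 Hz
wingbeat, short enough to rarely mix behaviours).  Per-window summary
features feed an XGBoost multi-class model over the six behaviour
classes; evaluation is by confusion matrix with per-class precision and
recall.

Feature set (fixed, documented contract): per axis mean, standard
deviation, min, max, skewness and excess kurtosis; window-local mean and
max VeDBA (5-sample running mean inside the window); the three pairwise
axis correlations; and the dominant non-DC frequency bin of the z-axis
spectrum with its power.  Degenerate (constant) windows define
correlations, skewness and kurtosis as 0.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signal import AccelTrace, running_mean

DEFAULT_WINDOW_SAMPLES = 16

FEATURE_NAMES = tuple(
    f"{ax}_{stat}"
    for ax in ("ax", "ay", "az")
    for stat in ("mean", "sd", "min", "max", "skew", "kurt")
) + (
    "corr_xy",
    "corr_xz",
    "corr_yz",
    "vedba_mean",
    "vedba_max",
    "zfreq_hz",
    "zfreq_power",
)


@dataclass(frozen=True)
class WindowLabels:
    """One behaviour class per complete window of a trace."""

    window_samples: int
    sample_rate: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.window_samples < 1 or self.sample_rate <= 0:
            raise ValueError("invalid window parameters")
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))

    @property
    def window_duration(self) -> float:
        """Window length in seconds (16 samples at 23 Hz ~= 0.7 s)."""
        return self.window_samples / self.sample_rate

    def __len__(self) -> int:
        return len(self.labels)


def make_windows(trace: AccelTrace, window_samples: int = DEFAULT_WINDOW_SAMPLES) -> list[tuple[int, int]]:
    """Consecutive half-open sample ranges [i*w, (i+1)*w); the trailing
    partial window is dropped.  A trace shorter than one window yields
    an empty list."""
    if window_samples < 2:
        raise ValueError(f"window_samples must be >= 2, got {window_samples}")
    n_windows = trace.n_samples // window_samples
    return [(i * window_samples, (i + 1) * window_samples) for i in range(n_windows)]


def window_true_labels(
    sample_labels: np.ndarray,
    windows: list[tuple[int, int]],
    sample_rate: float,
) -> WindowLabels:
    """Majority-vote ground-truth class per window (ties: first seen)."""
    labels = []
    for start, end in windows:
        counts = Counter(sample_labels[start:end])
        labels.append(counts.most_common(1)[0][0])
    w = windows[0][1] - windows[0][0] if windows else DEFAULT_WINDOW_SAMPLES
    return WindowLabels(w, sample_rate, np.asarray(labels, dtype=object))


def _window_vedba(arr: np.ndarray, smooth: int = 5) -> np.ndarray:
    """Window-local VeDBA, shape (m, w): running mean inside each window."""
    w = arr.shape[1]
    smooth = min(smooth, w if w % 2 == 1 else w - 1)
    static = running_mean(arr, smooth, axis=1)
    dba = arr - static
    return np.sqrt((dba**2).sum(axis=2))


def extract_features(trace: AccelTrace, windows: list[tuple[int, int]]) -> pd.DataFrame:
    """One feature row per window; deterministic given the trace."""
    if not windows:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    w = windows[0][1] - windows[0][0]
    starts = np.array([s for s, e in windows])
    if np.all(np.diff(starts, prepend=starts[0] - w) == w) and windows[-1][1] <= trace.n_samples:
        arr = trace.data[starts[0]: windows[-1][1]].reshape(len(windows), w, 3)
    else:
        arr = np.stack([trace.data[s:e] for s, e in windows])

    feats: dict[str, np.ndarray] = {}
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1)
    degenerate = sd < 1e-10  # constant signal: moments/correlations -> 0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = np.where(degenerate, 0.0, np.nan_to_num(sps.skew(arr, axis=1), nan=0.0))
        kurt = np.where(degenerate, 0.0, np.nan_to_num(sps.kurtosis(arr, axis=1), nan=0.0))
    for j, ax in enumerate(("ax", "ay", "az")):
        feats[f"{ax}_mean"] = mean[:, j]
        feats[f"{ax}_sd"] = sd[:, j]
        feats[f"{ax}_min"] = arr[:, :, j].min(axis=1)
        feats[f"{ax}_max"] = arr[:, :, j].max(axis=1)
        feats[f"{ax}_skew"] = skew[:, j]
        feats[f"{ax}_kurt"] = kurt[:, j]

    centred = arr - mean[:, None, :]
    for name, (a, b) in {"corr_xy": (0, 1), "corr_xz": (0, 2), "corr_yz": (1, 2)}.items():
        cov = (centred[:, :, a] * centred[:, :, b]).mean(axis=1)
        ok = ~degenerate[:, a] & ~degenerate[:, b]
        denom = np.where(ok, sd[:, a] * sd[:, b], 1.0)
        feats[name] = np.where(ok, cov / denom, 0.0)

    vw = _window_vedba(arr)
    feats["vedba_mean"] = vw.mean(axis=1)
    feats["vedba_max"] = vw.max(axis=1)

    spectrum = np.abs(np.fft.rfft(arr[:, :, 2], axis=1)) ** 2
    spectrum[:, 0] = 0.0  # ignore DC (gravity)
    kbin = spectrum.argmax(axis=1)
    feats["zfreq_hz"] = kbin * trace.sample_rate / w
    feats["zfreq_power"] = np.take_along_axis(spectrum, kbin[:, None], axis=1)[:, 0]

    return pd.DataFrame({name: feats[name] for name in FEATURE_NAMES})


@dataclass
class ClassifierModel:
    """A trained gradient-boosted behaviour classifier (raw booster)."""

    booster: "object"  # xgboost.Booster
    classes: np.ndarray
    feature_names: tuple[str, ...]

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        import xgboost

        raw = self.booster.predict(xgboost.DMatrix(X))
        if raw.ndim == 2:  # multi:softprob
            return raw.argmax(axis=1)
        return (raw > 0.5).astype(int)  # binary:logistic

    def save(self, path) -> None:
        """Serialise to ``path`` (booster JSON) plus ``path``.meta.json."""
        path = Path(path)
        self.booster.save_model(path)
        meta = {"classes": [str(c) for c in self.classes],
                "feature_names": list(self.feature_names)}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_classifier(path) -> ClassifierModel:
    import xgboost

    path = Path(path)
    booster = xgboost.Booster()
    booster.load_model(str(path))
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return ClassifierModel(booster, np.asarray(meta["classes"], dtype=object),
                           tuple(meta["feature_names"]))


DEFAULT_HYPERPARAMS = {"n_estimators": 200, "max_depth": 4, "learning_rate": 0.1}


def train_classifier(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train the boosted-tree model with inverse-frequency class weights.

    Requires at least two classes and 10 rows per present class; training
    is reproducible given the seed (single-threaded histogram trees).
    """
    import xgboost

    y_raw = np.asarray(labels, dtype=object)
    if len(y_raw) != len(features):
        raise ValueError("features and labels disagree in length")
    classes, y = np.unique(y_raw.astype(str), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training needs at least two behaviour classes")
    counts = np.bincount(y)
    if counts.min() < 10:
        lacking = classes[counts.argmin()]
        raise ValueError(f"class '{lacking}' has fewer than 10 training rows")

    params = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    model = xgboost.XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    sample_weight = (len(y) / (len(classes) * counts))[y]
    feature_names = tuple(features.columns)
    model.fit(features.to_numpy(dtype=float), y, sample_weight=sample_weight)
    return ClassifierModel(model.get_booster(), classes.astype(object), feature_names)


def predict(model: ClassifierModel, features: pd.DataFrame,
            window_samples: int = DEFAULT_WINDOW_SAMPLES,
            sample_rate: float = 23.0) -> WindowLabels:
    """One class per feature row; deterministic for a fixed model."""
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    idx = model.predict_indices(X)
    return WindowLabels(window_samples, sample_rate, model.classes[idx])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-by-class counts; rows are true classes, columns predicted."""

    counts: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    def recall_pct(self) -> pd.Series:
        """Per-class recall in percent: diagonal over the true-class total."""
        diag = pd.Series(np.diag(self.counts), index=self.counts.index, dtype=float)
        return 100.0 * diag / self.counts.sum(axis=1)

    def precision_pct(self) -> pd.Series:
        """Per-class precision in percent; NaN for never-predicted classes."""
        diag = pd.Series(np.diag(self.counts), index=self.counts.index, dtype=float)
        return 100.0 * diag / self.counts.sum(axis=0)

    def accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.to_numpy().sum())


def confusion(true: WindowLabels | np.ndarray, predicted: WindowLabels | np.ndarray) -> ConfusionMatrix:
    """Confusion matrix over all classes present in either sequence."""
    t = np.asarray(true.labels if isinstance(true, WindowLabels) else true, dtype=object)
    p = np.asarray(predicted.labels if isinstance(predicted, WindowLabels) else predicted, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    classes = sorted(set(t.astype(str)) | set(p.astype(str)))
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for ti, pi in zip(t.astype(str), p.astype(str)):
        table.loc[ti, pi] += 1
    return ConfusionMatrix(table)


def stratified_split(
    n: int, labels: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split (per-class shuffled tails)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels.astype(str)):
        idx = np.flatnonzero(labels.astype(str) == cls)
        rng.shuffle(idx)
        k = max(1, int(round(len(idx) * test_fraction)))
        test_idx.append(idx[:k])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(n), test)
    return train, test
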
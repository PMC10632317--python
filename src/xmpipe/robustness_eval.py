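"""Evaluation protocol: AUC with DeLong variance, paired DeLong test,
Fisher p-value combination, under-sampling, repeated splits, a reference
classifier, and single-axis perturbation sweeps.

The DeLong machinery is implemented from structural components (placement
values) rather than bootstrap; Fisher's method uses the regularized upper
incomplete gamma function for the chi-square survival probability.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.stats import rankdata

from .augment import (
    AugmentParams,
    PerturbSpec,
    apply_perturbation,
    rotate_flip,
    sample_augmentation,
)
from .lung_field import segment_lungs
from .preprocess import HistModParams, PreprocessMethod, preprocess_dispatch, resize_to
from .xray_io import NormImage


class DegenerateInputError(ValueError):
    """Score/label input on which the statistic is undefined."""


@dataclass(frozen=True)
class LabeledScores:
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        scores = np.asarray(self.scores, dtype=np.float64)
        if labels.shape != scores.shape or labels.ndim != 1:
            raise ValueError("labels and scores must be 1-D vectors of equal length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "scores", scores)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass(frozen=True)
class EvalResult:
    auc: float
    var: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


class SweepAxis(enum.Enum):
    GAMMA = "gamma"
    SHARP = "sharp"
    NOISE = "noise"

    @property
    def identity_value(self) -> float:
        return 1.0 if self is SweepAxis.GAMMA else 0.0


@dataclass(frozen=True)
class SweepResult:
    axis: SweepAxis
    grid: np.ndarray
    auc_mean: np.ndarray
    auc_ci: np.ndarray  # (len(grid), 2)
    n_repeats: int


def _placements(data: LabeledScores) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components via midranks.

    Returns (v10, v01, auc): per-positive and per-negative placement values
    whose means both equal the Mann-Whitney AUC with ties counted 1/2.
    """
    labels, scores = data.labels, data.scores
    m, n = data.n_pos, data.n_neg
    if m == 0 or n == 0:
        raise DegenerateInputError("both classes must be present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def roc_auc(data: LabeledScores) -> float:
    """AUC as the Mann-Whitney statistic with ties counted 1/2."""
    _, _, auc = _placements(data)
    return auc


def delong_variance(data: LabeledScores) -> float:
    if data.n_pos < 2 or data.n_neg < 2:
        raise DegenerateInputError("need >= 2 observations per class")
    v10, v01, _ = _placements(data)
    return float(np.var(v10, ddof=1) / data.n_pos + np.var(v01, ddof=1) / data.n_neg)


def delong_ci(data: LabeledScores, level: float = 0.95) -> EvalResult:
    """AUC with DeLong variance and normal-approximation CI, clipped to [0,1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    var = delong_variance(data)
    auc = roc_auc(data)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    ci = (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))
    return EvalResult(auc=auc, var=var, ci95=ci, n_pos=data.n_pos, n_neg=data.n_neg)


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    The same cases must be scored by both models.  Identical score vectors
    give p = 1; zero variance with a nonzero AUC difference reports p = 0
    with a warning.
    """
    a = LabeledScores(labels, scores_a)
    b = LabeledScores(labels, scores_b)
    if a.n_pos < 2 or a.n_neg < 2:
        raise DegenerateInputError("need >= 2 observations per class")
    v10a, v01a, auc_a = _placements(a)
    v10b, v01b, auc_b = _placements(b)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = float(np.var(d10, ddof=1) / a.n_pos + np.var(d01, ddof=1) / a.n_neg)
    diff = auc_a - auc_b
    if var <= 0.0:
        if abs(diff) < 1e-12:
            return 1.0
        warnings.warn(
            "degenerate DeLong comparison: zero variance with nonzero AUC difference",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df under H0."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvalues must be a nonempty 1-D vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("every p-value must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    # chi-square survival with 2k df via the regularized upper incomplete gamma
    combined = float(special.gammaincc(p.size, statistic / 2.0))
    return statistic, combined


def clamp_pvalues(pvalues) -> np.ndarray:
    """Replace exact zeros with machine epsilon (warns); for upstream use."""
    p = np.asarray(pvalues, dtype=np.float64).copy()
    if np.any(p == 0.0):
        warnings.warn("clamping p-values of exactly 0 to machine epsilon", RuntimeWarning)
        p[p == 0.0] = np.finfo(float).tiny
    return p


def undersample_majority(labels, seed: int) -> np.ndarray:
    """Indices keeping all minority cases plus an equal-size random subset
    of the majority class; sorted, reproducible per seed."""
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("both classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept_majority]))


def repeated_splits(
    n_pool: int, k: int, train_frac: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k random train/validation partitions of range(n_pool).

    Train size is round(train_frac * n_pool).  A single seed reproduces the
    identical list of splits, so different model settings can share them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(train_frac * n_pool))
    if n_train == 0 or n_train == n_pool:
        raise ValueError("train_frac leaves an empty partition")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(k):
        perm = rng.permutation(n_pool)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def _pixel_features(proc: NormImage, grid: int) -> np.ndarray:
    """Pooled intensities plus pooled gradient magnitudes, each channel
    centered per image.

    The gradient channel gives the model the edge/texture sensitivity of a
    convolutional network: informative on clean images but fragile under
    noise/blur, which is what the robustness sweeps probe.  Per-image
    channel centering removes global brightness / edge-energy offsets so
    contrast regimes share a common operating point.
    """
    intensity = resize_to(proc, grid).pixels.ravel()
    gy, gx = np.gradient(proc.pixels)
    gmag = np.hypot(gy, gx)
    scale = max(proc.shape[0] / grid, 1.0)
    pooled_grad = scale * _pool(gmag, grid).ravel()
    return np.concatenate([intensity - intensity.mean(), pooled_grad - pooled_grad.mean()])


def _pool(arr: np.ndarray, grid: int) -> np.ndarray:
    from skimage.transform import resize as _resize

    return _resize(arr, (grid, grid), order=1, anti_aliasing=arr.shape[0] > grid,
                   preserve_range=True)


@dataclass
class ReferenceClassifier:
    """Small stand-in model: preprocessing + pooled pixel features + ridge
    logistic regression.  Scores are probabilities in [0, 1]."""

    preprocess: PreprocessMethod
    feature_grid: int
    weights: np.ndarray
    bias: float
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    hist_params: HistModParams = field(default_factory=HistModParams)

    def features(self, img: NormImage) -> np.ndarray:
        mask = segment_lungs(img)
        proc = preprocess_dispatch(
            img,
            mask,
            self.preprocess,
            out_size=4 * self.feature_grid,
            hist_params=self.hist_params,
        )
        return _pixel_features(proc, self.feature_grid)

    def _score_features(self, feats: np.ndarray) -> float:
        z = (feats - self.feat_mean) / self.feat_scale
        logit = float(z @ self.weights + self.bias)
        return float(1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500))))

    def score(self, img: NormImage) -> float:
        return self._score_features(self.features(img))

    def score_batch(self, images) -> np.ndarray:
        return np.array([self.score(img) for img in images])

    def to_json(self, path) -> None:
        payload = {
            "preprocess": self.preprocess.value,
            "feature_grid": self.feature_grid,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feat_mean": self.feat_mean.tolist(),
            "feat_scale": self.feat_scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            preprocess=PreprocessMethod(payload["preprocess"]),
            feature_grid=int(payload["feature_grid"]),
            weights=np.asarray(payload["weights"]),
            bias=float(payload["bias"]),
            feat_mean=np.asarray(payload["feat_mean"]),
            feat_scale=np.asarray(payload["feat_scale"]),
        )


def train_reference_classifier(
    images,
    labels,
    preprocess: PreprocessMethod = PreprocessMethod.NONE,
    augment: AugmentParams | None = None,
    seed: int = 0,
    *,
    n_aug: int = 4,
    feature_grid: int = 32,
    balance: bool = True,
    C: float = 1.0,
) -> ReferenceClassifier:
    """Fit the reference classifier on (optionally augmented) images.

    Each training image contributes its clean preprocessed features plus
    ``n_aug`` augmented copies drawn per ``augment``; augmentation operates
    on the preprocessed image.  Deterministic per seed.
    """
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels).astype(int)
    if len(images) < 20:
        raise ValueError("need at least 20 training images")
    if labels.min() == labels.max():
        raise DegenerateInputError("training labels must contain both classes")

    rng = np.random.default_rng(seed)
    if balance:
        keep = undersample_majority(labels, seed=int(rng.integers(2**31 - 1)))
        images = [images[i] for i in keep]
        labels = labels[keep]

    n_feat = 2 * feature_grid**2
    clf = ReferenceClassifier(
        preprocess=preprocess,
        feature_grid=feature_grid,
        weights=np.zeros(n_feat),
        bias=0.0,
        feat_mean=np.zeros(n_feat),
        feat_scale=np.ones(n_feat),
    )
    def extract(image: NormImage) -> np.ndarray:
        mask = segment_lungs(image)
        proc = preprocess_dispatch(image, mask, preprocess, out_size=4 * feature_grid)
        return _pixel_features(proc, feature_grid)

    # augmentation corrupts the raw image *before* the model's preprocessing,
    # mirroring how hardware variation (and the sweeps) reach the model
    feats, ys = [], []
    for img, lab in zip(images, labels):
        feats.append(extract(img))
        ys.append(lab)
        n_copies = n_aug if augment is not None and augment.enabled else 0
        for _ in range(n_copies):
            aug_seed = int(rng.integers(2**31 - 1))
            spec, degrees, flip = sample_augmentation(augment, aug_seed)
            aug = rotate_flip(img, degrees, flip)
            aug = apply_perturbation(aug, spec, seed=aug_seed + 1)
            feats.append(extract(aug))
            ys.append(lab)

    X = np.asarray(feats)
    y = np.asarray(ys)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-9] = 1.0
    Xz = (X - mean) / scale
    model = LogisticRegression(C=C, max_iter=2000, solver="lbfgs", random_state=0)
    model.fit(Xz, y)
    clf.weights = model.coef_.ravel().copy()
    clf.bias = float(model.intercept_[0])
    clf.feat_mean = mean
    clf.feat_scale = scale
    return clf


def perturbation_sweep(
    model,
    images,
    labels,
    axis: SweepAxis,
    grid,
    n_repeats: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Evaluate a scoring model along one perturbation axis.

    For each grid value, every image is perturbed on that single axis
    (others held at identity), scored, and the AUC computed; the noise axis
    is repeated ``n_repeats`` times with fresh seeds.  The CI is a normal
    approximation across repeats (zero-width for deterministic axes).
    """
    if not isinstance(axis, SweepAxis):
        axis = SweepAxis(str(axis).lower())
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValueError("grid must be a nonempty 1-D vector")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if not np.any(np.isclose(grid, axis.identity_value)):
        raise ValueError(f"grid must contain the identity value {axis.identity_value}")
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise DegenerateInputError("labels must contain both classes")

    score_fn = model.score if hasattr(model, "score") else model
    rng = np.random.default_rng(seed)
    deterministic = axis is not SweepAxis.NOISE
    reps = 1 if deterministic else n_repeats
    aucs = np.empty((reps, len(grid)))
    for r in range(reps):
        for j, g in enumerate(grid):
            if axis is SweepAxis.GAMMA:
                spec = PerturbSpec(gamma=float(g))
            elif axis is SweepAxis.SHARP:
                spec = PerturbSpec(sharp=float(g))
            else:
                spec = PerturbSpec(noise_sigma=float(g))
            base_seed = int(rng.integers(2**31 - 1))
            scores = np.array(
                [
                    score_fn(apply_perturbation(img, spec, seed=base_seed + i))
                    for i, img in enumerate(images)
                ]
            )
            aucs[r, j] = roc_auc(LabeledScores(labels, scores))
    mean = aucs.mean(axis=0)
    if reps > 1:
        se = aucs.std(axis=0, ddof=1) / np.sqrt(reps)
    else:
        se = np.zeros(len(grid))
    half = 1.959963984540054 * se
    ci = np.stack([np.clip(mean - half, 0, 1), np.clip(mean + half, 0, 1)], axis=1)
    return SweepResult(axis=axis, grid=grid, auc_mean=mean, auc_ci=ci, n_repeats=reps)
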
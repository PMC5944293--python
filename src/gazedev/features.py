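"""Feature extraction from GaDe images and leave-one-out evaluation.

Extractors implement a single contract — GaDe image in, fixed-length
feature vector out — so the classification stage is agnostic to where the
features come from:

* :func:`extract_builtin` is a deterministic, dependency-free summary of
  each channel's deviation geometry (intensity histogram, occupancy, and
  distance of lit pixels to the nine target locations), 108 dimensions.
* :func:`extract_cnn` taps the three fully-connected layers of an
  ImageNet-pretrained CNN (pre- and post-activation, giving the six
  standard vectors l1..l6 of 4096/4096/4096/4096/1000/1000 dimensions).
  It is an optional plugin: it requires torch/torchvision and downloaded
  weights, and raises a clear error rather than silently falling back.

Classification is a linear-kernel SVM with the regularization constant
chosen by stratified two-fold cross-validation on the training set, and
cohorts are evaluated leave-one-out: one fold per subject, the classifier
(including its hyperparameter search and feature scaling) refit from
scratch on the remaining subjects each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import NINE_TARGETS
from .gade import GaDeImage

__all__ = [
    "FeatureVector",
    "EvaluationReport",
    "ExtractorUnavailableError",
    "extract_builtin",
    "extract_cnn",
    "train_linear_classifier",
    "evaluate_loo",
]

_HIST_BINS = 32
_C_GRID = tuple(10.0**k for k in range(-3, 4))

CNN_MODELS = ("AlexNet", "VGG-F", "VGG-M", "VGG-S", "VGG-16", "VGG-19")
LAYER_TAGS = ("l1", "l2", "l3", "l4", "l5", "l6", "all")


class ExtractorUnavailableError(RuntimeError):
    """Raised when a requested feature extractor cannot run in this install."""


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str
    layer_tag: str = "builtin"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def _target_pixels(size: int) -> np.ndarray:
    """(9, 2) array of (row, col) pixel centers of the nine targets."""
    pts = np.array([t.position for t in NINE_TARGETS])
    cols = np.floor(pts[:, 0] * size)
    rows = np.floor(pts[:, 1] * size)
    return np.stack([rows, cols], axis=1)


def extract_builtin(img: GaDeImage) -> FeatureVector:
    """Deterministic per-channel summary features, 3 x 36 = 108 dimensions.

    Per channel: a 32-bin histogram of nonzero pixel intensities normalized
    by the nonzero count, the nonzero-pixel count, the mean and maximum
    nonzero intensity, and the mean distance (normalized by image size) of
    nonzero pixels to the nearest of the nine target locations.  An all-zero
    channel contributes all zeros.
    """
    targets = _target_pixels(img.size)
    feats: list[np.ndarray] = []
    for chan in img.channels:
        rows, cols = np.nonzero(chan)
        vals = chan[rows, cols].astype(float)
        if len(vals):
            hist, _ = np.histogram(vals, bins=_HIST_BINS, range=(0.5, 255.5))
            hist = hist / len(vals)
            pix = np.stack([rows, cols], axis=1).astype(float)
            dists = np.sqrt(
                ((pix[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            extra = np.array(
                [len(vals), vals.mean(), vals.max(), dists.mean() / img.size]
            )
        else:
            hist = np.zeros(_HIST_BINS)
            extra = np.zeros(4)
        feats.append(np.concatenate([hist, extra]))
    return FeatureVector(values=np.concatenate(feats), extractor_id="builtin")


# --------------------------------------------------------------------------
# Optional CNN tap.

_TORCHVISION_IDS = {"AlexNet": "alexnet", "VGG-16": "vgg16", "VGG-19": "vgg19"}


def extract_cnn(img: GaDeImage, model_id: str, layer_tag: str = "all") -> FeatureVector:
    """Tap the fully-connected layers of an ImageNet-pretrained CNN.

    l1/l3/l5 are the input (pre-activation) vectors and l2/l4/l6 the output
    (post-activation) vectors of the three FC layers; ``all`` concatenates
    the six.  The image is resized to the model's native input (227 for
    AlexNet, 224 otherwise) before the forward pass.

    Requires the optional ``torch``/``torchvision`` install and locally
    cached pretrained weights; raises :class:`ExtractorUnavailableError`
    otherwise — the builtin extractor is never substituted silently.
    """
    if model_id not in CNN_MODELS:
        raise ValueError(f"model_id must be one of {CNN_MODELS}, got {model_id!r}")
    if layer_tag not in LAYER_TAGS:
        raise ValueError(f"layer_tag must be one of {LAYER_TAGS}, got {layer_tag!r}")
    try:
        import torch
        from torchvision import models as tv_models
        from torchvision.transforms.functional import resize, to_tensor
    except ImportError as exc:
        raise ExtractorUnavailableError(
            f"the CNN extractor needs the optional torch/torchvision install "
            f"(pip install 'gazedev[cnn]'); use extractor 'builtin' otherwise"
        ) from exc
    if model_id not in _TORCHVISION_IDS:
        raise ExtractorUnavailableError(
            f"{model_id} (MatConvNet-era architecture) has no torchvision "
            f"weights; available CNN extractors: {sorted(_TORCHVISION_IDS)}"
        )
    input_size = 227 if model_id == "AlexNet" else 224
    net = getattr(tv_models, _TORCHVISION_IDS[model_id])(weights="IMAGENET1K_V1")
    net.eval()
    fc_layers = [m for m in net.classifier if isinstance(m, torch.nn.Linear)]
    # Pre-activation taps l1/l3/l5 are the Linear outputs (inputs of the
    # ReLU/softmax transfer functions); l2/l4/l6 are the activation outputs.
    pre: list[np.ndarray] = []
    handles = [
        layer.register_forward_hook(
            lambda _mod, _inp, out: pre.append(out.detach().numpy().ravel())
        )
        for layer in fc_layers
    ]
    try:
        x = to_tensor(img.to_pil())
        x = resize(x, [input_size, input_size]).unsqueeze(0)
        with torch.no_grad():
            logits = net(x)
    finally:
        for h in handles:
            h.remove()
    taps = {
        "l1": pre[0],
        "l2": np.maximum(pre[0], 0.0),
        "l3": pre[1],
        "l4": np.maximum(pre[1], 0.0),
        "l5": pre[2],
        "l6": torch.softmax(logits, dim=1).numpy().ravel(),
    }
    values = (
        np.concatenate([taps[t] for t in LAYER_TAGS[:6]])
        if layer_tag == "all"
        else taps[layer_tag]
    )
    return FeatureVector(values=values, extractor_id=f"cnn:{model_id}", layer_tag=layer_tag)


# --------------------------------------------------------------------------
# Linear classification and leave-one-out evaluation.


def _as_matrix(features) -> np.ndarray:
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f, float) for f in features]
    return np.vstack(rows)


def train_linear_classifier(features, labels, seed: int = 0):
    """Linear-kernel SVM with C selected by stratified two-fold CV.

    Features are z-scored per dimension inside the pipeline, so scaling is
    always fit on training data only.  Returns the fitted
    :class:`~sklearn.model_selection.GridSearchCV` object; the selected C is
    ``clf.best_params_["svm__C"]``.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear"))]
    )
    cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    clf = GridSearchCV(
        pipe, {"svm__C": list(_C_GRID)}, cv=cv, scoring="accuracy", n_jobs=None
    )
    clf.fit(X, y)
    return clf


@dataclass
class EvaluationReport:
    """Aggregated held-out predictions of a leave-one-out evaluation.

    Metrics are percentages; ``strabismic`` is the positive class, so
    sensitivity is the detection rate among strabismic subjects and
    specificity the correct-rejection rate among normal subjects.
    """

    y_true: list[str]
    y_pred: list[str]
    fold_params: list[dict] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        t = np.asarray(self.y_true)
        p = np.asarray(self.y_pred)
        return {
            "TP": int(np.sum((t == "strabismic") & (p == "strabismic"))),
            "FN": int(np.sum((t == "strabismic") & (p == "normal"))),
            "TN": int(np.sum((t == "normal") & (p == "normal"))),
            "FP": int(np.sum((t == "normal") & (p == "strabismic"))),
        }

    @property
    def accuracy(self) -> float:
        c = self.counts
        return 100.0 * (c["TP"] + c["TN"]) / len(self.y_true)

    @property
    def specificity(self) -> float:
        c = self.counts
        n = c["TN"] + c["FP"]
        return 100.0 * c["TN"] / n if n else float("nan")

    @property
    def sensitivity(self) -> float:
        c = self.counts
        n = c["TP"] + c["FN"]
        return 100.0 * c["TP"] / n if n else float("nan")

    def summary(self) -> dict:
        return {
            "n": len(self.y_true),
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "counts": self.counts,
        }


def evaluate_loo(features, labels, seed: int = 0) -> EvaluationReport:
    """Leave-one-out evaluation of the linear classifier.

    Exactly one fold per subject; each fold reruns the full training recipe
    (scaling + two-fold hyperparameter search) on the other N-1 subjects and
    predicts the held-out one.  Requires N >= 3 and both classes present.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if len(y) < 3:
        raise ValueError("need at least 3 subjects for leave-one-out")
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")
    y_pred: list[str] = []
    fold_params: list[dict] = []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = train_linear_classifier(X[mask], y[mask], seed=seed)
        y_pred.append(str(clf.predict(X[i : i + 1])[0]))
        fold_params.append({"held_out": i, "C": clf.best_params_["svm__C"]})
    return EvaluationReport(y_true=[str(v) for v in y], y_pred=y_pred, fold_params=fold_params)
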
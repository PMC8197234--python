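"""Class-weighted CNN training and inference.

The training loss is weighted categorical cross-entropy

    L = (1/n) * sum_i sum_j  -y_ij * log(yhat_ij) * w_j,
    w_j = max_k n_k / n_j,

so every class contributes equally to the loss regardless of its count
(n_j * w_j = max_k n_k for all j), which matters here because blasts and
promonocytes are minorities relative to monocytes.

The reference backbone (``reference_small_cnn``) is a from-scratch numpy
CNN: a downsampling stem to 32x32, three 3x3 conv + ReLU + 2x2 max-pool
blocks (8/16/32 channels), global average pooling and a softmax head,
optimised with Adam.  It is small enough to train on one CPU in seconds
while exposing the full training contract (weighted loss, seeded
determinism, penultimate-layer features).  Published ImageNet backbones
(InceptionV3, ResNet50, Inception-ResNet, VGG16, DenseNet121) are named in
the registry but require a deep-learning framework; selecting one raises
:class:`BackboneUnavailableError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from monoclass.synthetic_cells import CLASSES
from monoclass.preprocess import PreparedPatch

MERGED_CLASSES: tuple[str, str] = ("monocyte", "precursor")
_EPS = 1e-7  # probability clip before log

KNOWN_BACKBONES = (
    "reference_small_cnn",
    "inceptionv3",
    "resnet50",
    "inception_resnet",
    "vgg16",
    "densenet121",
)


class BackboneUnavailableError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# class weights and loss

@dataclass(frozen=True)
class ClassWeights:
    """Per-class counts n_j and balancing weights w_j = max_k n_k / n_j."""

    classes: tuple[str, ...]
    counts: np.ndarray
    weights: np.ndarray


def compute_class_weights(labels, classes: tuple[str, ...] | None = None) -> ClassWeights:
    """Counts and inverse-frequency weights for a label list.

    Every class must appear at least once (a zero count would make its
    weight undefined and its gradient silent).
    """
    labels = list(labels)
    if classes is None:
        present = set(labels)
        canonical = [c for c in CLASSES + ("precursor",) if c in present]
        extra = [c for c in dict.fromkeys(labels) if c not in canonical]
        classes = tuple(canonical + extra)
    counts = np.array([labels.count(c) for c in classes], dtype=int)
    if np.any(counts == 0):
        missing = [c for c, n in zip(classes, counts) if n == 0]
        raise ValueError(f"class(es) absent from labels: {missing}")
    weights = counts.max() / counts.astype(float)
    return ClassWeights(classes=tuple(classes), counts=counts, weights=weights)


def onehot_encode(labels, classes: tuple[str, ...]) -> np.ndarray:
    """n x m one-hot matrix; raises on labels outside the class set."""
    index = {c: j for j, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in classes {classes}")
        out[i, index[lab]] = 1.0
    return out


def weighted_cce(y: np.ndarray, yhat: np.ndarray, w: ClassWeights | np.ndarray) -> float:
    """Weighted categorical cross-entropy, mean over samples.

    Reduces to the standard categorical cross-entropy when all weights are
    1.  Probabilities are clipped to [eps, 1] before the log.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    weights = w.weights if isinstance(w, ClassWeights) else np.asarray(w, dtype=float)
    if y.shape != yhat.shape or y.shape[1] != weights.shape[0]:
        raise ValueError(f"shape mismatch: y {y.shape}, yhat {yhat.shape}, w {weights.shape}")
    logp = np.log(np.clip(yhat, _EPS, 1.0))
    return float(-(y * logp * weights[None, :]).sum() / y.shape[0])


# ---------------------------------------------------------------------------
# reference backbone

@dataclass(frozen=True)
class TrainingSpec:
    backbone: str = "reference_small_cnn"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    rng_seed: int = 0
    init: str = "random"
    input_size: int = 32  # side length of the downsampling stem's output

    def __post_init__(self) -> None:
        if self.backbone not in KNOWN_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; known: {KNOWN_BACKBONES}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.backbone != "reference_small_cnn":
            raise BackboneUnavailableError(
                f"backbone {self.backbone!r} needs a deep-learning framework; "
                "only 'reference_small_cnn' ships with this package"
            )


@dataclass
class ModelHandle:
    """Opaque trained-model handle: parameters, class list, training history."""

    params: dict
    classes: tuple[str, ...]
    spec: TrainingSpec
    history: list = field(default_factory=list)  # per-epoch mean training loss
    trained: bool = False

    @property
    def feature_dim(self) -> int:
        return self.params["W3"].shape[0]


_CHANNELS = (8, 16, 32)


def _init_params(n_classes: int, rng: np.random.Generator) -> dict:
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    c1, c2, c3 = _CHANNELS
    return {
        "W1": he((c1, 3, 3, 3), 3 * 9), "b1": np.zeros(c1),
        "W2": he((c2, c1, 3, 3), c1 * 9), "b2": np.zeros(c2),
        "W3": he((c3, c2, 3, 3), c2 * 9), "b3": np.zeros(c3),
        # small-scale head: untrained predictions start near-uniform
        "Wf": rng.normal(0.0, 0.01, size=(c3, n_classes)), "bf": np.zeros(n_classes),
    }


def _conv_forward(x: np.ndarray, K: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution via 9 shifted einsums."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, K.shape[0], h, w))
    for i in range(3):
        for j in range(3):
            out += np.einsum("nchw,oc->nohw", xp[:, :, i:i + h, j:j + w], K[:, :, i, j])
    return out + b[None, :, None, None], xp


def _conv_backward(dout: np.ndarray, xp: np.ndarray, K: np.ndarray):
    n, o, h, w = dout.shape
    dK = np.zeros_like(K)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            dK[:, :, i, j] = np.einsum("nchw,nohw->oc", xp[:, :, i:i + h, j:j + w], dout)
            dxp[:, :, i:i + h, j:j + w] += np.einsum("nohw,oc->nchw", dout, K[:, :, i, j])
    return dxp[:, :, 1:-1, 1:-1], dK, db


def _pool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    x6 = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = x6.max(axis=(3, 5))
    mask = x6 == out[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)  # split gradient on ties
    return out, mask


def _pool_backward(dout: np.ndarray, mask: np.ndarray):
    n, c, h2, _, w2, _ = mask.shape
    d = mask * dout[:, :, :, None, :, None]
    return d.reshape(n, c, h2 * 2, w2 * 2)


def _forward(params: dict, x: np.ndarray, need_cache: bool = False):
    cache = {}
    a = x
    for layer in (1, 2, 3):
        z, xp = _conv_forward(a, params[f"W{layer}"], params[f"b{layer}"])
        r = np.maximum(z, 0.0)
        p, mask = _pool_forward(r)
        if need_cache:
            cache[layer] = (xp, z, mask)
        a = p
    feats = a.mean(axis=(2, 3))  # global average pool -> n x c3
    logits = feats @ params["Wf"] + params["bf"]
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    if need_cache:
        cache["pooled_shape"] = a.shape
        cache["feats"] = feats
    return probs, feats, cache


def _backward(params: dict, cache: dict, probs, y, sample_w):
    n = y.shape[0]
    grads = {}
    dlogits = (probs - y) * sample_w[:, None] / n
    grads["Wf"] = cache["feats"].T @ dlogits
    grads["bf"] = dlogits.sum(axis=0)
    dfeats = dlogits @ params["Wf"].T
    _, c, h, w = cache["pooled_shape"]
    da = np.broadcast_to(dfeats[:, :, None, None] / (h * w), cache["pooled_shape"]).copy()
    for layer in (3, 2, 1):
        xp, z, mask = cache[layer]
        dr = _pool_backward(da, mask)
        dz = dr * (z > 0)
        da, dK, db = _conv_backward(dz, xp, params[f"W{layer}"])
        grads[f"W{layer}"] = dK
        grads[f"b{layer}"] = db
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack_inputs(patches, input_size: int) -> np.ndarray:
    """Stack patches into an n x 3 x s x s tensor, downsampling via the stem."""
    arrs = []
    for p in patches:
        px = p.pixels if isinstance(p, PreparedPatch) else np.asarray(p, dtype=float)
        if px.shape[0] != input_size:
            px = resize(px, (input_size, input_size), order=1, mode="constant",
                        cval=0.0, anti_aliasing=px.shape[0] > input_size,
                        preserve_range=True)
        arrs.append(np.moveaxis(px, -1, 0))
    return np.stack(arrs)


def train(patches, labels, spec: TrainingSpec | None = None,
          classes: tuple[str, ...] | None = None) -> ModelHandle:
    """Train the reference CNN with the class-weighted loss and Adam.

    ``labels`` are class-name strings aligned to ``patches``.  At least two
    classes must be present and every class in ``classes`` must occur.
    Deterministic given ``spec.rng_seed``.  ``epochs=0`` returns an
    initialised but untrained handle.
    """
    spec = spec or TrainingSpec()
    cw = compute_class_weights(labels, classes)
    if len(cw.classes) < 2:
        raise ValueError("training needs at least 2 classes")
    y = onehot_encode(labels, cw.classes)
    x = _stack_inputs(patches, spec.input_size)

    rng = np.random.default_rng(spec.rng_seed)
    params = _init_params(len(cw.classes), rng)
    handle = ModelHandle(params=params, classes=cw.classes, spec=spec)
    if spec.epochs == 0:
        return handle

    sample_w = cw.weights[y.argmax(axis=1)]
    opt = _Adam(params, spec.learning_rate)
    n = x.shape[0]
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            probs, _, cache = _forward(params, x[idx], need_cache=True)
            losses.append(weighted_cce(y[idx], probs, cw))
            grads = _backward(params, cache, probs, y[idx], sample_w[idx])
            opt.step(params, grads)
        handle.history.append(float(np.mean(losses)))
    handle.trained = True
    return handle


def predict(model: ModelHandle, patches, batch_size: int = 64) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) in ``model.classes`` order."""
    x = _stack_inputs(patches, model.spec.input_size)
    out = []
    for start in range(0, x.shape[0], batch_size):
        probs, _, _ = _forward(model.params, x[start:start + batch_size])
        out.append(probs)
    return np.vstack(out)


def extract_features(model: ModelHandle, patches, batch_size: int = 64) -> np.ndarray:
    """Globally pooled last-conv-layer activations (n x 32), for t-SNE etc."""
    if not model.trained:
        raise ValueError("extract_features requires a trained model")
    x = _stack_inputs(patches, model.spec.input_size)
    out = []
    for start in range(0, x.shape[0], batch_size):
        _, feats, _ = _forward(model.params, x[start:start + batch_size])
        out.append(feats)
    return np.vstack(out)


# ---------------------------------------------------------------------------
# label / prediction merging (monocyte vs. precursor = promonocyte + blast)

def merge_label(label: str) -> str:
    return "monocyte" if label == "monocyte" else "precursor"


def merge_labels(labels) -> list[str]:
    return [merge_label(lab) for lab in labels]


def merge_predictions(probs: np.ndarray, scheme: str = "2-class",
                      classes: tuple[str, ...] = CLASSES):
    """Collapse promonocyte + blast probabilities into one precursor class.

    Returns (merged probs, merged class tuple).  ``scheme='identity'``
    returns the input unchanged.  Merged rows still sum to 1 because the
    merge only adds disjoint probabilities.
    """
    probs = np.asarray(probs, dtype=float)
    if scheme in ("identity", "3-class"):
        return probs, tuple(classes)
    if scheme != "2-class":
        raise ValueError(f"unknown merge scheme {scheme!r}")
    if probs.shape[1] != len(classes):
        raise ValueError("probability columns do not match class list")
    mono = [j for j, c in enumerate(classes) if c == "monocyte"]
    prec = [j for j, c in enumerate(classes) if c != "monocyte"]
    merged = np.column_stack([probs[:, mono].sum(axis=1), probs[:, prec].sum(axis=1)])
    return merged, MERGED_CLASSES
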
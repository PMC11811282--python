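"""Condition/individual discriminator over multitaper spectrograms.

Signals are segmented, converted to per-channel multitaper time-frequency
power (Slepian tapers, 0-200 Hz band, 100 ms window, 10 ms step by
default), compiled into a ``channels x frequency x time`` volume per
segment, and classified by a small configurable 3-D convolutional network
(conv blocks with average pooling, global average pooling, linear head)
trained with cross-entropy and Adam.  The network is self-contained:
forward and backward passes are written out explicitly and verified by
finite differences in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss
from sklearn.model_selection import train_test_split

from .signals import SignalSequence


# --------------------------------------------------------------------------
# multitaper spectrograms
# --------------------------------------------------------------------------
@dataclass
class SpectrogramParams:
    window_ms: float = 100.0
    step_ms: float = 10.0
    fmax: float = 200.0
    time_bandwidth: float = 4.0
    n_tapers: int = 7


@dataclass
class SpectrogramStack:
    """Per-channel multitaper power: ``(channels, freq_bins, time_frames)``."""

    power: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray
    params: SpectrogramParams

    @property
    def shape(self):
        return self.power.shape


def multitaper_spectrogram(segment, rate: float | None = None,
                           params: SpectrogramParams | None = None
                           ) -> SpectrogramStack:
    """Multitaper PSD per sliding frame, restricted to the 0-``fmax`` band.

    ``segment`` is a :class:`SignalSequence` or a ``(channels, T)`` array
    (then ``rate`` is required).  The frame count is
    ``(T - window) // step + 1``; a 2000 ms segment at 1000 Hz with the
    default 100 ms window and 10 ms step yields 191 frames.
    """
    params = params or SpectrogramParams()
    if isinstance(segment, SignalSequence):
        values, rate = segment.values, segment.sampling_rate
    else:
        values = np.atleast_2d(np.asarray(segment, dtype=float))
        if rate is None:
            raise ValueError("rate is required for bare arrays")
    win = int(round(params.window_ms * rate / 1000.0))
    step = int(round(params.step_ms * rate / 1000.0))
    T = values.shape[1]
    if T < win:
        raise ValueError(f"segment of {T} samples shorter than the "
                         f"{win}-sample window")
    tapers = dpss(win, params.time_bandwidth, Kmax=params.n_tapers)
    frames = sliding_window_view(values, win, axis=1)[:, ::step]  # (C,N,win)
    spec = rfft(frames[:, :, None, :] * tapers[None, None], axis=-1)
    power = (spec.real ** 2 + spec.imag ** 2).mean(axis=2)        # (C,N,F)
    freqs = rfftfreq(win, d=1.0 / rate)
    keep = freqs <= params.fmax
    power = np.ascontiguousarray(power[:, :, keep].transpose(0, 2, 1))
    n_frames = frames.shape[1]
    frame_times = (np.arange(n_frames) * step + win / 2.0) / rate
    return SpectrogramStack(power=power, freqs=freqs[keep],
                            frame_times=frame_times, params=params)


def segment_sequence(seq: SignalSequence, segment_ms: float = 2000.0
                     ) -> list[SignalSequence]:
    """Split a sequence into non-overlapping fixed-length segments."""
    n = int(round(segment_ms * seq.sampling_rate / 1000.0))
    return [seq.segment(i, i + n) for i in range(0, seq.n_steps - n + 1, n)]


def stacks_from_sequences(seqs, params: SpectrogramParams | None = None,
                          segment_ms: float | None = None):
    """Spectrogram stacks (and labels) for a list of sequences.

    With ``segment_ms`` each sequence contributes one stack per segment;
    otherwise one stack spans the full sequence.  Returns
    ``(stacks, conditions, individuals)``.
    """
    stacks, conds, inds = [], [], []
    for seq in seqs:
        pieces = ([seq] if segment_ms is None
                  else segment_sequence(seq, segment_ms))
        for piece in pieces:
            stacks.append(multitaper_spectrogram(piece, params=params))
            conds.append(seq.condition)
            inds.append(seq.individual)
    return stacks, np.array(conds), np.array(inds)


# --------------------------------------------------------------------------
# 3-D convolutional classifier
# --------------------------------------------------------------------------
@dataclass
class DiscriminatorConfig:
    """Architecture and training recipe.

    ``blocks`` lists ``(out_channels, kernel, pool)`` with 3-D kernel and
    pooling factors over the (channel, frequency, time) volume.  Training
    follows the reference recipe: cross-entropy, Adam at 5e-4, 100
    full-batch updates.
    """

    blocks: list = field(default_factory=lambda: [
        (8, (2, 3, 3), (1, 2, 2)),
        (8, (2, 3, 3), (1, 2, 2)),
    ])
    learning_rate: float = 5e-4
    n_updates: int = 100
    test_fraction: float = 0.2
    log_power: bool = True
    seed: int = 0


def _im2col(x, kshape):
    """Materialised valid-conv windows: (N, D', H', W', I*kd*kh*kw)."""
    win = sliding_window_view(x, kshape, axis=(2, 3, 4))
    n, i, d, h, w = win.shape[:5]
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    return np.ascontiguousarray(win).reshape(n, d, h, w, -1)


def _conv3d(x, K, col=None):
    """Valid, stride-1 3-D convolution. x: (N,I,D,H,W), K: (O,I,kd,kh,kw).

    Returns ``(out, col)`` where ``col`` is the materialised window matrix
    (reusable for the backward pass and across updates on fixed inputs).
    """
    if col is None:
        col = _im2col(x, K.shape[2:])
    out = col @ K.reshape(K.shape[0], -1).T      # (N,D',H',W',O)
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3)), col


def _conv3d_grads(col, K, gout, need_gx=True):
    """Gradients of a valid conv given the forward window matrix ``col``."""
    go = gout.transpose(0, 2, 3, 4, 1)           # (N,D',H',W',O)
    gK = np.tensordot(go, col, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
    gK = gK.reshape(K.shape)
    if not need_gx:
        return gK, None
    kd, kh, kw = K.shape[2:]
    gpad = np.pad(gout, ((0, 0), (0, 0), (kd - 1, kd - 1),
                         (kh - 1, kh - 1), (kw - 1, kw - 1)))
    Kf = np.ascontiguousarray(K[:, :, ::-1, ::-1, ::-1]
                              .transpose(1, 0, 2, 3, 4))  # (I,O,kd,kh,kw)
    gcol = _im2col(gpad, K.shape[2:])            # windows over O channels
    gx = gcol @ Kf.reshape(Kf.shape[0], -1).T    # (N,D,H,W,I)
    return gK, np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3))


def _avgpool(x, f):
    n, c, d, h, w = x.shape
    fd, fh, fw = f
    d2, h2, w2 = d // fd, h // fh, w // fw
    xt = x[:, :, :d2 * fd, :h2 * fh, :w2 * fw]
    return xt.reshape(n, c, d2, fd, h2, fh, w2, fw).mean(axis=(3, 5, 7))


def _avgpool_grad(xshape, f, gout):
    n, c, d, h, w = xshape
    fd, fh, fw = f
    d2, h2, w2 = gout.shape[2:]
    g = np.zeros(xshape)
    expanded = np.repeat(np.repeat(np.repeat(
        gout, fd, axis=2), fh, axis=3), fw, axis=4) / (fd * fh * fw)
    g[:, :, :d2 * fd, :h2 * fh, :w2 * fw] = expanded
    return g


class Conv3DClassifier:
    """Small 3-D CNN: conv+ReLU+avg-pool blocks, global pooling, linear head."""

    def __init__(self, input_shape, n_classes: int,
                 cfg: DiscriminatorConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg or DiscriminatorConfig()
        self.input_shape = tuple(input_shape)      # (C, F, Tf)
        self.n_classes = n_classes
        if rng is None:
            rng = np.random.default_rng(self.cfg.seed)
        self.kernels, self.biases, self.pools = [], [], []
        in_c = 1
        shape = list(self.input_shape)
        for out_c, kernel, pool in self.cfg.blocks:
            kernel = tuple(min(k, s) for k, s in zip(kernel, shape))
            fan_in = in_c * int(np.prod(kernel))
            K = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_c, in_c) + kernel)
            self.kernels.append(K)
            self.biases.append(np.zeros(out_c))
            shape = [s - k + 1 for s, k in zip(shape, kernel)]
            pool = tuple(min(p, max(1, s)) for p, s in zip(pool, shape))
            self.pools.append(pool)
            shape = [max(1, s // p) for s, p in zip(shape, pool)]
            in_c = out_c
        self.W = np.zeros((n_classes, in_c))
        self.b = np.zeros(n_classes)

    def params(self):
        return self.kernels + self.biases + [self.W, self.b]

    def forward(self, x, want_cache: bool = False, col0=None):
        """Logits for input volumes ``x`` of shape ``(N, C, F, Tf)``.

        ``col0`` optionally supplies the precomputed first-layer window
        matrix (the input is fixed across full-batch updates).
        """
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input geometry {x.shape[1:]} does not match the "
                f"classifier's {self.input_shape}")
        a = x[:, None]                             # (N, 1, C, F, Tf)
        cache = []
        for li, (K, bias, pool) in enumerate(zip(self.kernels, self.biases,
                                                 self.pools)):
            pre, col = _conv3d(a, K, col=col0 if li == 0 else None)
            pre = pre + bias[None, :, None, None, None]
            relu = np.maximum(pre, 0.0)
            pooled = _avgpool(relu, pool)
            cache.append((col, pre, relu.shape, pool))
            a = pooled
        feats = a.mean(axis=(2, 3, 4))             # (N, out_c)
        logits = feats @ self.W.T + self.b
        if want_cache:
            return logits, (cache, a.shape, feats)
        return logits

    def first_col(self, x) -> np.ndarray:
        """Precompute the first layer's window matrix for repeated updates."""
        return _im2col(x[:, None], self.kernels[0].shape[2:])

    def loss_and_grads(self, x, y_onehot, col0=None):
        """Mean cross-entropy and gradients for all parameters."""
        logits, (cache, a_shape, feats) = self.forward(x, want_cache=True,
                                                       col0=col0)
        n = x.shape[0]
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        gl = (probs - y_onehot) / n                # (N, classes)
        gW = gl.T @ feats
        gb = gl.sum(axis=0)
        gfeats = gl @ self.W                       # (N, out_c)
        spatial = int(np.prod(a_shape[2:]))
        ga = np.broadcast_to(
            gfeats[:, :, None, None, None] / spatial, a_shape).copy()
        gKs, gbs = [], []
        n_layers = len(self.kernels)
        for li, ((col, pre, relu_shape, pool), K) in enumerate(
                zip(reversed(cache), reversed(self.kernels))):
            grelu = _avgpool_grad(relu_shape, pool, ga)
            gpre = grelu * (pre > 0)
            gK, ga = _conv3d_grads(col, K, gpre,
                                   need_gx=li < n_layers - 1)
            gKs.append(gK)
            gbs.append(gpre.sum(axis=(0, 2, 3, 4)))
        gKs.reverse()
        gbs.reverse()
        return loss, gKs + gbs + [gW, gb], probs


class Adam:
    def __init__(self, params, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g ** 2
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# --------------------------------------------------------------------------
# training and application
# --------------------------------------------------------------------------
@dataclass
class TrainedDiscriminator:
    classifier: Conv3DClassifier
    classes: np.ndarray
    holdout_accuracy: float
    norm_mean: float
    norm_sd: float
    log_power: bool
    loss_trace: np.ndarray

    def preprocess(self, stacks) -> np.ndarray:
        X = np.stack([s.power if isinstance(s, SpectrogramStack) else s
                      for s in stacks])
        if self.log_power:
            X = np.log10(X + 1e-12)
        return (X - self.norm_mean) / self.norm_sd


def _as_volumes(stacks, log_power):
    X = np.stack([s.power if isinstance(s, SpectrogramStack) else np.asarray(s)
                  for s in stacks])
    if log_power:
        X = np.log10(X + 1e-12)
    return X


def train_discriminator(stacks, labels, *,
                        cfg: DiscriminatorConfig | None = None,
                        rng: np.random.Generator | None = None
                        ) -> TrainedDiscriminator:
    """Train the spectrogram classifier; returns it with held-out accuracy.

    The stacks are log-power-transformed, globally standardised (statistics
    from the training split), split 80/20 stratified by label, and the
    network is updated ``n_updates`` times full-batch with Adam.
    Reproducible given the config seed.
    """
    cfg = cfg or DiscriminatorConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    X = _as_volumes(stacks, cfg.log_power)
    idx = np.arange(len(labels))
    tr_idx, te_idx = train_test_split(
        idx, test_size=cfg.test_fraction, stratify=labels,
        random_state=cfg.seed)
    mean = float(X[tr_idx].mean())
    sd = float(X[tr_idx].std()) or 1.0
    Xn = (X - mean) / sd
    y = np.searchsorted(classes, labels)
    onehot = np.eye(len(classes))[y]

    clf = Conv3DClassifier(Xn.shape[1:], len(classes), cfg, rng)
    opt = Adam(clf.params(), lr=cfg.learning_rate)
    losses = np.empty(cfg.n_updates)
    X_tr = np.ascontiguousarray(Xn[tr_idx])
    y_tr = onehot[tr_idx]
    col0 = clf.first_col(X_tr)   # input fixed across full-batch updates
    for n in range(cfg.n_updates):
        loss, grads, _ = clf.loss_and_grads(X_tr, y_tr, col0=col0)
        opt.step(clf.params(), grads)
        losses[n] = loss
    pred = classes[np.argmax(clf.forward(Xn[te_idx]), axis=1)]
    acc = float(np.mean(pred == labels[te_idx]))
    return TrainedDiscriminator(classifier=clf, classes=classes,
                                holdout_accuracy=acc, norm_mean=mean,
                                norm_sd=sd, log_power=cfg.log_power,
                                loss_trace=losses)


def save_discriminator(disc: TrainedDiscriminator, path) -> None:
    """Persist a trained discriminator (architecture + weights + norm)."""
    import json

    clf = disc.classifier
    arrays = {}
    for i, (K, b) in enumerate(zip(clf.kernels, clf.biases)):
        arrays[f"kernel_{i}"] = K
        arrays[f"bias_{i}"] = b
    meta = dict(
        input_shape=list(clf.input_shape), n_classes=clf.n_classes,
        pools=[list(p) for p in clf.pools],
        blocks=[[o, list(k), list(p)] for o, k, p in clf.cfg.blocks],
        learning_rate=clf.cfg.learning_rate, n_updates=clf.cfg.n_updates,
        test_fraction=clf.cfg.test_fraction, log_power=clf.cfg.log_power,
        seed=clf.cfg.seed, classes=[str(c) for c in disc.classes],
        holdout_accuracy=disc.holdout_accuracy, norm_mean=disc.norm_mean,
        norm_sd=disc.norm_sd,
    )
    np.savez(path, W=clf.W, b=clf.b, meta=np.array(json.dumps(meta)),
             loss_trace=disc.loss_trace, **arrays)


def load_discriminator(path) -> TrainedDiscriminator:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = DiscriminatorConfig(
            blocks=[(o, tuple(k), tuple(p)) for o, k, p in meta["blocks"]],
            learning_rate=meta["learning_rate"], n_updates=meta["n_updates"],
            test_fraction=meta["test_fraction"], log_power=meta["log_power"],
            seed=meta["seed"])
        clf = Conv3DClassifier(tuple(meta["input_shape"]),
                               meta["n_classes"], cfg)
        for i in range(len(clf.kernels)):
            clf.kernels[i] = data[f"kernel_{i}"]
            clf.biases[i] = data[f"bias_{i}"]
        clf.W = data["W"]
        clf.b = data["b"]
        return TrainedDiscriminator(
            classifier=clf, classes=np.array(meta["classes"]),
            holdout_accuracy=meta["holdout_accuracy"],
            norm_mean=meta["norm_mean"], norm_sd=meta["norm_sd"],
            log_power=meta["log_power"], loss_trace=data["loss_trace"])


@dataclass
class ClassificationResult:
    labels: np.ndarray
    proportions: dict
    probabilities: np.ndarray


def classify(disc: TrainedDiscriminator, stacks) -> ClassificationResult:
    """Argmax class per stack plus the per-class proportion table."""
    if len(stacks) == 0:
        return ClassificationResult(labels=np.array([]), proportions={},
                                    probabilities=np.empty((0, len(disc.classes))))
    Xn = disc.preprocess(stacks)
    logits = disc.classifier.forward(Xn)
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    labels = disc.classes[np.argmax(logits, axis=1)]
    uniq, counts = np.unique(labels, return_counts=True)
    props = {u: c / len(labels) for u, c in zip(uniq, counts)}
    return ClassificationResult(labels=labels, proportions=props,
                                probabilities=probs)
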
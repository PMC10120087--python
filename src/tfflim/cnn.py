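"""Physics-inspired dilated CNN mapping (CMOS, iCCD) pairs to lifetime maps.

The two input images are concatenated as channels and processed by three
dilated Conv2D stages whose kernels extend only along the shear axis:
with kernel extent 11 and dilation 10 every tap lands exactly on one of
the +/-5 replica displacements at y = 10, so each feature sees precisely
the pixels that are causally coupled to its target pixel by the forward
model (a sparse 101-pixel receptive field).  A dense 3x3 head then acts
as a learned sliding-window binning stage and emits the lifetime map.
Training minimizes the intensity-weighted mean squared error

    L = 1/(N*M) * sum_ij q_ij * (tau_hat_ij - tau_ij)^2,

mirroring the photon-statistics argument that bright pixels admit a
lower-variance unbiased estimate, with Adam updates under an
exponentially decaying learning rate.

The implementation is a compact, dependency-free numpy CNN (explicit
forward/backward passes built on per-tap GEMMs); it is CPU-oriented and
sized for desk-scale experiments rather than large production training
runs.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import CNNSpec, SystemConfig, TrainConfig
from .forward import _field

__all__ = ["DilatedCNN", "build_model", "weighted_mse", "train", "predict",
           "load_model"]


# ---------------------------------------------------------------------------
# convolution primitive (per-tap GEMM formulation)

class _Conv2D:
    """2-D convolution with per-axis dilation, 'valid' or 'same' padding."""

    def __init__(self, c_in, c_out, kernel, dilation, pad, rng, linear=False,
                 pad_mode="edge"):
        self.kh, self.kw = kernel
        self.dh, self.dw = dilation
        self.pad = pad
        self.pad_mode = pad_mode
        self.linear = linear      # no ReLU after this layer
        fan_in = c_in * self.kh * self.kw
        self.w = (rng.standard_normal((c_out, c_in, self.kh, self.kw))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    @property
    def extent(self):
        return (self.dh * (self.kh - 1) + 1, self.dw * (self.kw - 1) + 1)

    def _padded(self, x):
        eh, ew = self.extent
        if self.pad == "same":
            ph, pw = (eh - 1) // 2, (ew - 1) // 2
            mode = "edge" if self.pad_mode == "edge" else "constant"
            return np.pad(x, ((0, 0), (0, 0), (ph, eh - 1 - ph),
                              (pw, ew - 1 - pw)), mode=mode), (ph, pw)
        return x, (0, 0)

    def forward(self, x):
        xp, _ = self._padded(x)
        eh, ew = self.extent
        n, c, h, w = xp.shape
        ho, wo = h - eh + 1, w - ew + 1
        if ho <= 0 or wo <= 0:
            raise ValueError("input smaller than the receptive span")
        y = np.empty((n, self.w.shape[0], ho, wo), dtype=np.float32)
        y[:] = self.b[None, :, None, None]
        for i in range(self.kh):
            for j in range(self.kw):
                sl = xp[:, :, i * self.dh:i * self.dh + ho,
                        j * self.dw:j * self.dw + wo]
                y += np.einsum("nchw,oc->nohw", sl, self.w[:, :, i, j],
                               optimize=True)
        self._x = x
        self._pre = y
        if self.linear:
            return y
        return np.maximum(y, 0.0)

    def backward(self, dy):
        if not self.linear:
            dy = dy * (self._pre > 0)
        x = self._x
        xp, (ph, pw) = self._padded(x)
        n, c, h, w = xp.shape
        ho, wo = dy.shape[2], dy.shape[3]
        self.dw_grad = np.zeros_like(self.w)
        self.db_grad = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                sl = xp[:, :, i * self.dh:i * self.dh + ho,
                        j * self.dw:j * self.dw + wo]
                self.dw_grad[:, :, i, j] = np.einsum(
                    "nohw,nchw->oc", dy, sl, optimize=True)
                dxp[:, :, i * self.dh:i * self.dh + ho,
                    j * self.dw:j * self.dw + wo] += np.einsum(
                        "nohw,oc->nchw", dy, self.w[:, :, i, j],
                        optimize=True)
        if not (ph or pw):
            return dxp
        H, W = x.shape[2], x.shape[3]
        if self.pad_mode == "edge":
            # edge padding replicates border pixels, so pad-region
            # gradients fold back onto the borders
            if ph:
                dxp[:, :, ph] += dxp[:, :, :ph].sum(axis=2)
                dxp[:, :, ph + H - 1] += dxp[:, :, ph + H:].sum(axis=2)
            if pw:
                dxp[:, :, :, pw] += dxp[:, :, :, :pw].sum(axis=3)
                dxp[:, :, :, pw + W - 1] += dxp[:, :, :, pw + W:].sum(axis=3)
        return dxp[:, :, ph:ph + H, pw:pw + W]

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw_grad, self.db_grad]


class DilatedCNN:
    """The network: three dilated stages plus a 3x3 head.

    ``norm`` holds the per-channel normalization scale (the training
    set's 99th-percentile intensity) and the label range; both are
    stored with the weights so inference reproduces the training
    pipeline exactly.
    """

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ks = (spec.kernel_shape[1], spec.kernel_shape[0])  # rows, cols
        dil = (1, spec.dilation)
        pads = {
            "same": ["same", "same", "same"],
            "valid": ["valid", "valid", "valid"],
            "hybrid": ["valid", "same", "same"],
        }[spec.padding_policy]
        widths = list(spec.feature_widths)
        self.layers: List[_Conv2D] = []
        c_prev = 2
        for w_out, pad in zip(widths, pads):
            self.layers.append(_Conv2D(c_prev, w_out, ks, dil, pad, rng,
                                       pad_mode=spec.pad_mode))
            c_prev = w_out
        self.layers.append(_Conv2D(c_prev, 1, spec.head_kernel, (1, 1),
                                   "same", rng, linear=True,
                                   pad_mode=spec.pad_mode))
        self.norm: Dict[str, float] = {"cmos": 1.0, "iccd": 1.0}
        self.label_range: Tuple[float, float] = (0.1, 8.0)

    @property
    def col_offset(self) -> int:
        """Input column of the first output column (valid-conv crop)."""
        off = 0
        for lay in self.layers:
            if lay.pad == "valid":
                off += (lay.extent[1] - 1) // 2
        return off

    def output_shape(self, input_shape):
        h, w = input_shape
        for lay in self.layers:
            if lay.pad == "valid":
                eh, ew = lay.extent
                h, w = h - eh + 1, w - ew + 1
        if h <= 0 or w <= 0:
            raise ValueError("input smaller than the receptive span")
        return h, w

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Forward pass: (N, 2, H, W) float input -> (N, 1, H', W')."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)

    @property
    def parameters(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def gradients(self):
        return [g for lay in self.layers for g in lay.grads]

    # -- persistence -------------------------------------------------
    def save(self, path) -> None:
        """Single-archive .npz: weights + spec + normalization metadata."""
        meta = {"spec": asdict(self.spec), "norm": self.norm,
                "label_range": list(self.label_range)}
        arrays = {"meta": np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)}
        for i, p in enumerate(self.parameters):
            arrays[f"p{i}"] = p
        np.savez_compressed(path, **arrays)


def load_model(path) -> DilatedCNN:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        spec = CNNSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in meta["spec"].items()})
        model = DilatedCNN(spec)
        for i, p in enumerate(model.parameters):
            p[...] = z[f"p{i}"]
        model.norm = meta["norm"]
        model.label_range = tuple(meta["label_range"])
    return model


def build_model(spec: CNNSpec,
                cfg: Optional[SystemConfig] = None) -> DilatedCNN:
    """Instantiate the network; with ``cfg`` also check that the dilated
    span covers the system's full replica chain."""
    if cfg is not None:
        spec.check_geometry(cfg)
    return DilatedCNN(spec)


def weighted_mse(pred, label, q) -> float:
    """Intensity-weighted MSE: mean of q * (pred - label)^2 over pixels."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    qa = _field(q, "q")
    if not (pred.shape == label.shape == qa.shape):
        raise ValueError("pred, label and q must share one shape")
    return float(np.mean(qa * (pred - label) ** 2))


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _load_triplets(dataset):
    """Accept a manifest directory or dict of stacked arrays."""
    if isinstance(dataset, dict) and "cmos" in dataset:
        return (np.asarray(dataset["cmos"], dtype=np.float32),
                np.asarray(dataset["iccd"], dtype=np.float32),
                np.asarray(dataset["tau"], dtype=np.float32),
                dataset.get("split"))
    import os

    from . import io as tio
    root = dataset
    with open(os.path.join(root, "manifest.json")) as fh:
        manifest = json.load(fh)
    cmos, iccd, tau = [], [], []
    for item in manifest["items"]:
        f = item["files"]
        cmos.append(tio.read_image(os.path.join(root, f["cmos"])))
        iccd.append(tio.read_image(os.path.join(root, f["iccd"])))
        tau.append(tio.read_image(os.path.join(root, f["tau"])))
    split = {k: np.asarray(v) for k, v in manifest["split"].items()}
    return (np.stack(cmos).astype(np.float32),
            np.stack(iccd).astype(np.float32),
            np.stack(tau).astype(np.float32), split)


def _crop_label(model: DilatedCNN, label):
    off = model.col_offset
    h, w = model.output_shape(label.shape[-2:])
    return label[..., :h, off:off + w]


def _loss_and_grad(model, x, label, weight):
    """Weighted-MSE loss and gradient w.r.t. the network output."""
    pred = model(x)[:, 0]
    diff = pred - label
    denom = float(np.prod(label.shape))
    loss = float(np.sum(weight * diff ** 2) / denom)
    dpred = (2.0 * weight * diff / denom).astype(np.float32)
    return loss, pred, dpred[:, None]


def train(dataset, spec: CNNSpec, tc: TrainConfig,
          cfg: Optional[SystemConfig] = None,
          model: Optional[DilatedCNN] = None):
    """Train the dilated CNN on a phantom dataset.

    ``dataset`` is a manifest directory written by
    :func:`tfflim.phantoms.generate_dataset` or an in-memory dict with
    stacked ``cmos``/``iccd``/``tau`` arrays (and optional ``split``
    index lists).  Channels are normalized by the training set's 99th
    percentile; the loss weight is the normalized CMOS intensity (a
    constant rescaling of the printed intensity-weighted MSE, which
    leaves the minimizer unchanged but keeps gradient scales sane).

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts
    with train/validation loss.  Training aborts with a
    ``FloatingPointError`` if the loss goes non-finite.
    """
    cmos, iccd, tau, split = _load_triplets(dataset)
    n = cmos.shape[0]
    if split is None:
        from .phantoms import split_indices
        tr, va, _te = split_indices(n, tc.split)
    else:
        tr, va = np.asarray(split["train"]), np.asarray(split["val"])
        if va.size == 0:
            va = tr[-max(1, len(tr) // 8):]
    if model is None:
        model = build_model(spec, cfg)
    model.norm = {
        "cmos": float(np.percentile(cmos[tr], 99)) or 1.0,
        "iccd": float(np.percentile(iccd[tr], 99)) or 1.0,
    }
    model.label_range = (float(tau.min()), float(tau.max()))
    x = np.stack([cmos / model.norm["cmos"], iccd / model.norm["iccd"]],
                 axis=1).astype(np.float32)
    label = _crop_label(model, tau)
    weight = _crop_label(model, cmos / model.norm["cmos"]).astype(np.float32)

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.parameters, tc.lr_initial)
    log = []
    # tail weight averaging: running mean of the weights over the final
    # avg_epochs epochs damps the stochastic-gradient jitter of short runs
    avg = None
    n_avg = 0

    def _eval(idx):
        tot = 0.0
        for k in range(0, len(idx), tc.batch_size):
            b = idx[k:k + tc.batch_size]
            loss, _, _ = _loss_and_grad(model, x[b], label[b], weight[b])
            tot += loss * len(b)
        return tot / max(len(idx), 1)

    val0 = _eval(va)
    for epoch in range(tc.epochs):
        opt.lr = tc.lr_initial * tc.lr_decay ** epoch
        order = rng.permutation(tr)
        run = 0.0
        for k in range(0, len(order), tc.batch_size):
            b = order[k:k + tc.batch_size]
            loss, _, dpred = _loss_and_grad(model, x[b], label[b], weight[b])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(dpred)
            opt.step(model.gradients)
            run += loss * len(b)
        if tc.avg_epochs and epoch >= tc.epochs - tc.avg_epochs:
            n_avg += 1
            if avg is None:
                avg = [p.copy() for p in model.parameters]
            else:
                for a, p in zip(avg, model.parameters):
                    a += (p - a) / n_avg
        log.append({"epoch": epoch, "lr": opt.lr,
                    "train_loss": run / len(order), "val_loss": _eval(va)})
    if avg is not None:
        for p, a in zip(model.parameters, avg):
            p[...] = a
        log[-1]["val_loss"] = _eval(va)
    if not log:
        log.append({"epoch": -1, "lr": 0.0, "train_loss": float("nan"),
                    "val_loss": val0})
    log[0]["val_loss_initial"] = val0
    return model, log


def predict(cmos, iccd, model: DilatedCNN, clip: bool = True):
    """Lifetime map for one (CMOS, iCCD) pair.

    Inputs are normalized with the model's recorded statistics; the
    output is clipped to the training label range (``clip=False`` to
    inspect raw network output).  Returns ``(tau_map, col_offset)``:
    with valid-padding policies the map covers input columns
    ``[col_offset, col_offset + width)``.
    """
    q = _field(cmos, "q")
    s = _field(iccd, "s")
    if q.shape != s.shape:
        raise ValueError("CMOS and iCCD images must share one shape")
    model.output_shape(q.shape)  # raises if below the receptive span
    x = np.stack([q / model.norm["cmos"], s / model.norm["iccd"]])[None]
    out = model(x)[0, 0].astype(float)
    if clip:
        out = np.clip(out, *model.label_range)
    return out, model.col_offset
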
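"""Cross-validation splitting, data augmentation and the training loop.

The optimization schedule mirrors common practice for this task: Adam with
an initial learning rate of 0.002 that halves after 15 epochs without
validation-loss improvement (floored at 1e-5), up to 300 epochs with early
termination allowed after epoch 240 when the validation loss has not
improved for 20 epochs, and best-validation weights restored at the end.
Desk-scale runs shrink these numbers via ``TrainSchedule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import LossParams
from .model import Denoiser3D
from .nn.loss import CombinedLoss
from .nn.optim import Adam

__all__ = ["FoldSplit", "TrainSchedule", "PlateauSchedule", "kfold_split",
           "augment", "train_denoiser"]


@dataclass
class FoldSplit:
    """Partition of subject IDs into k test folds with a validation subset.

    For each fold f: ``test_ids(f)`` is that fold; the remaining subjects —
    in the original shuffled order — form the training set, of which the
    first ``floor(val_fraction * n)`` are held out for validation.  The
    split is per-subject so no subject leaks between roles.
    """

    k: int
    fold_assignments: dict = field(default_factory=dict)
    val_fraction: float = 0.10
    seed: int = 0
    _order: list = field(default_factory=list, repr=False)

    def fold_ids(self, f: int) -> list:
        return [s for s in self._order if self.fold_assignments[s] == f]

    def test_ids(self, f: int) -> list:
        return self.fold_ids(f)

    def trainval_ids(self, f: int) -> list:
        return [s for s in self._order if self.fold_assignments[s] != f]

    def val_ids(self, f: int) -> list:
        tv = self.trainval_ids(f)
        return tv[: int(np.floor(self.val_fraction * len(tv)))]

    def train_ids(self, f: int) -> list:
        tv = self.trainval_ids(f)
        return tv[int(np.floor(self.val_fraction * len(tv))):]


def kfold_split(subject_ids: list, k: int, seed: int = 0,
                val_fraction: float = 0.10) -> FoldSplit:
    """Shuffle subjects and partition them into k near-equal test folds."""
    ids = list(subject_ids)
    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} must lie in [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    assignments = {}
    for f, chunk in enumerate(np.array_split(np.arange(len(order)), k)):
        for i in chunk:
            assignments[order[i]] = f
    return FoldSplit(k=k, fold_assignments=assignments,
                     val_fraction=val_fraction, seed=seed, _order=order)


# ---------------------------------------------------------------------------
# augmentation

def _dihedral_ops():
    """The 8 in-plane symmetries: {1, x-flip} x {1, y-flip} x {1, transpose}.

    Each op acts on the first two (in-plane) axes of a 3D volume.
    """
    def op(flip_x, flip_y, transpose):
        def f(v):
            if flip_x:
                v = v[::-1]
            if flip_y:
                v = v[:, ::-1]
            if transpose:
                v = v.swapaxes(0, 1)
            return v
        return f
    return [op(fx, fy, tr) for tr in (False, True)
            for fx in (False, True) for fy in (False, True)]


def _random_affine(vol: np.ndarray, angle: float,
                   shift: tuple[float, float]) -> np.ndarray:
    if angle != 0.0:
        vol = ndimage.rotate(vol, angle, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.0)
    if shift != (0.0, 0.0):
        vol = ndimage.shift(vol, (shift[0], shift[1], 0.0), order=1,
                            mode="constant", cval=0.0)
    return vol


def augment(volumes: np.ndarray, mode: str = "deterministic", seed: int = 0,
            shift_range: float = 8.0, rot_range: float = 45.0) -> np.ndarray:
    """Expand a volume stack by geometric augmentation.

    ``deterministic`` emits, per volume, all 8 combinations of x-flip,
    y-flip and in-plane transpose (8x expansion).  ``full`` additionally
    applies a random in-plane shift (uniform in +-shift_range voxels) and
    rotation (uniform in +-rot_range degrees) per output sample.  Calling
    with the same seed yields the same transform stream, so paired stacks
    (ASL / M0 / ground truth) augmented with one seed stay geometrically
    aligned.
    """
    if mode not in ("deterministic", "full"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    volumes = np.asarray(volumes)
    if volumes.ndim != 4:
        raise ValueError("volumes must be a 4D stack (n, x, y, z)")
    if volumes.shape[1] != volumes.shape[2]:
        raise ValueError("in-plane transpose requires square x/y dimensions")
    ops = _dihedral_ops()
    out = [f(v) for v in volumes for f in ops]
    if mode == "full":
        rng = np.random.default_rng(seed)
        aug = []
        for v in out:
            angle = float(rng.uniform(-rot_range, rot_range))
            shift = (float(rng.uniform(-shift_range, shift_range)),
                     float(rng.uniform(-shift_range, shift_range)))
            aug.append(_random_affine(v, angle, shift))
        out = aug
    return np.stack(out)


# ---------------------------------------------------------------------------
# optimization schedule

@dataclass
class TrainSchedule:
    max_epochs: int = 300
    early_stop_after: int = 240
    patience: int = 20
    lr_init: float = 0.002
    lr_min: float = 0.00001
    lr_drop: float = 0.5
    lr_patience: int = 15
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must be <= lr_init")
        if self.patience < 1 or self.lr_patience < 1:
            raise ValueError("patiences must be >= 1")

    def resolve_batch_size(self, n_train: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return int(min(8, max(2, n_train // 8)))


def micro_schedule(**kwargs) -> TrainSchedule:
    """Short schedule for CPU-scale runs.

    The learning rate is higher than the full-scale default because the
    micro models are far smaller and see far fewer samples per epoch.
    """
    defaults = dict(max_epochs=40, early_stop_after=40, patience=20,
                    lr_init=0.01, lr_patience=8, batch_size=8)
    defaults.update(kwargs)
    return TrainSchedule(**defaults)


class PlateauSchedule:
    """Halve the learning rate after ``lr_patience`` epochs without
    validation-loss improvement, floored at ``lr_min``."""

    def __init__(self, lr_init: float, drop: float, patience: int,
                 lr_min: float):
        self.lr = lr_init
        self.drop, self.patience, self.lr_min = drop, patience, lr_min
        self.best = np.inf
        self.since = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.since = 0
        else:
            self.since += 1
            if self.since >= self.patience:
                self.lr = max(self.lr_min, self.lr * self.drop)
                self.since = 0
        return self.lr


# ---------------------------------------------------------------------------
# training loop

def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _eval_loss(model: Denoiser3D, loss: CombinedLoss, x, y,
               batch_size: int) -> float:
    vals, weights = [], []
    for i in range(0, x.shape[0], batch_size):
        pred = model.forward(x[i:i + batch_size], training=False)
        vals.append(loss.forward(pred, y[i:i + batch_size]))
        weights.append(pred.shape[0])
    return float(np.average(vals, weights=weights))


def train_denoiser(model: Denoiser3D, train_pairs, val_pairs,
                   schedule: TrainSchedule = TrainSchedule(),
                   loss_params: LossParams = LossParams()
                   ) -> tuple[Denoiser3D, dict]:
    """Optimize the combined SSIM+MSE loss on (input, target[, M0]) pairs.

    ``train_pairs``/``val_pairs`` are tuples ``(X, Y)`` or ``(X, Y, M0)`` of
    stacks with shape (n, D, H, W); M0, when the model was built with
    ``include_m0``, is stacked as a second input channel.  Returns the model
    with best-validation weights restored and a history dict with per-epoch
    train/val loss and learning rate.
    """
    def unpack(pairs):
        if len(pairs) == 2:
            X, Y = pairs
            M0 = None
        else:
            X, Y, M0 = pairs
        x = model._stack_inputs(np.asarray(X), M0)
        y = np.asarray(Y, x.dtype)[:, None]
        return x, y

    xtr, ytr = unpack(train_pairs)
    xva, yva = unpack(val_pairs)
    if xtr.shape[0] == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(schedule.seed)
    batch_size = schedule.resolve_batch_size(xtr.shape[0])
    loss = CombinedLoss(w=loss_params.w)
    opt = Adam(model.params(), lr=schedule.lr_init)
    plateau = PlateauSchedule(schedule.lr_init, schedule.lr_drop,
                              schedule.lr_patience, schedule.lr_min)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = None
    since_best = 0

    for epoch in range(schedule.max_epochs):
        ep_losses = []
        for idx in _as_batches(xtr.shape[0], batch_size, rng):
            opt.zero_grad()
            pred = model.forward(xtr[idx], training=True)
            lval = loss.forward(pred, ytr[idx])
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}; "
                    f"lr={opt.lr:g}, batch={idx.tolist()}")
            dpred = loss.backward().astype(pred.dtype)
            model.backward(dpred)
            opt.step()
            ep_losses.append(lval)
        val = _eval_loss(model, loss, xva, yva, batch_size)
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val)
        history["lr"].append(opt.lr)

        if val < best_val - 1e-12:
            best_val = val
            best_state = [p.value.copy() for p in model.params()]
            best_bn = _bn_state(model)
            since_best = 0
        else:
            since_best += 1
        opt.lr = plateau.update(val)
        if (epoch + 1 >= schedule.early_stop_after
                and since_best >= schedule.patience):
            break

    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
        _restore_bn(model, best_bn)
    history["best_val_loss"] = float(best_val)
    return model, history


def _bn_state(model):
    from .nn.layers import BatchNorm3d
    out = []
    for b in model._all_blocks():
        for layer in getattr(b, "layers", [b]):
            if isinstance(layer, BatchNorm3d):
                out.append((layer.running_mean.copy(),
                            layer.running_var.copy()))
    return out


def _restore_bn(model, state):
    from .nn.layers import BatchNorm3d
    i = 0
    for b in model._all_blocks():
        for layer in getattr(b, "layers", [b]):
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[i][0]
                layer.running_var[...] = state[i][1]
                i += 1
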
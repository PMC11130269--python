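"""Neural emulators of the mechanistic simulator.

Two architectures map a (subject, scenario) feature encoding to the opioid
receptor-occupancy time course:

* **black-box** — all features concatenated into one input, a fully
  connected hidden layer, then an LSTM layer unrolled over the output grid
  producing a per-step occupancy;
* **semi-mechanistic** — the layer graph mirrors the mechanistic model's
  component structure: the opioid block and the naloxone block each drive
  their own LSTM track (whose hidden trajectories play the role of
  effect-site time courses), and the per-step track outputs are merged with
  the receptor-binding block in a final LSTM that emits occupancy.  There is
  no dense hidden layer anywhere, and no parameter path connects the
  naloxone inputs to the opioid track or vice versa.

Static condition vectors are repeated at every unrolled step — the standard
way to decode a sequence from a static conditioning input.  Occupancy is
squashed through a logistic output so predictions stay in [0, 1].

Training minimizes mean squared occupancy error with Adam; each epoch sets
aside a fresh random 10% of the training records and reports the error on
them.  Reported errors are squared error summed over time points and
averaged over records.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .nn import LSTM, Adam, Dense
from .params import TimeCourse
from .scenarios import EmulatorDataset, FeatureEncoding

__all__ = [
    "EmulatorSpec",
    "TrainConfig",
    "TrainingRecord",
    "BlackBoxEmulator",
    "SemiMechanisticEmulator",
    "build_blackbox",
    "build_semimechanistic",
    "build_emulator",
    "train",
    "predict_vf",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("blackbox", "semimechanistic")


@dataclass(frozen=True)
class EmulatorSpec:
    """Declarative description of one emulator network.

    sequence_length: number of output time points; dense_width applies only
    to the black-box hidden layer; recurrent_width is the hidden size of
    every LSTM layer; seed fixes the parameter initialization.
    """

    architecture: str
    sequence_length: int
    input_dims: tuple  # (opioid, naloxone, binding) block widths
    dense_width: int = 128
    recurrent_width: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.sequence_length < 2:
            raise ValueError("sequence_length must be >= 2")
        if self.dense_width < 1 or self.recurrent_width < 1:
            raise ValueError("layer widths must be >= 1")
        if len(self.input_dims) != 3 or any(d < 1 for d in self.input_dims):
            raise ValueError("input_dims must be three positive block widths")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam with per-epoch fresh 10% holdout."""

    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    holdout_frac: float = 0.1
    clip_norm: float = 5.0
    lr_schedule: str = "cosine"  # "cosine" anneals to final_lr_frac * lr
    final_lr_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.holdout_frac < 1:
            raise ValueError("holdout_frac must be in (0, 1)")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid batch_size or learning_rate")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for local epoch index 0..epochs-1."""
        if self.lr_schedule == "constant" or self.epochs == 1:
            return self.learning_rate
        frac = epoch / (self.epochs - 1)
        lo = self.final_lr_frac * self.learning_rate
        return lo + 0.5 * (self.learning_rate - lo) * (1 + np.cos(np.pi * frac))


@dataclass
class TrainingRecord:
    """Per-epoch training and holdout errors (squared occupancy error summed
    over time points, averaged over records) plus wall time."""

    train_errors: list = field(default_factory=list)
    holdout_errors: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)
    model: object = None

    def extend(self, other: "TrainingRecord") -> None:
        self.train_errors.extend(other.train_errors)
        self.holdout_errors.extend(other.holdout_errors)
        self.epoch_seconds.extend(other.epoch_seconds)
        self.model = other.model


def _broadcast_seq(x: np.ndarray, T: int) -> np.ndarray:
    """Repeat a static (B, D) vector at every of T steps without copying."""
    return np.broadcast_to(x[:, None, :], (x.shape[0], T, x.shape[1]))


class _EmulatorBase:
    spec: EmulatorSpec

    def __init__(self, spec: EmulatorSpec):
        self.spec = spec
        self.params: dict = {}
        self.optimizer: Adam | None = None
        self.epochs_trained = 0

    def _register(self, *layers) -> None:
        for layer in layers:
            self.params.update(layer.params)

    # subclasses implement forward(blocks) -> (y, cache) and
    # backward(dy, cache) -> grads
    def predict_occupancy(self, blocks: tuple[np.ndarray, ...]) -> np.ndarray:
        y, _ = self.forward(blocks)
        return y


class BlackBoxEmulator(_EmulatorBase):
    """Concatenated input -> dense hidden layer -> LSTM -> logistic output."""

    def __init__(self, spec: EmulatorSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        d_in = sum(spec.input_dims)
        self.dense = Dense("dense", d_in, spec.dense_width, rng, "tanh")
        self.lstm = LSTM("lstm", spec.dense_width, spec.recurrent_width, rng)
        self.out = Dense("out", spec.recurrent_width, 1, rng, "sigmoid")
        self._register(self.dense, self.lstm, self.out)

    def forward(self, blocks: tuple[np.ndarray, ...]):
        x = np.concatenate(blocks, axis=1)
        T = self.spec.sequence_length
        z, c_dense = self.dense.forward(x, self.params)
        hs, c_lstm = self.lstm.forward(_broadcast_seq(z, T), self.params)
        y, c_out = self.out.forward(hs, self.params)
        return y[..., 0], (c_dense, c_lstm, c_out)

    def backward(self, dy: np.ndarray, cache) -> dict:
        c_dense, c_lstm, c_out = cache
        grads: dict = {}
        dh = self.out.backward(dy[..., None], c_out, self.params, grads)
        dx_seq = self.lstm.backward(dh, c_lstm, self.params, grads)
        self.dense.backward(dx_seq.sum(axis=1), c_dense, self.params, grads)
        return grads


class SemiMechanisticEmulator(_EmulatorBase):
    """Opioid and naloxone input blocks drive separate LSTM tracks whose
    per-step outputs merge with the binding block in a final LSTM."""

    def __init__(self, spec: EmulatorSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        d_op, d_nx, d_bind = spec.input_dims
        W = spec.recurrent_width
        self.track_op = LSTM("track_op", d_op, W, rng)
        self.track_nx = LSTM("track_nx", d_nx, W, rng)
        self.merge = LSTM("merge", 2 * W + d_bind, W, rng)
        self.out = Dense("out", W, 1, rng, "sigmoid")
        self._register(self.track_op, self.track_nx, self.merge, self.out)

    def forward(self, blocks: tuple[np.ndarray, ...]):
        x_op, x_nx, x_bind = blocks
        T = self.spec.sequence_length
        h_op, c_op = self.track_op.forward(_broadcast_seq(x_op, T), self.params)
        h_nx, c_nx = self.track_nx.forward(_broadcast_seq(x_nx, T), self.params)
        u = np.concatenate(
            [h_op, h_nx, np.broadcast_to(x_bind[:, None, :],
                                         (x_bind.shape[0], T, x_bind.shape[1]))],
            axis=2,
        )
        h_m, c_m = self.merge.forward(u, self.params)
        y, c_out = self.out.forward(h_m, self.params)
        cache = (c_op, c_nx, c_m, c_out, h_op, h_nx)
        return y[..., 0], cache

    def backward(self, dy: np.ndarray, cache) -> dict:
        c_op, c_nx, c_m, c_out, _, _ = cache
        W = self.spec.recurrent_width
        grads: dict = {}
        dh_m = self.out.backward(dy[..., None], c_out, self.params, grads)
        du = self.merge.backward(dh_m, c_m, self.params, grads)
        self.track_op.backward(du[:, :, :W], c_op, self.params, grads)
        self.track_nx.backward(du[:, :, W:2 * W], c_nx, self.params, grads)
        return grads

    def track_activations(self, blocks: tuple[np.ndarray, ...]) -> dict:
        """Internal effect-site-analog trajectories, (B, T, width) each."""
        _, cache = self.forward(blocks)
        return {"opioid_track": cache[4], "naloxone_track": cache[5]}


def build_blackbox(spec: EmulatorSpec) -> BlackBoxEmulator:
    if spec.architecture != "blackbox":
        raise ValueError("spec.architecture must be 'blackbox'")
    return BlackBoxEmulator(spec)


def build_semimechanistic(spec: EmulatorSpec) -> SemiMechanisticEmulator:
    if spec.architecture != "semimechanistic":
        raise ValueError("spec.architecture must be 'semimechanistic'")
    return SemiMechanisticEmulator(spec)


def build_emulator(spec: EmulatorSpec) -> _EmulatorBase:
    return (build_blackbox if spec.architecture == "blackbox"
            else build_semimechanistic)(spec)


# ---------------------------------------------------------------------------
# Training


def _dataset_blocks(dataset: EmulatorDataset):
    return (dataset.inputs_opioid, dataset.inputs_naloxone,
            dataset.inputs_binding)


def _error_sum_time(model, blocks, targets, batch: int = 512) -> float:
    """Squared error summed over time, averaged over records."""
    n = targets.shape[0]
    total = 0.0
    for lo in range(0, n, batch):
        sl = slice(lo, min(lo + batch, n))
        y = model.predict_occupancy(tuple(b[sl] for b in blocks))
        total += float(np.sum((y - targets[sl]) ** 2))
    return total / n


def train(model, dataset: EmulatorDataset, config: TrainConfig) -> TrainingRecord:
    """Seeded minibatch training; resumable (optimizer state persists on the
    model, per-epoch randomness is derived from the global epoch index)."""
    blocks = _dataset_blocks(dataset)
    targets = dataset.targets
    n, T = targets.shape
    if n == 0:
        raise ValueError("dataset is empty")
    if T != model.spec.sequence_length:
        raise ValueError(
            f"target length {T} != spec sequence_length {model.spec.sequence_length}")
    if model.optimizer is None:
        model.optimizer = Adam(model.params, lr=config.learning_rate)
    record = TrainingRecord(model=model)
    for local_epoch in range(config.epochs):
        t_start = time.perf_counter()
        epoch_idx = model.epochs_trained
        model.optimizer.lr = config.lr_at(local_epoch)
        rng = np.random.default_rng([config.seed, epoch_idx])
        perm = rng.permutation(n)
        n_hold = max(1, int(round(config.holdout_frac * n)))
        if n_hold >= n:
            raise ValueError("holdout fraction leaves no training records")
        hold, fit = perm[:n_hold], perm[n_hold:]
        rng.shuffle(fit)
        for lo in range(0, fit.size, config.batch_size):
            idx = fit[lo:lo + config.batch_size]
            xb = tuple(b[idx] for b in blocks)
            yb = targets[idx]
            y, cache = model.forward(xb)
            resid = y - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch_idx}, "
                    f"batch offset {lo}")
            dy = 2.0 * resid / resid.size
            grads = model.backward(dy, cache)
            model.optimizer.step(model.params, grads, config.clip_norm)
        train_err = _error_sum_time(
            model, tuple(b[fit] for b in blocks), targets[fit])
        hold_err = _error_sum_time(
            model, tuple(b[hold] for b in blocks), targets[hold])
        record.train_errors.append(train_err)
        record.holdout_errors.append(hold_err)
        record.epoch_seconds.append(time.perf_counter() - t_start)
        model.epochs_trained += 1
    return record


def predict_vf(model, inputs, alpha: float, times: np.ndarray | None = None):
    """Map predicted occupancy through the PD equation v_f = 1 - alpha*r_op.

    ``inputs`` may be a FeatureEncoding (single record), a tuple of block
    arrays, or an EmulatorDataset.  Returns a TimeCourse for a single record
    when ``times`` is given, otherwise the (B, T) v_f array.
    """
    single = False
    if isinstance(inputs, FeatureEncoding):
        blocks = (inputs.opioid_block[None], inputs.naloxone_block[None],
                  inputs.binding_block[None])
        single = True
    elif isinstance(inputs, EmulatorDataset):
        blocks = _dataset_blocks(inputs)
        times = inputs.times if times is None else times
    else:
        blocks = tuple(np.atleast_2d(b) for b in inputs)
    r = model.predict_occupancy(blocks)
    v_f = np.clip(1.0 - alpha * r, 0.0, 1.0)
    if single and times is not None:
        return TimeCourse(times, r[0], v_f[0])
    return v_f


# ---------------------------------------------------------------------------
# Checkpoints: npz weights + JSON sidecar with the spec and training state


def save_checkpoint(model, path) -> None:
    path = str(path)
    arrays = dict(model.params)
    if model.optimizer is not None:
        st = model.optimizer.state()
        for k, v in st["m"].items():
            arrays[f"__adam_m__{k}"] = v
        for k, v in st["v"].items():
            arrays[f"__adam_v__{k}"] = v
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    sidecar = {
        "spec": dataclasses.asdict(model.spec),
        "epochs_trained": model.epochs_trained,
        "adam_t": model.optimizer.t if model.optimizer else None,
        "adam_lr": model.optimizer.lr if model.optimizer else None,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    spec_doc = sidecar["spec"]
    spec_doc["input_dims"] = tuple(spec_doc["input_dims"])
    spec = EmulatorSpec(**spec_doc)
    model = build_emulator(spec)
    data = np.load(base + ".npz")
    for k in model.params:
        model.params[k] = data[k]
    if sidecar.get("adam_t") is not None:
        opt = Adam(model.params, lr=sidecar["adam_lr"])
        opt.load_state({
            "t": sidecar["adam_t"],
            "m": {k: data[f"__adam_m__{k}"] for k in model.params},
            "v": {k: data[f"__adam_v__{k}"] for k in model.params},
            "lr": sidecar["adam_lr"],
        })
        model.optimizer = opt
    model.epochs_trained = sidecar["epochs_trained"]
    return model
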
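"""3D CNN classifier of overall-survival class from masked tumor volumes.

Architecture: three feature-extraction blocks, each a 3D convolution,
batch normalization, ReLU, dropout and 2x2x2 max pooling, with 6, 16 and
32 filters respectively; then a fully connected layer and softmax over the
three survival classes. Trained with stochastic gradient descent with
momentum (mini-batch 16, learning rate 3e-4 by default).

For saliency computation the model exposes the activations of the final
block's ReLU and the gradient of any class score with respect to them, plus
``head_forward`` which recomputes class scores from those activations (the
hook used by the finite-difference gradient oracle).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .preprocessing import SurvivalLabel, TumorVolume, augment

__all__ = [
    "ModelConfig", "TrainConfig", "PredictionScores", "SurvivalCNN",
    "build_model", "train", "predict_scores", "save_model", "load_model",
]


@dataclasses.dataclass
class ModelConfig:
    input_shape: tuple[int, int, int] = (48, 48, 18)
    in_channels: int = 4
    filters_per_block: tuple[int, int, int] = (6, 16, 32)
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: int = 2
    dropout: float = 0.2
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != 3:
            raise ValueError("exactly three conv blocks are required")
        f = self.filters_per_block
        if not (f[0] < f[1] < f[2]):
            raise ValueError(f"filters must be strictly increasing, got {f}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.filters_per_block = tuple(int(v) for v in self.filters_per_block)
        self.kernel = tuple(int(k) for k in self.kernel)

    def feature_shape(self) -> tuple[int, int, int]:
        """Spatial shape of the final ReLU's feature maps."""
        dims = self.input_shape
        for _ in range(2):  # pools of blocks 1 and 2 precede the last ReLU
            dims = tuple(d // self.pool for d in dims)
        return dims

    def flat_features(self) -> int:
        dims = tuple(d // self.pool for d in self.feature_shape())
        if any(d < 1 for d in dims):
            raise ValueError(
                f"input shape {self.input_shape} too small to survive 3 poolings")
        return int(np.prod(dims)) * self.filters_per_block[-1]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 16
    max_epochs: int = 100
    learning_rate: float = 3e-4
    momentum: float = 0.9
    seed: int = 0
    augment: bool = True
    max_rotation_deg: float = 10.0
    max_translation_vox: int = 5

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.max_epochs <= 0 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")


@dataclasses.dataclass
class PredictionScores:
    """Pre-softmax class scores and softmax probabilities, short/medium/long."""

    logits: np.ndarray
    probabilities: np.ndarray

    @property
    def predicted_class(self) -> SurvivalLabel:
        return SurvivalLabel(int(np.argmax(self.logits)))

    def to_json_dict(self) -> dict:
        return {
            "logits": {c.short_name: float(self.logits[c.value]) for c in SurvivalLabel},
            "probabilities": {c.short_name: float(self.probabilities[c.value])
                              for c in SurvivalLabel},
            "predicted_class": self.predicted_class.short_name,
        }


class SurvivalCNN:
    """Three conv blocks + dense softmax head, with saliency hooks."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        in_ch = config.in_channels
        relu_indices = []
        for block, f in enumerate(config.filters_per_block):
            layers.append(nn.Conv3D(in_ch, f, config.kernel, rng=rng, dtype=dtype,
                                    skip_input_grad=(block == 0)))
            layers.append(nn.BatchNorm3D(f, dtype=dtype))
            layers.append(nn.ReLU())
            relu_indices.append(len(layers) - 1)
            layers.append(nn.Dropout(config.dropout))
            layers.append(nn.MaxPool3D(config.pool))
            in_ch = f
        layers.append(nn.Flatten())
        layers.append(nn.Dense(config.flat_features(), config.n_classes,
                               rng=rng, dtype=dtype))
        self.layers = layers
        self.final_relu_index = relu_indices[-1]

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1:4] != self.config.input_shape or x.shape[4] != self.config.in_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"{self.config.input_shape + (self.config.in_channels,)}")
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def head_forward(self, activations: np.ndarray) -> np.ndarray:
        """Class scores recomputed from the final ReLU's activations.

        Inference mode throughout, so the map activations -> logits is the
        deterministic function differentiated by ``class_score_gradients``.
        """
        x = np.asarray(activations, dtype=self.dtype)
        if x.ndim == 4:
            x = x[None]
        for layer in self.layers[self.final_relu_index + 1:]:
            x = layer.forward(x, training=False)
        return x

    def class_score_gradients(self, volume: np.ndarray, class_index: int,
                              use_probability: bool = False
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Final-ReLU activations, the gradient of the class score w.r.t.
        them, and the logits, for one input volume.

        The class score is the pre-softmax logit by default;
        ``use_probability`` differentiates the softmax probability instead.
        """
        x = np.asarray(volume, dtype=self.dtype)
        if x.ndim == 4:
            x = x[None]
        head = self.layers[self.final_relu_index + 1:]
        # eval-mode forward, but cache inputs in the head for backprop
        for i, layer in enumerate(self.layers):
            in_head = i > self.final_relu_index
            if in_head and isinstance(layer, (nn.MaxPool3D, nn.Flatten, nn.Dense)):
                x = layer.forward(x, training=True)
            else:
                x = layer.forward(x, training=False)
            if isinstance(layer, nn.BatchNorm3D) and in_head:
                raise AssertionError("batch norm must not appear in the head")
            if i == self.final_relu_index:
                activations = x
        logits = x
        grad = np.zeros_like(logits)
        if use_probability:
            p = nn.softmax(logits)
            grad[:] = -p * p[:, class_index, None]
            grad[:, class_index] += p[:, class_index]
        else:
            grad[:, class_index] = 1.0
        for layer in reversed(head):
            if isinstance(layer, nn.Dropout):
                continue  # identity in inference mode
            grad = layer.backward(grad)
        return activations[0], grad[0], logits[0]

    # ----------------------------------------------------------------- admin
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer{i}_param{j}"] = p
            if isinstance(layer, nn.BatchNorm3D):
                state[f"layer{i}_running_mean"] = layer.running_mean
                state[f"layer{i}_running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p[...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, nn.BatchNorm3D):
                layer.running_mean = np.asarray(state[f"layer{i}_running_mean"])
                layer.running_var = np.asarray(state[f"layer{i}_running_var"])


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> SurvivalCNN:
    config.flat_features()  # validates shape survives the poolings
    return SurvivalCNN(config, seed=seed, dtype=dtype)


def predict_scores(model: SurvivalCNN, volume) -> PredictionScores:
    """Inference-mode class scores for one volume (dropout/batch-norm frozen)."""
    data = volume.data if isinstance(volume, TumorVolume) else np.asarray(volume)
    logits = model.forward(data, training=False)[0]
    return PredictionScores(logits=np.asarray(logits, dtype=np.float64),
                            probabilities=nn.softmax(np.asarray(logits, np.float64)))


@dataclasses.dataclass
class TrainResult:
    model: SurvivalCNN
    loss_history: list[float]
    accuracy_history: list[float]


def _as_array(volume) -> np.ndarray:
    return volume.data if isinstance(volume, TumorVolume) else np.asarray(volume)


def train(model: SurvivalCNN, cohort: list[tuple], cfg: TrainConfig) -> TrainResult:
    """Train by SGD with momentum on (volume, label) pairs.

    Fully deterministic given ``cfg.seed``: initialization is the model's,
    and shuffling, dropout masks and augmentation draws all derive from the
    one training seed. Returns the final-epoch model with loss history.
    """
    labels = np.array([int(lab) for _, lab in cohort])
    present = set(labels.tolist())
    missing = [c.short_name for c in SurvivalLabel if c.value not in present]
    if missing:
        raise ValueError(f"cohort lacks subjects for classes: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    aug_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.max_epochs)
    optimizer = nn.SGDMomentum(model.layers, cfg.learning_rate, cfg.momentum)
    n = len(cohort)
    loss_history: list[float] = []
    acc_history: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_seed = aug_seeds[epoch].generate_state(1)[0]
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xs = []
            for i in idx:
                vol, _ = cohort[i]
                if cfg.augment:
                    tv = vol if isinstance(vol, TumorVolume) else TumorVolume(
                        np.asarray(vol), source_id=str(i))
                    tv = augment(tv, seed=int((epoch_seed + int(i)) % (2 ** 31)),
                                 max_rotation_deg=cfg.max_rotation_deg,
                                 max_translation_vox=cfg.max_translation_vox)
                    xs.append(tv.data)
                else:
                    xs.append(_as_array(vol))
            x = np.stack(xs).astype(model.dtype)
            y = labels[idx]
            optimizer.zero_grad()
            logits = model.forward(x, training=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            model.backward(dlogits.astype(model.dtype))
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y).sum())
        loss_history.append(sum(losses) / n)
        acc_history.append(correct / n)
    return TrainResult(model=model, loss_history=loss_history,
                       accuracy_history=acc_history)


def save_model(model: SurvivalCNN, path: str | Path) -> Path:
    """Serialize weights as .npz with a JSON sidecar of the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_arrays())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.config),
                                  sort_keys=True, indent=2) + "\n")
    return path


def load_model(path: str | Path) -> SurvivalCNN:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    raw = json.loads(sidecar.read_text())
    for key in ("input_shape", "filters_per_block", "kernel"):
        raw[key] = tuple(raw[key])
    model = build_model(ModelConfig(**raw))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as state:
        model.load_state_arrays(dict(state))
    return model
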
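"""Goal-posture prediction networks.

A feed-forward network maps the movement goal — the target's position and
grasp-axis orientation (x, y, z, alpha, beta), optionally together with the
user's two proximal joint angles — to a 'goal' arm configuration whose five
distal joints the controller then drives toward.

Three variants are used:

``pc-``
    proximo-contextual, inputs (x, y, z, alpha, beta, sfe, saa), outputs
    the five distal angles; trained with learning rate 1.59e-7 and
    momentum 0.95 (the historical setting for *direct* application of the
    predictions to the arm).
``pc+``
    same inputs/outputs, learning rate 1e-4, momentum 0 (the setting for
    interpolation-based control where only on-target accuracy matters).
``c+``
    contextual only, inputs (x, y, z, alpha, beta), outputs all seven
    angles; only the five distal outputs are used downstream.

All variants share one architecture: two hidden layers of 256 rectified
linear units, a dropout layer at rate 0.5 (active only during training),
one hidden layer of 64 units, and a linear output layer.  Training is plain
stochastic gradient descent with momentum for 10 epochs at batch size 128,
minimising the squared error summed over each mini-batch.  Inputs and
outputs are z-scored with statistics fitted on the training data and
stored in the predictor (predictions are returned in degrees); under this
loss convention the printed learning rates sit in the classical stable
regime for SGD.

The network is implemented directly on NumPy: it is small, the training
recipe is fixed, and a self-contained implementation keeps training and
inference bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kinematics import (
    DISTAL,
    ArmGeometry,
    RangeOfMotion,
    TargetSpec,
    forward_kinematics_batch,
)
from .synthetic import TrainingSet

__all__ = [
    "NetworkSpec",
    "Predictor",
    "TablePredictor",
    "train",
    "saturate",
    "evaluate_goal_recovery",
    "save_predictor",
    "load_predictor",
]

#: printed training hyper-parameters per variant: (learning rate, momentum)
VARIANT_PARAMS = {
    "pc-": (1.59e-7, 0.95),
    "pc+": (1e-4, 0.0),
    "c+": (1e-4, 0.0),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training recipe of a goal-prediction network."""

    variant: str
    learning_rate: float
    momentum: float
    epochs: int = 10
    batch_size: int = 128
    hidden: tuple[int, ...] = (256, 256)
    dropout: float = 0.5
    final_hidden: int = 64

    @classmethod
    def for_variant(cls, variant: str, learning_rate: float | None = None) -> "NetworkSpec":
        """Spec for one of the named variants.  ``learning_rate`` may be
        overridden for demonstration runs (e.g. a practical rate in place
        of pc-'s historical 1.59e-7); the override is recorded in the spec.
        """
        v = variant.lower()
        if v not in VARIANT_PARAMS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANT_PARAMS)}")
        lr, mom = VARIANT_PARAMS[v]
        return cls(variant=v, learning_rate=learning_rate if learning_rate is not None else lr, momentum=mom)

    @property
    def n_inputs(self) -> int:
        return 5 if self.variant == "c+" else 7

    @property
    def n_outputs(self) -> int:
        return 7 if self.variant == "c+" else 5

    @property
    def requires_proximal(self) -> bool:
        return self.variant in ("pc-", "pc+")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, self.final_hidden, self.n_outputs)


def _he_init(rng: np.random.Generator, sizes: tuple[int, ...]):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


_DROPOUT_AFTER = 1  # dropout sits after the second hidden layer (index 1)


def _forward(weights, biases, X, dropout=0.0, rng=None):
    """Forward pass.  Returns (layer inputs, pre-activations, dropout mask);
    the last pre-activation is the linear network output.  Inverted dropout
    is applied after the second hidden layer, training mode only."""
    inputs, zs = [X], []
    mask = None
    h = X
    n_layers = len(weights)
    for li, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        zs.append(z)
        if li == n_layers - 1:
            break
        h = np.maximum(z, 0.0)
        if li == _DROPOUT_AFTER and dropout > 0.0:
            mask = (rng.random(h.shape) < (1.0 - dropout)) / (1.0 - dropout)
            h = h * mask
        inputs.append(h)
    return inputs, zs, mask


@dataclass
class Predictor:
    """A trained goal-prediction network.

    Holds the weights, the input z-score normalisation fitted at training
    time, and the spec describing variant and schema.  Prediction is a pure
    function of its inputs and the stored weights.
    """

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    @property
    def variant(self) -> str:
        return self.spec.variant

    @property
    def requires_proximal(self) -> bool:
        return self.spec.requires_proximal

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        """Raw network outputs (degrees) for inputs X of shape (N, n_inputs)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"variant {self.variant!r} expects {self.spec.n_inputs} inputs, got {X.shape[1]}"
            )
        Xn = (X - self.x_mean) / self.x_std
        _, zs, _ = _forward(self.weights, self.biases, Xn)
        return zs[-1] * self.y_std + self.y_mean

    def _inputs(self, target: TargetSpec, proximal) -> np.ndarray:
        ctx = target.context
        if self.requires_proximal:
            if proximal is None:
                raise ValueError(f"variant {self.variant!r} requires the proximal angles")
            return np.concatenate([ctx, np.asarray(proximal, dtype=float)])
        if proximal is not None:
            raise ValueError(f"variant {self.variant!r} takes no proximal input")
        return ctx

    def predict_goal(self, target: TargetSpec, proximal: np.ndarray | None = None) -> np.ndarray:
        """Predicted 'goal' distal configuration (hr, efe, fps, wru, wfe) in
        degrees, *before* range-of-motion saturation.  The c+ variant
        predicts all seven angles; only the distal five are returned."""
        out = self.predict_batch(self._inputs(target, proximal)[None, :])[0]
        return out[DISTAL] if self.spec.n_outputs == 7 else out


@dataclass
class TablePredictor:
    """Deterministic lookup predictor: returns the distal configuration of
    the posture each target was generated from.

    An idealised (zero-error) goal predictor used to probe the controller in
    isolation from network accuracy.  Targets are matched by their context
    vector.
    """

    targets: list[TargetSpec]
    postures: np.ndarray  # (N, 7) generating postures
    variant: str = "oracle"
    requires_proximal: bool = False

    def __post_init__(self):
        self._contexts = np.vstack([t.context for t in self.targets])
        self._distal = np.atleast_2d(self.postures)[:, DISTAL].astype(float)

    def predict_goal(self, target: TargetSpec, proximal=None) -> np.ndarray:
        d = np.linalg.norm(self._contexts - target.context, axis=1)
        return self._distal[int(np.argmin(d))].copy()


def _design_matrices(spec: NetworkSpec, samples: TrainingSet) -> tuple[np.ndarray, np.ndarray]:
    if spec.variant == "c+":
        return samples.contexts, samples.angles
    X = np.column_stack([samples.contexts, samples.proximal])
    return X, samples.distal


def train(spec: NetworkSpec, samples: TrainingSet, seed: int | None = None) -> Predictor:
    """Train a goal-prediction network with plain SGD + momentum.

    Deterministic given ``seed`` (weight init, batch shuffling and dropout
    masks all derive from it).  Requires at least one full batch of samples.
    """
    X, Y = _design_matrices(spec, samples)
    n = X.shape[0]
    if n < spec.batch_size:
        raise ValueError(f"need at least batch_size={spec.batch_size} samples, got {n}")
    rng = np.random.default_rng(seed)
    x_mean = X.mean(axis=0)
    x_std = np.where(X.std(axis=0) < 1e-12, 1.0, X.std(axis=0))
    Xn = (X - x_mean) / x_std
    # outputs are fitted on the z-scored scale (statistics kept in the
    # Predictor); predictions are mapped back to degrees
    y_mean = Y.mean(axis=0)
    y_std = np.where(Y.std(axis=0) < 1e-12, 1.0, Y.std(axis=0))
    Yn = (Y - y_mean) / y_std

    weights, biases = _he_init(rng, spec.layer_sizes)
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    n_layers = len(weights)

    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n - spec.batch_size + 1, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = Xn[idx], Yn[idx]
            inputs, zs, mask = _forward(weights, biases, xb, dropout=spec.dropout, rng=rng)
            # summed squared error over the mini-batch (z-scored outputs);
            # under this reduction the printed learning rates sit in the
            # stable SGD regime
            delta = 2.0 * (zs[-1] - yb)
            grads_w, grads_b = [None] * n_layers, [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                grads_w[li] = inputs[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ weights[li].T
                    if li - 1 == _DROPOUT_AFTER and mask is not None:
                        delta = delta * mask
                    delta = delta * (zs[li - 1] > 0)
            for li in range(n_layers):
                vel_w[li] = spec.momentum * vel_w[li] - spec.learning_rate * grads_w[li]
                vel_b[li] = spec.momentum * vel_b[li] - spec.learning_rate * grads_b[li]
                weights[li] = weights[li] + vel_w[li]
                biases[li] = biases[li] + vel_b[li]
    return Predictor(
        spec=spec, weights=weights, biases=biases,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
    )


def mse_loss(predictor: Predictor, samples: TrainingSet) -> float:
    """Mean squared prediction error (deg^2) of a predictor on a sample set."""
    X, Y = _design_matrices(predictor.spec, samples)
    pred = predictor.predict_batch(X)
    return float(np.mean((pred - Y) ** 2))


def saturate(distal: np.ndarray, rom: RangeOfMotion) -> np.ndarray:
    """Clamp a distal configuration to the range of motion, emulating the
    joint limits a physical prosthesis would enforce.  Idempotent."""
    lo, hi = rom.distal()
    return np.clip(np.asarray(distal, dtype=float), lo, hi)


def evaluate_goal_recovery(
    predictor,
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    targets: list[TargetSpec],
    postures: np.ndarray,
) -> dict[str, np.ndarray]:
    """Forward-kinematic accuracy of predicted goal postures.

    For each target (generated from a known posture), predict the distal
    goal given that posture's proximal angles, saturate it, rebuild the full
    configuration and compare its hand pose with the target: Euclidean
    position error (m) and grasp-axis angle error (deg).
    """
    postures = np.atleast_2d(postures)
    goals = np.empty((len(targets), 7))
    for i, tg in enumerate(targets):
        prox = postures[i, :2] if getattr(predictor, "requires_proximal", False) else None
        goals[i, :2] = postures[i, :2]
        goals[i, 2:] = saturate(predictor.predict_goal(tg, prox), rom)
    pos, axes = forward_kinematics_batch(geometry, goals)
    tpos = np.vstack([t.position for t in targets])
    taxes = np.vstack([t.grasp_axis() for t in targets])
    pos_err = np.linalg.norm(pos - tpos, axis=1)
    cosang = np.clip(np.sum(axes * taxes, axis=1), -1.0, 1.0)
    ang_err = np.degrees(np.arccos(cosang))
    return {"position_error_m": pos_err, "axis_error_deg": ang_err}


def save_predictor(predictor: Predictor, path) -> None:
    """Persist a predictor (spec, normalisation, weights) to one JSON file."""
    payload = {
        "format_version": 1,
        "spec": {
            "variant": predictor.spec.variant,
            "learning_rate": predictor.spec.learning_rate,
            "momentum": predictor.spec.momentum,
            "epochs": predictor.spec.epochs,
            "batch_size": predictor.spec.batch_size,
            "hidden": list(predictor.spec.hidden),
            "dropout": predictor.spec.dropout,
            "final_hidden": predictor.spec.final_hidden,
        },
        "x_mean": predictor.x_mean.tolist(),
        "x_std": predictor.x_std.tolist(),
        "y_mean": predictor.y_mean.tolist(),
        "y_std": predictor.y_std.tolist(),
        "weights": [W.tolist() for W in predictor.weights],
        "biases": [b.tolist() for b in predictor.biases],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_predictor(path) -> Predictor:
    with open(path) as fh:
        payload = json.load(fh)
    s = payload["spec"]
    spec = NetworkSpec(
        variant=s["variant"],
        learning_rate=s["learning_rate"],
        momentum=s["momentum"],
        epochs=s["epochs"],
        batch_size=s["batch_size"],
        hidden=tuple(s["hidden"]),
        dropout=s["dropout"],
        final_hidden=s["final_hidden"],
    )
    return Predictor(
        spec=spec,
        weights=[np.array(W) for W in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        x_mean=np.array(payload["x_mean"]),
        x_std=np.array(payload["x_std"]),
        y_mean=np.array(payload["y_mean"]),
        y_std=np.array(payload["y_std"]),
    )
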
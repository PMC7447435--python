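"""Training loop for the boundary-prediction network.

Each iteration samples random patches from the training volumes, augments
them, and takes an Adam step on the BCE-Dice loss.  Validation follows the
segmentation-oriented protocol: the predicted probability map is
thresholded, connected components of the sub-threshold (cell-interior)
region are labelled with 6-connectivity, and the adjusted Rand error
against the ground-truth cells is recorded.  The checkpoint with the
lowest validation ARand error is returned; the learning rate is halved
when validation stagnates.

With a fixed ``rng_seed`` and single-threaded execution, training is
deterministic: two runs produce identical loss curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ..metrics import arand_error
from .augment import AugmentConfig, apply_augmentations
from .inference import InferenceConfig, predict_tiled, standardize
from .losses import LossConfig, loss_and_grad_from_logits
from .unet import UNet

__all__ = ["TrainConfig", "TrainingSample", "Adam", "train", "validation_arand"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    Adam with ``β1=0.9``, ``β2=0.999``, L2 penalty ``1e-5`` and initial
    learning rate ``2e-4``; the rate is divided by ``lr_reduction_factor``
    when the validation ARand error has not improved for ``patience``
    consecutive validations.  ``patches_per_iteration`` patches of
    ``patch_shape`` are drawn per step.
    """

    patch_shape: tuple[int, ...] = (32, 32, 32)
    patches_per_iteration: int = 2
    max_iterations: int = 300
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    lr_reduction_factor: float = 2.0
    patience: int = 5
    validate_every: int = 25
    validation_threshold: float = 0.4
    rng_seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_iterations < 1 or self.patches_per_iteration < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class TrainingSample:
    """One annotated volume: raw image, binary boundary target, and (for
    validation) the ground-truth cell labels."""

    image: np.ndarray
    boundary: np.ndarray
    labels: np.ndarray | None = None


class Adam:
    """Adam with decoupled-from-nothing classic L2 penalty added to the
    gradient (weight decay skips biases and normalisation parameters)."""

    def __init__(self, params, lr: float, beta1: float, beta2: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _sample_patch(
    sample: TrainingSample, patch_shape, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    shape = sample.image.shape
    if any(p > s for p, s in zip(patch_shape, shape)):
        raise ValueError(f"patch {tuple(patch_shape)} larger than volume {shape}")
    origin = tuple(int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_shape))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
    return sample.image[sl], sample.boundary[sl]


def validation_arand(
    model: UNet, sample: TrainingSample, threshold: float = 0.4
) -> float:
    """ARand error of the segmentation obtained by thresholding the
    predicted boundary map and labelling connected components (6-conn)."""
    if sample.labels is None:
        raise ValueError("validation sample lacks ground-truth labels")
    prob = predict_tiled(model, sample.image, InferenceConfig(patch_shape=sample.image.shape))
    interior = prob <= threshold
    structure = ndi.generate_binary_structure(prob.ndim, 1)
    components, _ = ndi.label(interior, structure=structure)
    return arand_error(components, sample.labels)


def train(
    model: UNet,
    train_set: list[TrainingSample],
    val_set: list[TrainingSample],
    cfg: TrainConfig | None = None,
) -> tuple[UNet, dict]:
    """Train ``model``; return it loaded with the best-validation weights,
    plus a history dict (per-iteration loss, per-validation ARand, lr)."""
    cfg = cfg or TrainConfig()
    if not train_set or not val_set:
        raise ValueError("need at least one training and one validation sample")
    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(model.params, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.weight_decay)
    history: dict = {"loss": [], "val_arand": [], "val_iteration": [], "lr": []}
    best_arand = np.inf
    best_state = model.state()
    since_improved = 0

    for iteration in range(1, cfg.max_iterations + 1):
        batch_x, batch_t = [], []
        for _ in range(cfg.patches_per_iteration):
            img, tgt = _sample_patch(train_set[int(rng.integers(len(train_set)))],
                                     cfg.patch_shape, rng)
            img, tgt = apply_augmentations(img, tgt, cfg.augment, rng)
            batch_x.append(img)
            batch_t.append(tgt)
        x = np.stack(batch_x)[:, None]
        t = np.stack(batch_t)[:, None]
        logits = model.forward(x, training=True)
        loss, grad = loss_and_grad_from_logits(logits, t, cfg.loss)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at iteration {iteration}; "
                "check input scaling and learning rate"
            )
        model.zero_grad()
        model.backward(grad.astype(logits.dtype))
        opt.step()
        history["loss"].append(float(loss))

        if iteration % cfg.validate_every == 0 or iteration == cfg.max_iterations:
            arand = float(np.mean([
                validation_arand(model, s, cfg.validation_threshold) for s in val_set
            ]))
            history["val_arand"].append(arand)
            history["val_iteration"].append(iteration)
            history["lr"].append(opt.lr)
            if arand < best_arand:
                best_arand = arand
                best_state = model.state()
                since_improved = 0
            else:
                since_improved += 1
                if since_improved >= cfg.patience:
                    opt.lr /= cfg.lr_reduction_factor
                    since_improved = 0
    model.load_state(best_state)
    history["best_val_arand"] = float(best_arand)
    return model, history
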
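"""Two-headed multilayer perceptron for transition timing and target state.

A shared fully connected trunk feeds two softmax heads: an 11-way timing
head (censored + years 1..10) and a target-state head over the states
realized in the training set. Trained with joint cross-entropy (the state
term masked on censored rows) using Adam on mini-batches. Pure NumPy,
seeded and single-threaded deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSchema
from .dataset import ExampleSet

__all__ = ["ModelConfig", "MLPTransitionModel", "SplitHeadModel", "fit_dnn"]


@dataclass(frozen=True)
class ModelConfig:
    """Training hyper-parameters; serialized next to the weights."""

    hidden: tuple[int, ...] = (256, 256, 256, 256)
    activation: str = "relu"
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 20
    seed: int = 0
    shared_trunk: bool = True  # False trains one network per head

    def __post_init__(self) -> None:
        if not self.hidden or any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer sizes must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPTransitionModel:
    """Trained transition model; see :func:`fit_dnn`."""

    requires_features = True
    requires_context = False

    def __init__(
        self,
        config: ModelConfig,
        schema: FeatureSchema,
        state_class_ids: np.ndarray,
        loss_weights: tuple[float, float] = (1.0, 1.0),
    ) -> None:
        self.config = config
        self.schema = schema
        self.state_class_ids = np.asarray(state_class_ids, dtype=np.int64)
        self.n_dr = schema.horizon + 1
        self.loss_weights = loss_weights
        self.scaler_mean: np.ndarray | None = None
        self.scaler_scale: np.ndarray | None = None
        self.params: dict[str, np.ndarray] = {}
        self.training_log: pd.DataFrame | None = None

    # -- architecture -----------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        sizes = [self.schema.length, *self.config.hidden]
        p: dict[str, np.ndarray] = {}
        for i in range(len(sizes) - 1):
            p[f"W{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1])
            ).astype(np.float32)
            p[f"b{i}"] = np.zeros(sizes[i + 1], dtype=np.float32)
        top = sizes[-1]
        p["Wdr"] = rng.normal(0.0, np.sqrt(1.0 / top), (top, self.n_dr)).astype(np.float32)
        p["bdr"] = np.zeros(self.n_dr, dtype=np.float32)
        k = len(self.state_class_ids)
        p["Wst"] = rng.normal(0.0, np.sqrt(1.0 / top), (top, k)).astype(np.float32)
        p["bst"] = np.zeros(k, dtype=np.float32)
        self.params = p

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.config.activation == "relu" else np.tanh(z)

    def _act_grad(self, a: np.ndarray) -> np.ndarray:
        return (a > 0).astype(a.dtype) if self.config.activation == "relu" else 1.0 - a * a

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
        """Returns (layer inputs, pre-dropout activations, dropout masks,
        dr logits, state logits). ``inputs[i]`` feeds layer i; inverted
        dropout keeps inference mask-free."""
        inputs = [X]
        raw: list[np.ndarray] = []
        masks: list[np.ndarray] = []
        h = X
        for i in range(len(self.config.hidden)):
            a = self._act(h @ self.params[f"W{i}"] + self.params[f"b{i}"])
            raw.append(a)
            if rng is not None and self.config.dropout > 0.0:
                keep = 1.0 - self.config.dropout
                mask = (rng.random(a.shape) < keep).astype(a.dtype) / keep
                h = a * mask
                masks.append(mask)
            else:
                h = a
            inputs.append(h)
        return inputs, raw, masks, h @ self.params["Wdr"] + self.params["bdr"], h @ self.params["Wst"] + self.params["bst"]

    # -- training ---------------------------------------------------------

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.scaler_mean) / self.scaler_scale).astype(np.float32)

    def fit(self, train: ExampleSet, val: ExampleSet | None = None) -> "MLPTransitionModel":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.scaler_mean = train.X.mean(axis=0).astype(np.float32)
        sd = train.X.std(axis=0).astype(np.float32)
        sd[sd < 1e-8] = 1.0  # constant columns pass through unscaled
        self.scaler_scale = sd
        X = self._scale(train.X)
        y_dr = train.y_dr.astype(np.int64)
        state_pos = {s: i for i, s in enumerate(self.state_class_ids)}
        y_st = np.full(len(train), -1, dtype=np.int64)
        unc = train.y_dr != 0
        try:
            y_st[unc] = [state_pos[s] for s in train.y_state[unc]]
        except KeyError as e:
            raise ValueError(f"target state {e} absent from model support") from None
        self._init_params(rng)

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        log_rows = []
        n = len(train)
        w_dr, w_st = self.loss_weights
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, ydr_b, yst_b = X[idx], y_dr[idx], y_st[idx]
                inputs, raw, masks, zdr, zst = self._forward(xb, rng)
                pdr = _softmax(zdr)
                pst = _softmax(zst)
                m = len(idx)
                # joint loss: CE(timing) + CE(state) averaged over labelled rows
                ll_dr = -np.log(pdr[np.arange(m), ydr_b] + 1e-12)
                st_mask = yst_b >= 0
                n_st = max(int(st_mask.sum()), 1)
                ll_st = np.zeros(m)
                ll_st[st_mask] = -np.log(
                    pst[st_mask, yst_b[st_mask]] + 1e-12
                )
                loss = w_dr * ll_dr.mean() + w_st * ll_st.sum() / n_st
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (NaN/inf loss) at epoch {epoch}, "
                        f"batch {start // cfg.batch_size}; try a lower learning rate"
                    )
                epoch_loss += float(loss) * m

                # backward
                gdr = pdr
                gdr[np.arange(m), ydr_b] -= 1.0
                gdr *= w_dr / m
                gst = pst
                gst[np.arange(m), yst_b.clip(min=0)] -= 1.0
                gst[~st_mask] = 0.0
                gst *= w_st / n_st
                grads: dict[str, np.ndarray] = {}
                h_top = inputs[-1]
                grads["Wdr"] = h_top.T @ gdr
                grads["bdr"] = gdr.sum(axis=0)
                grads["Wst"] = h_top.T @ gst
                grads["bst"] = gst.sum(axis=0)
                dh = gdr @ self.params["Wdr"].T + gst @ self.params["Wst"].T
                for i in reversed(range(len(cfg.hidden))):
                    if masks:
                        dh = dh * masks[i]
                    dz = dh * self._act_grad(raw[i])
                    grads[f"W{i}"] = inputs[i].T @ dz
                    grads[f"b{i}"] = dz.sum(axis=0)
                    dh = dz @ self.params[f"W{i}"].T

                t += 1
                b1, b2, eps = 0.9, 0.999, 1e-8
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
                for k, g in grads.items():
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                    self.params[k] -= (
                        lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)
                    ).astype(np.float32)

            row = {"epoch": epoch, "train_loss": epoch_loss / n}
            if val is not None and len(val) > 0:
                row.update(self._validation_metrics(val))
            log_rows.append(row)
        self.training_log = pd.DataFrame(log_rows)
        return self

    def _validation_metrics(self, val: ExampleSet) -> dict[str, float]:
        p_dr, p_st = self.predict(val.X)
        acc_dr = float((p_dr.argmax(axis=1) == val.y_dr).mean())
        unc = val.y_dr != 0
        if unc.any():
            pred_state = self.state_class_ids[p_st[unc].argmax(axis=1)]
            acc_st = float((pred_state == val.y_state[unc]).mean())
        else:
            acc_st = float("nan")
        return {"val_acc_dr": acc_dr, "val_acc_state": acc_st}

    # -- inference --------------------------------------------------------

    def predict(
        self, X: np.ndarray, context: pd.DataFrame | None = None, batch: int = 8192
    ) -> tuple[np.ndarray, np.ndarray]:
        """Probability distributions (p_dr, p_state) for raw feature rows."""
        if self.scaler_mean is None:
            raise RuntimeError("model is not fitted")
        if X.shape[1] != self.schema.length:
            raise ValueError("feature matrix does not match model schema")
        outs_dr, outs_st = [], []
        for start in range(0, len(X), batch):
            xb = self._scale(X[start : start + batch])
            _, _, _, zdr, zst = self._forward(xb, rng=None)
            outs_dr.append(_softmax(zdr))
            outs_st.append(_softmax(zst))
        return np.concatenate(outs_dr), np.concatenate(outs_st)

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            scaler_mean=self.scaler_mean,
            scaler_scale=self.scaler_scale,
            state_class_ids=self.state_class_ids,
            **self.params,
        )
        meta = {
            "config": asdict(self.config),
            "schema": json.loads(self.schema.to_json()),
            "schema_hash": self.schema.schema_hash(),
            "loss_weights": list(self.loss_weights),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        if self.training_log is not None:
            self.training_log.to_csv(directory / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "MLPTransitionModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg = dict(meta["config"])
        cfg["hidden"] = tuple(cfg["hidden"])
        config = ModelConfig(**cfg)
        schema = FeatureSchema.from_json(json.dumps(meta["schema"]))
        if schema.schema_hash() != meta["schema_hash"]:
            raise ValueError("feature schema hash mismatch in saved model")
        data = np.load(directory / "weights.npz")
        model = cls(config, schema, data["state_class_ids"], tuple(meta["loss_weights"]))
        model.scaler_mean = data["scaler_mean"]
        model.scaler_scale = data["scaler_scale"]
        model.params = {
            k: data[k]
            for k in data.files
            if k not in ("scaler_mean", "scaler_scale", "state_class_ids")
        }
        return model


class SplitHeadModel:
    """Two independent networks, one per head (``shared_trunk=False``)."""

    requires_features = True
    requires_context = False

    def __init__(self, dr_model: MLPTransitionModel, state_model: MLPTransitionModel):
        self.dr_model = dr_model
        self.state_model = state_model
        self.schema = dr_model.schema
        self.state_class_ids = state_model.state_class_ids
        self.n_dr = dr_model.n_dr

    def predict(self, X, context=None):
        p_dr, _ = self.dr_model.predict(X)
        _, p_st = self.state_model.predict(X)
        return p_dr, p_st


def fit_dnn(
    train: ExampleSet,
    val: ExampleSet | None,
    config: ModelConfig,
) -> MLPTransitionModel | SplitHeadModel:
    """Train the transition classifier.

    The target-state head supports exactly the states observed uncensored in
    the training set; unseen states get probability zero at predict time.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    state_ids = np.unique(train.y_state[train.y_dr != 0])
    if len(state_ids) == 0:
        raise ValueError("training set contains no uncensored transitions")
    if config.shared_trunk:
        model = MLPTransitionModel(config, train.schema, state_ids)
        return model.fit(train, val)
    dr_model = MLPTransitionModel(config, train.schema, state_ids, loss_weights=(1.0, 0.0))
    st_cfg = ModelConfig(**{**asdict(config), "seed": config.seed + 1})
    st_model = MLPTransitionModel(st_cfg, train.schema, state_ids, loss_weights=(0.0, 1.0))
    dr_model.fit(train, val)
    st_model.fit(train, val)
    return SplitHeadModel(dr_model, st_model)
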
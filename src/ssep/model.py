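"""The substrate-specific effect predictor (SSEP) regressor.

A multi-input feed-forward network maps blocked features (sequence embedding,
in-silico predictor scores, mutation descriptors, ligand descriptors, local
interaction features) to a scalar activity score on the log10 uptake-ratio
scale (0 = wildtype-equivalent). Each block passes through its own affine
encoder, the encoded blocks are concatenated, and a fully connected trunk
produces the output. Training uses Adam with mean-squared-error loss, an
85/15 train-validation split with early stopping, optional deep-mutational-
scanning fine-tuning at a reduced learning rate, and grid-search
hyperparameter selection on mean held-out Spearman rho over repeated runs.

Two routes share this code: SSEP-SNV consumes the full block set for variants
with complete annotations, SSEP-UV consumes the reduced block set available
to partially annotated variants (including indels). When several structure
templates give several bundles for one variant-substrate pair, the final
SSEP score is the unweighted mean of the per-structure predictions.

The implementation is plain numpy with manual backpropagation; with a fixed
seed, training and prediction are bit-reproducible on a single thread.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureBundle

__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "TrainedModel",
    "SSEPScore",
    "FineTuneReport",
    "target_transform",
    "inverse_transform",
    "build_model",
    "pretrain",
    "fine_tune",
    "grid_search",
    "predict_pair",
    "stack_bundles",
]

TARGET_FLOOR_RATIO = 1e-3  # uptake ratios are clipped here before log10


class ConfigurationError(ValueError):
    pass


def target_transform(uptake_pct_wt):
    """Map %WT uptake to the model target scale: log10(uptake ratio).

    100 %WT maps to 0; the ratio is clipped at 1e-3 (so 0 %WT maps to -3).
    """
    ratio = np.asarray(uptake_pct_wt, dtype=float) / 100.0
    return np.log10(np.clip(ratio, TARGET_FLOOR_RATIO, None))


def inverse_transform(score):
    """Map a model-scale score back to %WT uptake."""
    return 100.0 * np.power(10.0, np.asarray(score, dtype=float))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings.

    ``block_dims`` fixes which feature blocks the input layer accepts and
    their widths; ``encoder_width=0`` turns the per-block encoders into
    pass-throughs (with ``trunk_widths=()`` and identity activation the whole
    network degenerates to an affine map, which is the linear reference mode).
    """

    block_dims: tuple[tuple[str, int], ...]
    encoder_width: int = 32
    trunk_widths: tuple[int, ...] = (64, 32)
    activation: str = "relu"
    dropout: float = 0.1
    learning_rate: float = 1e-3
    fine_tune_learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    fine_tune_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.block_dims:
            raise ConfigurationError("block_dims must name at least one block")
        for name, d in self.block_dims:
            if d < 1:
                raise ConfigurationError(f"block {name!r} width must be >= 1, got {d}")
        if self.encoder_width < 0 or any(w < 1 for w in self.trunk_widths):
            raise ConfigurationError("widths must be >= 1 (encoder_width 0 = passthrough)")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0 or self.fine_tune_learning_rate < 0:
            raise ConfigurationError("learning rates must be positive")
        if self.activation not in ("relu", "identity", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")

    @property
    def block_names(self) -> list[str]:
        return [n for n, _ in self.block_dims]


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    return z


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "tanh":
        return 1.0 - a * a
    return np.ones_like(z)


class _Net:
    """Parameter container + forward/backward for the blocked MLP."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        e = config.encoder_width
        concat_dim = 0
        for name, d in config.block_dims:
            if e > 0:
                scale = np.sqrt(2.0 / d)
                self.params[f"enc_{name}_W"] = rng.standard_normal((d, e)) * scale
                self.params[f"enc_{name}_b"] = np.zeros(e)
                concat_dim += e
            else:
                concat_dim += d
        prev = concat_dim
        for i, w in enumerate(config.trunk_widths):
            scale = np.sqrt(2.0 / prev)
            self.params[f"trunk_{i}_W"] = rng.standard_normal((prev, w)) * scale
            self.params[f"trunk_{i}_b"] = np.zeros(w)
            prev = w
        self.params["out_W"] = rng.standard_normal((prev, 1)) * np.sqrt(1.0 / prev)
        self.params["out_b"] = np.zeros(1)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _check_blocks(self, X: Mapping[str, np.ndarray]) -> None:
        cfg_names = set(self.config.block_names)
        given = set(X)
        unknown = given - cfg_names
        if unknown:
            raise ConfigurationError(
                f"input carries blocks {sorted(unknown)} the model was not configured for")
        missing = cfg_names - given
        if missing:
            raise ConfigurationError(f"input is missing blocks {sorted(missing)}")
        for name, d in self.config.block_dims:
            if X[name].shape[1] != d:
                raise ConfigurationError(
                    f"block {name!r} has width {X[name].shape[1]}, expected {d}")

    def forward(self, X: Mapping[str, np.ndarray], train_rng=None):
        """Forward pass; returns (predictions, cache). Dropout only if train_rng."""
        self._check_blocks(X)
        cfg = self.config
        cache = {"X": X, "enc": [], "trunk": []}
        parts = []
        for name, _ in cfg.block_dims:
            xb = X[name]
            if cfg.encoder_width > 0:
                z = xb @ self.params[f"enc_{name}_W"] + self.params[f"enc_{name}_b"]
                a = _act(z, cfg.activation)
                cache["enc"].append((name, xb, z, a))
                parts.append(a)
            else:
                cache["enc"].append((name, xb, None, xb))
                parts.append(xb)
        h = np.concatenate(parts, axis=1)
        cache["h0"] = h
        for i in range(len(cfg.trunk_widths)):
            z = h @ self.params[f"trunk_{i}_W"] + self.params[f"trunk_{i}_b"]
            a = _act(z, cfg.activation)
            if train_rng is not None and cfg.dropout > 0:
                mask = (train_rng.random(a.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                out = a * mask
            else:
                mask = None
                out = a
            cache["trunk"].append((h, z, a, mask))
            h = out
        cache["h_last"] = h
        pred = (h @ self.params["out_W"] + self.params["out_b"]).ravel()
        return pred, cache

    def backward(self, cache, dpred: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        d = dpred[:, None]
        h_last = cache["h_last"]
        grads["out_W"] = h_last.T @ d
        grads["out_b"] = d.sum(axis=0)
        dh = d @ self.params["out_W"].T
        for i in reversed(range(len(cfg.trunk_widths))):
            h_in, z, a, mask = cache["trunk"][i]
            if mask is not None:
                dh = dh * mask
            dz = dh * _act_grad(z, a, cfg.activation)
            grads[f"trunk_{i}_W"] = h_in.T @ dz
            grads[f"trunk_{i}_b"] = dz.sum(axis=0)
            dh = dz @ self.params[f"trunk_{i}_W"].T
        # split concat gradient back into block segments
        offset = 0
        for name, xb, z, a in cache["enc"]:
            width = a.shape[1]
            seg = dh[:, offset:offset + width]
            offset += width
            if z is not None:
                dz = seg * _act_grad(z, a, cfg.activation)
                grads[f"enc_{name}_W"] = xb.T @ dz
                grads[f"enc_{name}_b"] = dz.sum(axis=0)
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            mhat = self.m[k] / (1 - beta1 ** self.t)
            vhat = self.v[k] / (1 - beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedModel:
    """A (possibly trained) SSEP regressor for one route (SNV or UV)."""

    config: ModelConfig
    route: str = "SNV"
    net: _Net = None  # type: ignore[assignment]
    training_log: list = field(default_factory=list)
    target_scale: str = "log10_uptake_ratio"

    def __post_init__(self):
        if self.route not in ("SNV", "UV"):
            raise ConfigurationError(f"route must be SNV or UV, got {self.route!r}")
        if self.net is None:
            self.net = _Net(self.config, np.random.default_rng(self.config.seed))

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict(self, X: Mapping[str, np.ndarray]) -> np.ndarray:
        pred, _ = self.net.forward({k: np.asarray(v, float) for k, v in X.items()})
        return pred

    def predict_bundles(self, bundles: Sequence[FeatureBundle]) -> np.ndarray:
        X = stack_bundles(bundles, self.config.block_names)
        return self.predict(X)

    # --- checkpoint (text-serializable) -------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "format": "ssep-checkpoint-v1",
            "route": self.route,
            "target_scale": self.target_scale,
            "config": asdict(self.config),
            "weights": {k: v.tolist() for k, v in self.net.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        cfg_d = dict(d["config"])
        cfg_d["block_dims"] = tuple((n, int(w)) for n, w in cfg_d["block_dims"])
        cfg_d["trunk_widths"] = tuple(cfg_d["trunk_widths"])
        cfg = ModelConfig(**cfg_d)
        m = cls(config=cfg, route=d["route"], target_scale=d["target_scale"])
        for k, v in d["weights"].items():
            m.net.params[k] = np.array(v, dtype=float)
        return m


def build_model(config: ModelConfig, route: str = "SNV") -> TrainedModel:
    """Build an untrained model; route determines which bundles it may see."""
    return TrainedModel(config=config, route=route)


def stack_bundles(bundles: Sequence[FeatureBundle], block_names: Sequence[str]) -> dict:
    """Stack bundles into per-block design matrices for the given blocks."""
    X = {}
    for name in block_names:
        rows = []
        for b in bundles:
            v = b.blocks.get(name)
            if v is None:
                raise ConfigurationError(
                    f"bundle {b.variant}/{b.substrate} lacks block {name!r}")
            rows.append(np.asarray(v, dtype=float).ravel())
        X[name] = np.vstack(rows)
    return X


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def _run_training(model: TrainedModel, X: dict, y: np.ndarray, lr: float,
                  max_epochs: int, rng: np.random.Generator,
                  val: tuple | None = None, patience: int | None = None,
                  log: list | None = None) -> None:
    cfg = model.config
    n = y.size
    opt = _Adam(model.net.params, lr)
    best_val = np.inf
    best_params = None
    best_epoch = 0
    stale = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb = {k: v[idx] for k, v in X.items()}
            yb = y[idx]
            pred, cache = model.net.forward(Xb, train_rng=rng)
            if not np.all(np.isfinite(pred)):
                raise RuntimeError(
                    f"non-finite predictions at epoch {epoch} (lr={lr}); "
                    "training aborted — check feature scaling")
            dpred = 2.0 * (pred - yb) / yb.size
            grads = model.net.backward(cache, dpred)
            opt.step(model.net.params, grads)
        train_mse = _mse(model.net.forward(X)[0], y)
        if not np.isfinite(train_mse):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        entry = {"epoch": epoch, "train_mse": train_mse}
        if val is not None:
            Xv, yv = val
            val_mse = _mse(model.net.forward(Xv)[0], yv)
            entry["val_mse"] = val_mse
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in model.net.params.items()}
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
        if log is not None:
            log.append(entry)
        if val is not None and patience is not None and stale > patience:
            break
    if best_params is not None:
        model.net.params = best_params
        if log is not None:
            log.append({"epoch": "best", "best_epoch": best_epoch, "val_mse": best_val})


def pretrain(
    model: TrainedModel,
    X: Mapping[str, np.ndarray],
    y,
    split_fraction: float = 0.85,
    seed: int = 0,
    retrain_full: bool = False,
) -> TrainedModel:
    """Train with Adam + MSE on an 85/15 train-validation split.

    Early stopping monitors held-out MSE with the configured patience and the
    best weights are restored. With ``retrain_full`` the model is afterwards
    retrained on all data for the number of epochs the early-stopped run
    used (the final-model regimen). ``split_fraction=1.0`` disables the
    validation split and runs the full epoch budget.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError(f"pretraining requires >= 10 labeled pairs, got {y.size}")
    X = {k: np.asarray(v, dtype=float) for k, v in X.items()}
    rng = np.random.default_rng(seed)
    n = y.size
    if split_fraction >= 1.0:
        val = None
        Xtr, ytr = X, y
    else:
        perm = rng.permutation(n)
        n_tr = max(1, int(round(split_fraction * n)))
        tr, va = perm[:n_tr], perm[n_tr:]
        Xtr = {k: v[tr] for k, v in X.items()}
        ytr = y[tr]
        val = ({k: v[va] for k, v in X.items()}, y[va])
    model.training_log = []
    _run_training(model, Xtr, ytr, model.config.learning_rate,
                  model.config.max_epochs, rng, val=val,
                  patience=model.config.patience, log=model.training_log)
    if retrain_full and val is not None:
        best = [e for e in model.training_log if e.get("epoch") == "best"]
        epochs = int(best[0]["best_epoch"]) + 1 if best else model.config.max_epochs
        fresh = build_model(model.config, model.route)
        fresh.training_log = [{"stage": "retrain_full", "epochs": epochs}]
        _run_training(fresh, X, y, model.config.learning_rate, epochs,
                      np.random.default_rng(seed), log=fresh.training_log)
        return fresh
    return model


@dataclass
class FineTuneReport:
    n_records: int
    rho_before: float | None = None
    rho_after: float | None = None


def fine_tune(
    model: TrainedModel,
    X: Mapping[str, np.ndarray],
    y,
    seed: int = 0,
    eval_set: tuple | None = None,
) -> tuple[TrainedModel, FineTuneReport]:
    """Continue optimization on DMS-derived targets at the fine-tune rate.

    All weights stay trainable; the learning rate is the configured
    ``fine_tune_learning_rate`` (default 10x below pretraining). If an
    ``eval_set=(X_eval, y_eval)`` is supplied, held-out Spearman rho is
    reported before and after so the fine-tuning benefit is measurable.
    An empty DMS set is a warning no-op.
    """
    from scipy.stats import spearmanr

    y = np.asarray(y, dtype=float)
    report = FineTuneReport(n_records=int(y.size))
    if y.size == 0:
        warnings.warn("empty DMS set: fine-tuning skipped")
        return model, report
    X = {k: np.asarray(v, dtype=float) for k, v in X.items()}
    if eval_set is not None:
        Xe, ye = eval_set
        report.rho_before = float(spearmanr(model.predict(Xe), ye).statistic)
    if model.config.fine_tune_learning_rate > 0:
        _run_training(model, X, y, model.config.fine_tune_learning_rate,
                      model.config.fine_tune_epochs, np.random.default_rng(seed),
                      log=model.training_log)
    if eval_set is not None:
        Xe, ye = eval_set
        report.rho_after = float(spearmanr(model.predict(Xe), ye).statistic)
    return model, report


def grid_search(
    base_config: ModelConfig,
    grid: Sequence[Mapping],
    X: Mapping[str, np.ndarray],
    y,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
    route: str = "SNV",
) -> tuple[ModelConfig, pd.DataFrame]:
    """Grid-search hyperparameters on mean held-out Spearman rho.

    Each candidate is trained ``n_repeats`` times with distinct split/init
    seeds; the candidate with the highest mean rho wins. Ties break toward
    the smaller parameter count, then lexicographic config order. Returns the
    winning config and the full grid report.
    """
    from scipy.stats import spearmanr

    if not grid:
        raise ValueError("empty hyperparameter grid")
    seeds = list(seeds) if seeds is not None else list(range(n_repeats))
    y = np.asarray(y, dtype=float)
    rows = []
    failures = {}
    for gi, overrides in enumerate(grid):
        cfg = replace(base_config, **dict(overrides))
        rhos = []
        try:
            for s in seeds:
                m = build_model(replace(cfg, seed=s), route)
                rng = np.random.default_rng(s)
                perm = rng.permutation(y.size)
                n_tr = max(1, int(round(0.85 * y.size)))
                tr, va = perm[:n_tr], perm[n_tr:]
                Xd = {k: np.asarray(v, float) for k, v in X.items()}
                _run_training(m, {k: v[tr] for k, v in Xd.items()}, y[tr],
                              cfg.learning_rate, cfg.max_epochs, rng,
                              val=({k: v[va] for k, v in Xd.items()}, y[va]),
                              patience=cfg.patience)
                rho = spearmanr(m.predict({k: v[va] for k, v in Xd.items()}), y[va]).statistic
                rhos.append(float(rho) if np.isfinite(rho) else 0.0)
            n_params = build_model(cfg, route).n_parameters()
            rows.append({"grid_index": gi, "config": dict(overrides),
                         "mean_rho": float(np.mean(rhos)), "rho_per_seed": rhos,
                         "n_parameters": n_params})
        except Exception as exc:  # keep per-config diagnostics
            failures[gi] = repr(exc)
    if not rows:
        raise RuntimeError(f"all grid configs failed: {failures}")
    report = pd.DataFrame(rows)
    order = sorted(rows, key=lambda r: (-r["mean_rho"], r["n_parameters"],
                                        repr(sorted(r["config"].items()))))
    best = order[0]
    return replace(base_config, **best["config"]), report


@dataclass(frozen=True)
class SSEPScore:
    """One substrate-specific activity score (log10 uptake ratio vs WT)."""

    variant: str
    substrate: str
    score: float
    n_structures_averaged: int
    route: str = "SNV"
    gene: str = ""


def predict_pair(models: Mapping[str, TrainedModel],
                 bundles: Sequence[FeatureBundle]) -> SSEPScore:
    """Integrate per-structure predictions into one SSEP score.

    All bundles must belong to one (variant, substrate) pair. The route is
    chosen by majority completeness over the bundles (tie -> SNV); the score
    is the unweighted mean of the routed model's per-structure predictions.
    """
    bundles = list(bundles)
    if not bundles:
        raise ValueError("predict_pair requires at least one bundle")
    keys = {(b.variant, b.substrate) for b in bundles}
    if len(keys) > 1:
        raise ValueError(f"bundles span multiple pairs: {sorted(keys)}")
    n_full = sum(1 for b in bundles if b.completeness == "full")
    route = "SNV" if n_full * 2 >= len(bundles) else "UV"
    model = models[route]
    usable = [b for b in bundles
              if all(b.blocks.get(n) is not None for n in model.config.block_names)]
    if not usable:
        raise ConfigurationError(
            f"no bundle for {keys} carries the blocks the {route} model needs")
    preds = model.predict_bundles(usable)
    variant, substrate = next(iter(keys))
    return SSEPScore(variant=variant, substrate=substrate,
                     score=float(np.mean(preds)),
                     n_structures_averaged=len(usable), route=route,
                     gene=bundles[0].gene)
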
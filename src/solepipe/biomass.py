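"""Body dimensions -> weight regression.

Two regressors share one contract.  The closed-form allometric baseline fits
the standard length-weight power law W = alpha * L^beta * Wd^gamma by
ordinary least squares in log space; it is exact on noise-free power-law
data and serves as oracle and fallback.  The main regressor is a nine-layer
fully connected network (layer widths 2 -> 64 -> 64 -> 32 -> 32 -> 16 -> 16
-> 8 -> 1, ReLU hidden activations, linear output) trained with the Adam
optimizer at learning rate 0.001 and batch size 4 on standardized inputs and
standardized log-weight targets, with an 80/20 train-test split.  The
network is counted as nine layers including the input and output layers; a
convolutional architecture is not meaningful for two scalar inputs, so the
regressor is fully connected by design.  Training is pure NumPy — no GPU
framework is required — and is bit-reproducible from its seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .synthscene import BiomassRecord

ARCHITECTURE: tuple[int, ...] = (2, 64, 64, 32, 32, 16, 16, 8, 1)

#: Fractional margin outside the training input range beyond which
#: predictions trigger an extrapolation warning.
EXTRAPOLATION_MARGIN = 0.25


class DegenerateFitError(ValueError):
    """The design matrix is rank deficient (e.g. all lengths identical)."""


class ExtrapolationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MLPConfig:
    """Training hyperparameters; defaults follow the adopted recipe
    (Adam, lr 0.001, batch 4) with unstated knobs fixed to sensible values."""

    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 2000
    patience: int = 100  # early stopping on held-out loss; <=0 disables
    test_fraction: float = 0.2
    hidden_activation: str = "relu"
    optimizer: str = "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class FitReport:
    r2_train: float
    r2_test: float
    rmse_train_g: float
    rmse_test_g: float
    n_train: int
    n_test: int
    epochs_run: int
    loss_trace: list[float] = field(repr=False, default_factory=list)


@dataclass
class BiomassModel:
    """Dimensions -> weight regressor: network weights + standardization +
    allometric baseline coefficients.

    ``weights``/``biases`` are per-layer arrays (empty until an MLP is
    trained; the model then falls back to the baseline power law).  Inputs
    are standardized per feature; the MLP target is standardized log-weight,
    inverse-transformed to grams for reporting.
    """

    log_alpha: float
    beta: float
    gamma: float
    architecture: tuple[int, ...] = ARCHITECTURE
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    input_range: tuple[tuple[float, float], tuple[float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def has_mlp(self) -> bool:
        return len(self.weights) > 0

    # -- prediction --------------------------------------------------------
    def predict(self, length_cm, width_cm):
        length_cm = np.asarray(length_cm, dtype=np.float64)
        width_cm = np.asarray(width_cm, dtype=np.float64)
        if np.any(length_cm <= 0) or np.any(width_cm <= 0):
            raise ValueError("length_cm and width_cm must be strictly positive")
        self._warn_if_extrapolating(length_cm, width_cm)
        if not self.has_mlp:
            return np.exp(
                self.log_alpha
                + self.beta * np.log(length_cm)
                + self.gamma * np.log(width_cm)
            )
        x = np.stack(
            [np.atleast_1d(length_cm), np.atleast_1d(width_cm)], axis=1
        ).astype(np.float64)
        z = (x - self.x_mean) / self.x_sd
        out = _forward(z, self.weights, self.biases)[-1][:, 0]
        logw = out * self.y_sd + self.y_mean
        w = np.exp(logw)
        if np.isscalar(length_cm) or length_cm.ndim == 0:
            return float(w[0])
        return w

    def _warn_if_extrapolating(self, length_cm, width_cm) -> None:
        if self.input_range is None:
            return
        for name, vals, (lo, hi) in (
            ("length_cm", np.atleast_1d(length_cm), self.input_range[0]),
            ("width_cm", np.atleast_1d(width_cm), self.input_range[1]),
        ):
            span = hi - lo
            if np.any(vals < lo - EXTRAPOLATION_MARGIN * span) or np.any(
                vals > hi + EXTRAPOLATION_MARGIN * span
            ):
                warnings.warn(
                    f"{name} outside the training range [{lo:.3g}, {hi:.3g}] "
                    f"by more than {EXTRAPOLATION_MARGIN:.0%}",
                    ExtrapolationWarning,
                    stacklevel=3,
                )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "format": "solepipe-biomass-model",
            "version": 1,
            "log_alpha": self.log_alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "architecture": list(self.architecture),
            "activation": "relu",
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_sd": None if self.x_sd is None else self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "input_range": self.input_range,
            "metadata": self.metadata,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "BiomassModel":
        d = json.loads(text)
        if d.get("format") != "solepipe-biomass-model":
            raise ValueError("not a solepipe biomass model document")
        ir = d.get("input_range")
        return cls(
            log_alpha=d["log_alpha"],
            beta=d["beta"],
            gamma=d["gamma"],
            architecture=tuple(d["architecture"]),
            weights=[np.asarray(w, dtype=np.float64) for w in d["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in d["biases"]],
            x_mean=None if d["x_mean"] is None else np.asarray(d["x_mean"]),
            x_sd=None if d["x_sd"] is None else np.asarray(d["x_sd"]),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            input_range=None if ir is None else (tuple(ir[0]), tuple(ir[1])),
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "BiomassModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def predict_weight(model: BiomassModel, length_cm: float, width_cm: float) -> float:
    """Estimate one fish's weight in grams from its body dimensions."""
    return float(model.predict(float(length_cm), float(width_cm)))


# ---------------------------------------------------------------------------
# Allometric baseline


def fit_allometric_baseline(records: list[BiomassRecord]) -> tuple[float, float, float]:
    """OLS of log(weight) on [1, log(length), log(width)].

    Returns (log_alpha, beta, gamma).  Raises :class:`DegenerateFitError`
    when the design is rank deficient (all lengths equal, or length and
    width exactly collinear in log space).
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    L = np.array([r.length_cm for r in records])
    W = np.array([r.width_cm for r in records])
    G = np.array([r.weight_g for r in records])
    X = np.column_stack([np.ones_like(L), np.log(L), np.log(W)])
    y = np.log(G)
    if np.linalg.matrix_rank(X, tol=1e-9 * np.abs(X).max()) < 3:
        raise DegenerateFitError("log-log design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def baseline_model(records: list[BiomassRecord]) -> BiomassModel:
    """A BiomassModel using only the closed-form allometric power law."""
    log_alpha, beta, gamma = fit_allometric_baseline(records)
    L = [r.length_cm for r in records]
    W = [r.width_cm for r in records]
    return BiomassModel(
        log_alpha=log_alpha,
        beta=beta,
        gamma=gamma,
        input_range=((min(L), max(L)), (min(W), max(W))),
        metadata={"kind": "allometric-baseline", "n_records": len(records)},
    )


def exact_baseline(alpha: float, beta: float, gamma: float) -> BiomassModel:
    """A baseline model with given power-law coefficients (no fitting)."""
    return BiomassModel(log_alpha=math.log(alpha), beta=beta, gamma=gamma,
                        metadata={"kind": "allometric-exact"})


# ---------------------------------------------------------------------------
# MLP


def _forward(z, weights, biases):
    acts = [z]
    h = z
    last = len(weights) - 1
    for i, (w, b) in enumerate(zip(weights, biases)):
        h = h @ w + b
        if i < last:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return acts


def _init_params(architecture, rng):
    weights, biases = [], []
    for nin, nout in zip(architecture[:-1], architecture[1:]):
        # He-normal fan-in initialization for ReLU stacks
        weights.append(rng.normal(0.0, math.sqrt(2.0 / nin), size=(nin, nout)))
        biases.append(np.zeros(nout))
    return weights, biases


def evaluate_r2(predicted, observed) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    When SS_tot = 0 (constant observations): 1.0 if the residuals are also
    ~0, else 0.0 by convention.
    """
    p = np.asarray(predicted, dtype=np.float64)
    o = np.asarray(observed, dtype=np.float64)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 observations")
    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-24 * max(1.0, float(np.sum(o**2))) else 0.0
    return 1.0 - ss_res / ss_tot


def fit_biomass_mlp(
    records: list[BiomassRecord],
    config: MLPConfig | None = None,
    seed: int = 0,
) -> tuple[BiomassModel, FitReport]:
    """Train the nine-layer regressor on (length, width, weight) records.

    Inputs are standardized; the target is standardized log-weight (weights
    are multiplicative in allometry, so errors are modelled on the log
    scale); mini-batch Adam with MSE loss.  The held-out split doubles as
    the early-stopping monitor; the parameters with the best held-out loss
    are kept.  Fully reproducible from ``seed``.
    """
    config = config or MLPConfig()
    if len(records) < 20:
        raise ValueError(f"need >= 20 records to train, got {len(records)}")
    G = np.array([r.weight_g for r in records])
    if np.any(G <= 0):
        raise ValueError("weights must be strictly positive")
    X = np.array([[r.length_cm, r.width_cm] for r in records], dtype=np.float64)
    y = np.log(G)

    rng = np.random.default_rng(seed)
    n = len(records)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * config.test_fraction)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    x_mean = X[train_idx].mean(axis=0)
    x_sd = X[train_idx].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y[train_idx].mean())
    y_sd = float(y[train_idx].std()) or 1.0

    Ztr = (X[train_idx] - x_mean) / x_sd
    Zte = (X[test_idx] - x_mean) / x_sd
    ytr = (y[train_idx] - y_mean) / y_sd
    yte = (y[test_idx] - y_mean) / y_sd

    weights, biases = _init_params(ARCHITECTURE, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
    lr = config.learning_rate
    step = 0

    best_val = math.inf
    best_params = None
    best_epoch = 0
    trace: list[float] = []
    n_train = len(train_idx)

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            zb, yb = Ztr[idx], ytr[idx]
            acts = _forward(zb, weights, biases)
            pred = acts[-1][:, 0]
            err = pred - yb
            epoch_loss += float(np.sum(err**2))
            # backprop of mean-squared-error
            delta = (2.0 / len(idx)) * err[:, None]
            grads_w, grads_b = [None] * len(weights), [None] * len(weights)
            for li in range(len(weights) - 1, -1, -1):
                grads_w[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ weights[li].T) * (acts[li] > 0)
            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for li in range(len(weights)):
                m_w[li] = b1 * m_w[li] + (1 - b1) * grads_w[li]
                v_w[li] = b2 * v_w[li] + (1 - b2) * grads_w[li] ** 2
                weights[li] -= lr * (m_w[li] / corr1) / (np.sqrt(v_w[li] / corr2) + eps)
                m_b[li] = b1 * m_b[li] + (1 - b1) * grads_b[li]
                v_b[li] = b2 * v_b[li] + (1 - b2) * grads_b[li] ** 2
                biases[li] -= lr * (m_b[li] / corr1) / (np.sqrt(v_b[li] / corr2) + eps)
        trace.append(epoch_loss / n_train)
        val_pred = _forward(Zte, weights, biases)[-1][:, 0]
        val_loss = float(np.mean((val_pred - yte) ** 2))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = ([w.copy() for w in weights], [b.copy() for b in biases])
        if config.patience > 0 and epoch - best_epoch >= config.patience:
            break

    if best_params is not None:
        weights, biases = best_params

    model = BiomassModel(
        log_alpha=0.0,
        beta=0.0,
        gamma=0.0,
        architecture=ARCHITECTURE,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        input_range=(
            (float(X[:, 0].min()), float(X[:, 0].max())),
            (float(X[:, 1].min()), float(X[:, 1].max())),
        ),
        metadata={
            "kind": "mlp",
            "optimizer": config.optimizer,
            "learning_rate": config.learning_rate,
            "batch_size": config.batch_size,
            "epochs": config.epochs,
            "epochs_run": len(trace),
            "seed": seed,
            "test_fraction": config.test_fraction,
        },
    )
    try:
        la, be, ga = fit_allometric_baseline(records)
        model.log_alpha, model.beta, model.gamma = la, be, ga
    except DegenerateFitError:
        pass

    pred_tr = model.predict(X[train_idx, 0], X[train_idx, 1])
    pred_te = model.predict(X[test_idx, 0], X[test_idx, 1])
    report = FitReport(
        r2_train=evaluate_r2(pred_tr, G[train_idx]),
        r2_test=evaluate_r2(pred_te, G[test_idx]),
        rmse_train_g=float(np.sqrt(np.mean((pred_tr - G[train_idx]) ** 2))),
        rmse_test_g=float(np.sqrt(np.mean((pred_te - G[test_idx]) ** 2))),
        n_train=len(train_idx),
        n_test=len(test_idx),
        epochs_run=len(trace),
        loss_trace=trace,
    )
    return model, report
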
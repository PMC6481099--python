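"""Quantification models: small squared-error network and stepwise regression.

Two estimators map grayscale channel intensities to analyte
concentration.

The network is a five-stage multilayer perceptron for tabular
regression: four affine blocks with hyperbolic-tangent activations
followed by a single sigmoid output unit, trained by full-batch
adaptive-moment gradient descent on a squared-error loss.  Inputs are
/255-scaled intensities; the concentration target is min-max mapped
into an interior interval of (0, 1) (default [0.1, 0.9]) so the sigmoid
never has to saturate at the extreme standards, and predictions are
mapped back through the inverse affine.

The linear alternative is classical forward-backward stepwise multiple
regression on partial-F p-values (enter at p <= 0.05, remove at
p >= 0.10 by default).  Final models containing any predictor with a
variance inflation factor of 10 or more are rejected — such a
coefficient is unreliable — and the search is repeated without the
offending predictor.  The linear model consumes raw 0–255 intensities,
so published named-channel equations can be applied directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ContractError, DegenerateInputError, NumericalError
from .sampling import AssayDesign, FeatureTable

__all__ = [
    "MLPConfig",
    "MLPModel",
    "StepwiseConfig",
    "LinearModel",
    "RangeRestriction",
    "train_mlp",
    "predict",
    "stepwise_fit",
    "apply_linear_model",
    "restrict_range",
]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the five-stage network."""

    input_dim: int
    hidden: tuple[int, ...] = (64, 64, 32, 16)
    epochs: int = 3000
    seed: int = 0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    target_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        lo, hi = self.target_range
        if not (0.0 < lo < hi < 1.0):
            raise ContractError("target_range must lie strictly inside (0, 1)")


@dataclass
class MLPModel:
    """A trained network with its input/target scaling."""

    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    channel_names: tuple[str, ...]
    level_min: float
    level_max: float
    loss_history: dict[str, list[float]] = field(default_factory=dict)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in (0, 1) for a scaled feature matrix."""
        h = x
        n_hidden = len(self.config.hidden)
        for i in range(n_hidden):
            h = np.tanh(h @ self.weights[i] + self.biases[i])
        z = h @ self.weights[n_hidden] + self.biases[n_hidden]
        return 1.0 / (1.0 + np.exp(-z))

    def scale_target(self, levels: np.ndarray) -> np.ndarray:
        lo, hi = self.config.target_range
        if self.level_max == self.level_min:
            return np.full_like(np.asarray(levels, dtype=np.float64), 0.5 * (lo + hi))
        frac = (np.asarray(levels, dtype=np.float64) - self.level_min) / (
            self.level_max - self.level_min
        )
        return lo + (hi - lo) * frac

    def unscale_target(self, sigmoid_values: np.ndarray) -> np.ndarray:
        lo, hi = self.config.target_range
        if self.level_max == self.level_min:
            return np.full_like(np.asarray(sigmoid_values, dtype=np.float64), self.level_min)
        frac = (np.asarray(sigmoid_values, dtype=np.float64) - lo) / (hi - lo)
        return self.level_min + (self.level_max - self.level_min) * frac

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "version": 1,
            "config": {
                "input_dim": self.config.input_dim,
                "hidden": list(self.config.hidden),
                "epochs": self.config.epochs,
                "seed": self.config.seed,
                "learning_rate": self.config.learning_rate,
                "target_range": list(self.config.target_range),
            },
            "channel_names": list(self.channel_names),
            "level_min": self.level_min,
            "level_max": self.level_max,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        cfg = MLPConfig(
            input_dim=d["config"]["input_dim"],
            hidden=tuple(d["config"]["hidden"]),
            epochs=d["config"]["epochs"],
            seed=d["config"]["seed"],
            learning_rate=d["config"]["learning_rate"],
            target_range=tuple(d["config"]["target_range"]),
        )
        return cls(
            config=cfg,
            weights=[np.asarray(w, dtype=np.float64) for w in d["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in d["biases"]],
            channel_names=tuple(d["channel_names"]),
            level_min=float(d["level_min"]),
            level_max=float(d["level_max"]),
        )


def _feature_matrix(table: FeatureTable, channel_names: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in channel_names if c not in table.channel_names]
    if missing:
        raise ContractError(f"feature table lacks model channels {missing[:5]}")
    return table.data[list(channel_names)].to_numpy(dtype=np.float64)


def train_mlp(
    train: FeatureTable,
    config: MLPConfig | None = None,
    validation: FeatureTable | None = None,
) -> MLPModel:
    """Train the five-stage network on a scaled feature table.

    Full-batch adaptive-moment gradient descent minimizes the mean
    squared error between the sigmoid output and the scaled target for
    ``config.epochs`` passes.  The per-epoch training loss (and, when a
    validation table is given, validation loss) is retained so
    overtraining can be inspected as a divergence of the two curves.
    Reproducible: a fixed seed yields bit-identical weights.
    """
    if not train.scaled:
        raise ContractError("train_mlp requires /255-scaled features; call .scale()")
    if config is None:
        config = MLPConfig(input_dim=len(train.channel_names))
    if config.input_dim != len(train.channel_names):
        raise ContractError(
            f"config.input_dim={config.input_dim} but table has "
            f"{len(train.channel_names)} channels"
        )
    x = train.features()
    y = train.levels
    level_min, level_max = float(y.min()), float(y.max())

    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.hidden, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims, dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    model = MLPModel(
        config=config,
        weights=weights,
        biases=biases,
        channel_names=train.channel_names,
        level_min=level_min,
        level_max=level_max,
        loss_history={"train": []},
    )
    t = model.scale_target(y)[:, None]
    if validation is not None:
        if not validation.scaled:
            raise ContractError("validation table must be scaled")
        x_val = _feature_matrix(validation, train.channel_names)
        t_val = model.scale_target(validation.levels)[:, None]
        model.loss_history["validation"] = []

    if level_max == level_min:
        # Degenerate single-level target: the scaler pins every
        # prediction to that level, so there is nothing to optimize.
        model.loss_history["train"].append(0.0)
        return model

    params = weights + biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    n_hidden = len(config.hidden)
    n = x.shape[0]

    for epoch in range(1, config.epochs + 1):
        # forward
        activations = [x]
        h = x
        for i in range(n_hidden):
            h = np.tanh(h @ weights[i] + biases[i])
            activations.append(h)
        z = h @ weights[n_hidden] + biases[n_hidden]
        s = 1.0 / (1.0 + np.exp(-z))
        residual = s - t
        model.loss_history["train"].append(float(np.mean(residual**2)))
        if validation is not None:
            val_res = model.forward(x_val) - t_val
            model.loss_history["validation"].append(float(np.mean(val_res**2)))

        # backward
        grad_w = [np.empty(0)] * (n_hidden + 1)
        grad_b = [np.empty(0)] * (n_hidden + 1)
        delta = (2.0 / n) * residual * s * (1.0 - s)
        grad_w[n_hidden] = activations[n_hidden].T @ delta
        grad_b[n_hidden] = delta.sum(axis=0)
        for i in range(n_hidden - 1, -1, -1):
            delta = (delta @ weights[i + 1].T) * (1.0 - activations[i + 1] ** 2)
            grad_w[i] = activations[i].T @ delta
            grad_b[i] = delta.sum(axis=0)

        grads = grad_w + grad_b
        lr_t = config.learning_rate * np.sqrt(1.0 - config.beta2**epoch) / (
            1.0 - config.beta1**epoch
        )
        for j, grad in enumerate(grads):
            m[j] = config.beta1 * m[j] + (1.0 - config.beta1) * grad
            v[j] = config.beta2 * v[j] + (1.0 - config.beta2) * grad**2
            params[j] -= lr_t * m[j] / (np.sqrt(v[j]) + config.eps)
    return model


def predict(model: MLPModel, features: FeatureTable) -> np.ndarray:
    """Concentration estimates for a scaled feature table."""
    if not features.scaled:
        raise ContractError("predict requires /255-scaled features")
    x = _feature_matrix(features, model.channel_names)
    return model.unscale_target(model.forward(x)[:, 0])


@dataclass(frozen=True)
class StepwiseConfig:
    """Entry/removal thresholds and collinearity limit for stepwise search."""

    p_in: float = 0.05
    p_out: float = 0.10
    vif_max: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_in <= self.p_out < 1.0):
            raise ContractError("need 0 < p_in <= p_out < 1")
        if self.vif_max <= 1.0:
            raise ContractError("vif_max must exceed 1")


@dataclass(frozen=True)
class LinearModel:
    """Named-channel linear model: estimate = sum(coef * intensity) + constant."""

    terms: tuple[tuple[str, float], ...]
    constant: float
    vifs: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("nan")
    residual_df: int = 0
    empty: bool = False

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def equation(self, unit: str = "") -> str:
        """Human-readable named-channel equation."""
        parts = [f"{coef:+.4g} x {name}" for name, coef in self.terms]
        rhs = " ".join(parts) + f" {self.constant:+.4g}"
        lhs = f"concentration ({unit})" if unit else "concentration"
        return f"{lhs} = {rhs.lstrip('+')}"

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "version": 1,
            "terms": [[n, c] for n, c in self.terms],
            "constant": self.constant,
            "vifs": dict(self.vifs),
            "r_squared": self.r_squared,
            "residual_df": self.residual_df,
            "empty": self.empty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            terms=tuple((n, float(c)) for n, c in d["terms"]),
            constant=float(d["constant"]),
            vifs={k: float(v) for k, v in d.get("vifs", {}).items()},
            r_squared=float(d.get("r_squared", float("nan"))),
            residual_df=int(d.get("residual_df", 0)),
            empty=bool(d.get("empty", False)),
        )


def _ols_pvalues(y: np.ndarray, x: pd.DataFrame) -> pd.Series:
    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return fit.pvalues


_MIN_TOLERANCE = 1e-4  # classical stepwise entry floor on 1 - R2_j


def _entry_scan(
    y: np.ndarray, x_all: pd.DataFrame, included: list[str], pool: list[str]
) -> tuple[str | None, float]:
    """Best entry candidate by partial-F p-value, with tolerance screening.

    Residualizes every pool column and the response against the current
    model (constant + included predictors) in one orthogonal projection;
    the partial F statistic of each candidate is then a one-dimensional
    regression on the residuals, identical to the squared t of its
    coefficient in the augmented model.  Candidates with tolerance
    (1 - R2 on the included set) below ``_MIN_TOLERANCE`` are skipped.
    Ties break toward the earlier column in registry order.
    """
    if not pool:
        return None, np.inf
    n = y.size
    z = np.column_stack([np.ones(n)] + [x_all[c].to_numpy() for c in included])
    q, _ = np.linalg.qr(z)
    xp = x_all[pool].to_numpy(dtype=np.float64)
    x_res = xp - q @ (q.T @ xp)
    y_res = y - q @ (q.T @ y)
    ss_x = np.sum(x_res**2, axis=0)
    xc = xp - xp.mean(axis=0)
    ss_total = np.sum(xc**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tolerance = np.where(ss_total > 0, ss_x / np.where(ss_total > 0, ss_total, 1.0), 0.0)
    df = n - len(included) - 2
    if df < 1:
        return None, np.inf
    eligible = tolerance >= _MIN_TOLERANCE
    if not eligible.any():
        return None, np.inf
    beta = np.zeros(len(pool))
    beta[eligible] = (x_res[:, eligible] * y_res[:, None]).sum(axis=0) / ss_x[eligible]
    ss_reg = beta**2 * ss_x
    sse = np.sum(y_res**2) - ss_reg
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(sse > 0, ss_reg / (sse / df), np.inf)
    pvals = np.where(eligible, stats.f.sf(f_stat, 1, df), np.inf)
    p_min = pvals.min()
    if not np.isfinite(p_min):
        return None, np.inf
    # earliest registry column within floating-point noise of the minimum,
    # so duplicated predictors resolve to the canonical one
    best = int(np.flatnonzero(pvals <= p_min * (1.0 + 1e-6) + 1e-300)[0])
    return pool[best], float(pvals[best])


def _vifs(x: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: 1 / (1 - R2) of each column on the rest."""
    out: dict[str, float] = {}
    cols = list(x.columns)
    if len(cols) < 2:
        return {c: 1.0 for c in cols}
    for col in cols:
        others = [c for c in cols if c != col]
        fit = sm.OLS(
            x[col].to_numpy(), sm.add_constant(x[others], has_constant="add")
        ).fit()
        r2 = min(fit.rsquared, 1.0 - 1e-12)
        out[col] = float(1.0 / (1.0 - r2))
    return out


def stepwise_fit(
    train: FeatureTable,
    config: StepwiseConfig | None = None,
) -> LinearModel:
    """Forward-backward stepwise regression with VIF screening.

    Predictors enter on the smallest partial-F p-value at or below
    ``p_in`` and leave when their p-value in the current model reaches
    ``p_out``; ties break by registry column order, and candidates whose
    tolerance (1 - R2 on the current model) falls below 1e-4 are
    ineligible to enter.  Once the search
    reaches a fixed point, variance inflation factors are computed; if
    any reaches ``vif_max`` the worst offender is excluded from the
    candidate pool and the whole search restarts, so the accepted model
    never carries an unreliable coefficient.  If nothing meets ``p_in``
    the result is a constant-only model flagged ``empty``.
    """
    if config is None:
        config = StepwiseConfig()
    y = train.levels
    x_all = pd.DataFrame(
        train.raw_features(), columns=list(train.channel_names)
    )
    if len(y) < 4:
        raise DegenerateInputError("stepwise_fit needs at least 4 rows")
    if float(np.ptp(y)) == 0.0:
        raise DegenerateInputError("target has no variation")

    candidates = list(x_all.columns)
    banned: set[str] = set()

    while True:
        included: list[str] = []
        max_steps = 4 * len(candidates) + 4
        for _ in range(max_steps):
            changed = False
            # entry scan
            pool = [c for c in candidates if c not in included and c not in banned]
            best_name, best_p = _entry_scan(y, x_all, included, pool)
            if best_name is not None and best_p <= config.p_in:
                included.append(best_name)
                changed = True
            # removal scan
            if included:
                pvals = _ols_pvalues(y, x_all[included])
                worst = max(included, key=lambda c: float(pvals.get(c, 0.0)))
                if float(pvals.get(worst, 0.0)) >= config.p_out:
                    included.remove(worst)
                    changed = True
            if not changed:
                break

        if not included:
            return LinearModel(
                terms=(), constant=float(np.mean(y)), vifs={},
                r_squared=0.0, residual_df=len(y) - 1, empty=True,
            )
        vifs = _vifs(x_all[included])
        worst_vif = max(vifs, key=vifs.get)  # type: ignore[arg-type]
        if vifs[worst_vif] >= config.vif_max:
            banned.add(worst_vif)
            continue
        fit = sm.OLS(y, sm.add_constant(x_all[included], has_constant="add")).fit()
        return LinearModel(
            terms=tuple((c, float(fit.params[c])) for c in included),
            constant=float(fit.params["const"]),
            vifs=vifs,
            r_squared=float(fit.rsquared),
            residual_df=int(fit.df_resid),
        )


def apply_linear_model(
    model: LinearModel, features: FeatureTable | pd.DataFrame
) -> np.ndarray:
    """Evaluate a named-channel linear model on raw 0–255 intensities."""
    if isinstance(features, FeatureTable):
        data = pd.DataFrame(
            features.raw_features(), columns=list(features.channel_names)
        )
    else:
        data = features
    missing = [n for n in model.channel_names if n not in data.columns]
    if missing:
        raise ContractError(f"missing channel columns {missing}")
    est = np.full(len(data), model.constant, dtype=np.float64)
    for name, coef in model.terms:
        est += coef * data[name].to_numpy(dtype=np.float64)
    return est


@dataclass(frozen=True)
class RangeRestriction:
    """Record of levels removed from evaluation and the remaining range."""

    excluded_levels: tuple[float, ...]
    effective_range: tuple[float, float]
    n_removed: int


def restrict_range(
    estimates: np.ndarray,
    levels: np.ndarray,
    design: AssayDesign,
    exclude_levels: tuple[float, ...] | list[float] = (),
) -> tuple[np.ndarray, np.ndarray, RangeRestriction]:
    """Drop rows at excluded levels and report the remaining measurable range.

    Used for the reference-solution workflow: when the estimate for the
    zero-concentration standard is unreliable (a false positive), the
    zero level is excluded and the method's effective range becomes
    [lowest remaining level, highest level].
    """
    exclude = tuple(float(v) for v in exclude_levels)
    bad = set(exclude) - set(design.levels)
    if bad:
        raise ContractError(f"levels {sorted(bad)} not in the design")
    remaining = [lv for lv in design.levels if lv not in exclude]
    if not remaining:
        raise NumericalError("cannot exclude every level from evaluation")
    estimates = np.asarray(estimates, dtype=np.float64)
    levels = np.asarray(levels, dtype=np.float64)
    if estimates.shape != levels.shape:
        raise ContractError("estimates and levels must have equal length")
    mask = ~np.isin(levels, exclude)
    record = RangeRestriction(
        excluded_levels=exclude,
        effective_range=(min(remaining), max(remaining)),
        n_removed=int((~mask).sum()),
    )
    return estimates[mask], levels[mask], record
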
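"""Ensemble of small automated neural-network regressors for solubility.

Each candidate is a single-hidden-layer perceptron (6-12 hidden units,
transfer functions drawn from identity / logistic / tanh / exponential /
sine for both the hidden and the output layer) trained on the sum-of-squares
error by L-BFGS, with early stopping monitored on the test subset of a
70/15/15 train/test/validation split. A candidate joins the ensemble only if
it passes two acceptance criteria evaluated over the whole dataset on the
log10 mole-fraction scale: RMSD < 0.04 and at most four outliers
(|standardized residual| > 3). Accepted networks are kept sorted by RMSD;
ensemble predictions average the per-network outputs after discarding any
that imply a mole fraction outside (0, 1).

The networks are hand-rolled (scikit-learn's MLP lacks the sine and
exponential transfer functions); the estimator itself follows the
scikit-learn fit/predict contract and composes with its model selection
tools.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "ACTIVATIONS", "NetworkModel", "Ensemble", "EnsemblePrediction",
    "SannEnsembleRegressor", "split_dataset", "train_network",
    "evaluate_network", "build_ensemble", "predict", "convergence_curve",
]

# transfer functions: value and derivative (as a function of the value where
# cheap, of the pre-activation otherwise)
_EXP_CLIP = 30.0


def _identity(z):
    return z


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLIP, _EXP_CLIP)))


def _exponential(z):
    return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f(z), f'(z))
    "identity": (_identity, lambda z: np.ones_like(z)),
    "logistic": (_logistic, lambda z: _logistic(z) * (1.0 - _logistic(z))),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "exponential": (_exponential, _exponential),
    "sine": (np.sin, np.cos),
}

DEFAULT_SPLIT = (0.70, 0.15, 0.15)
TARGET_RANGE = (0.2, 0.8)  # internal min-max window for bounded outputs


def split_dataset(n_or_items, seed: int,
                  fractions: tuple[float, float, float] = DEFAULT_SPLIT):
    """Deterministic 70/15/15 train/test/validation split.

    Accepts a record count or a sequence; returns index arrays (for a count)
    or sub-lists. Sizes are round(0.70 n), round(0.15 n) and the remainder,
    so 160 records split 112/24/24.
    """
    items = None
    if isinstance(n_or_items, (int, np.integer)):
        n = int(n_or_items)
    else:
        items = list(n_or_items)
        n = len(items)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    rng = np.random.RandomState(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    train, test, val = (np.sort(perm[:n_train]), np.sort(perm[n_train:n_train + n_test]),
                        np.sort(perm[n_train + n_test:]))
    if items is None:
        return train, test, val
    return ([items[i] for i in train], [items[i] for i in test], [items[i] for i in val])


@dataclass
class NetworkModel:
    """A fitted single-hidden-layer perceptron with its acceptance metadata."""

    hidden_units: int
    activations: tuple[str, str]  # (hidden, output)
    seed: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    target_lo: float   # log10-x value mapped to TARGET_RANGE[0]
    target_hi: float
    rmsd: float = np.nan
    n_outliers: int = -1
    accepted: bool = False

    def _forward(self, x: np.ndarray) -> np.ndarray:
        f_h = ACTIVATIONS[self.activations[0]][0]
        f_o = ACTIVATIONS[self.activations[1]][0]
        h = f_h(x @ self.w1 + self.b1)
        return f_o(h @ self.w2 + self.b2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted log10 mole fraction for standardized features."""
        s = self._forward(np.asarray(x, dtype=float))
        lo, hi = TARGET_RANGE
        span = (self.target_hi - self.target_lo) or 1.0
        return self.target_lo + (s - lo) * span / (hi - lo)


@dataclass
class EnsemblePrediction:
    """Range-filtered ensemble mean for one query."""

    mean_log10x: float
    n_used: int
    n_discarded: int
    per_network: np.ndarray
    valid: bool = True


@dataclass
class Ensemble:
    """Accepted networks sorted by RMSD ascending, with the shared scaler."""

    networks: list[NetworkModel]
    scaler: StandardScaler
    split_spec: tuple[float, float, float] = DEFAULT_SPLIT

    def __len__(self) -> int:
        return len(self.networks)


def _scale_targets(y: np.ndarray, lo_hi: tuple[float, float]) -> np.ndarray:
    lo, hi = TARGET_RANGE
    span = (lo_hi[1] - lo_hi[0]) or 1.0
    return lo + (y - lo_hi[0]) * (hi - lo) / span


# output-layer bias start mapping the net output to mid-range (0.5)
_B2_INIT = {"identity": 0.5, "logistic": 0.0, "tanh": float(np.arctanh(0.5)),
            "exponential": float(np.log(0.5)), "sine": float(np.arcsin(0.5))}


def _init_weights(rng: np.random.RandomState, n_in: int, n_hidden: int,
                  output_activation: str):
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
    b2 = _B2_INIT[output_activation]
    return w1, b1, w2, b2


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, n_in, n_hidden):
    i = n_in * n_hidden
    w1 = theta[:i].reshape(n_in, n_hidden)
    b1 = theta[i:i + n_hidden]
    w2 = theta[i + n_hidden:i + 2 * n_hidden]
    b2 = theta[-1]
    return w1, b1, w2, b2


def train_network(features: np.ndarray, targets: np.ndarray,
                  hidden_units: int, activations: tuple[str, str], seed: int,
                  test_idx: Optional[np.ndarray] = None,
                  train_idx: Optional[np.ndarray] = None,
                  max_iter: int = 400) -> NetworkModel:
    """Fit one perceptron by L-BFGS on the sum-of-squares error.

    ``features`` must already be standardized. Training uses ``train_idx``
    rows; the test rows steer early stopping (the parameters with the lowest
    test error seen along the optimization path are kept). Deterministic for
    a fixed seed.
    """
    if not (6 <= hidden_units <= 64):
        raise ValueError(f"hidden_units out of range: {hidden_units}")
    for a in activations:
        if a not in ACTIVATIONS:
            raise ValueError(f"unknown activation {a!r}")
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n, n_in = x.shape
    if train_idx is None:
        train_idx = np.arange(n)
    x_tr, y_tr = x[train_idx], y[train_idx]
    lo_hi = (float(y_tr.min()), float(y_tr.max()))
    s_all = _scale_targets(y, lo_hi)
    s_tr = s_all[train_idx]

    f_h, df_h = ACTIVATIONS[activations[0]]
    f_o, df_o = ACTIVATIONS[activations[1]]

    def loss_grad(theta, xs, ss):
        w1, b1, w2, b2 = _unpack(theta, n_in, hidden_units)
        z1 = xs @ w1 + b1
        h = f_h(z1)
        z2 = h @ w2 + b2
        out = f_o(z2)
        r = out - ss
        loss = 0.5 * float(r @ r)
        d2 = r * df_o(z2)
        gw2 = h.T @ d2
        gb2 = d2.sum()
        dh = np.outer(d2, w2) * df_h(z1)
        gw1 = xs.T @ dh
        gb1 = dh.sum(axis=0)
        return loss, _pack(gw1, gb1, gw2, gb2)

    rng = np.random.RandomState(seed)
    theta0 = _pack(*_init_weights(rng, n_in, hidden_units, activations[1]))

    best = {"theta": theta0.copy(), "err": np.inf}
    if test_idx is not None and len(test_idx) > 0:
        x_te, s_te = x[test_idx], s_all[test_idx]

        def on_step(theta):
            w1, b1, w2, b2 = _unpack(theta, n_in, hidden_units)
            h = f_h(x_te @ w1 + b1)
            r = f_o(h @ w2 + b2) - s_te
            err = float(r @ r)
            if err < best["err"]:
                best["err"] = err
                best["theta"] = theta.copy()
    else:
        on_step = None

    try:
        res = minimize(loss_grad, theta0, args=(x_tr, s_tr), jac=True,
                       method="L-BFGS-B", callback=on_step,
                       options={"maxiter": max_iter})
        theta = best["theta"] if np.isfinite(best["err"]) else res.x
        diverged = not np.all(np.isfinite(theta))
    except (FloatingPointError, OverflowError):
        theta, diverged = theta0, True
    if diverged:
        theta = theta0
    w1, b1, w2, b2 = _unpack(theta, n_in, hidden_units)
    model = NetworkModel(hidden_units=hidden_units, activations=tuple(activations),
                         seed=seed, w1=w1, b1=b1, w2=w2, b2=float(b2),
                         target_lo=lo_hi[0], target_hi=lo_hi[1])
    if diverged:
        model.rmsd = np.inf
        model.n_outliers = len(y)
        model.accepted = False
    return model


def evaluate_network(model: NetworkModel, features: np.ndarray,
                     targets: np.ndarray) -> tuple[float, int]:
    """Whole-set RMSD (log10-x scale) and outlier count.

    An outlier is a record whose standardized residual exceeds 3 in absolute
    value (residual divided by the residual standard deviation).
    """
    pred = model.predict(features)
    res = pred - np.asarray(targets, dtype=float)
    rmsd = float(np.sqrt(np.mean(res ** 2)))
    sd = float(res.std())
    n_out = 0 if sd == 0 else int(np.sum(np.abs(res / sd) > 3.0))
    return rmsd, n_out


def _is_accepted(rmsd: float, n_outliers: int, rmsd_max: float,
                 max_outliers: int) -> bool:
    return (rmsd < rmsd_max) and (n_outliers <= max_outliers)


class SannEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Ensemble of accepted single-hidden-layer networks, scikit-learn style.

    Parameters
    ----------
    n_networks : target number of accepted networks (default 40; predictions
        of at least ~30 networks are generally needed for a stable mean).
    rmsd_max, max_outliers : acceptance criteria on the whole-dataset RMSD
        (log10-x scale, default 0.04) and outlier count (default 4).
    hidden_range : inclusive bounds for the hidden-layer width, default (6, 12).
    hidden_activations, output_activations : candidate transfer functions.
    max_attempts : cap on trained candidates before giving up.
    split : train/test/validation fractions, default (0.70, 0.15, 0.15).
    eval_on : 'all' evaluates acceptance over every record (default),
        'validation' over the validation subset only.
    random_state : seed controlling the split and all candidate draws.

    Attributes (after fit)
    ----------------------
    networks_ : accepted :class:`NetworkModel`s sorted by RMSD ascending.
    scaler_ : per-feature standardization fitted on the training subset.
    split_indices_ : (train, test, validation) index arrays.
    n_attempts_, n_rejected_rmsd_, n_rejected_outliers_ : training log.
    """

    def __init__(self, n_networks: int = 40, rmsd_max: float = 0.04,
                 max_outliers: int = 4, hidden_range: tuple[int, int] = (6, 12),
                 hidden_activations: Sequence[str] = ("identity", "logistic", "tanh",
                                                      "exponential", "sine"),
                 output_activations: Sequence[str] = ("identity", "logistic", "tanh",
                                                      "exponential", "sine"),
                 max_attempts: int = 2000,
                 split: tuple[float, float, float] = DEFAULT_SPLIT,
                 eval_on: str = "all",
                 max_lbfgs_iter: int = 400,
                 random_state: Optional[int] = None):
        self.n_networks = n_networks
        self.rmsd_max = rmsd_max
        self.max_outliers = max_outliers
        self.hidden_range = hidden_range
        self.hidden_activations = hidden_activations
        self.output_activations = output_activations
        self.max_attempts = max_attempts
        self.split = split
        self.eval_on = eval_on
        self.max_lbfgs_iter = max_lbfgs_iter
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.rmsd_max <= 0:
            raise ValueError("rmsd_max must be positive")
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.RandomState(seed)
        train_idx, test_idx, val_idx = split_dataset(X.shape[0], seed, self.split)
        self.split_indices_ = (train_idx, test_idx, val_idx)
        self.scaler_ = StandardScaler().fit(X[train_idx])
        xs = self.scaler_.transform(X)
        if self.eval_on == "all":
            eval_idx = np.arange(X.shape[0])
        elif self.eval_on == "validation":
            eval_idx = val_idx
        else:
            raise ValueError(f"eval_on must be 'all' or 'validation', got {self.eval_on!r}")

        accepted: list[NetworkModel] = []
        attempts = rej_rmsd = rej_out = 0
        log: list[dict] = []
        while len(accepted) < self.n_networks and attempts < self.max_attempts:
            attempts += 1
            hidden = int(rng.randint(self.hidden_range[0], self.hidden_range[1] + 1))
            acts = (str(rng.choice(list(self.hidden_activations))),
                    str(rng.choice(list(self.output_activations))))
            net_seed = int(rng.randint(0, 2 ** 31 - 1))
            model = train_network(xs, y, hidden, acts, net_seed,
                                  test_idx=test_idx, train_idx=train_idx,
                                  max_iter=self.max_lbfgs_iter)
            if not np.isfinite(model.rmsd) and model.n_outliers >= 0:
                rej_rmsd += 1  # diverged candidate
                continue
            model.rmsd, model.n_outliers = evaluate_network(model, xs[eval_idx], y[eval_idx])
            model.accepted = _is_accepted(model.rmsd, model.n_outliers,
                                          self.rmsd_max, self.max_outliers)
            log.append({"attempt": attempts, "hidden": hidden, "activations": acts,
                        "seed": net_seed, "rmsd": model.rmsd,
                        "n_outliers": model.n_outliers, "accepted": model.accepted})
            if model.accepted:
                accepted.append(model)
            elif model.rmsd >= self.rmsd_max:
                rej_rmsd += 1
            else:
                rej_out += 1
        if not accepted:
            raise RuntimeError(
                f"no network met the acceptance criteria (rmsd < {self.rmsd_max}, "
                f"outliers <= {self.max_outliers}) in {attempts} attempts; "
                f"attempt log: {log[-10:]}")
        accepted.sort(key=lambda m: m.rmsd)
        self.networks_ = accepted
        self.n_attempts_ = attempts
        self.n_rejected_rmsd_ = rej_rmsd
        self.n_rejected_outliers_ = rej_out
        self.attempt_log_ = log
        return self

    # -- prediction -------------------------------------------------------

    def _per_network(self, X) -> np.ndarray:
        check_is_fitted(self, "networks_")
        X = check_array(X)
        xs = self.scaler_.transform(X)
        return np.column_stack([net.predict(xs) for net in self.networks_])

    def predict_detailed(self, X, n_networks: Optional[int] = None
                         ) -> list[EnsemblePrediction]:
        """Per-query range-filtered means with discard bookkeeping.

        Predictions implying a mole fraction outside (0, 1) — log10 x > 0 —
        or non-finite values are discarded before averaging. A query whose
        predictions are all discarded is returned with ``valid=False``
        instead of propagating NaN silently.
        """
        per = self._per_network(X)
        if n_networks is not None:
            per = per[:, :n_networks]
        out = []
        for row in per:
            keep = np.isfinite(row) & (row <= 0.0)
            n_used = int(keep.sum())
            if n_used == 0:
                out.append(EnsemblePrediction(np.nan, 0, row.size, row, valid=False))
            else:
                out.append(EnsemblePrediction(float(row[keep].mean()), n_used,
                                              int(row.size - n_used), row))
        return out

    def predict(self, X) -> np.ndarray:
        """Filtered ensemble mean log10 mole fraction (NaN where no network
        yielded a physical value; see :meth:`predict_detailed`)."""
        return np.array([p.mean_log10x for p in self.predict_detailed(X)])

    def convergence_curve(self, x_row) -> list[tuple[int, float]]:
        """Filtered cumulative mean over the k best (lowest-RMSD) networks,
        for k = 1 .. ensemble size."""
        x_row = np.atleast_2d(np.asarray(x_row, dtype=float))
        per = self._per_network(x_row)[0]
        curve = []
        for k in range(1, per.size + 1):
            head = per[:k]
            keep = np.isfinite(head) & (head <= 0.0)
            curve.append((k, float(head[keep].mean()) if keep.any() else np.nan))
        return curve

    # -- persistence ------------------------------------------------------

    def to_bundle(self) -> dict:
        check_is_fitted(self, "networks_")
        return {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "scaler": {"mean": self.scaler_.mean_.tolist(),
                       "scale": self.scaler_.scale_.tolist()},
            "n_features_in": self.n_features_in_,
            "networks": [{
                "hidden_units": m.hidden_units, "activations": list(m.activations),
                "seed": m.seed, "w1": m.w1.tolist(), "b1": m.b1.tolist(),
                "w2": m.w2.tolist(), "b2": m.b2,
                "target_lo": m.target_lo, "target_hi": m.target_hi,
                "rmsd": m.rmsd, "n_outliers": m.n_outliers, "accepted": m.accepted,
            } for m in self.networks_],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_bundle()))

    @classmethod
    def from_bundle(cls, bundle: dict) -> "SannEnsembleRegressor":
        params = dict(bundle["params"])
        for key in ("hidden_range", "split"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        est = cls(**params)
        est.n_features_in_ = bundle["n_features_in"]
        scaler = StandardScaler()
        scaler.mean_ = np.array(bundle["scaler"]["mean"])
        scaler.scale_ = np.array(bundle["scaler"]["scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = est.n_features_in_
        est.scaler_ = scaler
        est.networks_ = [NetworkModel(
            hidden_units=m["hidden_units"], activations=tuple(m["activations"]),
            seed=m["seed"], w1=np.array(m["w1"]), b1=np.array(m["b1"]),
            w2=np.array(m["w2"]), b2=m["b2"], target_lo=m["target_lo"],
            target_hi=m["target_hi"], rmsd=m["rmsd"],
            n_outliers=m["n_outliers"], accepted=m["accepted"],
        ) for m in bundle["networks"]]
        return est

    @classmethod
    def load(cls, path: str | Path) -> "SannEnsembleRegressor":
        return cls.from_bundle(json.loads(Path(path).read_text()))


# -- thin functional wrappers ------------------------------------------------

def build_ensemble(features, targets, n_target_networks: int = 40,
                   max_attempts: int = 2000, seed: int = 0,
                   **kwargs) -> SannEnsembleRegressor:
    """Train candidates until ``n_target_networks`` pass the acceptance
    criteria (or ``max_attempts`` is exhausted); returns the fitted estimator."""
    est = SannEnsembleRegressor(n_networks=n_target_networks,
                                max_attempts=max_attempts,
                                random_state=seed, **kwargs)
    return est.fit(features, targets)


def predict(ensemble: SannEnsembleRegressor, descriptor) -> EnsemblePrediction:
    """Range-filtered ensemble prediction for one descriptor vector."""
    arr = descriptor.as_array() if hasattr(descriptor, "as_array") else np.asarray(descriptor)
    return ensemble.predict_detailed(np.atleast_2d(arr))[0]


def convergence_curve(ensemble: SannEnsembleRegressor, descriptor) -> list[tuple[int, float]]:
    arr = descriptor.as_array() if hasattr(descriptor, "as_array") else np.asarray(descriptor)
    return ensemble.convergence_curve(arr)
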
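"""Single-hidden-layer perceptron surrogate for the extraction responses.

The surrogate maps the 14 encoded process inputs to the three responses
(TPC, TC, AA).  Inputs and responses are min-max scaled to [0, 1] on the
training table; training minimizes the summed squared error on the scaled
responses with BFGS from a random initialization, and a topology search runs
multiple restarts over hidden-layer sizes and activation pairs, selecting the
candidate with the highest mean training r^2 across the three outputs.

With identity activations on both layers the network family is exactly the
family of affine maps, so on a full-row-rank table the best achievable loss
equals the ordinary-least-squares loss — a useful cross-check, since the
reference configuration for this system is the identity/identity network with
7 hidden neurons (129 parameters for a 14-7-3 topology).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .factor_space import FactorSpace, ScalingParams

__all__ = [
    "SurrogateModel",
    "ACTIVATIONS",
    "param_count",
    "train",
    "search",
    "r_squared",
]

# activation -> (f, f') with f' expressed via pre-activation z and value a=f(z)
_EXP_CLIP = 50.0


def _identity(z):
    return z


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLIP, _EXP_CLIP)))


def _tanh(z):
    return np.tanh(z)


def _exponential(z):
    return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))


ACTIVATIONS = ("identity", "logistic", "tanh", "exponential")
_FUNCS = {
    "identity": _identity,
    "logistic": _logistic,
    "tanh": _tanh,
    "exponential": _exponential,
}


def _act(name, z):
    try:
        a = _FUNCS[name](z)
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {ACTIVATIONS}")
    if name == "identity":
        da = np.ones_like(z)
    elif name == "logistic":
        da = a * (1.0 - a)
    elif name == "tanh":
        da = 1.0 - a * a
    else:  # exponential
        da = a
    return a, da


def param_count(n_in: int, n_hidden: int, n_out: int) -> int:
    """Trainable parameters of an (n_in, n_hidden, n_out) MLP with biases."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all layer sizes must be >= 1")
    return n_in * n_hidden + n_hidden + n_hidden * n_out + n_out


def _unpack(theta, n_in, n_hidden, n_out):
    i = 0
    W = theta[i:i + n_in * n_hidden].reshape(n_in, n_hidden); i += n_in * n_hidden
    b1 = theta[i:i + n_hidden]; i += n_hidden
    V = theta[i:i + n_hidden * n_out].reshape(n_hidden, n_out); i += n_hidden * n_out
    b2 = theta[i:i + n_out]
    return W, b1, V, b2


def _loss_grad(theta, Xs, Ys, n_hidden, acts):
    n, n_in = Xs.shape
    n_out = Ys.shape[1]
    W, b1, V, b2 = _unpack(theta, n_in, n_hidden, n_out)
    Z1 = Xs @ W + b1
    H, dH = _act(acts[0], Z1)
    Z2 = H @ V + b2
    P, dP = _act(acts[1], Z2)
    E = P - Ys
    loss = float(np.sum(E * E))
    G2 = 2.0 * E * dP                      # dL/dZ2
    gV = H.T @ G2
    gb2 = G2.sum(axis=0)
    G1 = (G2 @ V.T) * dH                   # dL/dZ1
    gW = Xs.T @ G1
    gb1 = G1.sum(axis=0)
    grad = np.concatenate([gW.ravel(), gb1, gV.ravel(), gb2])
    return loss, grad


@dataclass
class SurrogateModel:
    """A trained MLP surrogate with its scaling and fit statistics.

    Weights act on the min-max-scaled inputs and produce min-max-scaled
    responses; :meth:`forward` applies both scalings so callers work entirely
    in original units.
    """

    n_in: int
    n_hidden: int
    n_out: int
    activations: tuple           # (hidden, output)
    W: np.ndarray                # (n_in, n_hidden)
    b1: np.ndarray               # (n_hidden,)
    V: np.ndarray                # (n_hidden, n_out)
    b2: np.ndarray               # (n_out,)
    x_scaling: ScalingParams
    y_scaling: ScalingParams
    space: FactorSpace | None = None
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr, shape in (
            ("W", self.W, (self.n_in, self.n_hidden)),
            ("b1", self.b1, (self.n_hidden,)),
            ("V", self.V, (self.n_hidden, self.n_out)),
            ("b2", self.b2, (self.n_out,)),
        ):
            if np.asarray(arr).shape != shape:
                raise ValueError(f"{name} has shape {np.asarray(arr).shape}, "
                                 f"expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def topology(self) -> tuple:
        return (self.n_in, self.n_hidden, self.n_out)

    @property
    def n_params(self) -> int:
        return param_count(self.n_in, self.n_hidden, self.n_out)

    def forward(self, inputs: np.ndarray) -> np.ndarray:
        """Predict responses in original units from encoded inputs.

        Accepts a single input vector or a (runs x n_in) matrix.
        """
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
        if X.shape[1] != self.n_in:
            raise ValueError(
                f"expected {self.n_in} inputs per run, got {X.shape[1]}"
            )
        Xs = self.x_scaling.apply(X)
        H, _ = _act(self.activations[0], Xs @ self.W + self.b1)
        P, _ = _act(self.activations[1], H @ self.V + self.b2)
        out = self.y_scaling.invert(P)
        return out[0] if np.ndim(inputs) == 1 else out

    def predict_settings(self, settings) -> np.ndarray:
        """Predict from a raw settings mapping (requires an attached space)."""
        if self.space is None:
            raise ValueError("model has no attached factor space")
        return self.forward(self.space.encode(settings))

    def affine_equivalent(self) -> tuple:
        """For identity/identity networks: the equivalent (B, c) of x -> xB + c
        on the scaled scale."""
        if self.activations != ("identity", "identity"):
            raise ValueError("affine equivalent defined only for identity nets")
        return self.W @ self.V, self.b1 @ self.V + self.b2

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "topology": list(self.topology),
            "activations": list(self.activations),
            "W": self.W.ravel().tolist(),
            "b1": self.b1.tolist(),
            "V": self.V.ravel().tolist(),
            "b2": self.b2.tolist(),
            "x_scaling": self.x_scaling.to_dict(),
            "y_scaling": self.y_scaling.to_dict(),
            "space": None if self.space is None else self.space.to_dict(),
            "fit_stats": self.fit_stats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateModel":
        n_in, n_hidden, n_out = d["topology"]
        return cls(
            n_in=n_in, n_hidden=n_hidden, n_out=n_out,
            activations=tuple(d["activations"]),
            W=np.asarray(d["W"], dtype=float).reshape(n_in, n_hidden),
            b1=np.asarray(d["b1"], dtype=float),
            V=np.asarray(d["V"], dtype=float).reshape(n_hidden, n_out),
            b2=np.asarray(d["b2"], dtype=float),
            x_scaling=ScalingParams.from_dict(d["x_scaling"]),
            y_scaling=ScalingParams.from_dict(d["y_scaling"]),
            space=None if d.get("space") is None
            else FactorSpace.from_dict(d["space"]),
            fit_stats=d.get("fit_stats", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _prepare(table):
    X = table.encoded_inputs()
    Y = table.response_matrix()
    xs = ScalingParams.fit(X, columns=table.space.feature_names)
    ys = ScalingParams.fit(Y, columns=table.space.response_names)
    return X, Y, xs, ys


def train(table, n_hidden: int, activations=("identity", "identity"),
          seed: int | np.random.SeedSequence = 0, max_iter: int = 500,
          tol: float = 1e-8) -> SurrogateModel:
    """Train one MLP from one random initialization with BFGS.

    Weights and biases start uniform(-0.5, 0.5) from a seeded generator; the
    objective is the summed squared error over all outputs on the scaled
    responses.  An optimizer failure (non-finite loss) is retried once with a
    derived sub-seed before being surfaced.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    activations = tuple(activations)
    X, Y, xs, ys = _prepare(table)
    Xs, Ys = xs.apply(X), ys.apply(Y)
    n_in, n_out = Xs.shape[1], Ys.shape[1]
    nparams = param_count(n_in, n_hidden, n_out)

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    last_err = None
    for attempt, init_seed in enumerate([ss, ss.spawn(1)[0]]):
        rng = np.random.default_rng(init_seed)
        theta0 = rng.uniform(-0.5, 0.5, size=nparams)
        res = minimize(
            _loss_grad, theta0, args=(Xs, Ys, n_hidden, activations),
            jac=True, method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
        )
        if np.isfinite(res.fun) and np.all(np.isfinite(res.x)):
            W, b1, V, b2 = _unpack(res.x, n_in, n_hidden, n_out)
            model = SurrogateModel(
                n_in=n_in, n_hidden=n_hidden, n_out=n_out,
                activations=activations, W=W, b1=b1, V=V, b2=b2,
                x_scaling=xs, y_scaling=ys, space=table.space,
                fit_stats={
                    "loss": float(res.fun),
                    "n_iter": int(res.nit),
                    "converged": bool(res.success),
                    "attempt": attempt,
                },
            )
            r2 = r_squared(model, table)
            model.fit_stats["r2"] = [None if np.isnan(v) else float(v) for v in r2]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-NaN mean on degenerate tables
                model.fit_stats["mean_r2"] = float(np.nanmean(r2))
            return model
        last_err = res.message
    raise RuntimeError(f"training failed after retry: {last_err}")


def r_squared(model: SurrogateModel, table) -> np.ndarray:
    """Per-output r^2 = 1 - SSres/SStot on original units.

    A zero-variance response column has no defined r^2 and is reported as NaN
    with a warning.
    """
    Y = table.response_matrix()
    P = model.forward(table.encoded_inputs())
    ss_res = np.sum((Y - P) ** 2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    out = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        if ss_tot[j] == 0:
            warnings.warn(
                f"response column {table.space.response_names[j]!r} has zero "
                "variance; r^2 undefined", stacklevel=2,
            )
            out[j] = np.nan
        else:
            out[j] = 1.0 - ss_res[j] / ss_tot[j]
    return out


_ALL_PAIRS = tuple((h, o) for h in ACTIVATIONS for o in ACTIVATIONS)


def search(table, hidden_sizes=range(5, 21), activation_options=None,
           n_restarts: int = 2, seed: int = 0, max_iter: int = 500,
           tol: float = 1e-8, validation_table=None, keep_models: bool = False):
    """Multi-restart topology search over hidden sizes and activation pairs.

    Trains ``n_restarts`` networks per (hidden size, activation pair)
    configuration, each from an independent seeded initialization, and selects
    the candidate with the highest mean training r^2 over the three outputs;
    ties break toward fewer hidden neurons, then lower loss, then lower restart
    index.  Sub-seeds are a pure function of (seed, hidden size, activation
    pair, restart index), so enlarging ``n_restarts`` only extends the
    candidate set.

    When ``validation_table`` is given, candidates are ranked by mean r^2 on
    that table instead of the training table — appropriate whenever held-out
    runs exist, since with more parameters than runs the training r^2 of every
    large candidate saturates at 1 and cannot discriminate.

    Returns ``(best_model, log)`` where ``log`` is a list of per-candidate
    stat dicts.  With 12 screening runs and >= 5 hidden neurons the parameter
    count far exceeds the run count, so a training r^2 of 1.000 indicates
    interpolation of the training table, not generalization; the log entry
    ``interpolation_warning`` flags this.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if activation_options is None:
        activation_options = _ALL_PAIRS
    hidden_sizes = list(hidden_sizes)
    log, best, best_key = [], None, None
    n_runs = table.n_runs
    for h_idx, h in enumerate(hidden_sizes):
        for a_idx, acts in enumerate(activation_options):
            for r in range(n_restarts):
                ss = np.random.SeedSequence([int(seed), int(h), a_idx, r])
                entry = {
                    "n_hidden": h, "activations": tuple(acts), "restart": r,
                }
                try:
                    model = train(table, h, acts, seed=ss,
                                  max_iter=max_iter, tol=tol)
                except (RuntimeError, FloatingPointError) as exc:
                    entry.update(failed=True, error=str(exc))
                    log.append(entry)
                    continue
                mean_r2 = model.fit_stats["mean_r2"]
                entry.update(
                    failed=False,
                    loss=model.fit_stats["loss"],
                    r2=model.fit_stats["r2"],
                    mean_r2=mean_r2,
                    n_params=model.n_params,
                    interpolation_warning=model.n_params >= n_runs,
                )
                score = mean_r2
                if validation_table is not None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        score = float(
                            np.nanmean(r_squared(model, validation_table))
                        )
                    entry["validation_mean_r2"] = score
                entry["score"] = score
                if keep_models:
                    entry["model"] = model
                log.append(entry)
                if not np.isfinite(score):
                    continue
                key = (-score, h, model.fit_stats["loss"], r)
                if best_key is None or key < best_key:
                    best, best_key = model, key
    if best is None:
        raise RuntimeError("all training restarts failed")
    return best, log
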
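"""TSK linguistic model (TSK-LM) with interval prediction, and the
conventional linguistic-model baseline.

Each of the ``p`` linguistic contexts contributes one fuzzy rule.  The
rule consequent combines the context's triangular fuzzy number
``(r_t^-, r_t, r_t^+)`` with an affine function of the inputs:

    f_t = [r_t^- , r_t , r_t^+] + beta_t . x + delta_t

where ``beta_t`` (one coefficient per input) and the location offset
``delta_t`` are fitted jointly by least squares, followed by a global bias
``b0`` equal to the mean training residual of the modal output.  The rule
activations ``z_t`` are fuzzy c-means memberships of the input computed
over the pooled (context, cluster) centers and part-summed per context, so
``z_t >= 0`` and ``sum_t z_t = 1``.  The model output is a triangular fuzzy
number: modal value

    f* = sum_t z_t (r_t + delta_t + beta_t . x) + b0

with lower/upper bounds obtained by substituting ``r_t^-`` / ``r_t^+`` for
``r_t``.  Because the bounds are convex combinations of ordered break
points, ``f^- <= f* <= f^+`` always holds.

The *conventional LM* baseline keeps only the context fuzzy numbers
(``beta = 0``, ``delta = 0``, ``b0 = 0``); its modal output is
``sum_t z_t r_t``.  The TSK variant strictly generalises it, so its
training error can never be worse for the same granulation.

All fitting happens in min–max normalised [0, 1] space; predictions are
denormalised back to original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

from .granulation import (
    ContextSet,
    _fcm_memberships,
    cfcm_cluster,
    make_flexible_contexts,
    make_uniform_contexts,
)

__all__ = [
    "TSKLMModel",
    "IntervalPrediction",
    "activations",
    "fit_consequents",
    "compute_bias",
    "train",
]

VARIANTS = ("tsk_lm", "conventional_lm")


@dataclass
class IntervalPrediction:
    """Triangular-fuzzy-number output: support endpoints and modal value."""

    lower: float
    modal: float
    upper: float
    activations: np.ndarray


@dataclass
class TSKLMModel:
    context_set: ContextSet
    centers: tuple[np.ndarray, ...]   # per context, shape (c, d)
    fuzzifier: float
    linear_coeffs: np.ndarray         # (p, d)
    intercepts: np.ndarray            # (p,) fitted offsets on the break points
    bias: float
    x_min: np.ndarray                 # (d,)
    x_max: np.ndarray                 # (d,)
    y_min: float
    y_max: float
    variant: str = "tsk_lm"

    # -- basic shape accessors -------------------------------------------
    @property
    def p(self) -> int:
        return self.context_set.p

    @property
    def c(self) -> int:
        return self.centers[0].shape[0]

    @property
    def d(self) -> int:
        return self.centers[0].shape[1]

    # -- normalisation ----------------------------------------------------
    def _normalize_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / (self.x_max - self.x_min)

    def _denormalize_y(self, y):
        return self.y_min + np.asarray(y) * (self.y_max - self.y_min)

    # -- inference --------------------------------------------------------
    def _activations_normalized(self, Xn: np.ndarray) -> np.ndarray:
        """Rule activations for normalised inputs, shape (n, p)."""
        pooled = np.vstack(self.centers)                      # (p*c, d)
        sq = ((Xn[None, :, :] - pooled[:, None, :]) ** 2).sum(axis=2)  # (p*c, n)
        U = _fcm_memberships(sq, np.ones(Xn.shape[0]), self.fuzzifier)
        Z = U.reshape(self.p, self.c, -1).sum(axis=1)          # (p, n)
        return Z.T

    def activations(self, x) -> np.ndarray:
        """Activation vector ``z`` for one input point in original units."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._activations_normalized(self._normalize_x(x))[0]

    def _interval_normalized(self, Xn: np.ndarray):
        Z = self._activations_normalized(Xn)                   # (n, p)
        lin = Xn @ self.linear_coeffs.T + self.intercepts      # (n, p)
        out = []
        for bp in (
            self.context_set.lowers(),
            self.context_set.modes(),
            self.context_set.uppers(),
        ):
            out.append((Z * (bp + lin)).sum(axis=1) + self.bias)
        return out[0], out[1], out[2], Z

    def predict_batch(self, X):
        """Interval predictions for ``X`` (n, d), in original output units.

        Returns ``(lower, modal, upper)`` arrays of length n.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} input columns, got {X.shape[1]}")
        lo, mo, hi = self._interval_normalized(self._normalize_x(X))[:3]
        return self._denormalize_y(lo), self._denormalize_y(mo), self._denormalize_y(hi)

    def predict(self, x) -> IntervalPrediction:
        """Interval prediction for a single input point."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo, mo, hi, Z = self._interval_normalized(self._normalize_x(x))
        return IntervalPrediction(
            lower=float(self._denormalize_y(lo[0])),
            modal=float(self._denormalize_y(mo[0])),
            upper=float(self._denormalize_y(hi[0])),
            activations=Z[0],
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "scheme": self.context_set.scheme,
            "p": self.p,
            "c": self.c,
            "m": self.fuzzifier,
            "context_set": self.context_set.to_dict(),
            "centers": [V.tolist() for V in self.centers],
            "coefficients": self.linear_coeffs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "bias": self.bias,
            "normalization": {
                "x_min": self.x_min.tolist(),
                "x_max": self.x_max.tolist(),
                "y_min": self.y_min,
                "y_max": self.y_max,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSKLMModel":
        norm = d["normalization"]
        return cls(
            context_set=ContextSet.from_dict(d["context_set"]),
            centers=tuple(np.array(V, dtype=float) for V in d["centers"]),
            fuzzifier=float(d["m"]),
            linear_coeffs=np.array(d["coefficients"], dtype=float),
            intercepts=np.array(d["intercepts"], dtype=float),
            bias=float(d["bias"]),
            x_min=np.array(norm["x_min"], dtype=float),
            x_max=np.array(norm["x_max"], dtype=float),
            y_min=float(norm["y_min"]),
            y_max=float(norm["y_max"]),
            variant=d["variant"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TSKLMModel":
        return cls.from_dict(json.loads(s))


def activations(x, model: TSKLMModel) -> np.ndarray:
    """Rule-activation vector of ``x`` under ``model`` (sums to 1)."""
    return model.activations(x)


def fit_consequents(
    Z: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    context_set: ContextSet,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of the TSK consequent parameters.

    Solves ``min || (y - Z r) - Phi theta ||^2`` where ``r`` holds the
    context apexes and ``Phi`` has one column ``z_t * x_j`` per
    (context, input) pair plus one column ``z_t`` per context (the break
    point location offsets).  Uses a rank-revealing least-squares solve
    (minimum-norm solution on rank deficiency, so inactive contexts get
    exactly zero coefficients); a ridge solve with penalty ``ridge`` is the
    fallback if the SVD fails to converge.

    Returns ``(coeffs, intercepts)`` with shapes ``(p, d)`` and ``(p,)``.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one training row")
    n, p = Z.shape
    d = X.shape[1]
    target = y - Z @ context_set.modes()
    # columns: [z_1 x_1, ..., z_1 x_d, z_2 x_1, ..., z_p x_d, z_1, ..., z_p]
    Phi = np.concatenate(
        [(Z[:, :, None] * X[:, None, :]).reshape(n, p * d), Z], axis=1
    )
    try:
        theta, _, _, _ = np.linalg.lstsq(Phi, target, rcond=None)
    except np.linalg.LinAlgError:
        G = Phi.T @ Phi + ridge * np.eye(Phi.shape[1])
        theta = np.linalg.solve(G, Phi.T @ target)
    return theta[: p * d].reshape(p, d), theta[p * d :]


def compute_bias(y, modal_preds) -> float:
    """Mean training residual of the modal output (the global bias term)."""
    y = np.asarray(y, dtype=float).ravel()
    pred = np.asarray(modal_preds, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("cannot compute bias from empty input")
    if y.size != pred.size:
        raise ValueError("targets and predictions differ in length")
    return float(np.mean(y - pred))


def train(
    X,
    y,
    p: int,
    c: int,
    scheme: str = "flexible",
    variant: str = "tsk_lm",
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed=None,
) -> TSKLMModel:
    """Train a TSK-LM (or conventional-LM baseline) end to end.

    Pipeline: min–max normalise inputs and output (training statistics
    only) -> build ``p`` linguistic contexts on the output -> CFCM with
    ``c`` clusters inside each context -> rule activations on the training
    inputs -> global least squares for the linear consequents (TSK variant
    only) -> bias from the mean training residual.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if scheme not in ("uniform", "flexible"):
        raise ValueError("scheme must be 'uniform' or 'flexible'")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    # normalisation (training statistics only)
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    if np.any(x_max == x_min):
        j = int(np.argmax(x_max == x_min))
        raise ValueError(f"normalization: input column {j} is constant")
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        raise ValueError("normalization: degenerate output range")
    Xn = (X - x_min) / (x_max - x_min)
    yn = (y - y_min) / (y_max - y_min)

    # granulation
    maker = make_uniform_contexts if scheme == "uniform" else make_flexible_contexts
    try:
        ctx_set = maker(yn, p)
    except ValueError as e:
        raise ValueError(f"context construction: {e}") from e
    seeds = np.random.SeedSequence(seed).spawn(ctx_set.p)
    centers = []
    for t, ctx in enumerate(ctx_set.contexts):
        w = ctx.membership(yn)
        try:
            res = cfcm_cluster(
                Xn, w, c, m=m, tol=tol, max_iter=max_iter,
                seed=seeds[t], context_index=t,
            )
        except ValueError as e:
            raise ValueError(f"clustering: {e}") from e
        centers.append(res.centers)

    model = TSKLMModel(
        context_set=ctx_set,
        centers=tuple(centers),
        fuzzifier=m,
        linear_coeffs=np.zeros((ctx_set.p, X.shape[1])),
        intercepts=np.zeros(ctx_set.p),
        bias=0.0,
        x_min=np.asarray(x_min, dtype=float),
        x_max=np.asarray(x_max, dtype=float),
        y_min=y_min,
        y_max=y_max,
        variant=variant,
    )

    if variant == "tsk_lm":
        Z = model._activations_normalized(Xn)
        coeffs, intercepts = fit_consequents(Z, Xn, yn, ctx_set)
        model.linear_coeffs = coeffs
        model.intercepts = intercepts
        _, modal, _, _ = model._interval_normalized(Xn)
        model.bias = compute_bias(yn, modal)
    return model
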
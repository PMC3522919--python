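"""Linguistic contexts and context-based fuzzy c-means (CFCM) clustering.

A *linguistic context* is a triangular fuzzy set defined over the output
variable (here: energy expenditure).  An ordered family of ``p`` contexts
forms a Ruspini partition of the output range — at every point of the range
the context memberships sum to one — so each context can be read as a
linguistic label ("low", "moderate", "high", ...) for the output.

Context-based fuzzy c-means clusters the *input* space separately inside
each context: the membership column of data point ``k`` is constrained to
sum to ``w_tk``, the degree to which the point's output belongs to context
``t``.  Clusters therefore form within output-homogeneous granules, and
each (context, cluster) pair later becomes one rule of the linguistic
model.

The membership update for cluster ``i``, point ``k`` in context ``t`` is

    u_tik = w_tk / sum_j (||x_k - v_i|| / ||x_k - v_j||)^(2/(m-1))

and the cluster centers are the fuzzy weighted means

    v_i = sum_k u_tik^m x_k / sum_k u_tik^m

with fuzzifier ``m`` (default 2.0).  The alternation minimises the
objective ``J = sum_i sum_k u_tik^m ||x_k - v_i||^2`` subject to the
column-sum constraint, so ``J`` is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LinguisticContext",
    "ContextSet",
    "CFCMResult",
    "make_uniform_contexts",
    "make_flexible_contexts",
    "context_membership",
    "cfcm_cluster",
]


@dataclass(frozen=True)
class LinguisticContext:
    """Triangular fuzzy set over the output space with break points
    ``(r_minus, r_mode, r_plus)``.

    Boundary contexts of a partition are *open-shouldered*: membership stays
    at 1 beyond the apex on the unbounded side so that the partition of
    unity holds at the extremes of the output range.  The stored outer break
    point is clamped to the range limit (hence ``r_minus == r_mode`` for a
    left-shouldered context).
    """

    r_minus: float
    r_mode: float
    r_plus: float
    left_shoulder: bool = False
    right_shoulder: bool = False

    def __post_init__(self) -> None:
        if not (self.r_minus <= self.r_mode <= self.r_plus):
            raise ValueError(
                f"break points must be ordered, got "
                f"({self.r_minus}, {self.r_mode}, {self.r_plus})"
            )

    def membership(self, y):
        """Piecewise-linear membership degree of ``y`` (scalar or array)."""
        arr = np.asarray(y, dtype=float)
        out = np.zeros(arr.shape)
        # rising edge / left shoulder
        if self.left_shoulder:
            out = np.where(arr <= self.r_mode, 1.0, out)
        elif self.r_mode > self.r_minus:
            sel = (arr > self.r_minus) & (arr <= self.r_mode)
            out = np.where(
                sel, (arr - self.r_minus) / (self.r_mode - self.r_minus), out
            )
        else:
            out = np.where(arr == self.r_mode, 1.0, out)
        # falling edge / right shoulder
        if self.right_shoulder:
            out = np.where(arr > self.r_mode, 1.0, out)
        elif self.r_plus > self.r_mode:
            sel = (arr > self.r_mode) & (arr < self.r_plus)
            out = np.where(
                sel, (self.r_plus - arr) / (self.r_plus - self.r_mode), out
            )
        return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def context_membership(ctx: LinguisticContext, y):
    """Membership degree of ``y`` in context ``ctx`` (vectorised over y)."""
    return ctx.membership(y)


@dataclass(frozen=True)
class ContextSet:
    """Ordered family of ``p`` linguistic contexts partitioning the output range."""

    contexts: tuple[LinguisticContext, ...]
    output_range: tuple[float, float]
    scheme: str  # "uniform" | "flexible"

    @property
    def p(self) -> int:
        return len(self.contexts)

    def memberships(self, y) -> np.ndarray:
        """Context membership matrix, shape ``(p,)`` for scalar y, ``(p, n)`` else."""
        return np.stack([ctx.membership(np.asarray(y, float)) for ctx in self.contexts])

    def modes(self) -> np.ndarray:
        return np.array([c.r_mode for c in self.contexts])

    def lowers(self) -> np.ndarray:
        return np.array([c.r_minus for c in self.contexts])

    def uppers(self) -> np.ndarray:
        return np.array([c.r_plus for c in self.contexts])

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "output_range": list(self.output_range),
            "break_points": [[c.r_minus, c.r_mode, c.r_plus] for c in self.contexts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContextSet":
        bps = d["break_points"]
        contexts = tuple(
            LinguisticContext(
                *bp,
                left_shoulder=(t == 0),
                right_shoulder=(t == len(bps) - 1),
            )
            for t, bp in enumerate(bps)
        )
        return cls(contexts, tuple(d["output_range"]), d["scheme"])


def _contexts_from_apexes(apexes: np.ndarray, scheme: str) -> ContextSet:
    """Build half-overlapping triangles from strictly increasing apexes.

    Adjacent triangles cross at membership 0.5; the first and last contexts
    are shouldered so the family is a partition of unity on the full range.
    """
    p = len(apexes)
    span = apexes[-1] - apexes[0]
    if np.any(np.diff(apexes) <= 1e-12 * max(span, 1.0)):
        raise ValueError(f"insufficient output spread for {p} contexts")
    contexts = []
    for t in range(p):
        lo = apexes[t - 1] if t > 0 else apexes[0]
        hi = apexes[t + 1] if t < p - 1 else apexes[-1]
        contexts.append(
            LinguisticContext(
                float(lo),
                float(apexes[t]),
                float(hi),
                left_shoulder=(t == 0),
                right_shoulder=(t == p - 1),
            )
        )
    return ContextSet(tuple(contexts), (float(apexes[0]), float(apexes[-1])), scheme)


def _check_output(y: np.ndarray, p: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if p < 2:
        raise ValueError("need at least p = 2 contexts")
    if y.size < 2 or np.min(y) == np.max(y):
        raise ValueError("degenerate output range: output variable is constant")
    return y


def make_uniform_contexts(y, p: int) -> ContextSet:
    """``p`` triangular contexts with apexes equally spaced over ``[min(y), max(y)]``."""
    y = _check_output(y, p)
    apexes = np.linspace(np.min(y), np.max(y), p)
    return _contexts_from_apexes(apexes, "uniform")


def make_flexible_contexts(y, p: int) -> ContextSet:
    """``p`` contexts with apexes at the equally spaced quantiles of ``y``.

    Placing apexes at quantile levels ``t/(p-1)`` gives every context
    approximately equal probability mass, so no context is starved of data
    when the output distribution is skewed (the data-scarcity problem of
    equally *spaced* contexts).
    """
    y = _check_output(y, p)
    apexes = np.quantile(y, np.linspace(0.0, 1.0, p))
    return _contexts_from_apexes(apexes, "flexible")


@dataclass
class CFCMResult:
    """Outcome of context-based fuzzy c-means for one context.

    ``memberships[i, k]`` is the degree of point ``k`` in cluster ``i``;
    each column sums to the point's context weight ``context_weights[k]``.
    """

    centers: np.ndarray          # (c, d)
    memberships: np.ndarray      # (c, N)
    context_weights: np.ndarray  # (N,)
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def _fcm_memberships(sq_dist: np.ndarray, w: np.ndarray, m: float) -> np.ndarray:
    """Membership update: columns of the result sum to ``w``.

    ``sq_dist`` has shape ``(c, N)``.  Points coincident with one or more
    centers give their full weight to those centers, split equally.
    """
    expo = 1.0 / (m - 1.0)  # ratio of squared distances -> 2/(m-1) on distances
    U = np.empty_like(sq_dist)
    zero = sq_dist == 0.0
    singular = zero.any(axis=0)
    reg = ~singular
    if reg.any():
        sq = sq_dist[:, reg]
        ratio = sq / sq.min(axis=0)  # >= 1, so inv <= 1: no overflow
        inv = ratio**(-expo)
        U[:, reg] = inv / inv.sum(axis=0) * w[reg]
    if singular.any():
        share = zero[:, singular] / zero[:, singular].sum(axis=0)
        U[:, singular] = share * w[singular]
    return U


def cfcm_cluster(
    X,
    w,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed=None,
    init: np.ndarray | None = None,
    iteration_hook: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
    context_index: int | None = None,
) -> CFCMResult:
    """Run CFCM clustering of ``X`` under context weights ``w``.

    Parameters
    ----------
    X : array, shape (N, d) or (N,)
        Input points (normalised space; Euclidean distance).
    w : array, shape (N,)
        Context membership of each point, in [0, 1].  With ``w == 1``
        everywhere this is standard fuzzy c-means.
    c : int
        Number of clusters; must not exceed the number of points with
        positive weight.
    m : float
        Fuzzifier, > 1.
    tol, max_iter :
        Stop when ``max |U_new - U| < tol`` or after ``max_iter`` iterations.
    seed :
        Seed for the random membership initialisation (anything accepted by
        ``numpy.random.default_rng``).  Ignored when ``init`` is given.
    init : array (c, N), optional
        Explicit initial membership matrix; its columns are rescaled to sum
        to ``w``.
    iteration_hook : callable, optional
        Called as ``hook(iteration, U, V)`` after every iteration.
    context_index : int, optional
        Used only to label error messages.

    Returns
    -------
    CFCMResult
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    w = np.asarray(w, dtype=float).ravel()
    N = X.shape[0]
    if w.shape[0] != N:
        raise ValueError("w must have one weight per data point")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("context weights must lie in [0, 1]")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    label = "" if context_index is None else f" (context {context_index})"
    support = int((w > 0).sum())
    if support == 0:
        raise ValueError(f"empty context{label}: all context weights are zero")
    if not 1 <= c <= support:
        raise ValueError(
            f"c = {c} clusters exceed the {support} points with positive "
            f"weight{label}"
        )

    if init is not None:
        U = np.asarray(init, dtype=float).copy()
        if U.shape != (c, N):
            raise ValueError(f"init must have shape ({c}, {N})")
    else:
        rng = np.random.default_rng(seed)
        U = rng.uniform(size=(c, N))
    colsum = U.sum(axis=0)
    colsum[colsum == 0] = 1.0
    U *= w / colsum

    trace: list[float] = []
    converged = False
    it = 0
    V = np.zeros((c, X.shape[1]))
    for it in range(1, max_iter + 1):
        Um = U**m
        den = Um.sum(axis=1)
        pos = den > 0
        V[pos] = (Um[pos] @ X) / den[pos, None]
        sq = ((X[None, :, :] - V[:, None, :]) ** 2).sum(axis=2)  # (c, N)
        U_new = _fcm_memberships(sq, w, m)
        trace.append(float(((U_new**m) * sq).sum()))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if iteration_hook is not None:
            iteration_hook(it, U, V)
        if delta < tol:
            converged = True
            break

    return CFCMResult(
        centers=V,
        memberships=U,
        context_weights=w,
        fuzzifier=m,
        objective_trace=trace,
        converged=converged,
        iterations=it,
    )
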
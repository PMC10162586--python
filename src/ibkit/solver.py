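"""Generalized Information Bottleneck solver for one fixed (alpha, beta).

The optimization is

    min over q(m|x) of  H(M) - alpha * H(M|X) - beta * I(M:Y)

subject to the Markov constraint p(x, m, y) = p(x) q(m|x) p(y|x).
alpha = 1 is the standard Information Bottleneck, whose objective equals
I(M:X) - beta * I(M:Y); alpha = 0 is the Deterministic Information
Bottleneck, whose optimal encoders are hard assignments with H(M|X) = 0.

The solver is Blahut-Arimoto alternating minimization.  One iteration is
self-consistent: from the current encoder it forms the cluster marginal
q(m) and decoder q(y|m), then refreshes every encoder row

    q_new(m|x)  propto  exp( (ln q(m) - beta * d(x, m)) / alpha ),
    d(x, m) = KL( p(y|x) || q(y|m) ),

and, in the alpha = 0 limit, puts all mass on
argmax_m (ln q(m) - beta * d(x, m)), ties broken toward the lowest m.
Each iteration cannot increase the objective: the update is the exact
block minimizer of a variational functional that is convex in every
block for all alpha >= 0, so descent is monotone up to rounding.

All scores are handled in log space (natural logs internally; reported
quantities are bits).  Clusters whose marginal q(m) hits zero stay empty
(structural zeros); that keeps the descent property exact.  Optional
re-seeding of empty clusters is available but off by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .distributions import (
    ConditionalPMF,
    JointPMF,
    entropy,
    matrix_mutual_information,
)

_LN2 = float(np.log(2.0))


class InternalConsistencyError(RuntimeError):
    """Every candidate cluster scored -inf for some x; cannot happen for a
    valid encoder/joint pair and indicates corrupted state."""


@dataclass(frozen=True)
class GIBParams:
    """Solver controls for one bottleneck problem.

    Parameters
    ----------
    alpha:
        Weight of H(M|X) in the objective; 1 is standard IB, 0 is DIB.
    beta:
        Relevance-compression trade-off multiplier (>= 0).
    m_cardinality:
        Number of bottleneck clusters; ``None`` means the size of the
        x support, which suffices for the optimal frontier.
    max_iter, tol:
        Iteration cap and convergence tolerance on the change of the
        objective, in bits.
    n_restarts:
        Independent random initializations; the best final objective wins.
    seed:
        Master seed; restart seeds derive from (seed, beta index,
        restart index) so results do not depend on how a beta grid is
        chunked across processes.
    reseed_empty_clusters:
        If True, a cluster whose marginal collapses to zero is re-seeded
        with the single worst-fit x (hard assignment).  Breaks the exact
        monotone-descent guarantee; off by default.
    """

    alpha: float = 1.0
    beta: float = 1.0
    m_cardinality: int | None = None
    max_iter: int = 10_000
    tol: float = 1e-9
    n_restarts: int = 3
    seed: int = 0
    reseed_empty_clusters: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.m_cardinality is not None and self.m_cardinality < 1:
            raise ValueError("m_cardinality must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass(frozen=True)
class Encoder:
    """The stochastic map q(m|x): rows indexed by x support, columns by m."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2:
            raise ValueError("encoder must be a matrix")
        if np.any(q < 0):
            raise ValueError("encoder has negative entries")
        if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("encoder rows must sum to 1")
        object.__setattr__(self, "q", q)

    @property
    def n_x(self) -> int:
        return self.q.shape[0]

    @property
    def n_m(self) -> int:
        return self.q.shape[1]

    def is_deterministic(self) -> bool:
        """True when every row is one-hot."""
        return bool(np.all(np.isin(self.q, (0.0, 1.0))))

    def as_conditional(self) -> ConditionalPMF:
        return ConditionalPMF(self.q)


@dataclass(frozen=True)
class BottleneckSolution:
    """A converged solution at one beta: functionals (bits) plus encoder."""

    beta: float
    alpha: float
    i_mx: float
    i_my: float
    h_m: float
    h_m_given_x: float
    objective: float
    encoder: Encoder
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# support-restricted views of the joint
# ---------------------------------------------------------------------------


def _support_quantities(joint: JointPMF):
    """(p(x), p(x,y), p(y|x)) restricted to the x support."""
    keep = joint.x_support
    pxy = joint.matrix[keep]
    px = pxy.sum(axis=1)
    py_given_x = pxy / px[:, None]
    return px, pxy, py_given_x


def resolve_m_cardinality(joint: JointPMF, params: GIBParams) -> int:
    if params.m_cardinality is not None:
        return params.m_cardinality
    return int(joint.x_support.sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def initialize_encoder(
    params: GIBParams,
    x_support_size: int,
    restart_index: int,
    beta_index: int = 0,
) -> Encoder:
    """Random starting encoder, deterministic in (seed, beta_index, restart_index).

    For alpha > 0 every row is drawn uniformly on the simplex; for the
    deterministic regime (alpha = 0) every row is a one-hot at a
    uniformly random cluster.
    """
    m = params.m_cardinality
    if m is None:
        m = x_support_size
    ss = np.random.SeedSequence([params.seed, beta_index, restart_index])
    rng = np.random.default_rng(ss)
    if params.alpha > 0:
        q = rng.dirichlet(np.ones(m), size=x_support_size)
    else:
        cols = rng.integers(0, m, size=x_support_size)
        q = np.zeros((x_support_size, m))
        q[np.arange(x_support_size), cols] = 1.0
    return Encoder(q)


def _scores(q: np.ndarray, px, pxy, py_given_x, beta: float) -> np.ndarray:
    """ln q(m) - beta * d(x,m) in nats; -inf for empty clusters and
    support-violating (x, m) pairs."""
    n_x, n_m = q.shape
    qm = px @ q
    active = qm > 0
    if not np.any(active):  # pragma: no cover - encoder rows sum to 1
        raise InternalConsistencyError("all clusters empty")
    qmy = q.T @ pxy  # q(m, y) under the Markov constraint
    qygm = qmy[active] / qm[active, None]

    pos_p = py_given_x > 0
    ln_p = np.where(pos_p, np.log(np.where(pos_p, py_given_x, 1.0)), 0.0)
    self_term = np.sum(py_given_x * ln_p, axis=1)  # sum_y p ln p

    pos_q = qygm > 0
    ln_q = np.where(pos_q, np.log(np.where(pos_q, qygm, 1.0)), 0.0)
    cross = py_given_x @ ln_q.T  # (n_x, n_active)
    # (x, m) pairs where p(y|x) > 0 but q(y|m) = 0 have infinite divergence
    violates = (py_given_x @ (~pos_q).astype(float).T) > 0
    d = self_term[:, None] - cross
    d[violates] = np.inf

    scores = np.full((n_x, n_m), -np.inf)
    ln_qm = np.log(qm[active])
    if beta == 0:
        scores[:, active] = np.broadcast_to(ln_qm, (n_x, ln_qm.size))
    else:
        s = ln_qm[None, :] - beta * d
        s[violates] = -np.inf
        scores[:, active] = s
    return scores


def gib_iteration(encoder: Encoder, joint: JointPMF, params: GIBParams) -> Encoder:
    """One full self-consistent Blahut-Arimoto update of the encoder."""
    px, pxy, py_given_x = _support_quantities(joint)
    q = encoder.q
    scores = _scores(q, px, pxy, py_given_x, params.beta)
    finite = np.isfinite(scores)
    if not np.all(finite.any(axis=1)):
        raise InternalConsistencyError(
            "an x row has no admissible cluster; encoder state is corrupt"
        )
    if params.alpha > 0:
        z = scores / params.alpha
        log_rows = z - logsumexp(z, axis=1, keepdims=True)
        q_new = np.exp(log_rows)
        q_new /= q_new.sum(axis=1, keepdims=True)
    else:
        best = np.argmax(scores, axis=1)  # argmax takes the lowest index on ties
        q_new = np.zeros_like(q)
        q_new[np.arange(q.shape[0]), best] = 1.0

    if params.reseed_empty_clusters:
        q_new = _reseed_empty(q_new, px, pxy, py_given_x, params.beta)
    return Encoder(q_new)


def _reseed_empty(q: np.ndarray, px, pxy, py_given_x, beta: float) -> np.ndarray:
    """Move the worst-fit x values (largest divergence from their decoder)
    one-hot onto the empty clusters, one distinct x per cluster.
    Heuristic; can increase the objective."""
    empty = np.flatnonzero(px @ q <= 0)
    if empty.size == 0:
        return q
    scores = _scores(q, px, pxy, py_given_x, beta)
    donors = np.argsort(np.max(scores, axis=1))  # worst-fit x first
    q = q.copy()
    for m, x in zip(empty, donors):
        q[x] = 0.0
        q[x, m] = 1.0
    return q


def solution_functionals(encoder: Encoder, joint: JointPMF):
    """(I(M:X), I(M:Y), H(M), H(M|X)) in bits for an encoder on a joint.

    I(M:X) comes from the composed joint q(m,x) = p(x) q(m|x) and I(M:Y)
    from q(m,y) = sum_x q(m|x) p(x,y), per the Markov constraint.
    """
    px, pxy, _ = _support_quantities(joint)
    q = encoder.q
    qxm = q * px[:, None]
    qmy = q.T @ pxy
    qm = qxm.sum(axis=0)
    i_mx = matrix_mutual_information(qxm)
    i_my = matrix_mutual_information(qmy)
    h_m = entropy(qm)
    pos = q > 0
    row_h = -np.where(pos, q * np.log2(np.where(pos, q, 1.0)), 0.0).sum(axis=1)
    h_m_given_x = float(np.dot(px, row_h))
    return i_mx, i_my, h_m, h_m_given_x


def objective(encoder: Encoder, joint: JointPMF, params: GIBParams) -> float:
    """H(M) - alpha H(M|X) - beta I(M:Y), in bits.

    At alpha = 1 this equals I(M:X) - beta I(M:Y), the standard IB
    objective.
    """
    _, i_my, h_m, h_m_given_x = solution_functionals(encoder, joint)
    return h_m - params.alpha * h_m_given_x - params.beta * i_my


def solve_fixed_beta(
    joint: JointPMF,
    params: GIBParams,
    beta_index: int = 0,
    initial_encoder: Encoder | None = None,
) -> BottleneckSolution:
    """Best-of-``n_restarts`` Blahut-Arimoto solution at one (alpha, beta).

    Each restart iterates to a fixed point (|change in objective| <= tol)
    or to ``max_iter``; the restart with the lowest final objective wins.
    ``initial_encoder`` (e.g. a warm start from a neighbouring beta) is
    evaluated as one extra restart.
    """
    n_x = int(joint.x_support.sum())
    starts: list[Encoder] = [
        initialize_encoder(params, n_x, r, beta_index=beta_index)
        for r in range(params.n_restarts)
    ]
    if initial_encoder is not None:
        starts.append(initial_encoder)

    best = None
    for enc in starts:
        obj = objective(enc, joint, params)
        converged = False
        n_iter = 0
        for n_iter in range(1, params.max_iter + 1):
            enc = gib_iteration(enc, joint, params)
            new_obj = objective(enc, joint, params)
            if abs(new_obj - obj) <= params.tol:
                obj = new_obj
                converged = True
                break
            obj = new_obj
        if best is None or obj < best[1]:
            best = (enc, obj, n_iter, converged)

    enc, obj, n_iter, converged = best
    i_mx, i_my, h_m, h_m_given_x = solution_functionals(enc, joint)
    return BottleneckSolution(
        beta=params.beta,
        alpha=params.alpha,
        i_mx=i_mx,
        i_my=i_my,
        h_m=h_m,
        h_m_given_x=h_m_given_x,
        objective=obj,
        encoder=enc,
        n_iterations=n_iter,
        converged=converged,
    )
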
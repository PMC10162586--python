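"""Discrete probability objects and information-theoretic functionals.

Everything here works on finite alphabets of hashable, orderable symbols.
All information quantities are returned in **bits** (base-2 logarithms),
with the usual convention ``0 * log 0 = 0`` implemented by masking zero
entries rather than by adding pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

#: tolerance on the total mass of anything claiming to be a pmf
NORM_TOL = 1e-12


class InvalidPMFError(ValueError):
    """A matrix or vector cannot be interpreted as a probability mass function."""


class LengthMismatchError(ValueError):
    """Paired inputs differ in length."""


class EmptyInputError(ValueError):
    """An observation sequence is empty."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alphabet:
    """An ordered collection of distinct symbols with 0-based positions."""

    symbols: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def index(self) -> dict:
        """Map from symbol to its 0-based position."""
        return dict(self._index)

    def position(self, symbol: Hashable) -> int:
        return self._index[symbol]

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i: int):
        return self.symbols[i]

    @classmethod
    def from_observations(cls, obs: Sequence[Hashable]) -> "Alphabet":
        """Alphabet of the sorted unique symbols of a sequence."""
        return cls(tuple(sorted(set(obs))))


@dataclass(frozen=True)
class ProbabilityVector:
    """A vector of non-negative reals summing to one (within NORM_TOL)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1:
            raise InvalidPMFError("probability vector must be one-dimensional")
        if np.any(p < 0):
            raise InvalidPMFError("probability vector has negative entries")
        if abs(p.sum() - 1.0) > NORM_TOL:
            raise InvalidPMFError(
                f"probability vector sums to {p.sum()!r}, not 1 within {NORM_TOL}"
            )
        object.__setattr__(self, "p", p)

    def __len__(self) -> int:
        return len(self.p)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.p, dtype=dtype)


@dataclass(frozen=True)
class JointPMF:
    """A joint pmf p(x, y) on the product of two finite alphabets.

    Rows index x, columns index y.  Rows with zero total mass are legal
    but flagged via :attr:`x_support`: such x values never enter the
    bottleneck solver support because p(y|x) is undefined there.
    """

    matrix: np.ndarray
    x_alphabet: Alphabet
    y_alphabet: Alphabet

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise InvalidPMFError("joint pmf must be a matrix")
        if np.any(m < 0):
            raise InvalidPMFError("joint pmf has negative entries")
        if abs(m.sum() - 1.0) > NORM_TOL:
            raise InvalidPMFError(
                f"joint pmf sums to {m.sum()!r}, not 1 within {NORM_TOL}"
            )
        if m.shape != (len(self.x_alphabet), len(self.y_alphabet)):
            raise InvalidPMFError("joint pmf shape does not match alphabets")
        object.__setattr__(self, "matrix", m)

    @property
    def x_support(self) -> np.ndarray:
        """Boolean mask of x rows carrying positive mass."""
        return self.matrix.sum(axis=1) > 0

    @property
    def n_x(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_y(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ConditionalPMF:
    """A row-stochastic matrix: row i is the outcome pmf given symbol i.

    ``row_symbols`` records which conditioning symbols the rows refer to
    (zero-mass symbols are dropped when conditioning a joint).
    """

    matrix: np.ndarray
    row_symbols: tuple = None
    col_symbols: tuple = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise InvalidPMFError("conditional pmf must be a matrix")
        if np.any(m < 0):
            raise InvalidPMFError("conditional pmf has negative entries")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > NORM_TOL):
            raise InvalidPMFError("conditional pmf rows must each sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# constructors / estimators
# ---------------------------------------------------------------------------


def estimate_joint(
    x_obs: Sequence[Hashable], y_obs: Sequence[Hashable]
) -> JointPMF:
    """Plug-in (maximum-likelihood) joint pmf from paired observations.

    Entry (x, y) is the co-occurrence count divided by the total number of
    pairs; no smoothing is applied.  Alphabets are the sorted unique
    symbols of each sequence.
    """
    x_obs = list(x_obs)
    y_obs = list(y_obs)
    if len(x_obs) != len(y_obs):
        raise LengthMismatchError(
            f"x has {len(x_obs)} observations but y has {len(y_obs)}"
        )
    if not x_obs:
        raise EmptyInputError("observation sequences are empty")
    x_alpha = Alphabet.from_observations(x_obs)
    y_alpha = Alphabet.from_observations(y_obs)
    counts = np.zeros((len(x_alpha), len(y_alpha)))
    xi = np.fromiter((x_alpha.position(s) for s in x_obs), dtype=int)
    yi = np.fromiter((y_alpha.position(s) for s in y_obs), dtype=int)
    np.add.at(counts, (xi, yi), 1.0)
    return JointPMF(counts / len(x_obs), x_alpha, y_alpha)


def joint_from_matrix(
    raw: np.ndarray,
    x_symbols: Sequence[Hashable] | None = None,
    y_symbols: Sequence[Hashable] | None = None,
) -> JointPMF:
    """Joint pmf from a non-negative matrix, rescaled to total mass 1.

    This is the only place a not-quite-normalized input is rescaled;
    the JointPMF constructor itself rejects anything off by more than
    NORM_TOL.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise InvalidPMFError("expected a two-dimensional matrix")
    if np.any(raw < 0):
        raise InvalidPMFError("matrix has negative entries")
    total = raw.sum()
    if total <= 0:
        raise InvalidPMFError("matrix has no positive entries")
    x_alpha = Alphabet(tuple(x_symbols) if x_symbols is not None else tuple(range(raw.shape[0])))
    y_alpha = Alphabet(tuple(y_symbols) if y_symbols is not None else tuple(range(raw.shape[1])))
    return JointPMF(raw / total, x_alpha, y_alpha)


def marginal(joint: JointPMF, axis: str) -> ProbabilityVector:
    """Marginal pmf of a joint along ``axis`` ('x' for rows, 'y' for columns)."""
    if axis == "x":
        return ProbabilityVector(joint.matrix.sum(axis=1))
    if axis == "y":
        return ProbabilityVector(joint.matrix.sum(axis=0))
    raise ValueError("axis must be 'x' or 'y'")


def condition(joint: JointPMF, given: str) -> ConditionalPMF:
    """Conditional pmf of one variable given the other.

    ``given='x'`` returns p(y|x) with one row per x in the support;
    zero-mass conditioning symbols are dropped from the rows (they are
    recorded in ``JointPMF.x_support``), never an error.
    """
    if given == "x":
        mat = joint.matrix
        row_alpha, col_alpha = joint.x_alphabet, joint.y_alphabet
    elif given == "y":
        mat = joint.matrix.T
        row_alpha, col_alpha = joint.y_alphabet, joint.x_alphabet
    else:
        raise ValueError("given must be 'x' or 'y'")
    mass = mat.sum(axis=1)
    keep = mass > 0
    rows = mat[keep] / mass[keep, None]
    return ConditionalPMF(
        rows,
        row_symbols=tuple(s for s, k in zip(row_alpha.symbols, keep) if k),
        col_symbols=col_alpha.symbols,
    )


# ---------------------------------------------------------------------------
# information functionals (bits)
# ---------------------------------------------------------------------------


def _as_vector(p) -> np.ndarray:
    if isinstance(p, ProbabilityVector):
        return p.p
    return np.asarray(p, dtype=float)


def entropy(p) -> float:
    """Shannon entropy -sum p log2 p in bits, masking zero entries."""
    v = _as_vector(p)
    pos = v > 0
    return float(-np.sum(v[pos] * np.log2(v[pos])))


def conditional_entropy(cond: ConditionalPMF, weights) -> float:
    """H of the column variable given the row variable, in bits.

    ``weights`` is the pmf over the conditioning rows; the result is the
    weighted average row entropy.
    """
    w = _as_vector(weights)
    m = cond.matrix if isinstance(cond, ConditionalPMF) else np.asarray(cond, float)
    if len(w) != m.shape[0]:
        raise LengthMismatchError(
            f"{len(w)} weights for {m.shape[0]} conditional rows"
        )
    pos = m > 0
    rowsum = -np.where(pos, m * np.log2(np.where(pos, m, 1.0)), 0.0).sum(axis=1)
    return float(np.dot(w, rowsum))


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence D(p || q) in bits.

    Returns ``inf`` when p puts mass where q does not; always >= 0.
    """
    pv, qv = _as_vector(p), _as_vector(q)
    if len(pv) != len(qv):
        raise LengthMismatchError("p and q have different lengths")
    pos = pv > 0
    if np.any(qv[pos] <= 0):
        return float("inf")
    return float(np.sum(pv[pos] * (np.log2(pv[pos]) - np.log2(qv[pos]))))


def matrix_mutual_information(mat: np.ndarray) -> float:
    """Mutual information in bits of a joint pmf given as a bare matrix."""
    m = np.asarray(mat, dtype=float)
    px = m.sum(axis=1)
    py = m.sum(axis=0)
    pos = m > 0
    outer = np.outer(px, py)
    return float(
        np.sum(m[pos] * (np.log2(m[pos]) - np.log2(outer[pos])))
    )


def mutual_information(joint) -> float:
    """Mutual information I(X:Y) in bits of a joint pmf."""
    if isinstance(joint, JointPMF):
        return matrix_mutual_information(joint.matrix)
    return matrix_mutual_information(joint)
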
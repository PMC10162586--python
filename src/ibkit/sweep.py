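"""Trade-off curves: solve the bottleneck across a grid of beta values.

A sweep produces one :class:`~ibkit.solver.BottleneckSolution` per beta.
Because every beta gets its own deterministically derived restart seeds,
the result is bit-identical whether the grid is solved sequentially or
split into chunks across processes.  Cleaning removes dominated points
so the retained solutions trace a monotone frontier in the information
plane (I(M:X), I(M:Y)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .distributions import JointPMF, mutual_information
from .solver import BottleneckSolution, Encoder, GIBParams, solve_fixed_beta

#: tolerance (bits) when deciding that one solution dominates another
DOMINANCE_TOL = 1e-9

CURVE_COLUMNS = (
    "beta",
    "I_MX",
    "I_MY",
    "H_M",
    "H_M_given_X",
    "objective",
    "converged",
)


class SweepError(RuntimeError):
    """The solver failed at every beta of the grid."""


@dataclass(frozen=True)
class BetaGrid:
    """Strictly increasing positive beta values, optionally anchored at 0."""

    values: tuple
    include_zero_anchor: bool = False

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError("beta grid needs at least one value")
        if any(v <= 0 for v in vals):
            raise ValueError("grid values must be > 0 (use include_zero_anchor for beta=0)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def effective_values(self) -> tuple:
        """Grid values actually swept, with the optional beta=0 anchor first."""
        return ((0.0,) if self.include_zero_anchor else ()) + self.values

    def __len__(self) -> int:
        return len(self.effective_values)


def default_beta_grid(n_points: int = 30) -> BetaGrid:
    """Geometrically spaced grid from 0.1 to 100 inclusive."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return BetaGrid(tuple(np.geomspace(0.1, 100.0, n_points)))


@dataclass
class IBCurve:
    """Solutions over a beta grid plus the joint's own I(X:Y) ceiling."""

    solutions: list
    i_xy: float
    alpha: float
    cleaned: bool = False
    failures: list = field(default_factory=list)  # (beta, message) pairs

    def __len__(self) -> int:
        return len(self.solutions)

    def column(self, name: str) -> np.ndarray:
        """Array of one functional across solutions, ordered as stored."""
        return np.array([getattr(s, name) for s in self.solutions])


def _solve_one(joint, params, beta, index):
    try:
        sol = solve_fixed_beta(joint, replace(params, beta=beta), beta_index=index)
        return sol, None
    except Exception as exc:  # noqa: BLE001 - a failed beta must not kill the sweep
        return None, f"{type(exc).__name__}: {exc}"


def sweep(
    joint: JointPMF,
    grid: BetaGrid,
    params: GIBParams,
    n_processes: int = 1,
    warm_start: bool = False,
) -> IBCurve:
    """Solve the bottleneck at every beta of the grid.

    The output is independent of ``n_processes`` because restart seeds
    depend only on (seed, beta index, restart index).  ``warm_start``
    additionally feeds each beta the previous beta's winning encoder as
    an extra restart candidate; it forces sequential execution and is
    off by default (each beta is solved independently).
    """
    if n_processes < 1:
        raise ValueError("n_processes must be >= 1")
    betas = grid.effective_values

    if warm_start:
        results = []
        prev: Encoder | None = None
        for i, b in enumerate(betas):
            try:
                sol = solve_fixed_beta(
                    joint,
                    replace(params, beta=b),
                    beta_index=i,
                    initial_encoder=prev,
                )
                prev = sol.encoder
                results.append((sol, None))
            except Exception as exc:  # noqa: BLE001
                results.append((None, f"{type(exc).__name__}: {exc}"))
    elif n_processes == 1:
        results = [_solve_one(joint, params, b, i) for i, b in enumerate(betas)]
    else:
        results = Parallel(n_jobs=n_processes)(
            delayed(_solve_one)(joint, params, b, i) for i, b in enumerate(betas)
        )

    solutions = []
    failures = []
    for b, (sol, err) in zip(betas, results):
        if sol is None:
            failures.append((b, err))
        else:
            solutions.append(sol)
    if not solutions:
        raise SweepError(f"solver failed at every beta: {failures}")
    return IBCurve(
        solutions=solutions,
        i_xy=mutual_information(joint),
        alpha=params.alpha,
        cleaned=False,
        failures=failures,
    )


def _dominates(a: BottleneckSolution, b: BottleneckSolution, tol: float) -> bool:
    """True when a achieves at least b's relevance with at most b's rate,
    strictly better in one of the two."""
    return (
        a.i_mx <= b.i_mx + tol
        and a.i_my >= b.i_my - tol
        and (a.i_mx < b.i_mx - tol or a.i_my > b.i_my + tol)
    )


def clean_curve(curve: IBCurve, tol: float = DOMINANCE_TOL) -> IBCurve:
    """Drop dominated and duplicate solutions; sort the rest by I(M:X)."""
    if not curve.solutions:
        raise ValueError("cannot clean an empty curve")
    sols = list(curve.solutions)

    # collapse near-identical information-plane points, keeping the first
    unique: list[BottleneckSolution] = []
    for s in sols:
        if not any(
            abs(s.i_mx - u.i_mx) <= tol and abs(s.i_my - u.i_my) <= tol
            for u in unique
        ):
            unique.append(s)

    kept = [
        s
        for s in unique
        if not any(o is not s and _dominates(o, s, tol) for o in unique)
    ]
    kept.sort(key=lambda s: (s.i_mx, s.i_my))
    return IBCurve(
        solutions=kept,
        i_xy=curve.i_xy,
        alpha=curve.alpha,
        cleaned=True,
        failures=list(curve.failures),
    )


def write_curve(curve: IBCurve, path, delimiter: str = ",") -> None:
    """Write the curve as a delimited text table, 12 significant digits."""
    lines = [delimiter.join(CURVE_COLUMNS)]
    for s in curve.solutions:
        row = [
            f"{s.beta:.12g}",
            f"{s.i_mx:.12g}",
            f"{s.i_my:.12g}",
            f"{s.h_m:.12g}",
            f"{s.h_m_given_x:.12g}",
            f"{s.objective:.12g}",
            str(s.converged),
        ]
        lines.append(delimiter.join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
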
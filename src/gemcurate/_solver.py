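"""Thin deterministic wrappers around scipy's HiGHS LP/MILP solvers."""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp


@contextlib.contextmanager
def _quiet_fd1():
    """Silence C-level stdout chatter (HiGHS prints postsolve notes
    directly to fd 1) for the duration of a solve."""
    try:
        saved = os.dup(1)
    except OSError:  # no usable stdout; nothing to silence
        yield
        return
    try:
        with open(os.devnull, "wb") as devnull:
            os.dup2(devnull.fileno(), 1)
        yield
    finally:
        try:  # flush HiGHS's buffered C stdout into the null sink
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass
        os.dup2(saved, 1)
        os.close(saved)

__all__ = ["LPResult", "solve_lp", "solve_milp"]

_LP_OPTIONS = {"presolve": True}


@dataclass(frozen=True)
class LPResult:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    x: np.ndarray | None


def _status_of(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 2:
        return "infeasible"
    if res.status == 3:
        return "unbounded"
    return "infeasible"


def solve_lp(
    c: np.ndarray,
    a_eq: sparse.spmatrix | None,
    b_eq: np.ndarray | None,
    bounds: list[tuple[float, float]],
    a_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    maximize: bool = True,
) -> LPResult:
    """Solve max/min c.x subject to A_eq x = b_eq, A_ub x <= b_ub, bounds."""
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_LP_OPTIONS,
    )
    status = _status_of(res)
    if status != "optimal":
        return LPResult(status, None, None)
    return LPResult(status, sign * res.fun, res.x)


def solve_milp(
    c: np.ndarray,
    integrality: np.ndarray,
    bounds: list[tuple[float, float]],
    a_eq: sparse.spmatrix | None = None,
    b_eq: np.ndarray | None = None,
    a_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    maximize: bool = False,
) -> LPResult:
    """Solve a mixed-integer LP; integrality 1 marks integer variables."""
    constraints = []
    if a_eq is not None and a_eq.shape[0] > 0:
        constraints.append(LinearConstraint(a_eq, b_eq, b_eq))
    if a_ub is not None and a_ub.shape[0] > 0:
        constraints.append(
            LinearConstraint(a_ub, -np.inf * np.ones(a_ub.shape[0]), b_ub)
        )
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    from scipy.optimize import Bounds

    sign = -1.0 if maximize else 1.0
    with _quiet_fd1():
        res = milp(
            sign * np.asarray(c, dtype=float),
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lo, hi),
        )
    if res.status != 0 or res.x is None:
        status = "infeasible" if res.status == 2 else (
            "unbounded" if res.status == 3 else "infeasible"
        )
        return LPResult(status, None, None)
    return LPResult("optimal", sign * res.fun, res.x)
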
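"""Exact 0/1 integer linear program over runs.

One binary variable x_i per run, objective ``max sum x_i * L(r_i)``.  For
every pair of same-symbol runs i < j, selecting both forces every strictly
intermediate run of a different symbol to be dropped.  Two equivalent
constraint families encode this:

``pairwise``
    one constraint per intermediate run l:  x_l <= 2 - x_i - x_j;
``aggregated`` (default)
    one constraint per pair:
    sum_{i<l<j, sigma(r_l) != sigma(r_i)} x_l <= (j - i) * (2 - x_i - x_j).

The aggregated family keeps the model at most ceil(n/2)^2 constraints.

Solving goes through an abstract MIP-backend contract so the modelling
layer carries no solver dependency of its own; the default adapter uses
SciPy's HiGHS branch-and-bound (``scipy.optimize.milp``).  Only proven
optima are accepted — a timeout or incumbent-only answer raises, it is
never silently returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .runstring import LRSError, RunString, Selection, make_selection

FAMILIES = ("pairwise", "aggregated")


class ILPError(LRSError):
    """Raised when the backend cannot prove an optimum."""


@dataclass(frozen=True)
class ILPConstraint:
    """Sparse row ``sum coeffs[i] * x_i <= rhs`` over 1-based run indices."""

    coeffs: tuple[tuple[int, int], ...]
    rhs: int


@dataclass(frozen=True)
class ILPModel:
    n: int
    objective: tuple[int, ...]  # objective[i-1] = L(r_i), maximised
    constraints: tuple[ILPConstraint, ...]
    family: str = "aggregated"

    @property
    def constraint_bound(self) -> int:
        return math.ceil(self.n / 2) ** 2


class MIPBackend(Protocol):
    """Contract a backend must satisfy: binary vars, linear rows, proof of
    optimality.  ``solve`` returns ``(status, values)`` where status is
    ``"optimal"`` only for a proven optimum."""

    def solve(self, model: ILPModel) -> tuple[str, Sequence[float]]: ...


class HighsBackend:
    """Default adapter: SciPy's HiGHS mixed-integer solver."""

    def solve(self, model: ILPModel) -> tuple[str, Sequence[float]]:
        import numpy as np
        from scipy.optimize import Bounds, LinearConstraint, milp

        c = -np.asarray(model.objective, dtype=float)  # milp minimises
        constraints = []
        if model.constraints:
            a = np.zeros((len(model.constraints), model.n))
            ub = np.empty(len(model.constraints))
            for row, con in enumerate(model.constraints):
                for i, coef in con.coeffs:
                    a[row, i - 1] = coef
                ub[row] = con.rhs
            constraints.append(LinearConstraint(a, -np.inf, ub))
        res = milp(
            c,
            constraints=constraints,
            integrality=np.ones(model.n),
            bounds=Bounds(0, 1),
            # true optimality proof: the hardness instances have objective
            # coefficients ~1e5, where the solver's default relative gap
            # (1e-4) would allow stopping a few units short of the optimum
            options={"mip_rel_gap": 0.0},
        )
        if res.status == 0 and res.x is not None:
            return "optimal", list(res.x)
        return res.message or "failed", []


def build_ilp(rs: RunString, constraint_family: str = "aggregated") -> ILPModel:
    """Construct the ILP model for an instance (n >= 1).

    Model construction is deterministic: runs ascending, same-symbol pairs
    in lexicographic (i, j) order.
    """
    if rs.n < 1:
        raise LRSError("build_ilp needs a non-empty instance")
    if constraint_family not in FAMILIES:
        raise LRSError(
            f"unknown constraint family {constraint_family!r}; expected {FAMILIES}"
        )
    symbols = [r.symbol for r in rs.runs]
    positions: dict = {}
    for idx, sym in enumerate(symbols, start=1):
        positions.setdefault(sym, []).append(idx)

    pairs = sorted(
        (i, j)
        for occ in positions.values()
        for a, i in enumerate(occ)
        for j in occ[a + 1 :]
    )

    constraints: list[ILPConstraint] = []
    for i, j in pairs:
        mids = [l for l in range(i + 1, j) if symbols[l - 1] != symbols[i - 1]]
        if constraint_family == "pairwise":
            for l in mids:
                constraints.append(
                    ILPConstraint(((i, 1), (j, 1), (l, 1)), rhs=2)
                )
        else:
            d = j - i
            coeffs = tuple([(l, 1) for l in mids] + [(i, d), (j, d)])
            constraints.append(ILPConstraint(coeffs, rhs=2 * d))

    model = ILPModel(
        n=rs.n,
        objective=tuple(r.length for r in rs.runs),
        constraints=tuple(constraints),
        family=constraint_family,
    )
    if constraint_family == "aggregated":
        assert len(model.constraints) <= model.constraint_bound
    return model


def solve_ilp(
    rs: RunString,
    backend: MIPBackend | None = None,
    constraint_family: str = "aggregated",
) -> Selection:
    """Solve to proven optimality and decode the selection.

    Variable values above 0.5 count as selected (binary variables may come
    back as 0.9999... from floating-point backends).
    """
    if rs.n == 0:
        return make_selection(rs, ())
    model = build_ilp(rs, constraint_family)
    backend = backend or HighsBackend()
    status, values = backend.solve(model)
    if status != "optimal":
        raise ILPError(f"no proven optimum from MIP backend (status: {status})")
    indices = [i for i in range(1, rs.n + 1) if values[i - 1] > 0.5]
    return make_selection(rs, indices)


def to_lp_string(model: ILPModel) -> str:
    """Export the model in the standard LP file dialect (for debugging)."""
    lines = ["Maximize", " obj: " + " + ".join(
        f"{c} x{i}" for i, c in enumerate(model.objective, start=1)
    ), "Subject To"]
    for k, con in enumerate(model.constraints, start=1):
        terms = " + ".join(f"{coef} x{i}" for i, coef in con.coeffs)
        lines.append(f" c{k}: {terms} <= {con.rhs}")
    lines.append("Binary")
    lines.append(" " + " ".join(f"x{i}" for i in range(1, model.n + 1)))
    lines.append("End")
    return "\n".join(lines) + "\n"
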
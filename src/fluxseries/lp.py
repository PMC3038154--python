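"""Solver-neutral LP/MILP construction and solving.

Two backends share one contract: ``highs`` solves in-process through
scipy's HiGHS interface, ``glpk`` writes a CPLEX-LP file, runs the
``glpsol`` executable and parses its plain-text solution.  The file-based
route doubles as an independent cross-check of the in-process one.
"""

from __future__ import annotations

import math
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .model import Status

#: MILP time limit in seconds and MIP gap defaults; the only solver knobs
#: exposed by the contract.
MILP_TIME_LIMIT = 600.0
MIP_GAP_ABS = 1e-9
MIP_GAP_REL = 1e-6

_BINARY_ROUND_TOL = 1e-6


class SolverError(RuntimeError):
    """A backend failed in a way that is not a solution status."""


@dataclass
class Variable:
    name: str
    kind: str = "continuous"  # or "binary"
    lower: float = -math.inf
    upper: float = math.inf


@dataclass
class Constraint:
    name: str
    terms: dict[str, float]
    relation: str  # "<=", "=", ">="
    rhs: float


@dataclass
class LinearProblem:
    """An LP or MILP in variable/constraint form, order-deterministic."""

    variables: dict[str, Variable] = field(default_factory=dict)
    objective_sense: str = "MIN"
    objective_terms: dict[str, float] = field(default_factory=dict)
    constraints: list[Constraint] = field(default_factory=list)

    def add_variable(
        self,
        name: str,
        kind: str = "continuous",
        lower: float = -math.inf,
        upper: float = math.inf,
    ) -> str:
        if name in self.variables:
            raise ValueError(f"duplicate variable {name!r}")
        if kind not in ("continuous", "binary"):
            raise ValueError(f"unknown variable kind {kind!r}")
        if kind == "binary":
            lower, upper = max(lower, 0.0), min(upper, 1.0)
        self.variables[name] = Variable(name, kind, lower, upper)
        return name

    def add_constraint(
        self, name: str, terms: Mapping[str, float], relation: str, rhs: float
    ) -> None:
        if relation not in ("<=", "=", ">="):
            raise ValueError(f"unknown relation {relation!r}")
        for var in terms:
            if var not in self.variables:
                raise ValueError(f"constraint {name!r} uses undeclared {var!r}")
        self.constraints.append(Constraint(name, dict(terms), relation, rhs))

    def set_objective(self, sense: str, terms: Mapping[str, float]) -> None:
        if sense not in ("MIN", "MAX"):
            raise ValueError(f"unknown sense {sense!r}")
        for var in terms:
            if var not in self.variables:
                raise ValueError(f"objective uses undeclared variable {var!r}")
        self.objective_sense = sense
        self.objective_terms = dict(terms)

    @property
    def is_mip(self) -> bool:
        return any(v.kind == "binary" for v in self.variables.values())


@dataclass
class LPSolution:
    status: Status
    objective: float = math.nan
    values: dict[str, float] = field(default_factory=dict)


def check_solution(
    problem: LinearProblem, solution: LPSolution, tol: float = 1e-6
) -> list[str]:
    """Independent verifier: constraint violations of an OPTIMAL solution."""
    if solution.status is not Status.OPTIMAL:
        return ["solution is not OPTIMAL"]
    bad: list[str] = []
    for name, var in problem.variables.items():
        if name not in solution.values:
            bad.append(f"variable {name!r} has no value")
            continue
        x = solution.values[name]
        if x < var.lower - tol or x > var.upper + tol:
            bad.append(f"variable {name!r}={x} outside [{var.lower}, {var.upper}]")
    for con in problem.constraints:
        lhs = sum(c * solution.values.get(v, 0.0) for v, c in con.terms.items())
        ok = {
            "<=": lhs <= con.rhs + tol,
            "=": abs(lhs - con.rhs) <= tol,
            ">=": lhs >= con.rhs - tol,
        }[con.relation]
        if not ok:
            bad.append(f"constraint {con.name!r}: {lhs} {con.relation} {con.rhs}")
    return bad


# ---------------------------------------------------------------------------
# in-process backend (HiGHS via scipy)


def _solve_highs(problem: LinearProblem) -> LPSolution:
    names = list(problem.variables)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    c = np.zeros(n)
    sign = -1.0 if problem.objective_sense == "MAX" else 1.0
    for var, coeff in problem.objective_terms.items():
        c[index[var]] = sign * coeff
    lb = np.array([problem.variables[v].lower for v in names])
    ub = np.array([problem.variables[v].upper for v in names])
    integrality = np.array(
        [1 if problem.variables[v].kind == "binary" else 0 for v in names]
    )
    constraints = []
    if problem.constraints:
        rows, cols, data = [], [], []
        clo, cup = [], []
        for i, con in enumerate(problem.constraints):
            for var, coeff in con.terms.items():
                rows.append(i)
                cols.append(index[var])
                data.append(coeff)
            if con.relation == "<=":
                clo.append(-math.inf)
                cup.append(con.rhs)
            elif con.relation == ">=":
                clo.append(con.rhs)
                cup.append(math.inf)
            else:
                clo.append(con.rhs)
                cup.append(con.rhs)
        A = csr_matrix(
            (data, (rows, cols)), shape=(len(problem.constraints), n)
        )
        constraints = [LinearConstraint(A, clo, cup)]
    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options={
            "time_limit": MILP_TIME_LIMIT,
            "mip_rel_gap": MIP_GAP_REL,
        },
    )
    if res.status == 0:
        values = _rounded_values(problem, names, res.x)
        objective = sum(
            coeff * values[var] for var, coeff in problem.objective_terms.items()
        )
        return LPSolution(Status.OPTIMAL, objective, values)
    if res.status == 2:
        return LPSolution(Status.INFEASIBLE)
    if res.status == 3:
        return LPSolution(Status.UNBOUNDED)
    raise SolverError(f"HiGHS failure: status {res.status}: {res.message}")


def _rounded_values(
    problem: LinearProblem, names: list[str], x: np.ndarray
) -> dict[str, float]:
    values: dict[str, float] = {}
    for name, xi in zip(names, x):
        if problem.variables[name].kind == "binary":
            xi = 1.0 if xi > 0.5 else 0.0
        values[name] = float(xi)
    return values


# ---------------------------------------------------------------------------
# CPLEX-LP file writing and glpsol backend

# LP-format-safe names: alphanumeric kept, every other character escaped as
# "_xx" (two lowercase hex digits); a leading "v" guarantees a legal first
# character.  The map is reversible.


def sanitize_name(name: str) -> str:
    out = ["v"]
    for ch in name:
        if ch.isascii() and ch.isalnum():
            out.append(ch)
        else:
            out.append(f"_{ord(ch):02x}")
    return "".join(out)


def unsanitize_name(token: str) -> str:
    if not token.startswith("v"):
        raise ValueError(f"not a sanitized name: {token!r}")
    body = token[1:]
    out = []
    i = 0
    while i < len(body):
        if body[i] == "_":
            out.append(chr(int(body[i + 1 : i + 3], 16)))
            i += 3
        else:
            out.append(body[i])
            i += 1
    return "".join(out)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _lp_terms(terms: Mapping[str, float]) -> str:
    parts: list[str] = []
    for var, coeff in terms.items():
        tok = sanitize_name(var)
        if not parts:
            parts.append(f"{_fmt(coeff)} {tok}")
        elif coeff >= 0:
            parts.append(f"+ {_fmt(coeff)} {tok}")
        else:
            parts.append(f"- {_fmt(-coeff)} {tok}")
    return " ".join(parts)


def write_lp_file(problem: LinearProblem, path: str | Path) -> None:
    """Emit the problem in CPLEX LP format, deterministically ordered."""
    lines: list[str] = []
    lines.append("Maximize" if problem.objective_sense == "MAX" else "Minimize")
    obj = problem.objective_terms
    if not obj and problem.variables:
        # solvers reject an empty objective row; pin a zero coefficient
        first = next(iter(problem.variables))
        obj = {first: 0.0}
    lines.append(" obj: " + (_lp_terms(obj) if obj else "0 x0"))
    lines.append("Subject To")
    for i, con in enumerate(problem.constraints):
        rel = {"<=": "<=", "=": "=", ">=": ">="}[con.relation]
        lines.append(
            f" c{i}: {_lp_terms(con.terms)} {rel} {_fmt(con.rhs)}"
        )
    if not problem.constraints and problem.variables:
        # the LP dialect requires a nonempty constraint section
        first = sanitize_name(next(iter(problem.variables)))
        lines.append(f" c_void: 0 {first} >= -1")
    lines.append("Bounds")
    for name, var in problem.variables.items():
        tok = sanitize_name(name)
        lo = "-inf" if math.isinf(var.lower) else _fmt(var.lower)
        hi = "+inf" if math.isinf(var.upper) else _fmt(var.upper)
        lines.append(f" {lo} <= {tok} <= {hi}")
    binaries = [n for n, v in problem.variables.items() if v.kind == "binary"]
    if binaries:
        lines.append("Binary")
        for name in binaries:
            lines.append(f" {sanitize_name(name)}")
    lines.append("End")
    Path(path).write_text("\n".join(lines) + "\n")


_GLPSOL_STATUS = {
    "OPTIMAL": Status.OPTIMAL,
    "INTEGER OPTIMAL": Status.OPTIMAL,
    "INFEASIBLE": Status.INFEASIBLE,
    "INTEGER EMPTY": Status.INFEASIBLE,
    "UNBOUNDED": Status.UNBOUNDED,
    "INTEGER UNDEFINED": Status.INFEASIBLE,
    "UNDEFINED": Status.INFEASIBLE,
}


def read_solution_file(path: str | Path) -> LPSolution:
    """Parse a glpsol plain-text solution report."""
    text = Path(path).read_text()
    m = re.search(r"^Status:\s+(.+?)\s*$", text, re.MULTILINE)
    if not m:
        raise SolverError(f"no Status line in {path}")
    status_text = m.group(1).upper()
    status = None
    for key, val in _GLPSOL_STATUS.items():
        if key in status_text:
            status = val
            break
    if status is None:
        raise SolverError(f"unrecognized solver status {status_text!r}")
    if status is not Status.OPTIMAL:
        return LPSolution(status)
    objective = math.nan
    m = re.search(r"^Objective:\s+\S+\s*=\s*([-+0-9.eE]+)", text, re.MULTILINE)
    if m:
        objective = float(m.group(1))
    values: dict[str, float] = {}
    in_columns = False
    pending_name: Optional[str] = None
    for line in text.splitlines():
        if re.match(r"^\s*No\.\s+Column name", line):
            in_columns = True
            continue
        if in_columns:
            if re.match(r"^\s*No\.\s+Row name", line) or line.startswith("Karush"):
                break
            if re.match(r"^-+\s", line) or not line.strip():
                if values or pending_name:
                    if not line.strip() and values:
                        break
                continue
            fields = line.split()
            if pending_name is not None:
                # long names overflow onto their own line
                name, rest = pending_name, fields
                pending_name = None
            else:
                if not fields[0].isdigit():
                    continue
                if len(fields) == 2:
                    pending_name = fields[1]
                    continue
                name, rest = fields[1], fields[2:]
            # rest: [marker] status activity ...
            activity = None
            for tok in rest:
                if re.fullmatch(r"[-+]?[0-9.]+([eE][-+]?[0-9]+)?", tok):
                    activity = float(tok)
                    break
            if activity is None:
                activity = 0.0
            values[unsanitize_name(name)] = activity
    return LPSolution(status, objective, values)


def _solve_glpk(problem: LinearProblem) -> LPSolution:
    with tempfile.TemporaryDirectory(prefix="fluxseries_glpk_") as tmp:
        lp_path = Path(tmp) / "problem.lp"
        sol_path = Path(tmp) / "solution.txt"
        write_lp_file(problem, lp_path)
        cmd = ["glpsol", "--lp", str(lp_path), "-o", str(sol_path)]
        proc = subprocess.run(
            cmd, capture_output=True, text=True, timeout=MILP_TIME_LIMIT
        )
        if proc.returncode != 0 or not sol_path.exists():
            raise SolverError(
                f"glpsol failed (exit {proc.returncode}): "
                + proc.stdout[-500:]
                + proc.stderr[-500:]
            )
        # glpsol reports unboundedness only on stdout for LPs
        if "HAS UNBOUNDED SOLUTION" in proc.stdout.upper():
            return LPSolution(Status.UNBOUNDED)
        sol = read_solution_file(sol_path)
    if sol.status is Status.OPTIMAL:
        values = {
            name: (
                1.0
                if problem.variables[name].kind == "binary"
                and sol.values.get(name, 0.0) > 0.5
                else (
                    0.0
                    if problem.variables[name].kind == "binary"
                    else sol.values.get(name, 0.0)
                )
            )
            for name in problem.variables
        }
        # the report's Objective line carries more digits than the
        # column activities; prefer it
        objective = (
            sol.objective
            if sol.objective == sol.objective
            else sum(
                coeff * values[var]
                for var, coeff in problem.objective_terms.items()
            )
        )
        return LPSolution(Status.OPTIMAL, objective, values)
    return sol


_BACKENDS = {"highs": _solve_highs, "glpk": _solve_glpk}


def solve(problem: LinearProblem, backend: str = "highs") -> LPSolution:
    """Solve an LP/MILP; binary variables come back as exact 0/1."""
    if backend not in _BACKENDS:
        raise SolverError(
            f"unknown backend {backend!r}; available: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[backend](problem)
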
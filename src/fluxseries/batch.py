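"""Computation series: the upper layer over the single-solve routines.

A *simulation file* lists heterogeneous flux-balance tasks — objectives,
constraints, feasibility expectations, and evaluation expressions — and a
batch run executes them independently, producing an evaluation report
(one PASS/FAIL row per simulation) plus per-simulation solution files.
The same machinery drives the curation operations: flux variability
analysis, leak analysis, and pruning to the functional subnetwork.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import fabase
from .fabase import (
    ConstraintSet,
    Objective,
    ThermoConfig,
    effective_bounds,
    _base_problem,
    _flux_var,
)
from .lp import solve
from .model import (
    AlgorithmParams,
    FluxDistribution,
    Network,
    Status,
    add_sink,
    close_boundary,
)
from .modelio import write_val

OPTIMIZATION_CALLS = (
    "flux-min",
    "fba-max",
    "moma",
    "room",
    "fitness",
    "expression",
    "compute-FBA-T-c",
)


# ---------------------------------------------------------------------------
# evaluation expressions


class ExpressionError(ValueError):
    pass


@dataclass
class _Comparison:
    reaction: str
    op: str
    value: float
    absolute: bool = False

    def evaluate(self, fluxes: Mapping[str, float]) -> bool:
        if self.reaction not in fluxes:
            raise ExpressionError(f"unknown reaction {self.reaction!r}")
        x = fluxes[self.reaction]
        if self.absolute:
            x = abs(x)
        return {
            "<": x < self.value,
            "<=": x <= self.value,
            "==": x == self.value,
            ">=": x >= self.value,
            ">": x > self.value,
        }[self.op]

    def reaction_ids(self) -> set[str]:
        return {self.reaction}


@dataclass
class _BoolOp:
    op: str  # "and" | "or"
    left: object
    right: object

    def evaluate(self, fluxes: Mapping[str, float]) -> bool:
        if self.op == "and":
            return self.left.evaluate(fluxes) and self.right.evaluate(fluxes)
        return self.left.evaluate(fluxes) or self.right.evaluate(fluxes)

    def reaction_ids(self) -> set[str]:
        return self.left.reaction_ids() | self.right.reaction_ids()


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op><=|>=|==|<|>)"
    r"|(?P<num>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(
                    f"cannot tokenize {text[pos:].strip()!r}"
                )
            break
        pos = m.end()
        for kind in ("lpar", "rpar", "op", "num", "word"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val))
                break
    return tokens


class _Parser:
    """Recursive descent for:  expr := term ('or' term)*;
    term := factor ('and' factor)*;
    factor := '(' expr ')' | comparison;
    comparison := ['abs' '('] RXN [')'] OP NUMBER."""

    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind: str, value: Optional[str] = None):
        k, v = self.take()
        if k != kind or (value is not None and v != value):
            raise ExpressionError(f"expected {value or kind}, got {v!r}")
        return v

    def parse(self):
        node = self.expr()
        if self.i != len(self.tokens):
            raise ExpressionError(f"trailing input near {self.peek()[1]!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == ("word", "or"):
            self.take()
            node = _BoolOp("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("word", "and"):
            self.take()
            node = _BoolOp("and", node, self.factor())
        return node

    def factor(self):
        kind, value = self.peek()
        if kind == "lpar":
            self.take()
            node = self.expr()
            self.expect("rpar")
            return node
        if kind != "word":
            raise ExpressionError(f"expected reaction or '(', got {value!r}")
        self.take()
        absolute = False
        rxn = value
        if value == "abs" and self.peek()[0] == "lpar":
            self.take()
            absolute = True
            rxn = self.expect("word")
            self.expect("rpar")
        op = self.expect("op")
        num = float(self.expect("num"))
        return _Comparison(rxn, op, num, absolute)


@dataclass
class EvalExpression:
    """A side-condition on a flux distribution.

    Single-flux comparisons (optionally on the absolute value) combined
    with ``and``/``or`` and parentheses.  Comparisons use the exact
    solver values, with no zero-tolerance snapping.
    """

    text: str
    _ast: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._ast = _Parser(_tokenize(self.text)).parse()

    def evaluate(self, solution: FluxDistribution) -> bool:
        if not solution.optimal:
            raise ValueError("cannot evaluate a non-OPTIMAL solution")
        return self._ast.evaluate(solution.fluxes)

    def reaction_ids(self) -> set[str]:
        return self._ast.reaction_ids()


def evaluate(expr: "EvalExpression | str", solution: FluxDistribution) -> bool:
    if isinstance(expr, str):
        expr = EvalExpression(expr)
    return expr.evaluate(solution)


# ---------------------------------------------------------------------------
# simulation files


@dataclass
class SimulationSpec:
    """One entry of a computation series."""

    sim_id: str
    objective: Optional[Objective] = None
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    expect: str = "FEASIBLE"
    checks: list[EvalExpression] = field(default_factory=list)
    comment: str = ""


class SimulationSyntaxError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _parse_objective_line(rest: str, line_no: int) -> Objective:
    tokens = rest.split()
    if not tokens:
        raise SimulationSyntaxError(line_no, "empty OBJECTIVE")
    head = tokens[0]
    if head in ("flux-min", "min-flux"):
        return Objective(kind="MIN_WEIGHTED_FLUX")
    if head == "max":
        # "max R1", "max 2 R1 + 1 R2"
        coeffs: dict[str, float] = {}
        terms = " ".join(tokens[1:]).split("+")
        for chunk in terms:
            parts = chunk.split()
            if len(parts) == 1:
                coeffs[parts[0]] = coeffs.get(parts[0], 0.0) + 1.0
            elif len(parts) == 2:
                try:
                    c = float(parts[0])
                except ValueError:
                    raise SimulationSyntaxError(
                        line_no, f"bad coefficient {parts[0]!r}"
                    )
                coeffs[parts[1]] = coeffs.get(parts[1], 0.0) + c
            else:
                raise SimulationSyntaxError(line_no, f"bad term {chunk!r}")
        if not coeffs:
            raise SimulationSyntaxError(line_no, "OBJECTIVE max needs terms")
        return Objective(kind="MAX_LINEAR", coefficients=coeffs)
    raise SimulationSyntaxError(line_no, f"unknown objective {head!r}")


def _parse_constraint_line(
    rest: str, cs: ConstraintSet, line_no: int
) -> None:
    tokens = rest.split()
    if not tokens:
        raise SimulationSyntaxError(line_no, "empty CONSTRAINT")
    if tokens[0] == "knockout":
        if len(tokens) != 2:
            raise SimulationSyntaxError(line_no, "knockout takes one reaction")
        cs.knockouts.add(tokens[1])
        return
    if tokens[0] == "inhibit":
        if len(tokens) != 3:
            raise SimulationSyntaxError(
                line_no, "inhibit takes a reaction and an alpha"
            )
        cs.inhibitions[tokens[1]] = float(tokens[2])
        return
    m = re.fullmatch(
        r"(\S+)\s*(=|<=|>=)\s*([-+0-9.eE]+)", rest.strip()
    )
    if m:
        rid, op, val = m.group(1), m.group(2), float(m.group(3))
        if op == "=":
            cs.flux_fixes[rid] = val
        elif op == ">=":
            lo, hi = cs.flux_ranges.get(rid, (float("-inf"), float("inf")))
            cs.flux_ranges[rid] = (max(lo, val), hi)
        else:
            lo, hi = cs.flux_ranges.get(rid, (float("-inf"), float("inf")))
            cs.flux_ranges[rid] = (lo, min(hi, val))
        return
    m = re.fullmatch(
        r"(\S+)\s+in\s*\[\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*\]",
        rest.strip(),
    )
    if m:
        cs.flux_ranges[m.group(1)] = (float(m.group(2)), float(m.group(3)))
        return
    raise SimulationSyntaxError(line_no, f"cannot parse constraint {rest!r}")


def parse_simulations(
    path: str | Path, dialect: str = "canonical"
) -> list[SimulationSpec]:
    """Read a simulation description file.

    The *canonical* dialect is the block grammar
    ``SIMULATION <id> … OBJECTIVE … CONSTRAINT … EXPECT … CHECK … END``
    with ``#`` comments.  The *fasimu-native* dialect is a tolerant
    line-oriented reader for legacy series files: one record per
    non-comment line, ``<id> [<rxn><op><num> …] [expect=infeasible]``.
    """
    path = Path(path)
    if dialect == "canonical":
        return _parse_canonical(path)
    if dialect == "fasimu-native":
        return _parse_native(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_canonical(path: Path) -> list[SimulationSpec]:
    specs: list[SimulationSpec] = []
    seen: set[str] = set()
    current: Optional[SimulationSpec] = None
    open_line = 0
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        keyword, _, rest = line.partition(" ")
        rest = rest.strip()
        if keyword == "SIMULATION":
            if current is not None:
                raise SimulationSyntaxError(
                    line_no, f"SIMULATION inside unterminated block (line {open_line})"
                )
            if not rest:
                raise SimulationSyntaxError(line_no, "missing simulation id")
            if rest in seen:
                raise SimulationSyntaxError(line_no, f"duplicate sim_id {rest!r}")
            seen.add(rest)
            current = SimulationSpec(sim_id=rest)
            open_line = line_no
        elif current is None:
            raise SimulationSyntaxError(
                line_no, f"{keyword} outside a SIMULATION block"
            )
        elif keyword == "COMMENT":
            current.comment = (
                current.comment + " " + rest if current.comment else rest
            )
        elif keyword == "OBJECTIVE":
            current.objective = _parse_objective_line(rest, line_no)
        elif keyword == "CONSTRAINT":
            _parse_constraint_line(rest, current.constraints, line_no)
        elif keyword == "EXPECT":
            if rest not in ("FEASIBLE", "INFEASIBLE"):
                raise SimulationSyntaxError(
                    line_no, f"EXPECT must be FEASIBLE or INFEASIBLE, got {rest!r}"
                )
            current.expect = rest
        elif keyword == "CHECK":
            try:
                current.checks.append(EvalExpression(rest))
            except ExpressionError as exc:
                raise SimulationSyntaxError(line_no, str(exc))
        elif keyword == "END":
            specs.append(current)
            current = None
        else:
            raise SimulationSyntaxError(line_no, f"unknown keyword {keyword!r}")
    if current is not None:
        raise SimulationSyntaxError(
            open_line, f"SIMULATION {current.sim_id!r} missing END"
        )
    return specs


def _parse_native(path: Path) -> list[SimulationSpec]:
    specs: list[SimulationSpec] = []
    seen: set[str] = set()
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("//"):
            continue
        fields = line.split()
        sim_id = fields[0]
        if sim_id in seen:
            raise SimulationSyntaxError(line_no, f"duplicate sim_id {sim_id!r}")
        seen.add(sim_id)
        spec = SimulationSpec(sim_id=sim_id)
        for token in fields[1:]:
            if token.lower() in ("expect=infeasible", "infeasible"):
                spec.expect = "INFEASIBLE"
                continue
            m = re.fullmatch(r"(\S+?)(=|<=|>=)([-+0-9.eE]+)", token)
            if m:
                _parse_constraint_line(
                    f"{m.group(1)} {m.group(2)} {m.group(3)}",
                    spec.constraints,
                    line_no,
                )
            # unrecognized tokens are tolerated (documentation columns)
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# batch runs


@dataclass
class BatchRow:
    sim_id: str
    status: str
    objective: float
    expected: str
    passed: bool
    checks_failed: list[str] = field(default_factory=list)


@dataclass
class BatchReport:
    rows: list[BatchRow] = field(default_factory=list)

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.rows)

    @property
    def n_total(self) -> int:
        return len(self.rows)

    def to_tsv(self) -> str:
        lines = ["sim_id\tstatus\tobjective\texpected\tpassed\tchecks_failed"]
        for r in self.rows:
            obj = "" if r.objective != r.objective else f"{r.objective:.6g}"
            failed = ";".join(r.checks_failed) if r.checks_failed else "-"
            lines.append(
                f"{r.sim_id}\t{r.status}\t{obj}\t{r.expected}"
                f"\t{'PASS' if r.passed else 'FAIL'}\t{failed}"
            )
        return "\n".join(lines) + "\n"


def _dispatch(
    net: Network,
    spec: SimulationSpec,
    optimization_call: str,
    thermo: Optional[ThermoConfig],
    params: AlgorithmParams,
    reference: Optional[FluxDistribution],
    backend: str,
) -> FluxDistribution:
    obj = spec.objective
    call = optimization_call
    if obj is not None and call in ("flux-min", "fba-max"):
        call = {"MIN_WEIGHTED_FLUX": "flux-min", "MAX_LINEAR": "fba-max"}.get(
            obj.kind, call
        )
    if call == "flux-min":
        return fabase.flux_minimization(
            net, spec.constraints, params, backend=backend
        )
    if call == "fba-max":
        if obj is None or obj.kind != "MAX_LINEAR":
            raise ValueError(
                f"simulation {spec.sim_id!r}: fba-max needs a MAX objective"
            )
        return fabase.fba_maximize(
            net, obj.coefficients or {}, spec.constraints, params, backend=backend
        )
    if call == "moma":
        if reference is None:
            raise ValueError("moma requires a reference distribution")
        return fabase.moma_l1(
            net, reference, spec.constraints, params, backend=backend
        )
    if call == "room":
        if reference is None:
            raise ValueError("room requires a reference distribution")
        return fabase.room(
            net, reference, spec.constraints, params, backend=backend
        )
    if call == "fitness":
        if obj is None or obj.targets is None:
            raise ValueError("fitness requires an objective with targets")
        return fabase.fitness_maximization(
            net, obj.targets, None, spec.constraints, params, backend=backend
        )
    if call == "expression":
        if obj is None or obj.expression_states is None:
            raise ValueError("expression call requires expression states")
        dist, _ = fabase.expression_match(
            net, obj.expression_states, spec.constraints, params, backend=backend
        )
        return dist
    if call == "compute-FBA-T-c":
        return fabase.compute_fba_t_c(
            net, obj, spec.constraints, thermo, params, backend=backend
        )
    raise ValueError(f"unknown optimization_call {call!r}")


def run_batch(
    net: Network,
    specs: Sequence[SimulationSpec],
    optimization_call: str = "flux-min",
    thermo: Optional[ThermoConfig] = None,
    params: Optional[AlgorithmParams] = None,
    reference: Optional[FluxDistribution] = None,
    out_dir: Optional[str | Path] = None,
    backend: str = "highs",
    log=None,
) -> tuple[BatchReport, dict[str, FluxDistribution]]:
    """Run every simulation independently and evaluate the outcomes.

    A row PASSes iff the feasibility expectation is met and, for OPTIMAL
    results, every CHECK expression holds.  An INFEASIBLE result is a
    PASS when the spec expects it (non-existence tests); an unexpected
    UNBOUNDED status always fails.  Individual solver failures are
    recorded in their row and never abort the batch.  With ``out_dir``
    the evaluation TSV, one val file per optimal simulation, and a
    combined flux TSV are written there.
    """
    if optimization_call not in OPTIMIZATION_CALLS:
        raise ValueError(f"unknown optimization_call {optimization_call!r}")
    params = params or AlgorithmParams()
    report = BatchReport()
    solutions: dict[str, FluxDistribution] = {}
    for spec in specs:
        t0 = time.monotonic()
        try:
            dist = _dispatch(
                net, spec, optimization_call, thermo, params, reference, backend
            )
        except Exception as exc:  # individual failures never abort the batch
            report.rows.append(
                BatchRow(
                    spec.sim_id, "ERROR", float("nan"), spec.expect, False,
                    [f"error: {exc}"],
                )
            )
            continue
        solutions[spec.sim_id] = dist
        failed: list[str] = []
        if dist.status is Status.OPTIMAL:
            for check in spec.checks:
                try:
                    ok = check.evaluate(dist)
                except ExpressionError as exc:
                    ok = False
                    failed.append(f"{check.text} [{exc}]")
                    continue
                if not ok:
                    failed.append(check.text)
            passed = spec.expect == "FEASIBLE" and not failed
        elif dist.status is Status.INFEASIBLE:
            passed = spec.expect == "INFEASIBLE"
        else:  # UNBOUNDED is never what a curation test wants
            passed = False
        report.rows.append(
            BatchRow(
                spec.sim_id,
                dist.status.value,
                dist.objective_value,
                spec.expect,
                passed,
                failed,
            )
        )
        if log is not None:
            log(
                f"{spec.sim_id}: {dist.status.value} "
                f"objective={dist.objective_value:.6g} "
                f"({time.monotonic() - t0:.2f} s)"
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "evaluation.tsv").write_text(report.to_tsv())
        combined = ["reaction\t" + "\t".join(
            s.sim_id for s in specs if solutions.get(s.sim_id, _NOPT).optimal
        )]
        optimal_ids = [
            s.sim_id for s in specs if solutions.get(s.sim_id, _NOPT).optimal
        ]
        for sid in optimal_ids:
            write_val(solutions[sid], net, out / f"{sid}.val")
        for rid in net.reactions:
            combined.append(
                rid + "\t" + "\t".join(
                    f"{solutions[sid].fluxes[rid]:.6g}" for sid in optimal_ids
                )
            )
        (out / "solutions.tsv").write_text("\n".join(combined) + "\n")
    return report, solutions


_NOPT = FluxDistribution(Status.INFEASIBLE)


# ---------------------------------------------------------------------------
# flux variability analysis


@dataclass
class VariabilityResult:
    """Per-reaction flux ranges under the given constraints."""

    ranges: dict[str, tuple[float, float]]
    gamma: float = 1.0
    base_objective: Optional[float] = None


def fva(
    net: Network,
    constraints: Optional[ConstraintSet] = None,
    base_objective: Optional[Mapping[str, float]] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> VariabilityResult:
    """Flux variability analysis: 2·|reactions| LPs (+1 for the base).

    With a base objective c the constraint ``c·v ≥ γ·opt`` (γ =
    ``fva_gamma``) restricts the sweep to near-optimal flux states.
    """
    params = params or AlgorithmParams()
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        raise ValueError("constraint set is contradictory")
    base_value: Optional[float] = None
    if base_objective is not None:
        base = fabase.fba_maximize(
            net, base_objective, constraints, params, backend=backend
        )
        if not base.optimal:
            raise ValueError(
                f"base objective is {base.status.value}; cannot sweep"
            )
        base_value = base.objective_value
    ranges: dict[str, tuple[float, float]] = {}
    for rid in net.reactions:
        lohi = []
        for sense in ("MIN", "MAX"):
            prob = _base_problem(net, bounds)
            if base_value is not None:
                prob.add_constraint(
                    "near_optimal",
                    {_flux_var(r): c for r, c in base_objective.items()},
                    ">=",
                    params.fva_gamma * base_value,
                )
            prob.set_objective(sense, {_flux_var(rid): 1.0})
            sol = solve(prob, backend)
            if sol.status is not Status.OPTIMAL:
                raise ValueError(
                    f"FVA subproblem for {rid!r} is {sol.status.value}"
                )
            lohi.append(sol.objective)
        ranges[rid] = (lohi[0], lohi[1])
    return VariabilityResult(ranges, params.fva_gamma, base_value)


# ---------------------------------------------------------------------------
# leak analysis


def leak_analysis(
    net: Network,
    params: Optional[AlgorithmParams] = None,
    mode: str = "production",
    backend: str = "highs",
) -> list[tuple[str, float]]:
    """Metabolites producible from nothing (stoichiometric inconsistencies).

    All exchanges are closed in both directions; each internal metabolite
    gets a probe drain whose flux is maximized.  A positive optimum means
    the metabolite leaks.  ``mode="consumption"`` probes the reverse
    question (absorbable into nothing) and is off the default path.
    Returns ``(metabolite id, maximal leak rate)`` sorted by id.
    """
    if mode not in ("production", "consumption"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or AlgorithmParams()
    closed = close_boundary(net, "all")
    leaks: list[tuple[str, float]] = []
    for mid in sorted(closed.internal_metabolite_ids()):
        probed, sink_id = add_sink(closed, mid)
        if mode == "consumption":
            # flip the drain into a supply: can the net absorb M from nothing?
            probed.reactions[sink_id].stoichiometry[mid] = 1.0
        result = fabase.fba_maximize(
            probed, {sink_id: 1.0}, None, params, backend=backend
        )
        if result.optimal and result.objective_value > params.zero_tol:
            leaks.append((mid, result.objective_value))
        elif result.status is Status.UNBOUNDED:  # pragma: no cover - capped sinks
            leaks.append((mid, float("inf")))
    return leaks


# ---------------------------------------------------------------------------
# pruning to the functional subnetwork


def _restrict_network(net: Network, keep: set[str]) -> Network:
    """Sub-network of the kept reactions plus the metabolites they touch."""
    used_mets = {
        mid
        for rid in keep
        for mid in net.reactions[rid].stoichiometry
    }
    sub = Network(name=net.name + "_pruned" if net.name else "pruned")
    for mid, met in net.metabolites.items():
        if mid in used_mets:
            sub.add_metabolite(
                type(met)(met.id, met.name, met.compartment, met.is_boundary)
            )
    for rid, rxn in net.reactions.items():
        if rid in keep:
            sub.add_reaction(rxn.copy())
    return sub


def _restrict_constraints(
    cs: ConstraintSet, sub: Network
) -> Optional[ConstraintSet]:
    """Project a constraint set onto a sub-network.

    Constraints on removed reactions: knockouts and inhibitions become
    vacuous; fixes/ranges are vacuous iff they admit zero flux, else the
    spec cannot hold on the sub-network (returns None)."""
    out = ConstraintSet()
    for rid, val in cs.flux_fixes.items():
        if rid in sub.reactions:
            out.flux_fixes[rid] = val
        elif abs(val) > 1e-12:
            return None
    for rid, (lo, hi) in cs.flux_ranges.items():
        if rid in sub.reactions:
            out.flux_ranges[rid] = (lo, hi)
        elif not (lo <= 0.0 <= hi):
            return None
    out.knockouts = {r for r in cs.knockouts if r in sub.reactions}
    out.inhibitions = {
        r: a for r, a in cs.inhibitions.items() if r in sub.reactions
    }
    return out


def prune_network(
    net: Network,
    specs: Sequence[SimulationSpec],
    optimization_call: str = "flux-min",
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> tuple[Network, list[str]]:
    """Prune to the functional subnetwork defined by a simulation series.

    Phase 1 computes a flux-minimal solution for every spec and keeps the
    union U of reactions carrying flux above zero_tol.  Phase 2 verifies
    every spec on the restriction to U; a spec that became infeasible is
    re-solved on the full network with weights biased 1000:1 against
    non-U reactions and its support added to U, until the restriction
    supports all (originally feasible) specs.  Specs infeasible on the
    full network are reported and skipped.  Returns the restricted
    network and a log of removals and warnings.
    """
    if not specs:
        raise ValueError("pruning needs at least one simulation spec")
    params = params or AlgorithmParams()
    log: list[str] = []
    support: set[str] = set()
    feasible_specs: list[SimulationSpec] = []
    for spec in specs:
        sol = fabase.flux_minimization(
            net, spec.constraints, params, backend=backend
        )
        if not sol.optimal:
            log.append(
                f"warning: {spec.sim_id} is {sol.status.value} on the full "
                "network; skipped"
            )
            continue
        feasible_specs.append(spec)
        support |= {
            rid for rid, v in sol.fluxes.items() if abs(v) > params.zero_tol
        }
    for _round in range(len(feasible_specs) + 1):
        sub = _restrict_network(net, support)
        broken: list[SimulationSpec] = []
        for spec in feasible_specs:
            cs = _restrict_constraints(spec.constraints, sub)
            sol = (
                fabase.flux_minimization(sub, cs, params, backend=backend)
                if cs is not None
                else None
            )
            if sol is None or not sol.optimal:
                broken.append(spec)
        if not broken:
            break
        for spec in broken:
            biased = net.copy()
            for rid, rxn in biased.reactions.items():
                if rid not in support:
                    rxn.weight = rxn.weight * 1000.0
            sol = fabase.flux_minimization(
                biased, spec.constraints, params, backend=backend
            )
            if not sol.optimal:  # pragma: no cover - feasible on full net
                log.append(
                    f"warning: {spec.sim_id} unexpectedly "
                    f"{sol.status.value} on re-solve"
                )
                continue
            added = {
                rid for rid, v in sol.fluxes.items()
                if abs(v) > params.zero_tol
            } - support
            support |= added
            log.append(
                f"repair: {spec.sim_id} re-added {len(added)} reactions"
            )
    pruned = _restrict_network(net, support)
    removed = [rid for rid in net.reactions if rid not in support]
    for rid in removed:
        log.append(f"removed: {rid}")
    return pruned, log


def species_count(net: Network) -> tuple[int, int]:
    """(compartment-stripped species, localized metabolites).

    A localized metabolite is one (species, compartment) pair; species
    identity is the compartment-stripped name."""
    localized = len(net.metabolites)
    stripped = {
        (m.name or m.id).rsplit("[", 1)[0].removesuffix(f"_{m.compartment}")
        for m in net.metabolites.values()
    }
    return len(stripped), localized
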
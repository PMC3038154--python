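"""Single flux-balance optimizations: the basic layer.

Every function here builds and solves exactly one LP or MILP over the
steady-state flux polytope ``{v : S·v = 0, lb ≤ v ≤ ub}`` of a network,
optionally narrowed by a :class:`ConstraintSet` (fixed fluxes, ranges,
knockouts, partial enzyme inhibitions).

Objectives
----------
- linear maximization (biomass-style FBA),
- weighted flux minimization  min Σ w_i |v_i|,
- L1 minimization of metabolic adjustment (MOMA) against a reference,
- ROOM: minimal number of fluxes leaving a tolerance window around the
  reference (MILP),
- fitness maximization under partial enzyme inhibition,
- expression-profile matching (iMAT-style two-stage MILP),
- metabolic flux analysis: least-absolute-deviation fit to measured rates,
- any of the above under the concentration-based thermodynamic
  feasibility constraint (MILP with explicit ln-concentration variables).

All absolute values are linearized with nonnegative split variables; no
indicator constraints are used, so every LP/MILP backend stays usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .lp import LinearProblem, LPSolution, solve
from .model import (
    AlgorithmParams,
    FluxDistribution,
    Network,
    Status,
)

OBJECTIVE_KINDS = (
    "MAX_LINEAR",
    "MIN_WEIGHTED_FLUX",
    "MOMA_L1",
    "ROOM",
    "FITNESS",
    "EXPRESSION_MATCH",
    "MFA_FIT",
)


@dataclass
class Objective:
    """Descriptor of a metabolic target function.

    Exactly the fields demanded by ``kind`` must be present:
    ``coefficients`` for MAX_LINEAR, ``reference`` for MOMA_L1/ROOM,
    ``targets`` for FITNESS, ``expression_states`` for EXPRESSION_MATCH,
    ``measurements`` for MFA_FIT.  MIN_WEIGHTED_FLUX needs nothing beyond
    the per-reaction weights stored on the network.
    """

    kind: str = "MIN_WEIGHTED_FLUX"
    coefficients: Optional[dict[str, float]] = None
    reference: Optional[FluxDistribution] = None
    targets: Optional[dict[str, tuple[float, float]]] = None
    expression_states: Optional[dict[str, str]] = None
    measurements: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        required = {
            "MAX_LINEAR": "coefficients",
            "MOMA_L1": "reference",
            "ROOM": "reference",
            "FITNESS": "targets",
            "EXPRESSION_MATCH": "expression_states",
            "MFA_FIT": "measurements",
        }
        need = required.get(self.kind)
        if need is not None and getattr(self, need) is None:
            raise ValueError(f"objective kind {self.kind} requires {need}")


@dataclass
class ConstraintSet:
    """Additional per-simulation narrowing of the flux space."""

    flux_fixes: dict[str, float] = field(default_factory=dict)
    flux_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    knockouts: set[str] = field(default_factory=set)
    inhibitions: dict[str, float] = field(default_factory=dict)

    def validate(self, net: Network) -> None:
        for rid in (
            list(self.flux_fixes)
            + list(self.flux_ranges)
            + list(self.knockouts)
            + list(self.inhibitions)
        ):
            if rid not in net.reactions:
                raise KeyError(f"constraint references unknown reaction {rid!r}")
        for rid, alpha in self.inhibitions.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"inhibition of {rid!r}: alpha {alpha} not in [0,1]")
        for rid, (lo, hi) in self.flux_ranges.items():
            if lo > hi:
                raise ValueError(f"range for {rid!r}: {lo} > {hi}")


@dataclass
class ThermoConfig:
    """Thermodynamic data for the concentration-based feasibility MILP.

    rt
        R·T in kJ/mol; the default 2.577 corresponds to 310 K.
    dg0
        standard-transformed Gibbs reaction energies ΔG°' in kJ/mol per
        reaction; missing entries default to 0, which reduces the
        constraint to the pure loop law.
    lnc_bounds
        per-metabolite bounds on ln(c / (mol/l)); the default window
        [ln 1e-5, ln 1e-2] spans typical intracellular concentrations.
    margin
        surrogate for the strict inequality ΔG' < 0: active forward flux
        requires ΔG' ≤ −margin (kJ/mol).
    big_m_G
        big-M for the energy couplings (kJ/mol); must dominate any
        attainable |ΔG'|.
    """

    rt: float = 2.577
    dg0: dict[str, float] = field(default_factory=dict)
    lnc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_lnc: tuple[float, float] = (math.log(1e-5), math.log(1e-2))
    margin: float = 1e-3
    big_m_G: float = 1e4

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        lo, hi = self.default_lnc
        if lo > hi:
            raise ValueError("default_lnc inverted")
        for mid, (a, b) in self.lnc_bounds.items():
            if a > b:
                raise ValueError(f"lnc bounds for {mid!r} inverted")

    def lnc_range(self, metabolite_id: str) -> tuple[float, float]:
        return self.lnc_bounds.get(metabolite_id, self.default_lnc)


# ---------------------------------------------------------------------------
# problem assembly helpers


def effective_bounds(
    net: Network, constraints: Optional[ConstraintSet]
) -> Optional[dict[str, tuple[float, float]]]:
    """Per-reaction bounds after applying the constraint set.

    Returns ``None`` when some intersection is empty, which the callers
    report as INFEASIBLE (a first-class outcome, not an error).
    """
    bounds: dict[str, tuple[float, float]] = {
        rid: (rxn.lower_bound, rxn.upper_bound)
        for rid, rxn in net.reactions.items()
    }
    if constraints is None:
        return bounds
    constraints.validate(net)
    for rid in constraints.knockouts:
        bounds[rid] = (0.0, 0.0)
    for rid, alpha in constraints.inhibitions.items():
        lo, hi = bounds[rid]
        cap = alpha * max(abs(net.reactions[rid].lower_bound),
                          abs(net.reactions[rid].upper_bound))
        bounds[rid] = (max(lo, -cap), min(hi, cap))
    for rid, (rlo, rhi) in constraints.flux_ranges.items():
        lo, hi = bounds[rid]
        bounds[rid] = (max(lo, rlo), min(hi, rhi))
    for rid, val in constraints.flux_fixes.items():
        lo, hi = bounds[rid]
        bounds[rid] = (max(lo, val), min(hi, val))
    for rid, (lo, hi) in bounds.items():
        if lo > hi + 1e-12:
            return None
    return bounds


def _flux_var(rid: str) -> str:
    return f"v[{rid}]"


def _base_problem(
    net: Network, bounds: dict[str, tuple[float, float]]
) -> LinearProblem:
    """Flux variables plus steady-state mass balance for internal metabolites."""
    prob = LinearProblem()
    for rid in net.reactions:
        lo, hi = bounds[rid]
        prob.add_variable(_flux_var(rid), lower=lo, upper=hi)
    balance: dict[str, dict[str, float]] = {
        mid: {} for mid in net.internal_metabolite_ids()
    }
    for rid, rxn in net.reactions.items():
        for mid, coeff in rxn.stoichiometry.items():
            if mid in balance:
                balance[mid][_flux_var(rid)] = (
                    balance[mid].get(_flux_var(rid), 0.0) + coeff
                )
    for mid, terms in balance.items():
        if terms:
            prob.add_constraint(f"mass[{mid}]", terms, "=", 0.0)
    return prob


def _add_abs_split(
    prob: LinearProblem,
    rid: str,
    center: float,
    tag: str,
    span: float,
) -> tuple[str, str]:
    """Variables p, n ≥ 0 with v − p + n = center, so p + n ≥ |v − center|."""
    p = prob.add_variable(f"{tag}+[{rid}]", lower=0.0, upper=span)
    n = prob.add_variable(f"{tag}-[{rid}]", lower=0.0, upper=span)
    prob.add_constraint(
        f"{tag}[{rid}]",
        {_flux_var(rid): 1.0, p: -1.0, n: 1.0},
        "=",
        center,
    )
    return p, n


def _extract_fluxes(net: Network, sol: LPSolution) -> dict[str, float]:
    return {rid: sol.values[_flux_var(rid)] for rid in net.reactions}


def _infeasible() -> FluxDistribution:
    return FluxDistribution(Status.INFEASIBLE)


def _span(bounds: dict[str, tuple[float, float]], rid: str) -> float:
    lo, hi = bounds[rid]
    return max(abs(lo), abs(hi)) * 2 + 1.0


# ---------------------------------------------------------------------------
# the optimizations


def fba_maximize(
    net: Network,
    coefficients: Mapping[str, float],
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Maximize a linear objective c·v (biomass-style FBA)."""
    for rid in coefficients:
        if rid not in net.reactions:
            raise KeyError(f"objective references unknown reaction {rid!r}")
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    prob.set_objective(
        "MAX", {_flux_var(rid): c for rid, c in coefficients.items()}
    )
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), sol.objective
    )


def flux_minimization(
    net: Network,
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Weighted flux minimization: min Σ w_i |v_i| over the flux polytope.

    The reported objective is the weighted absolute flux sum.  With no
    constraints forcing activity the zero flux is trivially optimal.
    INFEASIBLE is the producibility-test outcome, not an exception.
    """
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    obj: dict[str, float] = {}
    for rid, rxn in net.reactions.items():
        p, n = _add_abs_split(prob, rid, 0.0, "abs", _span(bounds, rid))
        obj[p] = rxn.weight
        obj[n] = rxn.weight
    prob.set_objective("MIN", obj)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), sol.objective
    )


def moma_l1(
    net: Network,
    reference: FluxDistribution,
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """L1 minimization of metabolic adjustment.

    Finds the feasible flux vector of the (perturbed) network closest to
    the reference distribution in the L1 norm; the objective value is
    that distance.  With a zero reference this coincides with unit-weight
    flux minimization.
    """
    if not reference.optimal:
        raise ValueError("reference distribution must be OPTIMAL")
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    obj: dict[str, float] = {}
    for rid in net.reactions:
        ref = reference.fluxes.get(rid, 0.0)
        span = _span(bounds, rid) + abs(ref)
        p, n = _add_abs_split(prob, rid, ref, "dev", span)
        obj[p] = 1.0
        obj[n] = 1.0
    prob.set_objective("MIN", obj)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), sol.objective
    )


def room(
    net: Network,
    reference: FluxDistribution,
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Regulatory on/off minimization: MILP minimizing the number of
    significantly changed fluxes.

    A flux counts as unchanged when it stays inside the window
    ``v_ref ± (δ·|v_ref| + ε)``; the binary y_i relaxes reaction i to its
    full bounds at cost 1.  The objective value is the count of changed
    fluxes.
    """
    if not reference.optimal:
        raise ValueError("reference distribution must be OPTIMAL")
    params = params or AlgorithmParams()
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    obj: dict[str, float] = {}
    for rid in net.reactions:
        lo, hi = bounds[rid]
        ref = reference.fluxes.get(rid, 0.0)
        delta = params.room_delta * abs(ref) + params.room_epsilon
        y = prob.add_variable(f"y[{rid}]", kind="binary")
        obj[y] = 1.0
        # y=0 keeps v within the window; y=1 relaxes to the bounds
        m_up = max(0.0, hi - (ref + delta))
        m_dn = max(0.0, (ref - delta) - lo)
        prob.add_constraint(
            f"room_up[{rid}]",
            {_flux_var(rid): 1.0, y: -m_up},
            "<=",
            ref + delta,
        )
        prob.add_constraint(
            f"room_dn[{rid}]",
            {_flux_var(rid): 1.0, y: m_dn},
            ">=",
            ref - delta,
        )
    prob.set_objective("MIN", obj)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), round(sol.objective)
    )


def fitness_maximization(
    net: Network,
    targets: Mapping[str, tuple[float, float]],
    inhibitions: Optional[Mapping[str, float]] = None,
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Fitness of a partially inhibited enzyme state.

    ``targets`` maps reaction id → (weight, reference rate): each target k
    contributes its satisfaction f_k = min(1, v_k / ref_k), capped to
    [0, 1]; the fitness F = Σ w̄_k f_k with weights normalized to sum 1 is
    maximized and reported, so F ∈ [0, 1] (1 = all functions at their
    reference rate).  ``inhibitions`` maps reaction id → α ∈ [0, 1]; an
    inhibited reaction is capped at α times its normal bound magnitude.
    """
    if not targets:
        raise ValueError("at least one target is required")
    for rid, (_, ref) in targets.items():
        if rid not in net.reactions:
            raise KeyError(f"target references unknown reaction {rid!r}")
        if ref == 0:
            raise ValueError(f"target {rid!r} has zero reference rate")
    cs = ConstraintSet(
        flux_fixes=dict(constraints.flux_fixes) if constraints else {},
        flux_ranges=dict(constraints.flux_ranges) if constraints else {},
        knockouts=set(constraints.knockouts) if constraints else set(),
        inhibitions={
            **(dict(constraints.inhibitions) if constraints else {}),
            **(dict(inhibitions) if inhibitions else {}),
        },
    )
    bounds = effective_bounds(net, cs)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    total_w = sum(w for w, _ in targets.values())
    if total_w <= 0:
        raise ValueError("target weights must sum to a positive value")
    obj: dict[str, float] = {}
    for rid, (w, ref) in targets.items():
        f = prob.add_variable(f"fit[{rid}]", lower=0.0, upper=1.0)
        # f ≤ v/ref  ⇔  ref·f ≤ v (ref>0)  /  ref·f ≥ v (ref<0)
        rel = "<=" if ref > 0 else ">="
        prob.add_constraint(
            f"fitcap[{rid}]", {f: ref, _flux_var(rid): -1.0}, rel, 0.0
        )
        obj[f] = w / total_w
    prob.set_objective("MAX", obj)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), sol.objective
    )


def expression_match(
    net: Network,
    expression_states: Mapping[str, str],
    constraints: Optional[ConstraintSet] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> tuple[FluxDistribution, int]:
    """Infer a flux state agreeing maximally with an expression profile.

    Stage 1 (MILP) maximizes the agreement count A: a HIGH reaction
    agrees when it carries |v| ≥ activity_eps (two direction binaries),
    a LOW reaction when |v| ≤ zero_tol.  Stage 2 fixes A at its optimum
    and minimizes the weighted flux sum among agreement-optimal states.
    Returns the stage-2 distribution and A.
    """
    params = params or AlgorithmParams()
    for rid, state in expression_states.items():
        if rid not in net.reactions:
            raise KeyError(f"expression state for unknown reaction {rid!r}")
        if state not in ("HIGH", "LOW"):
            raise ValueError(f"state for {rid!r} must be HIGH or LOW")
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible(), 0

    def build() -> tuple[LinearProblem, dict[str, float], dict[str, float]]:
        prob = _base_problem(net, bounds)
        agreement: dict[str, float] = {}
        fluxsum: dict[str, float] = {}
        for rid, rxn in net.reactions.items():
            p, n = _add_abs_split(prob, rid, 0.0, "abs", _span(bounds, rid))
            fluxsum[p] = rxn.weight
            fluxsum[n] = rxn.weight
        for rid, state in expression_states.items():
            lo, hi = bounds[rid]
            m = max(abs(lo), abs(hi)) + params.activity_eps + 1.0
            if state == "HIGH":
                yf = prob.add_variable(f"hi+[{rid}]", kind="binary")
                yb = prob.add_variable(f"hi-[{rid}]", kind="binary")
                # v ≥ eps − m(1−yf)
                prob.add_constraint(
                    f"act_f[{rid}]",
                    {_flux_var(rid): 1.0, yf: -m},
                    ">=",
                    params.activity_eps - m,
                )
                # v ≤ −eps + m(1−yb)
                prob.add_constraint(
                    f"act_b[{rid}]",
                    {_flux_var(rid): 1.0, yb: m},
                    "<=",
                    -params.activity_eps + m,
                )
                prob.add_constraint(
                    f"act_xor[{rid}]", {yf: 1.0, yb: 1.0}, "<=", 1.0
                )
                agreement[yf] = 1.0
                agreement[yb] = 1.0
            else:
                y = prob.add_variable(f"lo[{rid}]", kind="binary")
                prob.add_constraint(
                    f"off_up[{rid}]",
                    {_flux_var(rid): 1.0, y: m},
                    "<=",
                    params.zero_tol + m,
                )
                prob.add_constraint(
                    f"off_dn[{rid}]",
                    {_flux_var(rid): 1.0, y: -m},
                    ">=",
                    -params.zero_tol - m,
                )
                agreement[y] = 1.0
        return prob, agreement, fluxsum

    prob1, agreement, _ = build()
    prob1.set_objective("MAX", agreement)
    sol1 = solve(prob1, backend)
    if sol1.status is not Status.OPTIMAL:
        return FluxDistribution(sol1.status), 0
    best_a = round(sol1.objective)

    prob2, agreement2, fluxsum2 = build()
    prob2.add_constraint("fix_agreement", agreement2, ">=", float(best_a))
    prob2.set_objective("MIN", fluxsum2)
    sol2 = solve(prob2, backend)
    if sol2.status is not Status.OPTIMAL:  # pragma: no cover - stage 1 witness
        return FluxDistribution(sol2.status), best_a
    dist = FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol2), sol2.objective
    )
    return dist, best_a


def mfa_fit(
    net: Network,
    measurements: Mapping[str, tuple[float, float]],
    params: Optional[AlgorithmParams] = None,
    constraints: Optional[ConstraintSet] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Least-absolute-deviation fit of a flux distribution to measurements.

    ``measurements`` maps reaction id → (measured value, weight).  The
    objective value is the weighted L1 residual Σ w |v − measured|; the
    fitted full flux vector is returned.
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    for rid in measurements:
        if rid not in net.reactions:
            raise KeyError(f"measurement for unknown reaction {rid!r}")
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    obj: dict[str, float] = {}
    for rid, (value, weight) in measurements.items():
        span = _span(bounds, rid) + abs(value)
        p, n = _add_abs_split(prob, rid, value, "res", span)
        obj[p] = weight
        obj[n] = weight
    prob.set_objective("MIN", obj)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL, _extract_fluxes(net, sol), sol.objective
    )


# ---------------------------------------------------------------------------
# thermodynamic feasibility


def _add_thermo(
    prob: LinearProblem,
    net: Network,
    bounds: dict[str, tuple[float, float]],
    thermo: ThermoConfig,
    params: AlgorithmParams,
) -> list[str]:
    """Attach ln-concentration variables and direction couplings.

    For every internal reaction r with actual Gibbs energy
    ΔG'_r = ΔG°'_r + RT·Σ_m n_{m,r}·ln c_m, flux beyond zero_tol in a
    direction requires ΔG' strictly on the exergonic side of that
    direction (|ΔG'| ≥ margin).  Exchange reactions are exempt: boundary
    reactions have no defined ΔG in an open system.  Returns the internal
    metabolite ids carrying ln c variables.
    """
    internal_mets = net.internal_metabolite_ids()
    for mid in internal_mets:
        lo, hi = thermo.lnc_range(mid)
        prob.add_variable(f"lnc[{mid}]", lower=lo, upper=hi)
    for rid in net.internal_reaction_ids():
        rxn = net.reactions[rid]
        lo, hi = bounds[rid]
        dg0 = thermo.dg0.get(rid, 0.0)
        m_v = max(abs(lo), abs(hi)) + 1.0
        m_g = thermo.big_m_G
        # ΔG'_r in terms of lnc: dg0 + rt Σ n lnc
        g_terms = {
            f"lnc[{mid}]": thermo.rt * coeff
            for mid, coeff in rxn.stoichiometry.items()
            if mid in net.metabolites and not net.metabolites[mid].is_boundary
        }
        a = prob.add_variable(f"fwd[{rid}]", kind="binary")
        b = prob.add_variable(f"bwd[{rid}]", kind="binary")
        prob.add_constraint(f"dir_xor[{rid}]", {a: 1.0, b: 1.0}, "<=", 1.0)
        # |v| ≤ zero_tol unless the matching direction binary is up
        prob.add_constraint(
            f"dir_fwd[{rid}]",
            {_flux_var(rid): 1.0, a: -m_v},
            "<=",
            params.zero_tol,
        )
        prob.add_constraint(
            f"dir_bwd[{rid}]",
            {_flux_var(rid): 1.0, b: m_v},
            ">=",
            -params.zero_tol,
        )
        # a = 1 ⇒ ΔG' ≤ −margin ; b = 1 ⇒ ΔG' ≥ +margin
        prob.add_constraint(
            f"dg_fwd[{rid}]",
            {**g_terms, a: m_g},
            "<=",
            -thermo.margin - dg0 + m_g,
        )
        prob.add_constraint(
            f"dg_bwd[{rid}]",
            {**g_terms, b: -m_g},
            ">=",
            thermo.margin - dg0 - m_g,
        )
    return internal_mets


def compute_fba_t_c(
    net: Network,
    objective: Optional[Objective] = None,
    constraints: Optional[ConstraintSet] = None,
    thermo: Optional[ThermoConfig] = None,
    params: Optional[AlgorithmParams] = None,
    backend: str = "highs",
) -> FluxDistribution:
    """Flux optimization under the concentration-based thermodynamic
    feasibility constraint (a MILP).

    Any linear objective (MAX_LINEAR) or weighted flux minimization is
    augmented with explicit ln-concentration variables and direction
    binaries; a reaction may carry flux beyond zero_tol only in a
    direction made exergonic by some admissible concentration vector.
    INFEASIBLE means no thermodynamically realizable flux distribution
    meets the objective and constraints — a first-class result.  The
    returned distribution carries a witness ln c vector.
    """
    params = params or AlgorithmParams()
    thermo = thermo or ThermoConfig()
    objective = objective or Objective(kind="MIN_WEIGHTED_FLUX")
    if objective.kind not in ("MAX_LINEAR", "MIN_WEIGHTED_FLUX"):
        raise ValueError(
            "thermodynamic solve supports MAX_LINEAR or MIN_WEIGHTED_FLUX "
            f"objectives, not {objective.kind}"
        )
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        return _infeasible()
    prob = _base_problem(net, bounds)
    if objective.kind == "MAX_LINEAR":
        for rid in objective.coefficients or {}:
            if rid not in net.reactions:
                raise KeyError(f"objective references unknown reaction {rid!r}")
        prob.set_objective(
            "MAX",
            {_flux_var(r): c for r, c in (objective.coefficients or {}).items()},
        )
    else:
        obj: dict[str, float] = {}
        for rid, rxn in net.reactions.items():
            p, n = _add_abs_split(prob, rid, 0.0, "abs", _span(bounds, rid))
            obj[p] = rxn.weight
            obj[n] = rxn.weight
        prob.set_objective("MIN", obj)
    internal_mets = _add_thermo(prob, net, bounds, thermo, params)
    sol = solve(prob, backend)
    if sol.status is not Status.OPTIMAL:
        return FluxDistribution(sol.status)
    return FluxDistribution(
        Status.OPTIMAL,
        _extract_fluxes(net, sol),
        sol.objective,
        log_concentrations={
            mid: sol.values[f"lnc[{mid}]"] for mid in internal_mets
        },
    )


# ---------------------------------------------------------------------------
# post-check


@dataclass
class CheckItem:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class CheckReport:
    items: list[CheckItem] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(item.passed for item in self.items)

    def failures(self) -> list[CheckItem]:
        return [i for i in self.items if not i.passed]


def post_check(
    net: Network,
    solution: FluxDistribution,
    constraints: Optional[ConstraintSet] = None,
    thermo: Optional[ThermoConfig] = None,
    params: Optional[AlgorithmParams] = None,
    tol: float = 1e-6,
    backend: str = "highs",
) -> CheckReport:
    """Independent verification of a computed flux distribution.

    Checks mass balance, bounds, and the constraint set arithmetic
    directly (no solver).  When thermodynamic data is given, it solves
    the concentration-feasibility subproblem with the flux signs fixed
    to the solution's signs — a pure LP in ln c — and fails on the
    reactions whose direction pattern admits no concentration witness
    (e.g. an active internal cycle).
    """
    params = params or AlgorithmParams()
    if not solution.optimal:
        raise ValueError("post_check requires an OPTIMAL solution")
    report = CheckReport()
    v = solution.fluxes
    for mid in net.internal_metabolite_ids():
        acc = 0.0
        for rid, rxn in net.reactions.items():
            coeff = rxn.stoichiometry.get(mid)
            if coeff:
                acc += coeff * v.get(rid, 0.0)
        report.items.append(
            CheckItem(
                f"mass_balance[{mid}]",
                abs(acc) <= tol,
                f"net production {acc:.3e}",
            )
        )
    bounds = effective_bounds(net, constraints)
    if bounds is None:
        report.items.append(
            CheckItem("constraints", False, "constraint set is contradictory")
        )
        return report
    for rid, (lo, hi) in bounds.items():
        x = v.get(rid, 0.0)
        report.items.append(
            CheckItem(
                f"bounds[{rid}]",
                lo - tol <= x <= hi + tol,
                f"v={x:.6g} not in [{lo}, {hi}]",
            )
        )
    if thermo is not None:
        prob = LinearProblem()
        for mid in net.internal_metabolite_ids():
            lo, hi = thermo.lnc_range(mid)
            prob.add_variable(f"lnc[{mid}]", lower=lo, upper=hi)
        active: list[str] = []
        for rid in net.internal_reaction_ids():
            x = v.get(rid, 0.0)
            if abs(x) <= params.zero_tol:
                continue
            active.append(rid)
            rxn = net.reactions[rid]
            dg0 = thermo.dg0.get(rid, 0.0)
            g_terms = {
                f"lnc[{mid}]": thermo.rt * coeff
                for mid, coeff in rxn.stoichiometry.items()
                if mid in net.metabolites
                and not net.metabolites[mid].is_boundary
            }
            if x > 0:
                prob.add_constraint(
                    f"dg[{rid}]", g_terms, "<=", -thermo.margin - dg0
                )
            else:
                prob.add_constraint(
                    f"dg[{rid}]", g_terms, ">=", thermo.margin - dg0
                )
        sol = solve(prob, backend)
        report.items.append(
            CheckItem(
                "thermodynamic_feasibility",
                sol.status is Status.OPTIMAL,
                "no concentration vector supports the flux directions of "
                + ", ".join(active)
                if sol.status is not Status.OPTIMAL
                else f"witness found for {len(active)} active reactions",
            )
        )
    return report
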
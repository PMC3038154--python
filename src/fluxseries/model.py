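"""Domain types for stoichiometric networks and flux distributions.

A :class:`Network` is the constraint system ``S·v = 0``, ``lb ≤ v ≤ ub``:
metabolites are the rows of the stoichiometric matrix S (boundary
metabolites are exempt from mass balance), reactions its columns.  All
iteration is in insertion order so that downstream solver files and
reports are reproducible byte-for-byte.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

#: Surrogate for an infinite flux bound.  Finite bounds are required for
#: big-M soundness in the MILP formulations, so missing bounds are replaced
#: by this magnitude on input.
INF_BOUND = 1e5


class Status(str, enum.Enum):
    """Outcome of a single optimization."""

    OPTIMAL = "OPTIMAL"
    INFEASIBLE = "INFEASIBLE"
    UNBOUNDED = "UNBOUNDED"


@dataclass
class Metabolite:
    """A (species, compartment) pair.

    ``is_boundary`` marks external pool metabolites that are exempt from
    the steady-state mass balance.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed net coefficient
    (negative = consumed).  ``weight`` is the nonnegative coefficient w_i
    used by weighted flux minimization (default 1).  ``is_exchange`` may be
    set explicitly; when ``None`` the network infers it (a reaction is an
    exchange iff it touches a boundary metabolite or its stoichiometry is
    one-sided, i.e. all coefficients share a sign).
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = INF_BOUND
    reversible: bool = False
    weight: float = 1.0
    is_exchange: Optional[bool] = None

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class Network:
    """An ordered collection of metabolites and reactions."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        name: str = "",
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "Network":
        return Network(
            (replace(m) for m in self.metabolites.values()),
            (r.copy() for r in self.reactions.values()),
            name=self.name,
        )

    # -- queries -----------------------------------------------------------
    def is_exchange(self, rxn_id: str) -> bool:
        """Whether a reaction crosses the system boundary.

        An explicit ``Reaction.is_exchange`` flag wins; otherwise a reaction
        is an exchange iff it involves a boundary metabolite or its net
        stoichiometry is one-sided (SBML models mark boundaries
        inconsistently, so both signals are honored).
        """
        rxn = self.reactions[rxn_id]
        if rxn.is_exchange is not None:
            return rxn.is_exchange
        coeffs = list(rxn.stoichiometry.values())
        if any(
            self.metabolites[m].is_boundary
            for m in rxn.stoichiometry
            if m in self.metabolites
        ):
            return True
        return all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs)

    def exchange_ids(self) -> list[str]:
        return [rid for rid in self.reactions if self.is_exchange(rid)]

    def internal_reaction_ids(self) -> list[str]:
        return [rid for rid in self.reactions if not self.is_exchange(rid)]

    def internal_metabolite_ids(self) -> list[str]:
        return [mid for mid, m in self.metabolites.items() if not m.is_boundary]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            list(self.metabolites) == list(other.metabolites)
            and list(self.reactions) == list(other.reactions)
            and all(
                a == b
                for a, b in zip(
                    self.metabolites.values(), other.metabolites.values()
                )
            )
            and all(
                a == b
                for a, b in zip(self.reactions.values(), other.reactions.values())
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Network {self.name or 'unnamed'}: "
            f"{len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


@dataclass
class FluxDistribution:
    """A solved flux vector.

    ``fluxes`` maps reaction id to flux v; it is populated only when
    ``status`` is OPTIMAL.  ``log_concentrations`` carries the witness
    ln c vector of a thermodynamic (MILP) solve.
    """

    status: Status
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = math.nan
    log_concentrations: Optional[dict[str, float]] = None

    @property
    def optimal(self) -> bool:
        return self.status is Status.OPTIMAL


@dataclass
class AlgorithmParams:
    """Numerical knobs shared by the optimization routines.

    zero_tol
        fluxes below this magnitude count as zero (also the activation
        threshold exempting a reaction from thermodynamic constraints).
    room_delta, room_epsilon
        relative / absolute half-width of the ROOM tolerance window
        ``δ·|v_ref| + ε``.
    activity_eps
        minimal flux magnitude for a reaction declared active in
        expression matching.
    fva_gamma
        fraction of the base optimum that flux variability analysis
        enforces (γ = 1 keeps the optimum exactly).
    big_m
        fallback big-M constant used when a reaction lacks usable finite
        bounds.
    """

    zero_tol: float = 1e-6
    room_delta: float = 0.03
    room_epsilon: float = 0.001
    activity_eps: float = 0.1
    fva_gamma: float = 1.0
    big_m: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "zero_tol",
            "room_delta",
            "room_epsilon",
            "activity_eps",
            "fva_gamma",
            "big_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.fva_gamma > 1:
            raise ValueError("fva_gamma must be at most 1")


# ---------------------------------------------------------------------------
# structural operations


def validate_network(net: Network) -> list[str]:
    """Return human-readable descriptions of every invariant violation.

    An empty list means the network is well-formed.  Violations are data,
    not exceptions: a curation workflow wants all of them at once.
    """
    violations: list[str] = []
    for mid, met in net.metabolites.items():
        if not mid:
            violations.append("metabolite with empty id")
        if not met.compartment:
            violations.append(f"metabolite {mid!r}: empty compartment")
    for rid, rxn in net.reactions.items():
        if not rid:
            violations.append("reaction with empty id")
        if not rxn.stoichiometry:
            violations.append(f"reaction {rid!r}: empty stoichiometry")
        for mid, coeff in rxn.stoichiometry.items():
            if mid not in net.metabolites:
                violations.append(
                    f"reaction {rid!r}: unknown metabolite {mid!r}"
                )
            if coeff == 0:
                violations.append(
                    f"reaction {rid!r}: zero coefficient for {mid!r}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rid!r}: lower_bound {rxn.lower_bound} exceeds "
                f"upper_bound {rxn.upper_bound}"
            )
        if not rxn.reversible and rxn.lower_bound < 0:
            violations.append(
                f"reaction {rid!r}: irreversible but lower_bound "
                f"{rxn.lower_bound} < 0"
            )
        if rxn.weight < 0:
            violations.append(f"reaction {rid!r}: negative weight {rxn.weight}")
    return violations


def stoichiometry_matrix(net: Network) -> pd.DataFrame:
    """The steady-state system S as a table.

    Rows are non-boundary metabolites, columns are reactions, both in
    network order; entry (m, r) is the net coefficient of m in r.
    """
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(problems))
    rows = net.internal_metabolite_ids()
    cols = list(net.reactions)
    df = pd.DataFrame(0.0, index=rows, columns=cols)
    for rid, rxn in net.reactions.items():
        for mid, coeff in rxn.stoichiometry.items():
            if mid in df.index:
                df.at[mid, rid] = coeff
    return df


def close_boundary(net: Network, mode: str = "all") -> Network:
    """Copy of the network with exchange fluxes shut off.

    ``mode="all"`` pins every exchange to zero (used by leak analysis);
    ``mode="uptake-only"`` zeroes only the directions that import matter,
    leaving excretion open.
    """
    if mode not in ("all", "uptake-only"):
        raise ValueError(f"unknown mode {mode!r}")
    out = net.copy()
    for rid in out.reactions:
        if not out.is_exchange(rid):
            continue
        rxn = out.reactions[rid]
        if mode == "all":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            continue
        # forward flux imports iff it net-produces an internal metabolite
        imports_forward = any(
            coeff > 0
            for mid, coeff in rxn.stoichiometry.items()
            if mid in out.metabolites and not out.metabolites[mid].is_boundary
        )
        if imports_forward:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
            rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    return out


def add_sink(net: Network, metabolite_id: str) -> tuple[Network, str]:
    """Copy of the network plus an irreversible drain for one metabolite.

    The sink consumes one unit per flux unit, bounds [0, INF_BOUND]; its id
    is ``SINK_<metabolite-id>``.  Probing a boundary metabolite is refused
    (it is already outside the mass balance).
    """
    if metabolite_id not in net.metabolites:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    if net.metabolites[metabolite_id].is_boundary:
        raise ValueError(
            f"metabolite {metabolite_id!r} is a boundary species; "
            "a sink probe is meaningless"
        )
    sink_id = f"SINK_{metabolite_id}"
    if sink_id in net.reactions:
        raise ValueError(f"sink {sink_id!r} already exists")
    out = net.copy()
    out.add_reaction(
        Reaction(
            id=sink_id,
            stoichiometry={metabolite_id: -1.0},
            name=f"sink for {metabolite_id}",
            lower_bound=0.0,
            upper_bound=INF_BOUND,
            is_exchange=True,
        )
    )
    return out, sink_id
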
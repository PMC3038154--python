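"""Deterministic synthetic networks for exercising every algorithm.

These are the package's study conditions: tiny networks with known
extreme pathways, an internal cycle for the loop law, a mass-creating
reaction for leak analysis, and seeded sparse random networks for
oracle-equivalence testing.  All constructors are reproducible
byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import string
from pathlib import Path

import numpy as np

from .model import Metabolite, Network, Reaction


def _met_id(i: int, n: int) -> str:
    if n <= 26:
        return string.ascii_uppercase[i]
    return f"M{i + 1}"


def make_chain(n: int = 3) -> Network:
    """Linear chain: EX_A (∅→A), R1..R(n−1) (step conversions), terminal
    excretion; all bounds [0, 10], unit weights."""
    if n < 1:
        raise ValueError("chain needs at least one metabolite")
    net = Network(name=f"chain{n}")
    mids = [_met_id(i, n) for i in range(n)]
    for mid in mids:
        net.add_metabolite(Metabolite(mid, name=f"metabolite {mid}"))
    net.add_reaction(
        Reaction(
            f"EX_{mids[0]}",
            {mids[0]: 1.0},
            lower_bound=0.0,
            upper_bound=10.0,
            is_exchange=True,
        )
    )
    for i in range(n - 1):
        net.add_reaction(
            Reaction(
                f"R{i + 1}",
                {mids[i]: -1.0, mids[i + 1]: 1.0},
                lower_bound=0.0,
                upper_bound=10.0,
            )
        )
    drain_id = f"EX_{mids[-1]}" if n > 1 else f"EX_{mids[-1]}_out"
    net.add_reaction(
        Reaction(
            drain_id,
            {mids[-1]: -1.0},
            lower_bound=0.0,
            upper_bound=10.0,
            is_exchange=True,
        )
    )
    return net


def make_parallel() -> Network:
    """Two competing routes from A to B: direct R1, or R2a then R2b via X.

    Flux minimization with unit weights prefers the one-step route; FVA
    with the product demand fixed shows the trade-off R1 ∈ [0, 1]."""
    net = Network(name="parallel")
    for mid in ("A", "B", "X"):
        net.add_metabolite(Metabolite(mid))
    net.add_reaction(
        Reaction("EX_A", {"A": 1.0}, upper_bound=10.0, is_exchange=True)
    )
    net.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, upper_bound=10.0))
    net.add_reaction(Reaction("R2a", {"A": -1.0, "X": 1.0}, upper_bound=10.0))
    net.add_reaction(Reaction("R2b", {"X": -1.0, "B": 1.0}, upper_bound=10.0))
    net.add_reaction(
        Reaction("EX_B", {"B": -1.0}, upper_bound=10.0, is_exchange=True)
    )
    return net


def make_loop() -> Network:
    """Closed 3-cycle A→B→C→A with no exchanges.

    The null space of S contains the cycle vector (1,1,1), so plain FBA
    admits any cycle flux in [0, 10]; the thermodynamic constraint
    forbids it (the Gibbs energies around the loop sum to zero)."""
    net = Network(name="loop3")
    for mid in ("A", "B", "C"):
        net.add_metabolite(Metabolite(mid))
    net.add_reaction(
        Reaction("R1", {"A": -1.0, "B": 1.0}, upper_bound=10.0, is_exchange=False)
    )
    net.add_reaction(
        Reaction("R2", {"B": -1.0, "C": 1.0}, upper_bound=10.0, is_exchange=False)
    )
    net.add_reaction(
        Reaction("R3", {"C": -1.0, "A": 1.0}, upper_bound=10.0, is_exchange=False)
    )
    return net


def make_leaky() -> Network:
    """Chain of three plus the mass-creating reaction R_bad (A → 2 A).

    R_bad makes A (and everything downstream) producible with all
    exchanges closed — the signature of a stoichiometric inconsistency.
    """
    net = make_chain(3)
    net.name = "leaky"
    net.add_reaction(
        Reaction(
            "R_bad",
            {"A": 1.0},  # net: one A created per flux unit
            name="unbalanced duplication A -> 2 A",
            upper_bound=10.0,
            is_exchange=False,
        )
    )
    return net


def make_random_network(n_mets: int, n_rxns: int, seed: int) -> Network:
    """Seed-deterministic sparse random network.

    Coefficients are drawn from {−2, −1, 1, 2}; about 20% of reactions
    are one-sided exchanges; bounds are [−2, 2] (reversible) or [0, 2].
    The same seed always yields an identical network.  Draws may be
    infeasible or unbounded for some objectives — status handling is
    itself under test downstream.
    """
    rng = np.random.default_rng(seed)
    net = Network(name=f"random_{n_mets}x{n_rxns}_{seed}")
    mids = [f"M{i + 1}" for i in range(n_mets)]
    for mid in mids:
        net.add_metabolite(Metabolite(mid))
    coeff_pool = np.array([-2.0, -1.0, 1.0, 2.0])
    for j in range(n_rxns):
        rid = f"R{j + 1}"
        if n_mets and rng.random() < 0.2:
            mid = mids[rng.integers(n_mets)]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            stoich = {mid: sign}
            is_exchange = True
        else:
            k = int(rng.integers(2, min(4, n_mets) + 1)) if n_mets >= 2 else 1
            chosen = rng.choice(n_mets, size=k, replace=False)
            stoich = {
                mids[i]: float(coeff_pool[rng.integers(4)]) for i in chosen
            }
            is_exchange = None
        reversible = bool(rng.random() < 0.5)
        lb, ub = (-2.0, 2.0) if reversible else (0.0, 2.0)
        net.add_reaction(
            Reaction(
                rid,
                stoich,
                lower_bound=lb,
                upper_bound=ub,
                reversible=reversible,
                is_exchange=is_exchange,
            )
        )
    return net


DEMO_SIMULATIONS = """\
# demo simulation series for the three-step chain network
# (EX_A -> A -> B -> C -> EX_C, all bounds [0, 10])

SIMULATION produce_C
  COMMENT producibility of C at rate >= 1
  OBJECTIVE flux-min
  CONSTRAINT EX_C >= 1
  EXPECT FEASIBLE
  CHECK R1 > 0 and EX_C >= 1
END

SIMULATION overdemand_C
  COMMENT demand above the uptake capacity must be unsatisfiable
  CONSTRAINT EX_C >= 100
  EXPECT INFEASIBLE
END

SIMULATION bounded_production
  COMMENT fixed production with a side condition on the uptake
  CONSTRAINT EX_C = 2
  EXPECT FEASIBLE
  CHECK abs(EX_A) <= 2.5
END
"""


def write_demo_simulations(path: str | Path) -> Path:
    """Emit the canonical-dialect demo simulation file (byte-deterministic).

    Three specs against make_chain(3): a feasible producibility test with
    a side-condition check, an expected-infeasible overdemand, and a
    fixed-rate production with an absolute-value check.
    """
    path = Path(path)
    path.write_text(DEMO_SIMULATIONS)
    return path
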
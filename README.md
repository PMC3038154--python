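# fluxseries

Batch flux-balance computation series over stoichiometric metabolic
networks, for network curation and structural analysis.

Constraint-based analysis treats a metabolic network as the linear
system **S·v = 0**, **lb ≤ v ≤ ub** — S the stoichiometric matrix, v the
flux vector — and asks optimization questions over it. Curating a
genome-scale reconstruction requires *many* such questions at once: can
this metabolite be produced on this medium, does this function survive
this enzyme knockout, is this flux state thermodynamically realizable?
`fluxseries` is built for exactly that workflow: a basic layer solves a
single LP/MILP per call, and an upper layer runs heterogeneous series of
them from a concise simulation description file with automatic
PASS/FAIL evaluation.

## What it computes

Single-solve routines (library functions, all returning a
`FluxDistribution`):

- linear maximization (biomass-style FBA),
- **weighted flux minimization** — min Σ wᵢ|vᵢ| subject to target
  demands,
- L1 **MOMA** and **ROOM** knockout simulation against a reference flux
  distribution,
- **fitness maximization** for partially inhibited enzymes
  (|vᵢ| ≤ αᵢ·capᵢ, fitness F = Σ w̄ₖ·min(1, vₖ/refₖ) ∈ [0, 1]),
- **expression-profile matching** (two-stage MILP: maximal agreement,
  then minimal flux),
- least-absolute-deviation fitting to measured fluxes,
- any linear or flux-minimization objective under the
  **concentration-based thermodynamic feasibility constraint**: explicit
  ln-concentration variables with
  ΔG'ᵣ = ΔG°'ᵣ + RT·Σₘ n₍ₘᵣ₎·ln cₘ, where active flux requires a
  strictly exergonic direction (a MILP; the loop law follows as a
  consequence),
- an independent `post_check` of any solution (mass balance, bounds,
  concentration witness with fixed flux signs).

Series-level operations: batch runs with evaluation reports, flux
variability analysis (FVA), leak analysis (metabolites producible from
nothing), and pruning to the functional subnetwork defined by a set of
simulations.

Models are read and written as SBML L2 (read v1–4, write v4) or a plain
flat text dialect; solutions as SBML, val files (reaction-id TAB flux,
for network visualization tools), and TSV reports. LP/MILP solving runs
in-process through HiGHS or file-based through GLPK (`glpsol`) via
CPLEX-LP files.

## Worked example

The built-in parallel network offers two routes from A to B: a direct
conversion R1, or the two-step detour R2a, R2b. Which route does the
cell use if it must excrete one unit of B with minimal total enzyme
usage — and what happens when R1 is knocked out?

```python
import fluxseries as fs
from fluxseries.fixtures import make_parallel

net = make_parallel()
demand = fs.ConstraintSet(flux_fixes={"EX_B": 1.0})

wild_type = fs.flux_minimization(net, demand)
print(wild_type.objective_value, wild_type.fluxes["R1"])

knockout = fs.ConstraintSet(flux_fixes={"EX_B": 1.0}, knockouts={"R1"})
mutant = fs.moma_l1(net, wild_type, knockout)
print(mutant.objective_value)

ranges = fs.fva(net, demand).ranges
print(ranges["R1"])
```

prints

```
3.0 1.0
3.0
(0.0, 1.0)
```

The flux-minimal wild type routes everything through R1 (total flux
3.0: uptake, R1, excretion). After the knockout, the nearest feasible
flux state sits at L1 distance 3.0 from the wild type (R1 drops 1, R2a
and R2b each rise 1). FVA shows R1 can carry anything between 0 and the
full demand — the two routes trade off freely until an objective picks
one.

The same questions run as a batch from a simulation file:

```
$ fluxseries simulate --model chain.txt --simulations sims.txt --call flux-min
sim_id	status	objective	expected	passed	checks_failed
produce_C	OPTIMAL	4	FEASIBLE	PASS	-
overdemand_C	INFEASIBLE		INFEASIBLE	PASS	-
bounded_production	OPTIMAL	8	FEASIBLE	PASS	-
```

`fluxseries prune`, `fluxseries fva`, `fluxseries leaks` and
`fluxseries validate` expose the curation operations; see
`docs/methods.md` for the formulations, defaults, and limitations.

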
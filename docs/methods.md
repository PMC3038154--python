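# Methods

## The constraint system

A metabolic network is the linear system **S·v = 0**, **lb ≤ v ≤ ub**:
rows of the stoichiometric matrix S are metabolites (boundary species are
exempt from mass balance), columns are reactions, and v is the flux
vector. Every computation in the package is one LP or MILP over this
polytope, optionally narrowed by a per-simulation constraint set: fixed
fluxes, flux ranges, knockouts (bounds forced to 0), and partial enzyme
inhibitions (|v_i| capped at α_i times the reaction's normal bound
magnitude, α ∈ [0, 1]).

Flux units are arbitrary but must be consistent. Missing or infinite
bounds are replaced by the finite surrogate ±1e5 on input: every MILP
formulation here relies on big-M couplings, and big-M reasoning is only
sound with finite bounds. Reversibility is carried entirely by the
bounds; the `reversible` flag of the input formats only selects the
default lower-bound sign.

A reaction is treated as an exchange (boundary-crossing) when it touches
a boundary metabolite or its net stoichiometry is one-sided — published
models mark their boundaries inconsistently, so both signals are
honored. The heuristic necessarily misreads mass-creating internal
reactions such as A → 2 A (net stoichiometry {A: +1}), which is why the
`Reaction.is_exchange` flag can be set explicitly and survives SBML and
flat-file round trips.

## Objectives

All absolute values are linearized with nonnegative split variables
(v − c = p − n, p, n ≥ 0, p + n ≥ |v − c|); no indicator constraints are
used, so any LP/MILP backend can solve every formulation.

- **Linear maximization** — max c·v (biomass-style FBA).
- **Weighted flux minimization** — min Σ w_i |v_i| subject to the target
  demands in the constraint set; w_i is per-reaction (default 1). With
  no demand the zero flux is trivially optimal. An INFEASIBLE status is
  the producibility-test outcome, not an error.
- **MOMA (L1)** — min Σ |v_i − v_ref,i| against a reference (wild-type)
  distribution. The L1 variant is deliberate: the solver contract is
  LP/MILP-only, and the L1 distance is an accepted linear alternative to
  the original quadratic objective (which is out of scope). With
  v_ref = 0 it coincides exactly with unit-weight flux minimization —
  this identity is under test.
- **ROOM** — MILP minimizing the number of fluxes outside the window
  v_ref ± (δ·|v_ref| + ε), defaults δ = 0.03, ε = 0.001. The binary
  relaxation big-Ms are derived per reaction from its own bounds
  (the tightest sound relaxation), not from one global constant.
- **Fitness maximization under enzyme deficiency** — targets are
  (weight, reference rate) pairs per reaction; each target contributes a
  satisfaction f_k ≤ v_k / ref_k capped to [0, 1], and the fitness
  F = Σ w̄_k f_k (weights normalized to sum 1) is maximized. The lower
  cap at 0 means a target driven in the wrong direction contributes
  nothing rather than a negative term, keeping F ∈ [0, 1]; for
  irreversible targets the cap is inactive by construction. F is
  anti-monotone in every inhibition α (tested).
- **Expression matching** — two-stage MILP. Stage 1 maximizes the
  agreement count A with an expression profile: a HIGH reaction agrees
  when |v| ≥ activity_eps (0.1 by default; two direction binaries,
  since |v| ≥ ε is disjunctive), a LOW reaction when |v| ≤ zero_tol
  (one binary). Stage 2 pins A at its optimum and minimizes the
  weighted flux sum among agreement-optimal states, so the reported
  distribution is parsimonious.
- **Measured-flux fitting (MFA)** — min Σ w |v_i − measured_i| over the
  measured subset; the residual is the objective, the full fitted flux
  vector is returned.

## Concentration-based thermodynamic feasibility

Each internal metabolite gets a variable ln c_m bounded by a
concentration window, default [ln 1e-5, ln 1e-2] mol/l — the span of
typical intracellular metabolite concentrations. Each internal reaction
has an actual Gibbs energy

    ΔG'_r = ΔG°'_r + RT · Σ_m n_{m,r} · ln c_m

with RT = 2.577 kJ/mol by default (8.314 J mol⁻¹ K⁻¹ × 310 K, body
temperature); ΔG°' defaults to 0, which reduces the constraint to the
pure loop law. Two direction binaries per reaction couple flux to
energy: flux above zero_tol forward forces ΔG' ≤ −margin, backward
forces ΔG' ≥ +margin. The margin (default 1e-3 kJ/mol) is the surrogate
for the strict inequality ΔG' < 0; reactions with |v| ≤ zero_tol are
exempt, as are exchange reactions — a boundary reaction has no defined
reaction energy in an open system.

Around any closed internal cycle the ln c terms cancel and the ΔG°'
sum to zero, so all steps cannot be simultaneously exergonic: the loop
law emerges from the formulation rather than being imposed as a
separate cycle constraint. INFEASIBLE is a first-class result meaning
no thermodynamically realizable flux distribution satisfies the
objective and constraints.

The energy big-M (default 1e4 kJ/mol) must dominate any attainable
|ΔG'|; with |ΔG°'| up to a few hundred kJ/mol and RT·Σ|n·ln c| of order
tens, the default leaves ample slack without harming MILP conditioning
at these problem sizes.

`post_check` verifies solutions independently: mass balance and bounds
by direct arithmetic, and — when thermodynamic data is given — a pure
LP in ln c with the flux signs frozen to the solution's signs. A
loop-carrying FBA solution fails this check; every solution produced by
the thermodynamic solver passes it.

## Solver layer

Problems are built in a solver-neutral variable/constraint form and
solved by one of two backends: in-process through HiGHS (scipy's
`milp`, handling both LP and MILP), or file-based through GLPK's
`glpsol` via CPLEX-LP files. The file-based route doubles as an
independent cross-check: tests require objective agreement between the
two backends on random bounded problems. Variable names are escaped to
LP-format-safe tokens with a reversible map. Binary results are rounded
to exact 0/1 at 1e-6. The only exposed solver knobs are a MILP time
limit (600 s) and the relative MIP gap (1e-6).

Alternate optima are broken by the solver, not by the formulation:
deterministic variable ordering makes results stable per backend but
not identical across backends, so all comparisons in the test suite are
on objective values, never on flux vectors.

## Batch series and evaluation

A simulation file lists independent tasks in a block grammar
(`SIMULATION … OBJECTIVE … CONSTRAINT … EXPECT … CHECK … END`); a
tolerant line-oriented secondary dialect reads legacy series files. A
run executes every task through the selected routine, evaluates the
CHECK expressions (single-flux comparisons, optionally on |v|, combined
with and/or/parentheses, using exact solver values with no zero
snapping), and reports one PASS/FAIL row per task. An INFEASIBLE result
passes when the task expects it — non-existence tests are a normal part
of network curation — while an unexpected UNBOUNDED always fails, and a
per-task error never aborts the batch. Outputs are an evaluation TSV,
one val file (reaction-id TAB flux) per optimal task for network
visualization tools, and a combined flux TSV.

## Curation operations

- **FVA** — per-reaction minimum and maximum flux: 2·|reactions| LPs,
  plus one when a base objective is given, in which case c·v ≥ γ·opt
  restricts the sweep (γ = 1 by default, i.e. exactly optimal states).
- **Leak analysis** — all exchanges are closed in both directions, then
  each internal metabolite gets a probe drain whose flux is maximized;
  a positive optimum marks the metabolite as producible from nothing, a
  stoichiometric inconsistency. The reverse probe (absorbable into
  nothing) exists behind a mode flag and is off by default.
- **Pruning** — phase 1 collects the support union U of flux-minimal
  solutions of every task; phase 2 verifies each task on the
  restriction to U and repairs failures by re-solving on the full
  network with weights biased 1000:1 against non-U reactions, until the
  restriction supports every originally-feasible task. Support-union
  pruning is one member of a family of functional-subnetwork
  algorithms; because flux-minimal solutions are not unique, two runs
  with different solvers can retain slightly different reaction sets.
  The soundness property (every task keeps its flux-min objective
  within 1e-5 on the pruned network) and monotonicity (adding a task
  never shrinks the retained set) are what the test suite enforces.

## Synthetic study networks

The fixture module defines the study conditions; its defaults are not
tuning knobs. The chain (uptake → n−1 conversions → excretion, bounds
[0, 10]) pins every flux once a demand is set. The parallel network has
two routes of different length between the same metabolites, giving
known flux-minimization optima (3 vs 4 steps) and a known FVA trade-off.
The 3-cycle with no exchanges has the cycle vector in the null space of
S, exercising the loop law. The leaky network adds A → 2 A to the
chain, the minimal stoichiometric inconsistency. Random networks
(coefficients in {−2, −1, 1, 2}, ~20% one-sided exchanges, bounds
[−2, 2] or [0, 2]) are seed-deterministic and deliberately allowed to be
infeasible or unbounded for some objectives, since status handling is
itself under test.

These fixtures do not emulate genome-scale features — compartments,
cofactor coupling, or realistic degree distributions — so passing tests
demonstrates correctness of the formulations and algorithms, not
numerical robustness on models with thousands of reactions, where MILP
conditioning and solver choice dominate.

### Oracles

The test suite checks the L1 objectives against an enumeration oracle
that uses no LP solver: the minimum of a weighted L1 objective over the
flux polytope is attained where the mass-balance rows plus active
hyperplanes from {lb_i, ub_i, kink_i} span flux space, so pinning every
choice of n − rank(S) coordinates and solving the remaining square
system by least squares visits all candidate optima. ROOM is checked by
brute force over all binary change patterns with an LP feasibility
probe per pattern. The oracle-equivalence tests run on 50 seeded random
networks of at most 8 reactions (tolerance 1e-5); the FVA sandwich test
checks 1,000 sampled feasible points per fixture against the computed
ranges. Problem sizes are chosen so the whole default suite runs in a
few seconds on one CPU.

## Numerical choices

| Parameter | Default | Meaning |
| --- | --- | --- |
| zero_tol | 1e-6 | flux considered zero; thermo exemption threshold |
| room_delta / room_epsilon | 0.03 / 0.001 | ROOM window half-width δ·‖v_ref‖ + ε |
| activity_eps | 0.1 | minimal flux of an expression-active reaction |
| fva_gamma | 1.0 | optimality fraction retained in FVA sweeps |
| rt | 2.577 kJ/mol | R·T at 310 K |
| lnc window | [ln 1e-5, ln 1e-2] | concentration bounds, mol/l |
| margin | 1e-3 kJ/mol | strict-inequality surrogate for ΔG' < 0 |
| big_m_G | 1e4 kJ/mol | energy coupling big-M |
| INF_BOUND | 1e5 | finite surrogate for missing bounds |

## Known limitations

- Quadratic MOMA, regulatory (Boolean) constraints, and gene–protein–
  reaction rules are out of scope.
- SBML level 3 is read leniently without FBC-package bound support;
  `stoichiometryMath` is rejected.
- The exchange heuristic cannot distinguish a one-sided unbalanced
  internal reaction from a true exchange without the explicit flag.
- Pruned reaction sets depend on alternate-optima selection and are
  reproducible per backend, not across backends.
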
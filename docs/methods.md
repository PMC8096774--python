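# Methods

## Model

A chemical reaction network with n species and r irreversible reactions
evolves under mass-action kinetics,

    dx/dt = S v(x, k),    v_j = k_j ∏_i x_i^{s_ij},

where s_ij is the reactant stoichiometry of reaction j and S holds
products minus reactants.  Reversible reactions are stored expanded as two
irreversible columns sharing a `parent_id`; this keeps one rate constant
per column and lets a gain-of-function projection remove a single
direction.  Constant species (non-consumable inflows) stay in the state
vector with their S-rows zeroed, so each contributes one trivial
conservation law instead of being eliminated — the bookkeeping for open
networks then needs no special cases.  Stoichiometric coefficients are
unrestricted integers even though signaling networks are at most
bimolecular in practice.  Reactions with an empty reactant side are
accepted as zero-order boundary inflows and logged.

## Conservation-law enumeration

Semi-positive conservation vectors form the pointed cone
ker(Sᵀ) ∩ ℝⁿ₊.  Its extreme rays — the minimal moiety vectors — are
computed by double description over exact integer arithmetic: rays start
as the n unit vectors, each column of S is imposed as one equality
constraint, rays on the hyperplane survive, and adjacent pairs with
opposite signs combine (adjacency by the combinatorial support test, valid
because every intermediate cone sits inside the orthant).  Outputs are
scaled to coprime integers and sorted lexicographically by support, so the
generator order is deterministic.  Rank is computed over the rationals
(sympy), never by floating-point thresholds, so the basis condition
p = n − rank(S) is decided exactly.  When the cone genuinely needs more
generators than the left-null-space dimension, all generators are kept but
basis-dependent operations (elemental solve, class descriptors, LoF
projections) refuse to run with an explanatory error — the theory behind
those operations assumes a basis.

Elemental species are chosen deterministically: species are scanned in
table order and each conservation law takes the first unit column of N
that is still unassigned.  A law is labelled trivial when its support is
exactly one constant species.

## Mutations

A null LoF of elemental species j zeroes every secondary species of law j,
zeroes the total c_j, and re-solves x₁ = c̃ − N₂x̃₂.  The projector is
defined only for elemental species; partial ("leaky") LoF is out of scope.
A secondary species carrying several moieties is zeroed outright and the
molecules of the *other* moieties bound in it reappear in free elemental
form — the operator is implemented literally, with no attempt to model the
kinetics of that instantaneous redistribution.

GoF zeroes S-columns while keeping the rate constants, so the projection
is reversible and the removed fluxes are still evaluated (they simply no
longer move the state).  The rank condition rank(G_H(S)) = rank(S) is
checked exactly; when it holds, every original generator is re-verified
against the projected matrix as a kernel-equality certificate.  When it
fails, composed mutations still run but the result is stamped
`scc_changing`: the compatibility classes differ and order independence of
the final state is no longer guaranteed.

`deactivation_reactions` suggests H by pattern: reactions consuming the
active form without regenerating it, plus the conversion steps draining
the bound intermediates they produce.  It is a heuristic and is never
applied without explicit confirmation.

A worked caveat on composed mutations: on the phospho-cycle fixture, a
2-LoF choice {K, P} (kinase *and* phosphatase) freezes every reaction that
touches the substrate moiety, so the free/modified split of A stays
wherever the initial projection put it — the projected system then has a
continuum of steady states per class and order independence genuinely
fails, exactly as the theory predicts when the global-stability hypothesis
is dropped.  The shipped order-independence checks therefore use LoF
{A, P} plus the GoF deactivation block, for which all projected systems
remain globally stable per class.

## Steady-state integration

The steady state is operational: the solution value at the end of a fixed
window [0, 2.5e7] time units, integrated with a variable-order implicit
multistep solver and the analytic mass-action Jacobian.  Defaults:
rtol 1e-6, atol 1e-12 nM, all exposed.  `||dx/dt||_inf` at the solver's
output points is the convergence diagnostic; the relative drift of every
conserved total (tolerance 1e-6) is checked on each run and a violation
raises an integrity error, tying the dynamics back to the exact
conservation analysis.  An optional early exit on a sustained small
derivative norm exists but is off by default so the fixed-window protocol
is reproduced exactly.

Solver choice: scipy's `BDF` stepper can freeze its step size on this
problem class — after the transient the steps stop growing, so a 2.5e7
window takes millions of steps; we reproduced this on a two-species linear
isomerization with plain scipy at several tolerances.  The default is
therefore LSODA, which switches itself onto BDF multistep formulas in
stiff regions and showed no such pathology; `method="BDF"` remains
available.  Because equilibria of the mass-action system are fixed points
of the discrete scheme and exponentially attracting here, terminal states
are far more accurate than rtol suggests (the isomerization closed form is
recovered to ~1e-15 relative).

Negative concentrations are never clipped in the trajectory.  Terminal
entries below −atol abort with an integrity error; entries in [−atol, 0)
are reported as 0.  The public flux evaluator treats values in
[−1e-9, 0) as zero and rejects anything lower.  Relative steady-state
differences d_i = (x^m_{e,i} − x_{e,i})/x_{e,i} with a zero denominator
are encoded as missing (NaN), never ±∞.

## Class sampling and the stability protocol

Random members of a class c are built sequentially: unconserved species
get log₁₀-uniform draws on [1e-5, 1e5]; the non-elemental conserved
species, visited in a random permutation, each take u·min_j c_j/γ_ji over
the laws that involve them (u ~ U[0,1]) with the residual totals updated
in place — the min over the *current* residuals guarantees feasibility;
each elemental species then absorbs the residual of its unique law.
Membership N x = c holds by construction up to rounding (≤1e-10 relative).
Constant species keep their declared values and are excluded from the
draws; when a random class is generated (totals log₁₀-uniform on
[1e-2, 1e3]), the trivial laws are pinned to those declared constants.
The scheme is a specific sequential construction, not a uniform sample of
the class polytope, and is reproduced as such.

The stability protocol draws 5 classes, scatters 30 points in each
(verifying co-membership before integrating), integrates all of them over
the fixed window, and compares per-species coefficients of variation
(sample standard deviation over mean, denominator m − 1) of initial
versus terminal values over the non-constant species.  The pass rule —
mean terminal CV at least one order of magnitude (factor 10, configurable)
below the mean initial CV in every class — operationalizes the qualitative
claim that scattered starts collapse onto one steady state.  Species whose
terminal mean is zero have an undefined CV and are excluded with a count;
the ten worst-CV species are listed to surface slow convergers rather than
failing on them.  One master seed spawns an independent substream per
class, so reports are bit-for-bit reproducible.

## Synthetic fixtures

FIX-style fixtures carry their own certificates.  The isomerization
network A ⇌ B has the closed-form equilibrium x_A = c·k_r/(k_f + k_r); the
phospho cycle A + K ⇌ AK → A* + K, A* + P ⇌ A*P → A + P has three moiety
laws with supports {A, A*, AK, A*P}, {K, AK}, {P, A*P} and elemental
species {A, K, P}.  Random conservative networks are grown from motifs —
per-moiety isomerization pairs plus binding/conversion species — because
random integer matrices almost never have sign-constrained left kernels;
the construction makes the moiety-count vectors a simplicial set of
extreme rays, which is emitted as ground truth.  Defaults use small
integer rate constants so worked examples are reproducible bit-for-bit.

These fixtures emulate the conservation structure, stiffness pattern, and
projection behavior of real signaling networks at toy scale (≤ 12 species
in oracle-checked tests); they do not emulate realistic rate-constant
spreads (many orders of magnitude), network diameter, or the 400+-species
scale of curated cancer-signaling models, so passing tests demonstrate
correctness of the machinery, not biological fidelity of any particular
pathway.  Problem sizes in the shipped checks — 50 oracle-checked random
networks, 20 drift trajectories, 100 closed-form draws, 5 × 30 stability
integrations — were chosen to exercise every code path at desk scale.

## Known limitations

* Only mass-action kinetics; Michaelis–Menten/Hill laws, stochastic
  simulation, and spatial models are out of scope by design.
* LoF is all-or-nothing; GoF covers only deactivation-removal (the
  zero-complex constitutive-production extension is noted as future work).
* Network input is the two-table TSV dialect; SBML import is not included.
* No bifurcation or multistationarity analysis: global stability is
  supported numerically per class, never proved.
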
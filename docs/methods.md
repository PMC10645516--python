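# Methods

## The model class

`selsym` works with finite two-allele selection processes described from
the gene's-eye view: a fixed set *G* of *n* genetic sites (one per
haploid individual, two per diploid), a binary population state
**x** ∈ {0,1}^G recording which allele sits at each site, and — for every
state — a joint probability distribution p_x(α, U) over *replacement
events*. An event is a parentage map α : G → G (site *g* inherits or
retains the allele of site α(g); α need not be a bijection) together
with a mutation set U ⊆ G of sites whose inherited allele is flipped.
One time step samples (α, U) and sets

    x'_g = x_{α(g)}   for g ∉ U,
    x'_g = 1 − x_{α(g)} for g ∈ U,

which defines the selection Markov chain on the 2^n states. Population
size and structure are fixed; all model detail (spatial structure,
mating, migration, update rule) lives inside p.

A permutation σ of sites is a **symmetry** of the process when

    p_x(α, U) = p_{xσ}(σ⁻¹∘α∘σ, σ⁻¹(U))   for all x, α, U,

with xσ the permuted state ((xσ)_g = x_{σ(g)}). The symmetries form a
group Sym(G, p) acting on sites on the left and on states on the right,
and every symmetry preserves transition probabilities,
P(x→y) = P(xσ→yσ), hence also m-step probabilities, fixation
probabilities and stationary distributions. (Some presentations write
the transformed map as σ∘α∘σ⁻¹; the condition implemented here is the
σ⁻¹∘α∘σ form, which is the one consistent with the right action
(xσ)τ = x(σ∘τ) and is what the test suite verifies numerically via
transition preservation.)

Grouping states into orbits [x] = {xσ} yields the reduced chain with
P([x]→[y]) = Σ_{z∈[y]} P(x→z); transition preservation makes this
well-defined (strong lumpability). The number of orbits is given by
Burnside's lemma, R = (1/S) Σ_σ m^{c(σ)} with c(σ) the cycle count of σ,
S the group order and m the number of alleles, and is bracketed by

    max(n+1, 2 + (2^n − 2)/S) ≤ R ≤ 2 + (1/S) Σ_{k=1}^{n−1} C(n,k)·gcd(S, k!(n−k)!).

## Conventions and update rules

The classical model families do not pin down every microscopic detail
(self-replacement, death/birth ordering), so the constructors fix and
document one convention each; symmetry groups are only reproducible
relative to these choices. See the `process_core` module docstring for
the full list. The load-bearing ones:

- **Moran death step**: the dying site is uniform over all n sites, so
  self-replacement is possible in the well-mixed model. Death–birth on
  graphs draws the dying site uniformly, then a parent among its
  in-neighbours proportional to edge weight × fitness.
- **Mutation** is iid per site with probability u, applied after
  replacement: p_x(α, U) = p_x(α)·u^|U|(1−u)^(n−|U|).
- **Aggregation**: microscopic draws yielding the same (α, U) are merged
  before any symmetry comparison — the symmetry condition compares
  probabilities of events, not of sampling narratives.
- **Class model**: the default class-to-class parent weight matrix is 1
  within a class and 1/2 across classes. Any constant off-diagonal in
  (0, 1) would do; it must differ from the diagonal so that classes are
  actually distinguishable (otherwise the model degenerates to
  well-mixed and the detected group is larger than the class group).
- **Island model**: migration rate defaults to 1/10 and must lie
  strictly in (0, 1) — at 0 the demes are disconnected and the fixation
  axiom fails, at 1 the within-island component vanishes. The constant
  is a typical "low migration" choice; any value in (0, 1) yields the
  same symmetry group.
- **Indexing**: sites are 0-based internally, 1-based in files, cycle
  notation and reports. States are indexed by Σ_g x_g·2^g (site 0 least
  significant); orbit representatives are minimal-index members and
  orbits are ordered by representative, making all outputs
  deterministic.
- **Composition**: compose(σ, τ)(g) = σ(τ(g)), giving the right-action
  law (xσ)τ = x(σ∘τ) exactly.

## Arithmetic and numerical choices

Symmetry detection and lumpability are *equality* tests, so every
built-in model with rational parameters is constructed in exact
`Fraction` arithmetic end to end: support probabilities, transition
matrices, absorption solves (Gaussian elimination over rationals) and
stationary distributions (exact nullspace of Pᵀ − I, with uniqueness
required: nullity must be 1). Float-mode tables (user input) are
compared with relative tolerance 1e-9, and probabilities below 1e-15
are treated as absent so that noise cannot manufacture asymmetry.
Bounds are returned as exact rationals without rounding; the
integrality of R enters only in comparisons.

## Algorithms and size limits

- **Group search** is brute force over all n! candidate permutations,
  capped at n ≤ 8 (40 320 candidates). The decision problem contains
  graph automorphism, so no clever general search is attempted; for
  larger n, callers supply generators and get the (verified) closure,
  which the group property guarantees is a subgroup of Sym(G, p).
- **Closure** is repeated product saturation over canonical image
  vectors — simple and exact at the orders that arise here.
- **Structure groups** are materialised as explicit element sets up to
  order 10^6 (Burnside needs per-element cycle counts).
- **Chains** are limited to n ≤ 12 (4096 states), stored as sparse
  rational row dicts. Wright–Fisher supports (n^n maps per state) are
  limited to n ≤ 6 by default.
- **Fixation axiom**: condition "p_x(α_k) > 0 in every state" is read as
  the marginal over mutation sets — the condition is written without U
  and marginalisation is the only reading consistent with the
  framework. The decision runs pairwise-merge reachability over the
  always-possible maps D (the synchronizing-automaton criterion: a
  constant composite over D exists iff every pair of sites can be
  merged by some word over D — sound and complete). Witnesses are
  assembled by greedily collapsing the image of the running composite
  and re-verified by explicit composition before being returned; they
  are not minimal in length (only existence is required), and maps may
  repeat. An exhaustive semigroup-closure oracle cross-checks the
  decision in the test suite at n ≤ 5.
- **Lumpability check**: `build_reduced_chain` always verifies, for
  every member of every source orbit, that row sums onto each target
  orbit agree. For partitions from true symmetry groups this is a
  theorem; the check guards user-supplied groups and misapplied
  partitions.

## Synthetic fixtures

`random_process` draws a reproducible random support per state with
exact rational probabilities and mixes in a uniform single-replacement
backbone (weight 1/4 spread over the n² dying/parent choices), which
guarantees the fixation axiom by construction. Generic random processes
have trivial symmetry with overwhelming probability, which makes them
useful negatives. `symmetrize_process` averages any process over a
permutation group, p'_x(α,U) = (1/S) Σ_σ p_{xσ}(σ⁻¹ασ, σ⁻¹U); group
closure makes every element of the group a symmetry of the result, so
symmetrized random processes provide fixtures with a prescribed group.
These generators emulate arbitrary members of the model class, not any
particular biological scenario; tests passing on them demonstrate the
combinatorial machinery, not the fit of any concrete model to data.

## Problem sizes used in tests

Brute-force group detection is exercised up to n = 8 (the undirected
cycle, order 16) and across all built-in families at n ≤ 6; orbit
enumeration cross-checks Burnside counts for groups up to order 40 320
over up to 2^7 states and 3 alleles; chain-level invariants (transition
preservation, lumpability, fixation, stationarity) run at n ≤ 6 where
all checks are exact. These sizes keep the default suite fast while
covering each formula's edge cases (n = 1, prime n, equal-size blocks,
trivial and full groups).

## Known limitations

- Only two-allele *dynamics* are supported; m > 2 alleles appear in the
  orbit-counting operations alone (the Burnside formula generalises by
  replacing 2 with m).
- Population size and structure are fixed; no dynamic graphs,
  multi-locus genetics or varying ploidy.
- No Monte-Carlo simulation, continuous-time chains, or approximate
  lumping of asymmetric chains.
- Symmetry detection beyond n = 8 requires user-supplied generators;
  the package verifies them but cannot certify that the closure is the
  *full* symmetry group.
- A diploid well-mixed population of N individuals (2N sites, group
  S_N × (S_2)^N as the block-partition structure) has, by Burnside, 6
  reduced states at N = 2 — the genotype-triple count C(N+2, 2); the
  package reports the Burnside/brute-force value.
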
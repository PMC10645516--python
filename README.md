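# selsym

Symmetry analysis and orbit reduction for finite two-allele selection
processes — exact, from the model's transition probabilities alone.

Models of natural selection in structured populations (Moran,
Wright–Fisher, graph-, class- and island-structured variants) share a
common skeleton: a fixed set *G* of *n* genetic sites, a binary state
**x** ∈ {0,1}^G saying which allele occupies each site, and a per-state
distribution p_x(α, U) over replacement events — a parentage map α
(site *g* inherits from α(g)) plus a mutation set U of flipped sites.
This induces a Markov chain on 2^n states, which quickly becomes
unwieldy. The classical escape is symmetry: a permutation σ of sites
with

&nbsp;&nbsp;&nbsp;&nbsp;p_x(α, U) = p_{xσ}(σ⁻¹∘α∘σ, σ⁻¹(U)) for all x, α, U

preserves every transition probability, P(x→y) = P(xσ→yσ). The
symmetries form a group; its orbits on states give a *reduced* chain
P([x]→[y]) = Σ_{z∈[y]} P(x→z) whose size R follows from Burnside's
lemma, R = (1/S) Σ_σ 2^{c(σ)}, and is bounded by
max(n+1, 2+(2^n−2)/S) ≤ R ≤ 2 + (1/S) Σ_k C(n,k)·gcd(S, k!(n−k)!).

`selsym` is for modellers who want these reductions *verified rather
than assumed*: it detects the symmetry group of a process directly from
its probabilities (exact rational arithmetic, so equality really means
equality), proves lumpability by checking it, reduces the chain, counts
and bounds orbits, and decides the fixation axiom (can one site's
lineage take over the population?) with a checkable witness.

## Worked example

```python
from selsym import (
    star_moran_db, symmetry_group, site_orbits, build_chain,
    build_reduced_chain, state_orbits, count_reduced_states,
    state_count_bounds, fixation_probabilities,
)

proc = star_moran_db(5)          # hub + 4 leaves, death-birth updating
group = symmetry_group(proc)     # brute force over all 5! permutations
print(group.order)               # 24  -- any permutation of the 4 leaves
orbs = site_orbits(group)
print(orbs.orbits, orbs.transitive)   # [[0], [1, 2, 3, 4]] False

R = count_reduced_states(group)
print(R)                         # 10  -- hub allele x leaf occupancy = 2n
b = state_count_bounds(proc.n, group.order)
print(b.lower, b.upper)          # 6 22

chain = build_reduced_chain(build_chain(proc), state_orbits(group))
print(chain.R)                   # 10  -- lumpability checked member by member

rho = fixation_probabilities(proc)
print(rho.single_mutant(0))      # 1/2 -- a mutant arising at the hub
print(rho.single_mutant(1))      # 1/8 -- at any leaf (all four agree)
```

The detected group of order 24 is the full permutation group of the
leaves — the hub is structurally distinct, so the site action is not
transitive and fixation probability depends on where the mutant lands:
under death–birth updating a dying leaf always copies the hub, so the
hub seat is strongly favoured (1/2 vs 1/8; the five values sum to 1, as
neutrality requires). The 32-state chain lumps exactly to 10 orbit
states.

Everything is also reachable from the shell:

```
echo '{"structure": "star", "n": 5}' > star.json
selsym count --spec star.json
# {"order": 24, "reduced_states": 10, "alleles": 2}
```

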
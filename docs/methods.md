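# Methods

## Model

The package treats regulation inference as qualitative perturbation
propagation on a *causality graph* compiled from *regulated reactions*.

A regulated reaction couples a transformation (substrate set → product set)
with its regulators (activators `+`, inhibitors `-`, modulators `?`; the
three roles are disjoint within one reaction). Regulatory effects are
represented in the same formalism as product-only reactions fed by an
unmodeled, non-limiting substrate, so a single record type carries both
metabolic and regulatory knowledge. Two normalizations precede compilation:
species-specific reactions with identical substrate and product sets are
merged (regulator roles united, reversible if any duplicate was; a molecule
holding conflicting roles across duplicates is an error by default and is
demoted to modulator under the lenient option — silent sign loss seemed
worse than an explicit choice), and nine generic currency molecules (ATP,
ADP, NTP, NDP, phosphate, Coenzyme A, water, H+, and a reserved
`__protein_remnants__` id the KB author may map) are deleted from all roles.
A reaction left without products is dropped: the formalism requires every
reaction to produce something.

Compilation follows a quasi-stationary reading of elasticity coefficients.
Nodes: `quantity(M)` for every molecule, `availability(M)` (summed
production rate) only for molecules that are substrates somewhere, `v(R)`
per reaction. Edges per reaction R:

* `availability(M) →+ v(R)` for each substrate;
* `quantity(A) →+ v(R)`, `quantity(I) →- v(R)`, `quantity(X) →? v(R)` for
  activators, inhibitors, modulators;
* `v(R) →+ quantity(P)` for each product, plus `v(R) →+ availability(P)`
  when P has an availability node;
* if R is explicitly regulated, `v(R) →- quantity(S)` for each substrate
  (the reaction drains its substrates); otherwise
  `availability(M1) →- quantity(M2)` over ordered pairs of distinct
  substrates (the reaction is limited by its substrates).

All reactions compile forward-only (reversibility is recorded but ignored
here; an experimental `split_reversible` reading was considered and
rejected as a default because most reversible records are complex
formations whose product is consumed nowhere else). A reaction with one
substrate and no regulator receives no speed→substrate feedback: neither
rule applies. The per-reaction edge count is exactly
`s + a + i + m + p + p' + (s if regulated else s·(s−1))` with `p'` the
number of products owning availability nodes; this closed form is enforced
as a test contract.

## Sign propagation

Influence between ordered node pairs is the set of achievable *walk* sign
labels: `+` for a walk with an even number of negative edges and no
unknown edge, `-` for odd, `?` once any unknown-sign edge is crossed
(unknown is absorbing). Walks, not simple paths: with cycles,
parity-reachability over walks is well-defined and polynomial, whereas
sign existence over simple paths is NP-hard. The consequence is visible in
a 2-cycle `x →+ y`, `y →- x`: the pair (x, y) carries both labels because
the 3-edge walk x→y→x→y has odd parity.

The closure is a boolean fixpoint over three sparse reachability blocks
(even, odd, unknown-seen), one row per requested source node; each
iteration extends every walk by one edge and the loop stops when no new
(node, state) pair appears — at most 3·|V| iterations. Self-influence is
excluded from all explanation queries (a molecule never explains itself),
but diagonal labels produced by cycles are kept in the closure so it agrees
exactly with the independent test oracle, a length-bounded dense dynamic
program over walks of length ≤ 3·|V| (the product graph has 3·|V| states,
so a shortest label-realizing walk never needs more steps).

The explanatory view splits each node into up/down variants, removes the
variant contradicting each observed target sign, and reduces influence
queries to parity lookups: same variation needs a `+` label, opposite a
`-`. A `?` label influences both variations, flagged unknown; a pair with
both a signed and a `?` label keeps both, and the scoring option
`count_unknown` (default true, since modulators are admitted as genuine
regulators) decides whether unknown-flagged influence counts.

## Scoring

Each candidate is tried under both variation hypotheses. Coverage counts
targets whose observed variation is influenced consistently; sign-free
targets count under either variation. Specificity multiplies coverage by
(1 − p), where p is the hypergeometric upper tail P(X ≥ k) for an urn with
one ball per gene in the compiled subgraph (N), targets among them white
(K), the candidate's influenced genes as draws (n) and explained targets
as successes (k). The inclusive tail (≥ k) is the standard enrichment
convention. The tail is computed with exact integer binomials. The urn is
gene-only by default (`urn_kinds` widens it); candidate reporting supports
gene-only and all-molecule views separately. A candidate that itself
appears in the target list with a known sign keeps only the concordant
hypothesis; otherwise the better-scoring hypothesis is reported with its
sign. No multiple-testing correction is applied across candidates.

Ranking keeps exact-equality tie groups (*ex aequo*); the retained list is
the smallest group prefix covering the requested size, and a cutoff through
a group of size g with m slots inside yields hit probability m/g. The
recommended retained size is 50–100 candidates.

## Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| hubs n | 1000 | most-connected molecules ignored during expansion |
| levels | 3 | rounds of reaction selection around the list |
| top_n | 100 | retained candidates |
| score key | specificity | ranking key |
| urn kinds | gene | hypergeometric ball population |
| count_unknown | true | modulator-mediated influence counts |

Hubs block frontier expansion but are retained inside selected reactions
("temporarily ignored"); the stricter delete-outright reading is available
as an option. Frontier membership is tested in every role (substrate,
product, regulator); an option restricts matching to substrate/product
roles.

## Synthetic knowledge bases

The generator emulates the qualitative regime of curated
regulatory/metabolic databases at roughly one-third scale: ~3.6k molecules
(3000 metabolites, 400 genes, 200 enzymes, 20 TFs) and ~2.5k regulated
reactions. Metabolite participation counts are drawn from a truncated
discrete power law P(k) ∝ k^-(1+hub_strength) (default exponent 2,
truncation 40) realized by a stub-pool construction, which yields hub
metabolites and a degree distribution whose naive log-log least-squares fit
lands at γ ≈ 2.0 (molecule participation) / ≈ 2.3 (bipartite projection)
with |Pearson|·100 ≈ 95–98 — inside the scale-free regime reported for
curated reaction networks. Enzymes regulate half the reactions; signs are
heavily positive (5% inhibitors, 5% modulators), matching the strong excess
of positive over negative influence in curated sources.

Each of the 20 TFs receives a planted regulon of 10–30 genes, each target
wired directly (depth 1) or through one intermediate TF (depth 2). The
implied sign of a planted target is the parity product along its actual
chain — verified against the compiled causality graph at generation time —
so a perfect method can recover every regulon. Observed lists are then
degraded explicitly; the benchmark default erases all signs
(sign_noise = 1, erase), since curated TF→target lists typically carry no
signs. All randomness derives from one integer seed through per-stage
child seeds, so identical config + seed gives byte-identical KB files.

What the generator does *not* emulate: stoichiometry and mass balance,
cross-species redundancy, complex formation, identifier noise, and the
sheer size of real databases. Passing benchmarks here demonstrate that the
pipeline recovers planted structure under realistic topology and sign
composition, not that it matches any particular curated database's
accuracy figures, which depend on proprietary content.

## Benchmark protocol

Each case (target list + known regulator) runs the full pipeline at the
default operating point (hubs 1000, levels 3) for both ranking keys and
both candidate views; success at each cutoff is the ex-aequo hit
probability, aggregated as the mean over cases × 100. Cases whose known
regulator is absent from the KB are dropped and counted. The negative
control redeals all target entries between lists (lengths preserved,
seeded) and reruns everything.

At the default operating point the synthetic benchmark recovers planted
TFs in the specificity top-10 with mean probability above 0.8 while the
shuffled control stays several-fold lower. Two honest caveats. First,
without hub exclusion (hubs 0) recovery collapses: the planted TF→TF layer
makes nearly every candidate influence nearly every gene, so the
specificity urn saturates (p → 1) — the synthetic analog of the motivation
for hub removal. Second, strong hub exclusion leaves small per-case
subnetworks (tens of molecules), so the shuffled control's success is
inflated relative to large-database conditions (a random candidate sits in
a short list); the true-vs-control gap, not the control's absolute value,
is the meaningful quantity, and the control varies noticeably with the
generator seed.

## Topology statistics

Degree fits use least squares on log10 P(k) vs log10 k over the nonzero
bins of the empirical degree density of the undirected projection
(molecule–reaction bipartite graph for a KB, collapsed multigraph for a
causality graph), reporting γ = −slope and r = |Pearson| × 100 — the
0–100 convention used in the comparable literature tables. The fit refuses
fewer than three distinct nonzero degrees. This naive density fit is
deliberate (it mirrors the classic metabolic-network methodology) and is
known to flatten when singleton high-degree bins are abundant; it is not a
maximum-likelihood power-law estimator. Path metrics (characteristic
length L, diameter D) are computed on the largest connected component,
exactly up to 2000 nodes and otherwise from a seeded BFS source sample, in
which case L is an estimate and D a lower bound, both flagged.

## Problem sizes

The test suite and acceptance script run everything at desk scale: 500
random graphs (|V| ≤ 12) for closure-vs-oracle equivalence, 200 random KBs
for compilation contracts, exhaustive hypergeometric checks to N = 25,
10 generator seeds for the topology regime, and the 20-case planted
benchmark with its shuffled control; the full run completes in about a
minute on one core.
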
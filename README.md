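# regfinder

Propose **upstream regulators** for a list of regulated molecules — the
differentially expressed genes of a transcriptome study, or a panel of
metabolites that moved together — by tracing signed causal paths through a
knowledge base of biochemical reactions and regulatory effects.

The package is aimed at systems biologists who have a molecule list and a
curated reaction/regulation knowledge base and want a ranked, sign-consistent
short list of candidate regulators, together with a benchmark harness and a
synthetic knowledge-base generator for validating the whole procedure
offline.

## The method

1. **Regulated reactions.** Reactions (substrates → products, with
   activators, inhibitors and modulators) and regulatory effects
   (regulator → target, signed `+`/`-`/`?`) are unified: an effect becomes an
   irreversible reaction producing its target from an unmodeled, non-limiting
   substrate, with the regulator in the role matching its sign.
   Species-specific duplicates are merged; generic currency molecules (ATP,
   ADP, NTP, NDP, phosphate, Coenzyme A, water, H+, protein remnants) are
   stripped.

2. **Neighborhood extraction.** Starting from the target list, reactions are
   selected by up to 3 rounds of frontier expansion ("levels of
   neighboring"); the most-connected molecules (hubs, default the top 1,000)
   are ignored during expansion so the neighborhood stays specific.

3. **Causality graph.** Each molecule M gets a node `quantity(M)`; each
   molecule that is a substrate anywhere gets `availability(M)` (its summed
   production rate); each reaction R gets a speed node `v(R)`. Signed edges
   encode the qualitative elasticities, e.g. `availability(M) →+ v(R)` per
   substrate, `quantity(A) →+ v(R)` per activator (`−` inhibitor, `?`
   modulator), `v(R) →+ quantity(P)` per product, and negative feedback from
   `v(R)` onto substrate quantities (regulated case) or between substrate
   couples (unregulated case).

4. **Sign propagation.** For each ordered node pair the achievable path-sign
   labels over walks are computed: `+` if a walk with an even number of
   negative edges exists, `-` if odd, `?` if a walk crosses an unknown-sign
   edge. After splitting nodes into up/down variants and removing the variant
   contradicting each observed target sign, a candidate hypothesis
   (molecule C, sign s) *explains* target T when it influences T's observed
   variation consistently.

5. **Scoring.** For each candidate hypothesis,

   - *coverage* = number of targets explained;
   - *p* = hypergeometric upper tail P(X ≥ k) with N = genes in the graph,
     K = targets among them, n = genes the candidate influences, k = targets
     explained;
   - *specificity* = coverage × (1 − p).

   Candidates sharing an identical score form an *ex aequo* tie group; a
   cutoff slicing a group of size g with m slots left scores m/g.

## Worked example

A toy knowledge base with one effect `a →+ g` and one reaction
`{b, c} → {d}` activated by `e`; the observed list is `d` up:

```
$ regfinder find --kb toy_kb.json --targets targets.tsv --hubs 0 \
      --urn-kinds gene,metabolite,protein --out cand.tsv --meta meta.json
4 candidates scored; 4 retained -> cand.tsv

$ cat cand.tsv
rank  tie_group  candidate_id  kind        hypothesis_sign  coverage  n_influenced  p     specificity  explained_targets
1     1          e             protein     +                1         3             0.75  0.25         d:+
2     2          b             metabolite  +                0         0             1     0
3     2          c             metabolite  +                0         0             1     0
4     2          d             gene        +                0         0             1     0
```

The activator `e` is the only candidate explaining the increase of `d`
(coverage 1, via the positive path `quantity(e) → v(r2) → quantity(d)`); its
p of 0.75 reflects that it influences 3 of the 4 urn molecules, so the
overlap with the single target is unsurprising and specificity is modest.
Compiling the full toy KB yields a causality graph of 10 nodes and 8 signed
edges (6 positive, 2 negative).

Other subcommands: `regfinder simulate` generates a synthetic knowledge base
with planted TF→target regulons (ground truth written alongside),
`regfinder benchmark` replays directories of annotated target lists and
reports success-at-top-n grids with a shuffled-list control, and
`regfinder topology` prints degree power-law and path statistics
(γ, r, L, D) of a knowledge base or its causality graph.

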
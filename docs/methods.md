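# Methods

## The problem

A protein with `2d` oxidized cysteines forms `d` intra-chain disulfide
bonds. Knowing *which* cysteines pair — the connectivity pattern — is a
perfect matching on the cysteine set, one of `(2d-1)!!` possibilities,
and is far harder to predict than the oxidation states themselves.
`cystree` predicts the pattern without any training data, from the
evolutionary record of the protein's family.

## Model and procedure

The biological premise is tandem compensatory mutation: when one
cysteine of a bond is lost during evolution, the selective pressure on
its now-unpaired partner changes and the partner tends to be lost as
well, within a short evolutionary window. Pairs of cysteines that
disappear *together* on a branch of the family's phylogeny are therefore
likely bond partners. Two modeling assumptions make this tractable:

1. the connectivity pattern is conserved within the family, and
2. over the sampled evolutionary depth, oxidized cysteines are only
   lost, never regained (regaining a lost bond needs two independent
   mutations back to cysteine — negligible at family scale).

The pipeline, given a query with oxidized positions `C = (c1..cn)` and
an MSA of homologs:

1. **Filter.** Keep only homologs with an *even* number of cysteines at
   the columns aligned to `C`. An odd count marks a spurious single
   mutation that would blur the pairwise signal. Zero is even: such rows
   are retained (they are harmless — all-zero labels generate no
   weight).
2. **Root the tree.** Append a shuffled copy of the query as an
   outgroup, build a neighbor-joining tree from p-distances (Kimura
   correction optional), root at the midpoint of the outgroup's pendant
   edge, then drop the outgroup.
3. **Label.** Each leaf gets a bit vector over `C` (1 = cysteine
   present). Every inner node gets the bitwise OR of its children, in
   one post-order pass. Under the loss-only model this is the
   maximum-parsimony ancestral reconstruction: a cysteine is present in
   an ancestor iff some descendant still carries it, which dates each
   loss as late as the observations allow. Because OR is associative,
   commutative and idempotent the result is independent of traversal
   and child order, and generalizes unchanged to multifurcations.
4. **Infer.** For each leaf, read the label path from an all-zeros
   sentinel through the leaf up to the root and compare adjacent
   labels. If `mu` bits switch on at a step (towards the root):
   `mu = 0` — nothing; `mu = 2` — the unambiguous pair's edge gains
   weight 1; even `mu > 2` — the time resolution of the sampled tree
   cannot separate the `mu/2` simultaneous tandem losses, so each of
   the `mu(mu-1)/2` candidate pairs gains `2/(mu(mu-1))`; odd `mu` —
   a parity-breaking step, ignored. Every informative step thus
   deposits total weight exactly 1, an exact conservation law the tests
   assert. (A relaxed scheme that also *penalizes* edges between
   mutated and conserved cysteines on parity-breaking steps is known
   not to pay for its complexity and is deliberately not implemented.)
5. **Match.** The weighted graph over `C` is resolved by maximum-weight
   *perfect* matching (blossom algorithm on an offset graph so perfect
   matchings always dominate, as in Edmonds–Gabow-style solvers), giving
   the predicted pattern.

When fewer than 2 homologs survive filtering, the prediction falls back
to a seeded uniform random matching and is flagged — comparable to how
an empty homology search must be scored in benchmarks.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `correction` | `none` | distance model for NJ; p-distance suffices because inference uses only the topology, not branch lengths |
| `drop_outgroup` | `True` | remove the shuffled outgroup before labeling; its random label carries no signal |
| `seed` | 42 (CLI) | outgroup shuffle and random fallback |

Coordinates are 1-based in all CLI input/output, 0-based in the API.

## Numerical and design choices

- **NJ determinism.** Q-criterion ties are broken by the
  lexicographically smallest pair of cluster ids (a cluster carries its
  smallest leaf id); negative branch lengths are clamped to zero with
  the deficit moved to the sister branch. NJ on additive matrices
  provably recovers the generating topology; tests check this
  exhaustively for up to 6 taxa and against an independent NJ
  implementation.
- **Matching determinism.** Among equal-weight optima the
  lexicographically smallest pair list is returned, by greedily fixing
  the smallest feasible pair and re-solving; this makes the production
  solver agree pair-for-pair with the brute-force enumerator (the
  oracle up to 16 cysteines, `(n-1)!!` candidates). Weight comparisons
  use an absolute tolerance of 1e-9.
- **Zero-length branches** are legal; labels propagate across them.
  Missing Newick branch lengths read as 0.
- **Micro vs macro Rb.** Rb is micro-averaged (pooled bonds) within a
  report stratum. Note that `Qp <= Rb` is guaranteed per protein and
  per fixed-bond-count stratum, but micro-averaged Rb over *mixed* bond
  counts can fall below Qp (a correct 1-bond protein lifts Qp more than
  pooled Rb); the report tables are per-bond-count, where the
  inequality holds.
- **Random baselines.** Against a uniform random matching,
  `E[Rb] = 1/(2d-1)` and `E[Qp] = 1/(2d-1)!!`; both closed forms and a
  seeded Monte-Carlo estimator are provided and agree within sampling
  error.

## The simulator

`cystree.simulator` generates families under the exact model the
inference assumes, with a planted pattern as ground truth. A random
binary tree (successive leaf splitting, exponential branch lengths,
mean 0.1) carries a root sequence with cysteines at the planted
positions. Per branch:

- background sites substitute with `p_sub` (default 0.03 per site,
  giving realistic 30–60% divergence between distant family members at
  the default depth) to a uniformly random non-cysteine residue;
- each intact bond *fires* with `p_loss` (default 0.3), losing one
  partner, and the other partner follows on the same branch with
  probability `p_tandem`;
- a widowed cysteine (partner already gone) is lost with `p_loss / 2` —
  the same marginal hazard each cysteine had while its bond was intact.
  This choice is deliberate: it makes the fate of a cysteine
  independent of its partner's when `p_tandem = 0`, so that setting is
  a true no-signal control, while `p_tandem = 1` reproduces pure
  whole-bond tandem loss;
- lost cysteines restore with `p_restore` (default 0 — the loss-only
  model).

Defaults (64 leaves, sequence length 120, 3 bonds planted at spread-out
positions, deliberately *not* the lexicographically-first pairing so the
matcher's tie-break can never fake a recovery) define the standard
recovery experiment.

What the simulator does **not** emulate: indels and alignment error,
realistic substitution matrices, rate heterogeneity, oxidation-state
misassignment. Passing recovery tests therefore bound what the
inference achieves when homology search and alignment are perfect; real
families add noise in all of those places.

## Expected recovery and its ceiling

With full tandem coupling every label is pairwise-consistent, and one
can show each planted pair's edge weight dominates any competing edge's
— the planted pattern is always *among* the maximum-weight matchings.
The only failures are exact ties: two bonds whose retention pattern
over the sampled leaves is identical (most often both extinct in every
leaf) are information-theoretically indistinguishable, and the
deterministic tie-break then picks an arbitrary optimum. Under the
default conditions this intrinsic ceiling is measured at ~95% exact
recovery (94.8 ± 0.7% over 1000 replicates); with coupling switched off
recovery sits at the 1/15 chance level, and it rises monotonically with
`p_tandem` in between. Problem sizes throughout the test suite and the
reproduction script (64-leaf families, 100 replicates per condition,
10^5 Monte-Carlo draws, 500–1000 random matching instances) were chosen
as the smallest at which these effects are statistically unambiguous.

## Known limitations

- Rooted trees with very poor outgroup placement (a shuffle that by
  chance resembles the family) are not detected; the shuffle's seed is
  exposed precisely so such runs are reproducible.
- The even-cysteine filter discards genuinely informative homologs
  whose odd count comes from alignment error rather than biology.
- For queries whose families have no cysteine turnover at all (no
  losses anywhere), all candidate edges tie and the returned pattern is
  just the deterministic tie-break — the run log's informative-step
  count (equal to the total graph weight) makes this visible.
- The 523-dimension pair encoder is provided for stacking with
  supervised models; no trained model ships with the package.
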
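# cystree

Unsupervised prediction of **disulfide-bond connectivity** from known
cysteine oxidation states, using the evolutionary record of the
protein's family.

A protein with `2d` oxidized cysteines `C = (c1, …, c2d)` forms `d`
disulfide bonds; the connectivity pattern is a perfect matching on `C`,
one of `(2d−1)!!` candidates. `cystree` exploits *tandem compensatory
mutation*: when evolution removes one cysteine of a bond, the unpaired
partner tends to be lost soon after, so cysteine pairs that vanish
together on branches of the family's phylogeny are likely bond
partners. The method

1. filters the homolog alignment to sequences with an even cysteine
   count at the oxidized columns,
2. builds a neighbor-joining tree and roots it with a shuffled-query
   outgroup,
3. reconstructs ancestral cysteine presence by maximum parsimony under
   a loss-only model (inner label = OR of children),
4. converts every even-sized tandem-loss step on a leaf-to-root label
   path into edge weights on a connectivity graph (a `μ`-cysteine step
   adds `2/(μ(μ−1))` to each of its `μ(μ−1)/2` candidate pairs, total
   weight 1 per informative step), and
5. resolves the graph by maximum-weight perfect matching.

Predictions are scored with the field's standard indexes: `Rb`
(correctly predicted bonds / observed bonds) and `Qp` (fraction of
proteins with a fully correct pattern), against the random baselines
`E[Rb] = 1/(2d−1)` and `E[Qp] = 1/(2d−1)!!`.

The package also ships a seeded family simulator implementing the same
loss-only tandem model with a planted pattern (so every stage is
testable end to end without external databases), and the 523-dimension
cysteine-pair encoder (2 × 13 window columns × 20 amino-acid
frequencies + log separation + 2 relative-order dimensions) used to
stack unsupervised predictions onto supervised learners.

See `docs/methods.md` for the model, assumptions, parameter choices and
known limitations.

## Worked example

Simulate a 64-leaf family with a planted 3-bond pattern, then predict
it back from the alignment alone:

```sh
$ cystree simulate --seed 7 --out fam
query=query cys=11,26,41,61,81,101

$ cystree predict --msa fam/alignment.fasta --query query \
      --cys 11,26,41,61,81,101 --seed 1 --out pred -v
query=query
bonds=3
seed=1
fallback_random=False
n_homologs=64
total_graph_weight=152.99999999999997
n_informative_steps=153
11	61
26	81
41	101
```

The three output lines are the predicted bonds (1-based residue
positions): 11–61, 26–81, 41–101 — exactly the planted pattern in
`fam/truth.tsv`. The log confirms all 64 homologs survived the
even-cysteine filter and that 153 informative tandem-loss steps were
read off the tree (the total graph weight equals that count, an exact
conservation law of the weighting scheme). Scoring the prediction:

```sh
$ awk '{print "query\t"$0}' pred/prediction.tsv > predfmt.tsv
$ cystree evaluate --truth fam/truth.tsv --pred predfmt.tsv
 bonds  proteins    Rb    Qp  Rb_random  Qp_random
     3         1 100.0 100.0       20.0        6.7
overall Rb=100.0 Qp=100.0
```

Both bonds-level and protein-level scores are perfect, against a 6.7%
chance of guessing a 3-bond pattern at random. `predict` exits with
code 3 (and flags the run) when too few homologs survive filtering and
the pattern had to be guessed randomly; `cystree encode-pairs` writes
the 523-dimension feature matrix for all candidate bonds.

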
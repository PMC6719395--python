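# ppmspace

**Exploring the full solution space of tumor phylogeny deconvolution from
bulk sequencing data.**

Bulk DNA sequencing of a tumor measures, for each somatic mutation `c` and
each sample `p`, a frequency `f_{p,c}` — the fraction of cells carrying the
mutation.  Under the perfect phylogeny (infinite sites) model, these
frequencies factor as

```
F = U · B
```

where `B` is the `n × n` binary genotype matrix of a rooted clonal tree `T`
(row `c` holds the mutations on the root-to-`c` path) and `U` holds the
mixing proportions of the clones in each sample.  The catch, well known but
easy to forget downstream, is that this factorization is usually **not
unique**: the same `F` can be explained by many distinct clonal trees.
`ppmspace` is a toolkit for making that non-uniqueness explicit.  It is
aimed at researchers building or evaluating tumor-phylogeny methods who need
ground truth about the solution space rather than a single point estimate.

Everything rests on two classical facts.  The *ancestry graph* `G_F` has an
edge `(c, d)` whenever `f_{p,c} ≥ f_{p,d}` in every sample; every solution
tree is a spanning arborescence of `G_F`.  An arborescence is a solution
exactly when it satisfies the *sum condition*

```
f_{p,c}  ≥  Σ_{d ∈ children(c)} f_{p,d}      for all samples p, mutations c,
```

equivalently when the induced mixture
`u_{p,c} = f_{p,c} − Σ_{d ∈ children(c)} f_{p,d}` is nonnegative.

What the package does with this:

- **count** — exact arborescence counts via the directed matrix-tree
  theorem (integer Bareiss determinants; in-degree-product shortcut for
  single-source DAGs), a polynomial-time upper bound on the number of
  solutions;
- **enumerate** — every solution, by arborescence enumeration with
  sum-condition-invariant pruning (exact solution counting is #P-complete,
  so this carries an explicit size guard, default n ≤ 13);
- **sample** — solutions *exactly uniformly at random* by rejection: uniform
  arborescence draws (independent parent choice on DAGs; root-weighted
  cycle-popping / loop-erased walks in general) filtered by the sum
  condition, with a chi-square uniformity audit usable on any tool's tree
  samples;
- **constrain** — shrink the solution set with single-cell (root-path or
  chain reading) and long-read (ancestral comparability) constraints;
- **simulate** — ground-truthed instances (uniform labeled topologies,
  Dirichlet clone proportions, per-sample partition mixing, exact rational
  arithmetic end to end), plus edge recall and error-free read-count export.

See `docs/methods.md` for the model, the algorithms, every tunable default
and the simulator's scope.

## Worked example

A single sample with frequencies 0.8, 0.5, 0.2:

```python
import ppmspace as pp

F = pp.validate_frequency_matrix([[0.8, 0.5, 0.2]])
print("arborescences:", pp.upper_bound_solutions(F))
for sol in pp.enumerate_solutions(F):
    print(sorted(sol.tree.edges()),
          "U =", [[str(u) for u in row] for row in sol.mixture.values])

sols, report = pp.rejection_sample(F, 10_000, seed=7)
print("acceptance rate:", report.acceptance_rate)
for key, cnt in sorted(report.observed.items()):
    print(dict(key), cnt / report.acceptances)
```

prints

```
arborescences: 2
[('mut1', 'mut2'), ('mut1', 'mut3')] U = [['1/10', '1/2', '1/5']]
[('mut1', 'mut2'), ('mut2', 'mut3')] U = [['3/10', '3/10', '1/5']]
acceptance rate: 1.0
{'mut2': 'mut1', 'mut3': 'mut1'} 0.5074
{'mut2': 'mut1', 'mut3': 'mut2'} 0.4926
```

One bulk sample totally orders the frequencies, so the ancestry graph is a
total order with two spanning arborescences — and here *both* satisfy the
sum condition: the data cannot distinguish the chain (mut3 below mut2) from
the branching tree (mut2 and mut3 as siblings).  The mixtures `U` are exact
rationals reconstructing `F = U·B` identically.  Both arborescences being
solutions, the rejection sampler accepts every draw (rate 1.0) and splits
~50/50 between the two trees, as a uniform sampler must.  A long-read pair
`{mut2, mut3}` or a single cell `{mut1, mut2, mut3}` would collapse the
space to the chain (`pp.filter_solutions`).

The same analysis from the shell:

```sh
$ ppmspace stats F.tsv      # n, sources, branching coefficient, counts
$ ppmspace count F.tsv
2
$ ppmspace enumerate F.tsv -o sols.jsonl
$ ppmspace sample F.tsv -k 10000 --seed 7 -o sampled.jsonl --report report.json
$ ppmspace simulate -n 7 -m 2 --seed 42 --cells 3 --pairs 2 -o instance/
$ ppmspace filter sols.jsonl --freq F.tsv --pairs pairs.tsv -o kept.jsonl
$ ppmspace recall sols.jsonl instance/truth_tree.tsv
```

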
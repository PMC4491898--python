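# paretodp

Exact two-dimensional Pareto optimization inside a small algebraic
dynamic-programming (ADP) engine, demonstrated on RNA secondary-structure
prediction with two competing objectives and on joint pairwise RNA
alignment-and-folding (the Sankoff problem).

The package separates a dynamic program into a *tree grammar* (search
space), *evaluation algebras* (scoring + choice), and *products* of
algebras that combine two objectives: lexicographic (`product_lex`),
weighted-sum (`product_add_lambda`), and the Pareto product
(`product_pareto`), whose choice function is the Pareto front operator.
Because the Pareto product preserves Bellman's principle for strictly
monotone scoring algebras, the tabulated DP returns the *exact* front of
the (exponential) candidate space.

## Layout

| module               | contents |
|----------------------|----------|
| `paretodp.pareto`    | score pairs, order orientation, domination, the quadratic definitional front (test oracle), front operators `pf_sort` / `pf_isort` / `pf_lex` / `pf_smooth` / `pf_nosort`, linear `pareto_merge`, harmonic numbers |
| `paretodp.engine`    | signatures, tree grammars, tabulated evaluation, candidate enumeration, algebra products, the three Pareto evaluation strategies (`standard`, `sorted`, `eager`), monotonicity spot-checks |
| `paretodp.fold`      | folding grammar, simplified energy model (per-pair + per-stack), Boltzmann pair probabilities by inside–outside, expected-accuracy scoring, `fold_pareto` |
| `paretodp.sankoff`   | joint alignment-and-consensus-folding grammar, similarity (`SIM`) and base-pairing (`PROB`) algebras with corrected / anti-correlated variants, `sankoff_pareto`, an independent recurrence implementation for cross-checking |
| `paretodp.io` / `synth` / `cli` | FASTA and report I/O, seeded sequence generation, front-size simulation, operator benchmarking, the `paretodp` command |

## CLI

All commands are deterministic given `--seed`; the configuration is echoed
as `#` header lines in every output.

```sh
# seeded synthetic sequences
paretodp --seed 7 generate --n-sequences 5 --min-length 30 --max-length 40 --out seqs.fa

# Pareto front of (energy, expected accuracy) per record, with structures
paretodp fold seqs.fa --strategy eager

# joint alignment and folding of the first two records
paretodp sankoff pair.fa --variant corrected --psi partition --gap -3

# front-size Monte Carlo vs the harmonic law H(N)
paretodp --seed 3 simulate-front-size -n 100 --replicates 2000

# comparison-count benchmark of the front operators
paretodp bench-pf --sizes 1000,10000 --distributions random,sorted,anticorrelated
```

Exit codes: 0 success, 2 usage error, 3 malformed input.

## Notes

- Minimization is handled by orienting comparisons (`OrderSpec`), never by
  negating stored scores; energies are reported on their natural scale.
- `pf_lex` assumes lexicographically sorted input; the check runs only in
  debug mode so the linear-time bound survives in production.
- The energy model is deliberately simple and configurable (it is *not* a
  full nearest-neighbour parameter set); the Pareto machinery is
  model-agnostic.
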
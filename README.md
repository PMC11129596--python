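# contphy

Bayesian inference of time-calibrated phylogenies from multiple correlated
continuous characters.

The package implements, at desk scale:

- **Time trees with heterochronous tips and sampled ancestors** (`contphy.tree`):
  Newick/NEXUS parsing and writing (sampled ancestors as zero-length terminal
  edges), the deterministic tree → phylogenetic variance–covariance matrix,
  taxon pruning, and maximum-clade-credibility summarization with clade
  posterior probabilities and node-age HPD intervals.
- **Multivariate Brownian-motion likelihood** (`contphy.bm`): a dense
  Kronecker-construction reference oracle and two linear-time pruning
  algorithms — the classic three-quantity (Felsenstein-style) recursion and a
  quadratic-coefficient ("general") recursion — with per-character relative
  rates, an among-character correlation matrix (or its upper-triangular
  factor), a global clock rate, intraspecific variance added at the tips, and
  maximum-likelihood profiling of root character values.
- **Linear shrinkage of trait correlations** (`contphy.shrinkage`):
  within-species variance/correlation estimation from replicate measurements
  and the archetypal ridge estimator `rho* = delta I + (1 - delta) rho_hat`,
  with a deterministic leave-one-out cross-validation grid search for `delta`.
- **Fossilized-birth–death and BDSS tree models** (`contphy.treeprocess`):
  an event-driven forward simulator with Poisson fossilization, Bernoulli
  extant sampling and pruning of unsampled history; analytic log-densities
  validated against the simulator; a direct (rejection) BDSS simulator
  conditioned on sample counts and tip-time orientation.
- **Synthetic data** (`contphy.simdata`): BM tip characters, tree-free white
  noise, their convex mixture, and within-species individual replicates.
- **MCMC inference** (`contphy.inference`): single-chain Metropolis–Hastings
  over the continuous-morphology posterior (likelihood × tree prior ×
  parameter priors) with scalar scalers, Gibbs updates for the clock rate and
  root values, node-age/root/tree-scale moves, constrained subtree exchange,
  and a reversible-jump sampled-ancestor toggle; HPD intervals, effective
  sample sizes, and coverage/accuracy study drivers.
- **Morphometrics** (`contphy.morphometrics`): generalized Procrustes
  superimposition, Procrustes distances, landmark flattening/normalization,
  and SMACOF metric MDS with per-iteration stress tracking.

## CLI

All subcommands are under a single entry point:

```sh
contphy simulate-tree --model fbd --lambda 1.0 --mu 0.25 --psi 0.1 \
    --stop-time 3.0 --seed 1 --out tree.nwk
contphy simulate-chars --tree tree.nwk --k 4 --pairwise-corr 0.5 \
    --w 1.0 --seed 2 --out chars.tsv
contphy loglik --tree tree.nwk --chars chars.tsv --algorithm felsenstein
contphy infer --tree tree.nwk --chars chars.tsv --chain-length 20000 \
    --sample-every 20 --seed 3 --out run
contphy shrink --replicates replicates.tsv --out shrinkage
contphy procrustes --landmarks landmarks.tsv --out aligned.tsv
contphy mds --landmarks landmarks.tsv --seed 4 --out mds.tsv
contphy coverage --n-reps 100 --seed 5 --out coverage.tsv
```

File formats are plain text: Newick/NEXUS trees (tip dates recoverable from
branch lengths, optional `taxon<TAB>age` sidecar), tab-separated character
matrices (`taxon` + one column per character), replicate tables
(`species<TAB>individual<TAB>char...`), and landmark tables
(`specimen<TAB>landmark<TAB>x<TAB>y<TAB>z`). Stochastic commands require
`--seed` and write a JSON provenance sidecar.

## Conventions

- Node ages are times before present; the youngest tip anchors age 0 unless
  explicit tip dates are given.
- Taxon ordering in covariance matrices is lexicographic by tip label.
- Sampled ancestors are stored (and serialized) as zero-length terminal
  edges.
- All stochastic APIs take explicit integer seeds; no global random state.
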
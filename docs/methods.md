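# Methods

This note documents the models and procedures implemented in `cfnforest`,
the defaults chosen where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Preprocessing

Input is a samples×genes real matrix with an explicit missing-value mask
(empty cells or `NA` in files). The chain is:

1. **Missing-sample filter.** A sample is dropped iff its missing fraction
   strictly exceeds the threshold (default 0.20); a sample at exactly the
   threshold is kept. The denominator is the gene count before filtering.
2. **KNN imputation** (default k = 5). Distance between two samples is the
   plain Euclidean distance over the genes observed in both; each missing
   cell is the mean of the k nearest samples that observe that gene. When a
   held-out sample is imputed, neighbours are drawn from the training
   samples only. Observed entries are never altered. (This deliberately
   uses unscaled shared-gene distances; implementations that rescale by the
   shared-gene count can rank neighbours differently.)
3. **Per-gene standardization** to (f − E(f)) / spread. The default spread
   is the population standard deviation; `divisor="var"` divides by the
   variance instead for compatibility with that convention. Zero-spread
   genes map to all-zero columns. The fitted (mean, spread) pairs are
   serializable and are reused verbatim on validation/test folds — they are
   never refitted on held-out data.

## Flexible neural trees

A tree's leaves emit feature values; an internal node of arity M outputs
σ(Σ ω_j I_j + θ) over its children. Evaluation is bottom-up and vectorised
over samples. The pre-activation is clamped to ±500 before exponentiation,
which changes no output by more than ~1e−200 but avoids floating overflow.
Leaves carry no weights of their own; all weights live on internal nodes.
A bare-leaf tree is legal (it can arise during evolution) but carries no
trainable parameters.

Parameters flatten to a vector in pre-order node order, (ω_1..ω_M, θ) per
node — the bridge to the swarm optimizer. Trees serialize to JSON
(node type, arity, feature index, weights, bias, children).

**Fitness** is the root-mean-square error between the {0,1} bit target and
the tree output, minimized; it is exactly zero iff every sample is
reproduced.

## Structure search (GGGP)

Generation, crossover and mutation are all grammar-constrained, so every
individual in every generation is syntactically valid: arities come from
the configured function set, leaves from the input features, and depth
never exceeds the bound (default 5; a single node has depth 1).

Open choices and their defaults:

- A nonterminal expands to a function node with probability 0.55 (else a
  leaf). Higher values produce bloated trees whose long parameter vectors
  the swarm cannot fit at realistic budgets; lower values collapse the
  population toward bare leaves. 0.55 keeps random trees at roughly 5–30
  parameters.
- Selection is tournament selection over `tournament_size` (default 3)
  *distinct* individuals — sampling without replacement is what makes a
  full-population tournament deterministically return the best individual.
- Elitism of exactly one guarantees a monotone best-fitness trajectory.
- Crossover swaps one uniformly chosen subtree of each parent, resampling
  swap points until both offspring respect the depth bound (up to 20
  attempts, then parent copies). Parents are never mutated in place.
- Mutation replaces a uniformly chosen node by a fresh random subtree
  fitting the remaining depth budget, with probability `mutation_prob`
  (default 0.2).
- Initial weights and biases are U(−1, 1).
- The loop stops at `generations` or as soon as fitness < 1e−4.

## Parameter search (PSO)

Velocities follow v ← ωv + c₁r₁(p_best − x) + c₂r₂(g_best − x), clamped
componentwise to ±V_max; positions follow x ← x + v with no position
clamp. Defaults are the standard constriction-equivalent values ω = 0.729,
c₁ = c₂ = 1.49445, swarm 30, 50 iterations, V_max = 4, constant inertia.

- r₁, r₂ are drawn per **dimension** per particle per update. The scalar
  variant (one draw per particle, matching the scalar notation of the
  update rule) is available via `per_dimension=False`, but it confines each
  move to the span of three vectors and in benchmarks fails to reach 1e−3
  on a 10-dimensional sphere within 200 iterations for most seeds, where
  the per-dimension variant reaches ~1e−10 on every seed tried.
- The swarm is seeded around the incumbent tree's parameters (one particle
  exactly at them, the rest perturbed by U(−1,1)) so PSO refines rather
  than restarts; initial velocities are zero, making the first moves purely
  attraction-driven. With zero iterations the tree is returned unchanged.
- The g_best trace is monotone non-increasing by construction, and the
  returned tree's fitness never exceeds the incumbent's.

## The alternating training loop

`train_fnt` alternates structure search and parameter search for
`outer_rounds` rounds (default 3), stopping early when fitness falls below
tolerance or the relative improvement drops under 1e−3. Rounds after the
first seed the GP population with the PSO-refined incumbent plus a handful
of forced mutants of it (population_size/5), so tuned weights propagate
through crossover. The returned tree is the best post-refinement tree over
all rounds.

## Class codes, groups, forests

M classes are coded on L = ⌈log₂ M⌉ bits; class i receives the big-endian
binary representation of i in class-list order (documented so model files
are portable). For M not a power of two the surplus codes are unused:
decoding minimizes Euclidean distance over the *valid* codes only, with
ties broken toward the smallest class index. Each group holds one FNT per
bit; a forest bags K groups (default 5), each trained on a classical
n-out-of-n bootstrap, redrawn (bounded retries) if a class is entirely
absent. Forest output is the componentwise mean over groups. Each group
consumes an independently spawned random stream, so growing K never
changes the groups already trained.

For the rows a forest was trained on, the forest also exposes out-of-bag
(OOB) scores: the mean over the groups whose bootstrap excluded the row
(falling back to the full mean for rows in-bag everywhere).

## The cascade

Each layer trains three forests with function sets {+2,+3,+4}, {+2,+3,+5}
and {+2,+4,+5}. Enhancement features accumulate: layer ℓ reads the
original features plus the 3·L outputs of *every* previous layer, so its
input width is base + (ℓ−1)·3·L.

- **Training-row enhancement features are OOB scores**, not in-sample
  predictions: in-sample scores are optimistically accurate and teach
  deeper layers to over-trust them (measured ≈ 5 points of cross-validated
  macro-F1 on the four-class benchmark). Held-out samples simply get the
  forests' predictions — no label information flows.
- **Confidence gate.** A sample is confident iff every component of the
  layer's fused score lies in [0, low] ∪ [high, 1], closed at both cut
  points (defaults 0.2 / 0.8). Confident training samples stop
  contributing to deeper layers' training pools (`train_on="uncertain"`,
  the default; `"all"` retrains every layer on the full pool). The
  degenerate region low = high covers all of [0,1] and disables the gate.
- **Depth.** A stratified validation split (default fraction 0.25) scores
  the whole cascade after each layer; growth stops at `max_layers`
  (default 5), when the gain stays under `min_gain` (0.005) for `patience`
  (1) layers, or when the uncertain pool empties or loses a class. The
  returned model is trimmed to the best validated depth.
- **Fusion.** The final score of a sample exiting at layer j is
  y_f = Σ_{i≤j} ω_i y_i with the weights renormalized over the traversed
  prefix. Default weights ω_i = i / (1 + ⋯ + N) increase with depth and
  sum to one, keeping y_f a proper weighted average in [0,1]^L. The
  alternative `weights="literal"` uses ω_i = i / (1 + ⋯ + i) = 2/(i+1) —
  a decreasing sequence that does not sum to one, so fusion renormalizes
  it over the traversed layers as well.

A note on the gate's worked illustration used in the tests: with region
[0, 0.2] ∪ [0.8, 1], the five score vectors {[0.07,0.03], [0.35,0.44],
[0.52,0.67], [0.83,0.12], [0.95,0.14]} split into three confident vectors
(1st, 4th and 5th — every component inside the region) and two uncertain
ones. Conventions under which the 4th vector would be uncertain exist but
are not well defined by the all-components rule, so the rule is applied
uniformly and the 4th vector counts as confident.

## Synthetic benchmark data

`SyntheticSpec`/`make_dataset` emulate the statistical structure the
classifier assumes: the first `n_informative` genes are split into M
disjoint blocks of near-equal size (all informative genes are used; block
sizes differ by at most one), class c's block mean is raised by `shift`,
every gene carries N(0, noise_sd) noise, and cells go missing uniformly at
random. Defaults describe a four-class cohort of 50 samples per class with
40 genes, 10 informative, shift 2.0, unit noise and 5 % missingness.

What this does *not* emulate: RNA-seq count distributions (negative
binomial), library-size effects, batch structure, or correlated gene
modules. Because the model consumes z-scored values, Gaussian fixtures
exercise every code path; passing tests demonstrate correct mechanics and
recovery of linear mean-shift signal, not performance on real cohorts.

## Performance characteristics and known limitations

- The M-ary decomposition trains the L code bits independently, so
  per-sample accuracy behaves like the product of per-bit accuracies. On
  the default four-class benchmark (100 training samples per fold) the
  bagged forests reach per-bit test accuracies of ≈ 0.87–0.91 — at the
  level of a per-bit logistic regression or small regularized MLP on the
  same folds — which caps single-layer four-class accuracy near 0.75–0.83.
  Deeper layers with enhancement features recover a few points (two-fold
  CV macro-F1 ≈ 0.73–0.83 across seeds at small search budgets: K = 3,
  population 20, 10 generations, PSO 20×30, ≤ 3 layers). Methods that
  model all classes jointly (nearest centroid, random forest) reach ≈ 0.92
  on the same data; the gap is a property of the log₂M-bit output coding
  at this sample size and effect size, not of the search budgets —
  raising them does not close it.
- GP structure search is noisy at small budgets; two runs with different
  seeds can differ by several points of accuracy. Everything is exactly
  reproducible under a fixed seed.
- Problem sizes in the test-suite and acceptance runs (tens of genes,
  dozens-to-hundreds of samples, small GP/PSO budgets) were chosen to keep
  desk-scale runs in the minutes range; all budgets scale via the config.
- No gradient training of weights (PSO only), no parsimony pressure, no
  redundant error-correcting output codes, no multi-grained scanning: the
  implementation deliberately stays within the architecture described
  above.
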
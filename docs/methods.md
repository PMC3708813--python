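# Methods

## Model

Two binary characters — a focal character *h* (gene presence/absence of a
chaperone such as bacterial Hsp90) and a partner *X* (another gene, or a
binarized organismal trait) — evolve along a rooted phylogeny with branch
lengths as a continuous-time Markov chain on the four joint states
1:(h−,X−), 2:(h+,X−), 3:(h−,X+), 4:(h+,X+). Simultaneous changes of both
characters are excluded, so the generator has eight free off-diagonal
entries q12, q13, q21, q31, q24, q34, q42, q43 (qxy = rate from joint state
x to y); the four slots 1↔4 and 2↔3 are exactly zero and the diagonal is the
negative row sum. The four dependency models are rate-equality restrictions:
independent (q12=q34, q21=q43, q13=q24, q31=q42; 4 free), mutual (none; 8),
partner-follows-focal (q12=q34, q21=q43; 6) and focal-follows-partner
(q13=q24, q31=q42; 6). The model assumes a correct, fixed tree, homogeneous
rates across lineages and time, and independence of different partner
characters given the focal one — all idealisations; see Limitations.

Likelihood of the observed tip states is computed by the pruning algorithm
(post-order propagation of conditional likelihoods through per-branch
transition matrices exp(Q·t)), combined at the root with a prior over the
four states. The root prior is uniform (¼,¼,¼,¼) by default and can be set
to the model's stationary distribution or any fixed distribution; the
uniform default keeps the null and alternative models on the same footing
and measured calibration was indistinguishable between the two choices.

## Fitting

Free rates are estimated by bounded maximum likelihood in log-rate space
(L-BFGS-B; bounds 1e-8 to 100 events per unit branch length per rate).
Starting points are optional warm starts plus `n_restarts` log-uniform
random draws within the bounds, all derived from a seed, so any fit is
bit-reproducible. Ties between restarts keep the earliest. The package's
default for a standalone `fit_ml` call is 10 restarts. The LRT helper fits
the 4-parameter independent model first (deterministic initial guess of 2
events per mean root-to-tip depth, plus restarts), warm-starts the
8-parameter mutual model from that solution — which guarantees
lnL₈ ≥ lnL₄ and hence a non-negative statistic — and finally re-polishes
the independent fit from the mutual solution projected (geometric mean of
tied slots) onto the independence constraints, a monotone improvement of
the null likelihood.

## Screen, classification, consensus

Per screen run every partner character is tested with 2·ΔlnL against χ²
with 4 degrees of freedom (the free-parameter difference of the nested
pair) and corrected across characters by Benjamini–Hochberg at the chosen
FDR (default 5%). Replicate runs differ only in optimizer restarts; the
consensus rule (associated iff flagged in ≥ `agree_threshold` of `n_runs`
runs; conventionally 90/100 at full scale, 23/25 at desk scale) absorbs
run-to-run optimisation noise. Per-(run, character) seeds are derived by
hashing the master seed with the run index and the character id, so results
are invariant to character ordering. Classification fits all four models
(dependency models warm-started from the independent fit), picks the
per-run AIC minimizer with ties broken toward fewer parameters and then a
fixed model order, and applies the same consensus rule. Classification is
meant to run on screen survivors (the two-stage scheme is the stringency
mechanism); the library does not forbid calling it directly for
diagnostics.

Measured null calibration under the standard simulation conditions
(200-leaf Yule tree, gain = loss = 0.5): the LRT rejects at 0.066 at
α = 0.05 over 500 null datasets, inside the exact binomial 95% interval
around 0.05; the null statistic is mildly stochastically larger than χ²₄
(mean ≈ 4.4), a known finite-sample/boundary effect of rate bounds at this
tree size. These numbers are recomputed by `tests/test_acceptance.py`.

## Client index

Client scoring uses the unrestricted (8-rate) fit only. Zero rates are
replaced by 0.001 × the smallest nonzero rate so the chain is irreducible;
the stationary distribution is then the solution of the balance equations
Qᵀπ = 0 with one equation replaced by the normalization Σπ = 1 — an exact
4×4 linear solve rather than a long-time matrix-exponential limit (the two
agree to 1e-6 in tests). PCI = C/((C+D)(A+C)) equals 1 identically under
the independence restrictions and is invariant to rescaling all rates by a
common factor (time-unit invariance). Because no natural threshold exists,
client calling is rank-based: per run the `top_k` lowest-PCI characters
form a candidate set and the consensus rule intersects them across runs;
both `top_k` (default 20) and the threshold are explicit parameters, and
per-run sets and means are both reported.

## Enrichment

Over-representation of annotation categories in a result set against the
background of all analyzed characters uses the upper-tail hypergeometric
probability P(X ≥ k) without mid-p correction, drops categories with fewer
than 4 background members, and controls FDR by Benjamini–Hochberg at 5% by
default.

## Input handling

Newick trees must carry branch lengths; zero-length branches are replaced
by ε = 1e-5 (all transition matrices then well-conditioned; ε is a
parameter). Polytomies are accepted natively by the pruning algorithm.
Trees and matrices are pruned to their exact shared taxon labels
(whitespace-stripped string equality, no fuzzy matching). Characters with
fewer than 5 present or 5 absent taxa are dropped — near-invariant profiles
carry no gain/loss signal. Gene matrices must be complete; trait tables may
have missing annotations, and each trait analysis prunes the tree to its
annotated taxa (≥3 required). Trait recodings: pathogenic toward any host →
1; thermophilic or hyperthermophilic → 1; anaerobic → 0 with every other
annotated oxygen class → 1; more than one habitat category → 1. The
category vocabulary is a parameter because upstream annotation tokenization
varies between sources.

## Synthetic data

The generator emulates the statistical structure of a phylogenetic
profiling screen: a birth–death tree (default pure birth, rate 1, so a
150-taxon tree has mean depth ≈ ln 150 ≈ 4), a focal character with gain =
loss = 0.5 (stationary presence ½, a handful of events per root-to-tip
path), and partner genes in labelled blocks. Default block rates: background
(independent) genes gain = loss = 0.5; dependent genes use 10-fold rate
contrasts between focal-present and focal-absent states; client-like genes
additionally have gain-without-focal = 0.01 ≪ loss-without-focal = 1.
Characters are simulated by exact Gillespie realization of the joint chain
along each branch (root state from the regularized stationary distribution
unless fixed) and re-simulated up to a retry cap if they fail the 5/5
variation filter, with the retry count recorded in the truth table.

A screen dataset carries a single focal column, so by default every partner
gene is simulated *conditional on one recorded focal realization*: the
focal path (piecewise-constant states along every edge) is stored and each
partner evolves as a two-state chain whose gain/loss rates switch with the
focal state (Markov-modulated simulation). This is exact whenever the
focal character's own rates do not depend on the partner (independent and
partner-follows-focal blocks, including client-like genes) and realizes
only the partner-direction dependence for mutual or focal-follows-partner
rates. The alternative mode (`shared_focal=False`) gives each gene a fresh
exact joint realization, which is marginally correct per gene but leaves
the shared focal column independent of every partner column — suitable only
for per-gene fitting studies, for which `simulate_pair` is the direct tool.

What the simulator does **not** emulate: horizontal transfer as explicit
donor–recipient events (gains are independent per lineage), rate
heterogeneity across lineages or in time, correlated blocks of genes
(operons), tree estimation error, or annotation noise. Passing tests on
synthetic data therefore demonstrate correctness and calibration of the
inference machinery under the model's own assumptions, not robustness to
their violation in real genomic data.

## Numerical choices

Per-branch transition matrices use the eigendecomposition of the 4×4
generator shared across all edges; the pruning sweep applies
P·v = V·diag(exp(wt))·(V⁻¹·v) per edge in a compiled kernel with per-node
rescaling against underflow. When the eigenvector matrix is
ill-conditioned (defective generators at exact rate ties) the code falls
back to scipy's Padé/scaling-squaring `expm` per branch; the public
`transition_probabilities` always uses scipy's `expm`, so the fast path is
cross-checked against an independent route in the tests (agreement 1e-10;
row-sum tolerance 1e-8). Likelihood ratios are floored at zero. AIC ties
resolve toward fewer parameters, then a fixed model order. Degenerate
inputs (all-zero rates, traits identical to the focal character, invariant
characters after pruning) raise typed errors or logged warnings rather
than producing silent numbers.

## Problem sizes

The test suite's calibration studies use the sizes that make the checks
statistically meaningful at desk scale: 500 null datasets on a 200-leaf
tree for type-I error, 20 replicates each at 50 vs 400 taxa for estimator
consistency, 20 replicates at 300 taxa for classification recovery, and a
50-gene screen (5 client-like) on a 120-leaf tree with 25 runs/threshold
23/top-k 10 for client recovery. Full-scale screens (hundreds of genomes,
thousands of genes, 100 runs) use identical code paths.

## Known limitations

- The χ²₄ reference for the LRT is asymptotic; at a few hundred taxa the
  null statistic is slightly inflated (see calibration above), so
  marginal associations near the threshold deserve skepticism.
- PCI is computed from point estimates of rates; the replicate-run
  consensus propagates optimisation variability but not statistical
  uncertainty in the rates themselves.
- The conditional simulation mode under-represents partner→focal feedback
  for mutual dynamics, as described above.
- Characters are analyzed pairwise against the focal one; indirect
  associations through a third character are not deconfounded.
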
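# Methods

## Model

`structdrift` simulates *structural drift*: neutral genetic drift
generalized to ordered populations with memory. A population of M haploid
individuals is a length-M string of alleles over a finite alphabet
(binary, `{'0','1'}`, throughout the canonical library). The sampling
process is represented by a unifilar probabilistic finite-state generator
(an ε-machine): a set of causal states S with per-symbol transition
probabilities T^(a)_{σσ'}, where each symbol emitted from a state
determines the next state uniquely. Each generation, the current machine
M_t generates a sample P_t of length M; the next machine M_{t+1} is
re-estimated from P_t; the chain iterates. Classical Fisher–Wright drift
is the special case of a single-state (IID, biased-coin) machine, where
re-estimation reduces to binomial resampling of the bias.

Drift terminates at *structural stasis*: the vanishing of the allelic
entropy (entropy rate)

    h_mu = − Σ_σ π(σ) Σ_{(a,σ')} T^(a)_{σσ'} log2 T^(a)_{σσ'}   [bits/allele]

computed in closed form on the recurrent part of the machine, with π the
stationary state distribution (left unit eigenvector of the state-to-state
matrix). Stasis subsumes fixation, deletion, and periodic equilibria: it
holds exactly when no recurrent state branches. The companion measure is
the allelic complexity C_mu = −Σ_σ π(σ) log2 π(σ) (bits of state memory);
the (h_mu, C_mu) plane is the complexity-entropy (CE) diagram used to
visualize subspace structure. Block entropy H(L) of the length-L word
distribution is computed by exact enumeration (guarded at |A|^L ≤ 10^6)
and is used only for cross-checks, since H(L) diverges for aperiodic
processes and is not a stasis test.

All measures are computed on the recurrent component only; transient
states are excluded from π, h_mu and C_mu.

## Estimation and the PSV proposals

Re-estimation feeds the sample through the machine (the maximum-likelihood
start state; ties broken by state-identifier order), counts edge
traversals, and normalizes counts per state. Edges with zero count are
deleted immediately — no pseudocounts — because stasis requires edges to
vanish at finite sample sizes. A state whose outgoing edges were never
traversed (possible only for the final state of the parse path or for
states off the path) keeps its previous distribution; unvisited states are
flagged transient, and unvisited states that cannot even reach the visited
set are dropped so the recurrent part stays a single terminal component.

Full ε-machine reconstruction is replaced by two explicit topology
proposals arbitrated by penalized likelihood (a pseudo-sampling-variable
scheme):

- **Innovation** (off by default): a state is chosen uniformly and cloned;
  each of its incoming transitions is rerouted to the clone independently
  with probability 1/2 (resampled until at least one is rerouted and one
  kept; states with fewer than two incoming edges reject immediately).
  Gaussian noise (σ = 0.05 by default, in probability units) is added to
  the clone's outgoing probabilities, clipped to [10⁻⁶, 1] and
  renormalized, so the noise step alone can never delete an edge.
  The candidate is kept iff it assigns the sample a strictly higher
  log-likelihood (uniform model prior, so MAP reduces to maximum
  likelihood; ties keep the incumbent, i.e. the smaller machine).
- **Loss**: when any edge probability falls below `merge_threshold`
  (default 3/M — an edge supported by at most about two observations),
  every pairwise state merging is formed. Unifilarity conflicts are
  resolved by recursively merging the conflicting targets; the merged
  topology is re-fitted to the sample by the same count-normalization and
  canonicalized. Candidates and incumbent are scored with
  AIC = 2k − 2 ln L̂, by default corrected for finite samples,
  AICc = AIC + 2k(k+1)/(n−k−1), n the sample length; the minimizer wins,
  ties broken toward fewer states, then fewer edges.

The parameter count is k = number of transitions — one probability
parameter per edge. Counting only per-state free parameters (edges minus
states) would give the two-state golden-mean topology and the one-state
coin the same penalty; since the golden-mean MLE always fits its own
samples at least as well as the IID MLE, state merging would then never be
selected and the biased-coin subspace would be unreachable from the golden
mean. Counting every edge makes the penalty grow with model size, which is
what lets a smaller machine with adequate fit win at near-zero edge
probabilities — the regime in which merges are observed to fire.

Both proposal rates default to once per generation. Innovation is scored
on raw likelihood and loss on penalized likelihood; the asymmetry is
deliberate: innovations must pay for themselves in fit immediately, while
simplifications are granted a complexity credit.

## Per-generation order of operations

generate → (innovate?) → re-estimate → (loss?) → stasis test. The stasis
test runs on the post-re-estimation machine, whose probabilities are exact
integer-count ratios; a stasis machine therefore has h_mu exactly 0.0 and
the 10⁻¹² tolerance is only a guard. Stasis is provably absorbing here:
every recurrent edge has probability 1, re-estimation reproduces it
exactly, a noise-free clone ties and is rejected, and no edge sits below
the merge threshold.

## Canonicalization and subspace signatures

`canonicalize` trims transient states, merges states whose future word
distributions agree (partition refinement to depth |S|, probabilities
compared after rounding at the tolerance, default 10⁻⁹), and relabels
states S0, S1, … breadth-first from the state with the lexicographically
smallest behavioral signature; it is idempotent and preserves the word
distribution. A subspace *signature* is the canonical topology with
probabilities discarded, encoded relabeling-invariantly (minimum over BFS
root choices). Machines differing only in positive transition
probabilities share a signature; any support change is a subspace jump.
Note the all-'0's and all-'1's fixed coins are distinct topologies (their
single edges carry different symbols); analyses that follow the "fixed
coin" pathway treat the pair as its two symbol variants.

Dwell time in a subspace counts generations from the entry record
(inclusive) to the exit record (exclusive), with the terminal record
excluded; this makes the pathway decomposition an exact accounting
identity: the grand mean stasis time equals the pathway-weight sum of
pathway means, and each pathway mean equals the sum of its per-subspace
mean dwells. At each subspace entry the outgoing probability vectors of
the branching states are recorded, so post-jump dwell times can be
compared against classical absorption times started from the entry bias.

## Classical baseline

The `kimura` module implements the memoryless chain directly: allele
count j ~ Binomial(M, i/M) per generation, Δp moments (0, p(1−p)/M), and
the diffusion-limit conditional absorption times
t̄1(p) = −(1/p)·4Ne(1−p)ln(1−p) and t̄0(p) = −4Ne·(p/(1−p))·ln p, with the
boundary value t̄1(p→0) = 4Ne. Ne counts diploid individuals; for haploid
samples of M alleles use Ne = M/2. Conditional means average only
realizations absorbed at the conditioning boundary. An exact small-M
oracle (`conditional_absorption_times`) solves the absorbing chain by a
Doob h-transform and linear algebra and agrees with the diffusion formula
to within 5% at M = 50.

## Simulated conditions

The ensemble experiments use sample length M = 100 and 400 realizations
per setting — ensembles of a size that give standard errors a few percent
of the means for these processes — with initial biases on a 0.1-spaced
grid. The classical calibration uses diploid populations of N = 100
individuals (M = 200 alleles), the structural-drift comparisons haploid
M = 100. Reported stochastic comparisons use 3-standard-error bands.

## What the generator does and does not emulate

Populations are generated internally by the machines themselves; there is
no external data. The framework emulates neutral, constant-size,
non-overlapping-generation drift with sampling memory; it does not model
mutation, selection, recombination, diploid genotype structure, or
spatially/graph-structured reproduction. Passing tests therefore
demonstrate the internal consistency of the drift dynamics and their
agreement with classical theory in the memoryless subspace — not fidelity
to any empirical population.

## Numerical choices and degenerate inputs

- Log base 2 throughout; natural log only inside AIC (converted
  internally).
- Probability-comparison tolerance 10⁻⁹ (canonicalization rounding);
  row-stochasticity enforced at 10⁻⁹ on construction; stationary
  distribution solved by dense linear algebra (machines are tiny).
- `biased_coin(p=0)` and `p=1` degenerate to the fixed coin; branching
  constructors reject probabilities outside (0,1).
- The golden-mean constructor exposes which symbol may not repeat
  (`forbidden`, default `'1'`); state counts and information measures are
  unaffected by the choice.
- Parsing a sample with no admissible path returns −∞ log-likelihood;
  re-estimation then raises, and proposal scoring treats the candidate as
  +∞ (rejected).
- `max_generations` defaults to 10⁵ as a safety cap (absorption is almost
  surely finite); capped runs are flagged unabsorbed and excluded, with a
  warning, from stasis-time statistics.
- Master seed spawns per-realization child generators via NumPy
  seed-sequence spawning, so ensembles are reproducible and order-
  independent.

## Known limitations

- The innovation/loss rates, noise scale and merge threshold are modeling
  choices, not fitted quantities; the qualitative subspace phenomenology
  is robust to them but jump *rates* are not, and sensitivity should be
  reported alongside any quantitative use.
- Signatures distinguish symbol-relabeled topologies (e.g. the two fixed
  coins); an alphabet-permutation-invariant variant would halve some
  pathway inventories.
- The word-distribution enumerator is exponential in L by design (guarded);
  entropy-rate estimates for large-alphabet machines should rely on the
  closed form instead.
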
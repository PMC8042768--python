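# Methods

## Model

Each site k of an ultraconserved element (UCE) of length l evolves by a
continuous-time Markov process on {A, C, G, T} whose rate matrix combines
three ingredients:

1. **Mutation.** A global 4×4 mutation-rate matrix **M** shared by all UCEs.
   The default parameterisation is the unrestricted 12-rate model (UNREST):
   eleven free nonnegative rates with the G→T rate pinned at 1 to fix the
   relative scale; diagonals are negative row sums. JC, HKY and GTR
   parameterisations are available for restricted analyses.

2. **Spatially varying stabilizing selection.** Every UCE has an optimal
   nucleotide sequence n\* (fixed across the tree) and a Gaussian
   sensitivity profile

   f(x) = Nes_max · exp(−(x − x̄)² / (2σ²)),

   with peak composite sensitivity Nes_max ≥ 0, center x̄ ∈ [1, l]
   (continuous, 1-based), and width σ > 0 in site units. f is the
   *composite* Ne·s: only the product of effective population size and
   selection coefficient is identifiable from substitution data, so the
   profile parameterises it directly. The per-copy selection coefficient at
   site k is s(k) = f(k)/Ne with Ne a fixed configuration constant
   (default 10⁶, diploid b = 1); no result depends on Ne beyond O(s)
   corrections. `sequence_fitness` consequently returns the
   population-scaled fitness exp(−Σ d·f), i.e. the per-copy fitness raised
   to the Ne power, where d is the binary mismatch distance.

3. **Drift.** A mutant j arising in a resident population fixed for i fixes
   with probability u = (1 − r^b)/(1 − r^(2Ne)), where r is the
   resident/mutant fitness ratio (r = e^(+s) for a change away from the
   optimum, e^(−s) toward it, 1 between two non-optimal bases) and b is 1
   for diploids, 2 for haploids. This is the diffusion limit of a
   Wright–Fisher population with 2Ne gene copies under multiplicative
   (semidominant) allelic selection — the convention the forward-simulation
   tests use. The substitution rate is q_ij = 2b·μ_ij·Ne·u_ij; in the
   neutral limit (f = 0, b = 1) this reduces exactly to μ_ij, and for a
   deleterious change it approaches the classic 2b·μ_ij·f/(e^(2f) − 1).

Each site's stationary distribution π solves πQ = 0 (direct linear solve
with the simplex constraint; eigen-decomposition fallback with a residual
check). Root state frequencies equal π — the process is assumed to start at
equilibrium — and the model is non-reversible, so root placement matters
and no pulley-principle rerooting is ever applied.

### Branch-length calibration (scale factor)

Raw matrices are rescaled so one unit of branch length equals one expected
substitution per site. Two conventions are implemented:

* **per-site** (default): every site's Q is divided by that site's own
  stationary rate C_k = −Σ_i π_i q_ii. The calibration then holds exactly
  at every site; conserved sites carry a full substitution load whose
  changes are mostly unobservable (they revert toward the optimum), which
  is precisely why a spatially invariant GTR+Γ fit of such data
  underestimates tree length by roughly half on the benchmark scenarios —
  the behavior this model family was designed to expose. A tiny floor
  (10⁻¹²) guards effectively frozen sites.
* **mean**: all sites divided by the dataset-wide mean stationary rate,
  preserving relative substitution-flux differences between sites. Under
  this convention GTR+Γ recovers tree length almost unbiasedly on the same
  data, so it is kept as an engine option for sensitivity analyses rather
  than as the default.

Under per-site scaling the likelihood factorises over UCEs and sites with
no global coupling; under mean scaling the shared C couples all UCEs, and
the optimizer holds C fixed within the separable stages and refreshes it
between stages (re-running a stage once, then reverting, if a refresh ever
loses likelihood — so the reported trace is monotone in both modes).

## Likelihood

Felsenstein pruning over rooted binary trees with per-site 4×4 transition
matrices P(t) = exp(Qt). Batched eigen-decomposition computes all sites'
and branches' matrices at once (complex eigensystems are expected for
non-reversible Q; ill-conditioned eigenbases fall back to
scaling-and-squaring `expm`). Per-node rescaling with accumulated log
scalers controls underflow. Gaps and IUPAC ambiguity codes are a single
MISSING state contributing partial likelihood 1 at the leaf, so an
all-missing column contributes exactly zero log-likelihood and an
all-missing taxon is equivalent to pruning that leaf.

Evaluations collapse alignment columns that share both a rate-matrix class
and an observed pattern; this is exact and matters most for the GTR engine
(whose per-UCE matrices make columns within a UCE exchangeable) and for
neutral data.

### GTR+Γ comparison model

The spatially invariant comparison model is GTR+Γ partitioned by UCE: each
UCE gets its own five free exchangeabilities (G–T pinned at 1), base
frequencies (fitted by maximum likelihood, not empirical counts) and Gamma
shape α, with branch lengths shared across UCEs by default (a per-UCE
branch-length mode exists). The unit-mean Gamma density is discretised by
generalized Gauss–Laguerre quadrature (default four categories, eight
optional), computed by Golub–Welsch on the Jacobi matrix so the normalized
weights are stable for any α — the raw quadrature weights overflow beyond
α ≈ 170. A site's likelihood is the weight-averaged category likelihood,
and the model-averaged site rate used in reports is the posterior mean
Σ r_c w_c L_c / Σ w_c L_c.

Model comparison uses AICc with sample size n = taxa × sites. For the
selection model, K = 11 mutation rates + 3 shape parameters per UCE +
branch count + one parameter per optimal nucleotide (Σ l_u); counting the
optima is a deliberate (and conservative for the model) choice, with a
configuration switch to exclude them. For GTR+Γ, K = 9 per UCE + branches.

## Optimization

Four-stage hill climbing, repeated until the total log-likelihood improves
by < 1% between cycles or 12 total cycles:

1. **Branch lengths** — bounded 1-D search (Brent, bounds [10⁻⁹, 10],
   tolerance 10⁻⁷) per branch, sweeping pendant edges first and then edges
   in increasing "generation" (an edge is optimized only after every edge
   below it), repeated until < 1% improvement or 10 total sweeps. A
   proposal is accepted only if it improves the likelihood.
2. **Shape parameters** — per-UCE bounded Nelder–Mead over (log Nes_max,
   x̄, log σ); log coordinates keep the simplex conditioned where the
   likelihood saturates in Nes_max (a frozen core looks the same at
   Nes_max 15 and 30). Bounds: Nes_max ∈ [0, 50], x̄ ∈ [1, l],
   σ ∈ [0.1, 10l]. The first cycle uses three starts: the incumbent, a
   conservation heuristic (centroid and spread of the invariant columns)
   and a seeded random draw.
3. **Mutation rates** — bounded Nelder–Mead over the 11 free log rates,
   maximizing the exact total log-likelihood.
4. **Optimal sequence** — for every site, score the four candidate optima
   (rebuilding that site's Q and π, scale factor held fixed during the
   sweep) and keep the argmax; ties keep the incumbent.

Any bounded derivative-free simplex-family optimizer satisfies the
contract; scipy's bounds-respecting Nelder–Mead is used, with per-stage
evaluation caps (configurable, all ≤ 5,000).

Starting values: random seeded profiles, unit mutation rates (a
Jukes–Cantor start), majority-rule optimal nucleotides (ties break to the
alphabetically first base; all-missing columns default to A), and branch
lengths from an F81 fit to the concatenated data. All randomness flows
from a single seed; identical seeds give bitwise-identical fits.

## Simulation

Ancestral states are drawn from each site's stationary distribution and
propagated down each branch by sampling rows of the exact P(t) — no
within-branch event simulation. The two benchmark scenarios are ten-taxon
rooted trees (nine ingroup taxa plus an outgroup) whose branches are
either long (0.10 expected substitutions/site) or short (0.025), with
placements differing between the scenarios; the exact placements are
documented stand-ins using the same branch-length alphabet as the original
design. Per-UCE generating profiles are drawn with centers uniform in
[0.3l, 0.7l], widths uniform in [l/10, l/4], and Nes_max log-uniform in
[4, 32]; optimal sequences are uniform random, and the generating mutation
matrix has a fixed 2:1 transition:transversion bias. The Nes_max range
makes conserved cores effectively frozen — the defining property of
ultraconserved elements — and is the regime in which the benchmark
reproduces the expected qualitative contrasts (decisive AICc preference
for the selection model and a ~2× GTR+Γ tree-length underestimate).
Emulating the full design means 22 UCEs totalling ~10,000 sites with 50
replicates; the packaged benchmark runs 22 UCEs at 2,200 total sites with
five replicates (tests) or three (acceptance script), chosen so a complete
run finishes on a single desktop core.

What the simulations do **not** emulate: indels and alignment error,
lineage-varying optima, within-locus recombination of profiles, taxon
sampling beyond ten tips, and empirical base-composition quirks. Passing
recovery tests therefore demonstrate internal consistency of estimator and
generator at desk scale, not field performance on real alignments.

## Known estimation behavior and limitations

* The per-site optimal nucleotides are incidental parameters: their ML
  re-estimation at ten taxa systematically flatters the data (a
  drift-fixed site is assigned its observed base as "optimal"), which
  biases the fitted profiles flat-and-wide — σ̂ is biased upward (median
  σ̂/σ ≈ 1.7–2.1 on the benchmark), Nes_max downward in the frozen regime
  (its likelihood is nearly flat above the freezing point), and ingroup
  tree length upward (≈ +25–65% across benchmark replicates). The bias
  reproduces from any starting point, including the generating truth, and
  is inherent to maximizing over per-site optima at small taxon counts.
* Because the model is non-reversible yet nearly rerooting-invariant in
  practice, the two branches adjacent to the root are poorly identified;
  include an outgroup and read ingroup branch lengths.
* Ne is fixed, not estimated; only composites Ne·s are identified.
* The binary mismatch distance ignores biochemical similarity between
  nucleotides; the Gaussian is the only spatial form implemented.
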
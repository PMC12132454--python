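# Methods

## Model

`optimshift` studies a quantitative trait under Gaussian stabilizing
selection in a diploid, panmictic Wright–Fisher population of constant size
N with free recombination and linkage equilibrium (infinite-sites,
bi-allelic loci).  An individual's trait value is the sum of its alleles'
effects; fitness declines with squared distance from an optimal value, with
1/VS the strength of selection.  Environmental noise is not simulated
explicitly: its only effect in this model is to widen the fitness function,
so it is absorbed into VS.

The population starts at mutation–selection–drift balance (MSDB) around the
optimum; at t = 0 the optimum jumps by Λ and stays there.  The question the
package answers is how the response decomposes between a highly polygenic
shift of many small allele frequencies and the fixation of a few
large-effect alleles, as a function of the trait's genetics (mutational
input 2NU to large-effect alleles, their effect-size distribution, the
small/intermediate-effect variance σ²) and its ecology (the shift size Λ).

### Units

Everything internal is measured in units of δ = √(VS/2N), the scale of
mean-phenotype fluctuations at MSDB.  In these units VS = 2N, δ = 1, and an
allele of effect a has population-scaled selection coefficient Se = a² at
MSDB.  Se ≈ 5 separates (nearly) neutral from strongly selected dynamics
under the under-dominant stabilizing term (the analogue of the usual
Se ≈ 1 for semi-dominant selection); "large effect" means Se ≫ 5, and the
configurable cutoff `Se_min` (default 20) bounds the support of the
large-effect mutational distribution with a safety margin.  The CLI accepts
raw trait units plus (N, VS) and converts on the way in.

### Allele dynamics

A single generation changes an allele's frequency x with moments

    E[Δx] = ( a·D/VS − (a²/VS)(½ − x) ) · x(1 − x),
    V[Δx] = x(1 − x) / 2N,

where D is the distance of the mean phenotype from the optimum.  The first
term is directional selection (semi-dominant, signed by the allele's
orientation relative to the shift), the second stabilizing selection
against the minor allele (under-dominant, orientation-free).  For a rare
allele the two terms balance at D = a/2: alleles with effects larger than
twice the current distance are opposed by selection from the start.

## Engines

Both stochastic engines realize the moments with one binomial draw per
segregating allele per generation: x' ~ Binomial(2N, clip(x + E[Δx], 0, 1))/2N.
This matches both moments to O(1/N) and is the standard per-locus forward
scheme under linkage equilibrium.  The expected frequency is clipped before
the draw because the first-moment formula is a diffusion approximation and
can leave [0, 1] for extreme a·D.

**Hybrid engine** (`dynamics.run_hybrid`): tracked large-effect alleles
evolve stochastically; the small/intermediate-effect background is an
infinitesimal ("Fisherian") component of fixed variance σ² whose mean
advances deterministically by (1 − e^{−σ²/VS})·D per generation.  This
factor — rather than (σ²/VS)·D — makes the allele-free engine reproduce the
continuous Lande solution D(t) = Λe^{−σ²t/VS} exactly at integer t, so the
discretization error of the background is zero rather than O((σ²/VS)²t).
The distance is never integrated on its own; every generation it is
recomputed from the bookkeeping identity

    D = Λ − mean_bg − Σᵢ orientationᵢ · 2aᵢ · (xᵢ − xᵢ(0⁻)),

with xᵢ(0⁻) the pre-shift frequency (x₀ for standing alleles, 0 for new
mutations), which keeps the phenotype and allele accounting exactly
consistent (asserted to 1e-9 in the tests).

New tracked mutations arrive as Poisson(2NU) per generation at frequency
1/2N with symmetric ±1 orientation — mutation is directionally unbiased
both before and after the shift; selection, not mutation, creates the
aligned excess.  By default mutation is injected only while the adaptation
window is open (t ≤ T_end, below): once the background alone has carried
the population within δ of the optimum, a new large-effect mutant is
opposed by selection from birth and cannot contribute, so later injections
only add runtime.  Recurrent mutation over the full horizon is available
via `mutation_window=math.inf`.

Runs stop early once |D| < 1e-3 δ, no tracked allele segregates, and the
mutation window has closed; `full_horizon=True` disables this, and
fixation-fraction experiments may stop as soon as all allele fates are
resolved.

**Fully polygenic engine** (`dynamics.run_polygenic`): every allele of
every effect size is tracked explicitly, with no deterministic background
and recurrent mutation throughout; the initial state is a fresh MSDB draw.
It warns when the MSDB variance is not large relative to the typical
squared effect (i.e., when the run is not actually in the highly polygenic
regime it is meant for).

## MSDB standing architecture

Before the shift D = 0, so only the stabilizing term acts.  The
sojourn-time density of a new mutant entering at 1/2N follows the standard
two-branch diffusion formula with scale density G(x) = exp(Se·x(1−x));
with input 2NU the equilibrium density of segregating alleles is 2NU·t(x).
All quadrature is done in log space (G reaches e^{Se/4}, overflowing
doubles beyond Se ≈ 2800 otherwise) on a logit-spaced grid that resolves
both boundaries below the 1/2N scale.  The segregating range is taken as
the full lattice cells of copy numbers 1..2N−1, i.e. [1/4N, 1 − 1/4N]:
because t(x) ~ 1/x at the lower boundary, the half-cell below the entry
frequency carries 20–30% of the total sojourn time for strongly selected
alleles, and integrating over full cells makes the continuum total agree
with the exact discrete-chain expected lifetime to within a few percent
(verified against the Wright–Fisher transition-matrix oracle).  `sample_standing` draws the allele count from the
Poisson mean 2NU·∫dist(Se)·T_soj(Se)dSe and each (Se, x₀) from the joint
density by inverse CDF on cached per-effect grids; `burnin_engine` produces
the same architecture by brute-force forward simulation (default 40N
generations with a drift check on the running variance) and serves as its
cross-check.  Replicates that happen to draw zero standing alleles are
retained.

Two mutational families are built in: a point mass in Se (single-effect
experiments) and an exponential density in Se truncated to
[Se_min, Se_max]; the class interface accepts any density over Se.  Signs
are always symmetric.

## Analytic layer

`lande_distance` is the exponential approach Λe^{−VA·t/VS}; the adaptation
window T_end = (VS/σ²)·ln(Λ/δ) is the time at which the background-only
distance reaches δ.  `mean_fitness_reduction` reports
1 − exp(−Λ²/(2(VS+VA))) — the mean-fitness ratio relative to a population
with the same phenotypic variance centered at the optimum, so the
variance-dependent normalization cancels; with VA = 0 a shift of 0.8·√VS
costs 1 − e^{−0.32} ≈ 27% of mean fitness.

### Establishment

A rare aligned allele of effect a has per-copy selective advantage
s(t) = (a/VS)(D_L(t) − a/2), with D_L the background-only Lande decay (its
own contribution to D is negligible while rare).  Single-copy survival is
computed by the backward recursion of the discrete-generation branching
process with Poisson(1 + s(t)) offspring,

    p(t) = 1 − exp(−(1 + s(t)) · p(t+1)),

run from the sign-reversal horizon (s = 0; a lineage still alive then has
typically grown large) down to the arrival time; with σ² = 0 this collapses
to the classic fixed point p = 1 − e^{−(1+s)p} ≈ 2s.  An allele at
frequency x₀ has 2N·x₀ copies treated as independent lineages, so
establishment is 1 − (1 − p₁)^{2Nx₀} — exact for integer copy numbers and
equal to the Poissonized 1 − e^{−2Nx₀p₁} to O(p₁²) (the distinction is a
~25% effect for single copies under strong selection; the form is also
exact for fractional copy numbers, since the engine's first binomial
update Poisson-thins the initial copies).  Against exact Wright–Fisher
transition-matrix absorption at N = 50 the recursion is accurate to well
under 5%.  The survival-to-reversal horizon keeps the conditioned
emergent-size law below consistent with the branching martingale; its
price is that establishment for arrivals close to the reversal time is
only an upper bound (the fixation integrals suppress those arrivals
through the crossing factor regardless).

### Crossing and fixation

Conditional on establishing, the allele's ascent is tracked by the
deterministic system

    dx/dt = E[Δx],    dD/dt = −(σ²/VS)·D − 2a·dx/dt,

and the decisive event is reaching frequency ½ while selection on the
allele is still positive ("crossing the Rubicon"): past ½ the stabilizing
term switches sides.  `reaches_half` exposes exactly this indicator.  The
fixation probability composes three factors:

1. **Establishment** as above.
2. **Emergence and crossing.**  A lineage that escapes the stochastic
   low-copy phase emerges at frequency Gamma(n_surv, scale 1/(2N·p₁)),
   where n_surv is the number of surviving founder lineages (Poisson with
   mean −2Nx₀·ln(1−p₁), which makes P(n_surv ≥ 1) equal the establishment
   probability exactly) — the standard limit of a supercritical branching
   process conditioned on survival: each surviving copy contributes an
   Exp(1)-distributed multiple of 1/(2N·p₁).  The allele crosses iff the
   emergent frequency exceeds the critical deterministic starting
   frequency x_crit, located by bisection of `reaches_half` in log
   frequency.  For one copy this is the closed form exp(−x_crit·2N·p₁);
   for many copies the Gamma concentrates at x₀ and the sharp indicator
   1[x₀ ≥ x_crit] is recovered.
3. **Post-crossing fixation.**  Fixation after crossing is not treated as
   certain: the factor u(½ | D_cross) is the diffusion fixation
   probability from ½ with the distance frozen at its value when the
   deterministic path crosses (scale density exp(Se·y(1−y) − 2aD·y)).  It
   is ½ at D = 0 — the unstable under-dominant equilibrium — and
   approaches 1 once the crossing margin clears the drift scale.  Because
   u transitions within a narrow band of starting frequencies just above
   x_crit, it is tabulated on a grid log-spaced in the excess x − x_crit,
   and the single-founder term integrates u over the Exp(1) emergent
   excess rather than evaluating it at the mean.

Standing-allele probabilities average over the normalized MSDB sojourn
density of x₀; new-allele probabilities average over a uniform arrival
time in [0, T_end] with the establishment curve and the reach integration
evaluated under the time-shifted distance.  All probabilities refer to an
aligned allele; with symmetric mutation only half of mutations are
aligned, and opposing alleles never fix, so expected-fixation counts carry
a factor ½.

`expected_fixations` multiplies these per-allele probabilities by the
mutational flux (2NU·T_soj standing alleles; 2NU·T_end new arrivals) and is
valid only in the non-interfering low-input regime (it warns above
2NU = 1); the high-input regime, where concurrently ascending alleles
shorten each other's directional window, is deliberately simulation-only.

`classify_regime` partitions shift sizes for a given effect into
no-establishment (Λ < a/2), establishment-without-fixation, standing-can-fix
and most-established-fix bands, with thresholds located by bisection.
Because the exact sojourn density places (astronomically small) mass
arbitrarily close to x = ½, the strict threshold for "fixation probability
positive" would degenerate to a/2; probabilities below 1e-6 — far beyond
any Monte-Carlo resolution — are therefore treated as zero when locating
thresholds.

### Known limitations of the approximation

The emergent-size law captures the variability of the stochastic
low-copy phase, but drift accumulated *after* emergence — along the climb
from tens of copies to frequency ½ — is not modeled, and neither are
drift-assisted crossings (an allele wandering across ½ against
selection).  In bin-resolved comparisons at N = 1000, establishment
matches simulation to ~0.01 across the board, while the crossing
probability for alleles starting at 2–20 copies is overestimated by up to
~0.07 absolute inside the fixation-onset transition band of shift sizes
(roughly Λ between 2.5a and 3.2a at a² = 200, σ² = 40); just below the
onset the analytic probability instead undershoots slightly because
lucky drift-assisted crossings are missing.  Outside that band —
including the entire no-establishment, establishment-only, and
most-established-fix regimes — analytic and simulation agree within
Monte-Carlo resolution (9 of 10 shift sizes on a grid spanning all four
regimes, 2000 replicates each, 3-SE check).  The discrepancy shrinks
with N as drift coarsens relative to selection.

## Experiments

`run_replicates` composes MSDB sampling and the hybrid engine over
independent replicate streams derived from one master seed with
`SeedSequence(seed, spawn_key=(replicate,))` — a counter-based, injective
scheme recorded in the run manifest, so any single replicate can be
reproduced in isolation.  The long-term contribution of large-effect
alleles is the fraction of the shift their fixations account for:
Σ orientation·2a·(1 − x_ref)/Λ over fixed alleles, with x_ref = x₀ for
standing alleles and 0 for new mutations (the mean-phenotype change a
fixation causes relative to the pre-shift state); opposing-sign fixations
(vanishingly rare, tracked separately) enter negatively.

`grid_scan` fills a two-axis grid (any two of 2NU, Λ, σ², or the pair
(VA(0), p)) with the Monte-Carlo probability that at least one tracked
allele fixes, or with the mean contribution.  The (VA(0), p) axes — total
MSDB variance and the proportion contributed by large-effect alleles — are
converted via σ² = (1−p)·VA(0) and 2NU = p·VA(0)/V₁, with V₁ the MSDB
variance per unit input from quadrature; cells with an unreachable
combination are flagged invalid.  `smooth_grid` applies a separable
Gaussian filter with reflecting boundaries, which preserves the grid's
total mass exactly; bandwidth 0 is the identity.

## Numerical choices and problem sizes

Sojourn grids use 4001 logit-spaced points (relative quadrature error
< 1e-3 against the exact N = 50 matrix aggregates); the reach ODE is
integrated with RK45 at rtol 1e-8 with event detection for the ½-crossing
and the sign reversal; threshold bisections resolve Λ to < 0.1% of the
bracket.  Test-suite simulations run at N = 250–1000 with replicate counts
(100 for contribution sweeps, 2000 per grid point for the
analytic-vs-simulation comparison) chosen so the whole suite completes on
a laptop-class single core; the same code scales to the N = 5000,
600-replicate setting through the CLI (`--full`-scale configs are ordinary
configs with larger N, generations and replicates).

## What the generator does and does not emulate

The synthetic conditions are the model's own: MSDB initial states, a
sudden permanent optimum shift, constant N, free recombination, no
dominance, no pleiotropy, no linkage, a constant background variance σ²
in the hybrid engine.  Passing tests therefore validate the internal
consistency of model, approximations and engines — not the behavior of
real traits, where background variance responds to the shift, pleiotropy
taxes large-effect alleles, and optima move gradually or repeatedly.
Within the model, the hybrid engine's constant-σ² background is itself an
approximation that the fully polygenic engine relaxes.
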
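# Methods

## The question

A lytic phage that can productively infect two host species seems to have
an unambiguous advantage over a specialist restricted to one of them.
`phagepatch` implements a family of models showing why that intuition can
fail when hosts live in dense, ephemeral aggregations: rejecting the worse
host is profitable whenever contact with it predicts that the better host
is nearby.  No genetic trade-off is assumed anywhere — generalist and
specialist are identical on the shared host A.

## Closed-form within-patch fitness (`phagepatch.analytic`)

A phage particle inside a patch exits at rate α, decays at rate λ, and
makes infectious contacts at rate θ, a fraction p of them with host A.
Infections are assumed to burst only after the aggregation has dispersed,
so an infection on host H is worth its burst size F_H, and an exit is
worth 1 (the particle survives to forage elsewhere).  Expected
reproductive success is

    W_G = (θ p F_A + θ(1−p) F_B + α) / (α + θ + λ)        (generalist)
    W_S = (θ p F_A + α) / (α + θ p + λ)                   (specialist)

Setting W_G = W_S and writing net fecundities n = F − 1 gives the
breakeven net fecundity of host B

    n_B* = (n_A θ p − λ) / (α + θ p + λ)

and the breakeven quality ratio

    R* = n_B*/n_A ≈ θ p / (α + θ p + λ),

the approximation dropping λ from the numerator (demographic equilibrium
requires n_A θ p ≫ λ).  R* is the fraction of host A's net value that
host B must offer before a generalist matches a specialist; it approaches
1 when finding host A from inside a patch is nearly certain.  Two limits
anchor the algebra: with α = 0 and n_A θ p = λ (a closed population at
demographic equilibrium) the breakeven is exactly n_B = 0, and with
α = λ = 0 it is n_B = n_A (R* = 1).  Negative breakeven values (when
n_A θ p < λ) are returned unclamped and read as "any host with positive
net value should be accepted".

## Single-patch Monte Carlo (`phagepatch.single_patch`)

Each trial draws one fate from the competing-risk distribution implied by
the rates (specialists renormalize over {exit, decay, contact-A};
contacts with B are non-events for them).  Two relaxations of the
analytic assumptions are modeled:

- **In-patch bursting (ω).**  With probability ω an infected cell bursts
  before leaving.  The infecting phage is then credited with F_H times
  the expected success of one progeny particle, in which secondary
  infections are valued at the expected burst size of the host contacted
  — one closed-form level of recursion, which keeps the trial variance
  bounded without biasing the mean.
- **Host-composition noise (n_eff).**  The realized host-A fraction for
  each block of 1,000 trials is drawn as Binomial(n_eff, p)/n_eff,
  emulating sampling variation in patches of effective size n_eff.

Because each fate distribution has at most six distinct outcome values,
trials are generated as multinomial outcome counts — an exact equivalent
of trial-by-trial simulation — and the bootstrap resamples those count
tables.  This makes 10^5-trial grids and 1,000-replicate bootstraps
essentially free.

R* is inferred exactly as one would from simulated fitness curves:
generalist mean fitness versus F_B is fitted by OLS (it is affine in F_B
at ω = 0 and close to affine otherwise), specialist fitness by its grand
mean (it does not depend on F_B), and the crossing F_B* is converted via
R* = (F_B* − 1)/(F_A − 1).  If the fitness difference never changes sign
on the grid, the grid is extended upward once before an inference-failure
error.  Bootstrap replicates resample trials within every grid point;
replicates whose fitted generalist slope is non-positive cannot produce a
crossing and, when they are ≤1% of replicates, are re-drawn (the
"swapping" pass); more frequent failures raise an error recommending
more trials.  Intervals are 2.5/97.5 percentiles.

Known behavior, reproduced by the tests: with ω up to 1 the inferred R*
stays within 0.05 of the analytic value (the burst-inside valuation
slightly lowers the crossing, and the line fit averages the mild
curvature of W_G in F_B); with n_eff = 4 the specialist's fitness is hurt
by Jensen's inequality (W_S is concave in the realized p), so R* falls
well below the fixed-composition prediction — small patches are often
effectively single-host, blunting the cost of generalism.

## Patch metapopulation (`phagepatch.metapop`, `phagepatch._kernels`)

The ecological simulation tracks many patches suspended in a well-mixed
medium.  Per patch, nine integers: two resources, uninfected hosts A and
B, free generalists and specialists, and infected classes I_GA, I_GB,
I_SA (specialists never infect B).  The medium holds planktonic hosts and
free phage; nothing infects in the medium.  Twenty-eight event channels
drive each patch (arrivals, divisions, detachments, decays, resource
decay, phage arrivals/exits/decays, three infections, and
burst/decay/detachment of the three infected classes), simulated exactly
with the Gillespie algorithm inside fixed 20-minute cycles.  Per cycle:
patches step in random order, medium classes are thinned binomially with
survival exp(−λΔt), exhausted patches (resource < 5% of endowment and ≤5
susceptible hosts) are culled with occupants spilled into the medium
(infected cells lysing on the way), and new patches are added every χ
cycles — one dual-resource patch (*together*) or one patch of each
single resource (*apart*).

Numerical/design choices worth noting:

- Host detachment rate is d·k/(k + x): maximal (d) when the relevant
  resource x is exhausted, half-maximal at x = k.  The same function, on
  the host's resource, applies to infected cells.
- Detaching or culled infected cells lyse immediately into the medium
  (their burst times far exceed patch lifetimes under the default
  β = 8.33×10⁻⁶ h⁻¹), releasing Poisson(F_H) progeny.
- The *together* endowment is Y of each resource, matching the total
  resource influx of the two single-resource patches added per period in
  *apart*.
- Division requires at least one whole resource unit and consumes it;
  per-patch ledgers make endowment = remaining + consumed + decayed an
  exact integer identity, which the tests assert.
- One seeded NumPy `Generator` drives everything in a run (patch-order
  shuffling included), so trajectories are bit-reproducible; the
  virtual-particle layer (below) has its own stream.
- Arrival rates read the medium at event time; patches are stepped
  sequentially within a cycle, which is the model's own coarse-graining
  of inter-patch coupling.
- The inner loop is compiled with numba; the dataclass API
  (`PatchState`, `event_rates`, `step_patch`, `run_cycle`) wraps the same
  kernels, so the readable surface and the fast path cannot diverge.

## Experiment pipeline (`phagepatch.pipeline`)

Candidate parameter sets draw the nine varied rates log-uniformly over
about three decades each.  A set is *suitable* when a generalist-only
ensemble (one run per random F_B in 0–25) keeps each host and the phage
above an abundance floor with means above a threshold and negligible
trend over the measurement window (criteria are plain config fields;
reference values 10,000 / 5,000 / 0.5% with 5-year burn-in and 5-year
measurement).  A patch-count bound guards against runaway accumulation of
uncolonized patches.

Competition runs start both strategies under trickle migration: after a
settling period, each cycle injects independent Poisson numbers of
generalists and of specialists, each with mean 2×10⁻⁵ times the current
total medium phage — equal means by construction, so migration is
strategy-neutral and only prevents stochastic loss.  The specialist share
of all phage, averaged over the tail window and over replicates, is the
outcome; replicates losing host B are excluded (a majority of them
excludes the parameter set).  Sweeping F_B and fitting the generalized
sigmoid y = a + f/(1 + e^{b(F_B − c)}) (several starts for c; midpoints
averaged when they agree, an error demanding more data when they do not)
gives the frequency midpoint, hence R* = (midpoint − 1)/(F_A − 1).
Parameter sets whose generalist-only infections of B run below 2% of
infections of A are excluded as uninformative (host B effectively
unavailable), and flat frequency profiles trigger one rerun at one-fifth
migration before exclusion.  Bootstrap CIs resample replicate fractions
within each F_B point and refit.

## Opportunity-cost probe (`phagepatch.probe`)

P(A|B) — the probability that a phage contacting host B would, if it
rejected that host, contact a host-A individual before decaying — is
measured with virtual tracer particles in a specialist-only system.  A
tracer is spawned at rate θ·S·B (each specialist–host-B contact), then
exits patches at α, re-enters at φ from the medium, decays at λ_p
(including the once-per-cycle medium thinning), and is absorbed as a
success on contact with a host-A individual.  Tracers never infect and
never alter real state; all tracer randomness comes from a dedicated RNG
stream, so a probe-carrying run's real trajectory is bit-identical to a
probe-free run with the same seed (asserted by test).  Spawning is
disabled during burn-in and a terminal buffer; tracers still unresolved
at the end count as failures, which the buffer keeps rare.  In a static
patch the success fraction reduces to the competing-risk closed form
θA/(θA + λ_p), which the tests verify.  Across parameter sets, ordinary
least squares of inferred R* on measured P(A|B) quantifies how well
opportunity cost predicts the advantage of specialists.

## Reduced-scale study conditions (`phagepatch.fixtures`)

The metapopulation has no single population-size dial: abundances emerge
from the rates.  The reference conditions (populations ≥10⁴, 100-year
competitions, 25+ replicates) are far beyond a laptop test suite, so the
package carries reduced-scale fixtures found by the same procedure at
smaller scale: log-uniform sampling, then a stability screen requiring
three-way coexistence, bounded patch counts and no strong drift over
years of model time, starting from 10³ of each host and the generalist.
The packaged ensemble members hold populations of order 10³ with a
handful of concurrent patches; competitions run 1.5 years with a 1-year
averaging window, three replicates per F_B point, and phage initialized
at equal strategy frequencies so the short window reflects the direction
of selection rather than the slow build-up of migrants.  The
twelve-member together-treatment ensemble was selected from the screen's
survivors to span the measured opportunity cost P(A|B) (≈0.06–0.5) —
the usual design when testing a predictor: spread the design points
along the predictor axis, then measure the response independently.  What passing at
this scale shows: the direction and ordering of effects (specialist
advantage in *together*, its absence in *apart*, the positive
R*–P(A|B) association) under demographic noise that is, if anything,
stronger than at reference scale.  What it does not show: the reference
ensemble's quantitative R* distribution or regression R², which depend on
population sizes and run lengths we deliberately scale down.

## Known limitations

- The sequential-patch approximation means patches early in a cycle see
  a medium not yet depleted by later patches; this is inherited from the
  model design and vanishes as cycles shorten.
- The single-patch sampler values one level of progeny recursion in
  closed form; for ω near 1 and very large burst sizes this understates
  the variance (not the mean) of deep within-patch epidemics.
- Host B extinction is detected at the end of a run (extinction is
  irreversible here, since hosts have no external source), so transient
  re-colonization dynamics are not distinguished.
- The apart-treatment signal is weak at reduced scale (selection
  differences per cycle are tiny near F_B = 1), so its R* carries wide
  intervals; this mirrors the reference analysis, which also found the
  apart treatment the harder inference.
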
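# Methods

## Model

The analysis treats six navigation pools as a closed system.  A tagged
fish's latent monthly state couples location with vital/technical status:
alive-operable in pool *j* (A/O-*j*), dead-operable (D/O), alive-expired
(A/E), dead-expired (D/E).  Three parameter groups drive the dynamics:

| parameter | meaning | units / support | prior |
|---|---|---|---|
| φ | monthly survival probability, constant over pools and time | [0,1] | U(0,1) |
| δ | monthly battery-retention probability | [0,1] | U(0,1) |
| ψ | pool-transition matrix, destination row × origin column, column-stochastic | 6×6 simplex columns | Dirichlet(1,…,1) per column |
| β_j | pool-level detection effect | ℝ | N(θ, σ) |
| θ | hyper-mean of the pool effects | ℝ | N(0, 1) |
| σ | hyper-SD of the pool effects | (0, 5) | U(0, 5) |

Survival is pool-invariant by design: too few fish are tagged in some
pools to identify pool-level survival, and movement is deliberately
time-invariant (no seasonal covariates).  Because the system is treated as
closed, permanent emigration past the most downstream pool is absorbed
into mortality — φ is "apparent survival" in the usual mark-recapture
sense.

Detection in pool *j*, month *t* is logistic in the effort covariate
x_{j,t} (mean receivers deployed per day, computed from deployment records
by exact day counting over half-open [deploy, retrieve) intervals):
ρ_{j,t} = logistic(−5 + β_j x_{j,t}).  The intercept is pinned at −5 so an
unmonitored pool-month has ρ = logistic(−5) ≈ 0.0067 rather than an
estimated baseline: detection without receivers is (nearly) impossible by
construction, and ρ is never hard-set to zero.  β_j < 0 is allowed by the
prior; the reporting layer flags decreasing curves rather than truncating.

The observation alphabet is {detected-in-pool-1..6, not-detected,
battery-expired}.  Dead fish with live batteries are asserted unobservable
(the preprocessing filters exist precisely to remove tags that keep
pinging from a carcass or river bottom).  From the projected
tag-expiration date onward the data assert the battery-expired symbol,
which only the expired states can emit.

## Likelihood

The latent states are marginalized with the scaled forward algorithm,
initialized at a point mass on A/O-(release pool) in the release month
(the release observation is asserted, contributing probability one; a fish
whose entire history is its release month contributes likelihood 1 and is
retained).  Observation sequences are truncated one month into the
asserted-expired block: the expired states form a closed set whose members
emit the expired symbol with probability one, so later months multiply the
likelihood by exactly one (a property the test-suite verifies).  The
recursion is vectorized across fish (all histories in a cohort share the
transition matrix and the monthly emission tables), and equals brute-force
enumeration over all latent paths to 1e-10 on short histories.

An implementation-level note on δ identifiability: because expiry is
asserted at the *projected* date, the likelihood sees each tag's
time-to-expiry as exactly its projected lifetime, and δ is informed by the
implied geometric waiting time (plus the attrition structure of
non-detection).  The synthetic generator is made distributionally coherent
with this by drawing each tag's true lifetime from the battery process —
geometric with monthly retention δ — and reporting that as the projected
expiration date, i.e. projections are treated as exact.  Fixed lifetimes
can be pinned per tagging cohort instead, but then the projected dates
carry information about δ that did not come from the battery process, and
recovery of δ is no longer meaningful.

## Sampling

All parameters are mapped to an unconstrained space (logits for φ, δ and
σ/5; additive log-ratio with the last pool as anchor for each ψ column,
whose log-Jacobian is the sum of all six log-probabilities; identity for
β, θ) and sampled with random-walk Metropolis.  Three moves are composed
per iteration, each posterior-invariant:

1. a global proposal from the Haario-adapted full covariance
   (target acceptance 23.4%);
2. one round-robin block proposal — (φ, δ), a single ψ column, or the β
   vector — with its own adapted scale (target 35%), which is what lets
   the six 5-dimensional simplex blocks mix at desk scale;
3. conditional updates of the hyperparameters: θ | β, σ is conjugate
   normal (exact Gibbs) and σ gets three Metropolis steps on its
   unconstrained scale.  Both touch only the prior, so the cached log
   posterior is corrected analytically without likelihood evaluations.

Covariances and step sizes adapt during warm-up only; retained draws come
from a fixed kernel.  Chains start from a cheap moment-style center
(add-one-smoothed observed residency transitions for ψ; β sized so ρ ≈ 0.5
at each pool's mean effort) plus N(0, 0.15²) jitter per chain.  Defaults
are 3 chains × (2,000 warm-up + 6,000 retained draws); a production preset
mirrors the heavyweight 3 × (10,000 + 100,000 thinned by 3) budget.
Convergence is monitored by the classic (non-split) Gelman–Rubin R̂ on
every scalar, with R̂ < 1.1 required of the top-level parameters
(φ, δ, θ, σ); R̂ is defined as 1.0 when total variance is zero.
Correctness of the sampler is established by a dense-grid numerical
posterior on a collapsed single-pool model (trivial ψ, fixed N(0,1) β
prior): MCMC moments match the grid within a quarter of a posterior SD.

Derived outputs: the movement matrix reports the posterior mean of the
product φ·δ·ψ_{ij} (not the product of posterior means; a config switch
selects the alternative), so columns sum to E[φδ]; detection curves report
the posterior median and central 95% interval of ρ(x) on a grid from 0 to
each pool's maximum observed effort.

## Preprocessing rules

* **Effort**: per pool-month, total receiver-days divided by days in the
  month; exact day arithmetic; intervals clipped to the study calendar
  with a warning; splitting a deployment interval never changes the total.
* **Suspect tags**: a fish is removed if its only detections fall within
  30 days of release ("first30"), or if at least two of three stationary
  conditions hold: (1) the totality of its detections is one continuous
  event (inter-detection gaps ≤ 7 days) on a single receiver or on
  receivers within 1,000 m of each other; (2) the maximum river distance
  among its detecting receivers (at least two distinct receivers) is under
  1,000 m; (3) its only pool of detection is its release pool.  Two
  definitional choices where the rule set is otherwise underdetermined:
  "continuously detected" requires at least two detections (one lone ping
  is not a detection *event*), and the distance condition is defined over
  receiver pairs — if a single receiver satisfied it vacuously, every
  single-receiver event would automatically meet two conditions and the
  two-of-three logic would collapse.  Evaluation order is fixed
  (single-event, distance, pool).  Fish with zero detections are retained.
* **Monthly residency**: the pool with the most distinct detection-days in
  the month; ties broken by detection count; double ties by the previous
  month's pool, else the lowest pool index (logged).  Receivers flagged
  as lock-mounted are excluded everywhere — from residency, from the
  filter rules, and from movement classification — because a signal at a
  lock cannot be attributed to one side of the dam.
* **Histories**: one symbol per month from release (asserted at the
  release pool, including for mid-month releases) to the calendar end;
  detections after the projected expiration date are dropped and the
  expired symbol is asserted from the calendar month containing that date.

## Synthetic generator

The generator emulates the study conditions the model assumes: Markovian
monthly pool transitions, constant monthly survival and battery retention,
per-pool logistic detection in effort, known projected expiration dates.
The default scenario is 6 pools (lengths 130/125/120/30/40/25 km), 36
months, 200 fish released across all pools in months 1–3, φ = 0.96,
δ = 0.97, a diagonally dominant ψ (stay ≈ 0.80–0.82, downstream favored
over upstream), and β on an even grid from 0.3 to 3 (θ = 1.65, σ = 1).
The receiver plan (20/7/4/3/3/2 stations, within the realistic 0–21 per
pool) is paired against the β grid so every pool's monthly detection
probability sits near 0.6–0.9: a recovery study is only a test of the
estimator if the design is informative about every ψ column, and weakly
monitored pools would instead measure Dirichlet-prior shrinkage.  Two
stations have partial deployments so effort varies in time.

Months are 30-day blocks for raw-event generation (the monthly model is
indifferent to day counts; calendar-month arithmetic is exercised in the
preprocessing tests with real-date fixtures).  A detected fish-month emits
a shifted-geometric number of detections (mean = daily rate × 30, default
30) at uniform timestamps; multi-detection months are scattered across at
least two stations, reflecting a live fish roaming a multi-kilometre pool
past stations ~2 km apart — genuinely stationary signatures are created
only by the artifact injector.  Planted artifacts: fish detected only in
their first ~25 days ("first30"), dropped tags pinging one station every
0.5–3 days for months ("stationary"), and mobile two-pool control fish
that every filter must keep.  Labels live in a side truth table only.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: receiver range variation and environmental noise
in detection efficiency, within-month movement (excursions that the
monthly reduction would collapse exist in real data but are not
generated), seasonally varying movement, harvest, tag failure before the
projected date, emigration from the six-pool system, and
detection-probability differences between species.

## Test and acceptance problem sizes

The replicated recovery study uses 20 replicates of the default scenario
at a reduced sampler budget (3 × (1,500 + 2,000)); the acceptance script
runs 12 replicates.  These sizes give stable pooled coverage estimates
(180 coverage events across φ, δ, θ and the six ψ diagonals) while keeping
a full run on one core in the minutes range.  Coverage is assessed pooled
across the nine monitored quantities: with twenty 95% intervals per
parameter, per-parameter thresholds would be dominated by binomial noise.
The dense-grid cross-check uses a 40³ grid over (φ, δ, β) on a 30-fish,
24-month single-pool cohort; grid discretization error there is an order
of magnitude below the posterior SDs.

## Known limitations

* Marginalizing the latent states gives the exact posterior of the printed
  model but no per-fish state reconstructions; a forward-filtering
  backward-sampling pass would be the natural extension.
* δ's identification leans on the asserted projected expiration dates (see
  above); if real projections are biased, δ absorbs that bias.
* φ conflates mortality with permanent emigration downstream, and the
  suspect-tag filter removes genuine immediate post-tagging deaths, so φ
  is conditioned on surviving the tagging process.
* The adaptive sampler is tuned for this model family's scale (~40
  parameters, a few hundred histories); much larger state spaces would
  need gradient-based sampling.
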
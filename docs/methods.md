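# Methods

## Model

`uvpol` simulates RNA polymerase II (RNAPII) transcription on a small
ensemble of representative genes sharing one finite pool of polymerases,
before and after the introduction of transcription-blocking DNA damage
(UV-type lesions).  The simulator is continuous in time and in position
along the gene, and discrete in events (a process-oriented, event-driven
kernel rather than a fixed-step integrator).

State and dynamics:

* **Initiation.**  Initiation events form a Poisson process with
  mass-action rate `initiation_rate_per_free_pol x free_pool`.  Each event
  is assigned to a gene by a multinomial draw over the gene
  `initiation_weight`s; the polymerase is placed at the TSS unless the
  TSS-proximal footprint is occupied, in which case the attempt is dropped
  (not queued).  The mass-action form makes initiation decline smoothly as
  the pool is depleted, which is the mechanism of interest: a
  pool-independent rate would produce an implausible all-or-nothing
  shutdown.
* **Elongation.**  Engaged polymerases translocate at a common constant
  speed.  Head-to-tail exclusion is enforced with a fixed `footprint`
  (minimum spacing).  Because all movers share one speed, a moving
  polymerase can only be caught by a *stationary* obstacle: a lesion, a
  stalled neighbour's footprint boundary, the optional pause site, or the
  gene end.
* **Damage.**  At damage onset (relative time 0, after burn-in) each gene
  receives `Poisson(length x lesion_density)` lesions at uniform positions
  on the template strand; each lesion's lifetime is exponential with mean
  `lesion_halflife / ln 2` (so the half-life parameter is literally the
  time at which half the lesions have been repaired by TC-NER, which is
  modelled as nothing more than this removal clock).  A polymerase
  reaching a lesion stalls; followers queue head-to-tail behind it.
* **Removal and fates.**  Engaged polymerases carry exponential removal
  clocks with status-dependent hazards: `moving_removal_hazard` while
  translocating, `stalled_removal_hazard` while halted - at a lesion *or
  queued behind one*; we read the elevated "halted" risk as applying to the
  whole queue, since a queued polymerase is biochemically
  indistinguishable from the lesion-proximal one in this model.  Clocks
  are redrawn at every status change (the memoryless reading of a
  "probability of removal at any moment").  A removed polymerase recycles
  to the free pool with probability `removal_recycle_prob`, otherwise it
  is degraded and permanently lost.  Completion at the gene end has its
  own `completion_recycle_prob` (default 1).
* **Toggles.**  `degradation_enabled=False` (the K1268R regime, a
  non-degradable polymerase) is implemented as recycle probability 1;
  `dissociation_enabled=False` (the pile-up thought experiment) as stalled
  hazard 0.  These are the only fields a regime changes.

Event handling uses a binary heap with deterministic tie-breaking
(repair < pause-end < completion < stall < removal < initiation <
snapshot, then insertion order) and versioned invalidation: every
polymerase carries a revision counter, bumped whenever its motion or
hazard context changes; stale heap entries are discarded on pop.  Queued
polymerases resume through an explicit wake cascade when their blocker
resumes or disappears, then immediately re-stall against whatever obstacle
remains; this reproduces the piecewise-linear trajectories of the
recompute-the-collision-time formulation exactly, and the kernel is
checked in distribution against an independent fixed-step (dt = 0.01 s)
brute-force simulator in the test suite.

**Burn-in.**  Runs start with every polymerase free and advance without
damage for `burn_in_time` (default 5 longest-gene transit times), then in
windows of one transit time until initiation and completion counts per
window agree within 5%.  Failure to converge within 20 transit times is an
error, not a warning - it means the configuration has no pre-damage steady
state.

**Replicates and summaries.**  Because lesion placement is stochastic, a
scenario is run `n_replicates = 100` independent times (seeds
`seed + i`); binned occupancy is averaged across replicates into a density
map standing in for the polymerase density of a pool of cells.  Summary
operations: length-stratified metagene profiles on a relative TSS->TTS
axis (100 points; classes short < 30 kb, medium 30-100 kb, long >= 100 kb,
lower-inclusive); log-linear exponential fits of the surviving pool
(`pool_size - degraded`, i.e. free + engaged - the whole-extract
western-blot readout, not chromatin-only); late/early shutdown ratios;
per-lesion queue lengths; and a normalized L1 profile distance with a
replicate-bootstrap null band (n_boot = 1000, percentile interval) as the
package's operationalization of "the profile did not change" - the
original observation was visual, so some such statistic had to be chosen.

## Parameters

Positions are nucleotides, times seconds; config files accept unit
suffixes ("100kb", "45min", "1.5h").  Defaults describe a 20 J/m2-
equivalent exposure on a scaled-down pool and are all config-overridable.
Values marked (*) are package defaults chosen from the literature or by
calibration, not quantities printed in any source data.

| parameter | default | rationale |
|---|---|---|
| `pool_size` | 500 (*) | scaled-down pool; large enough for smooth density maps, small enough for fast replicates |
| `initiation_rate_per_free_pol` | 5e-4 /s (*) | puts ~60% of the pool on a 100-kb gene at steady state (engaged:free ~ 3:2), a plausible busy-gene occupancy |
| `elongation_speed` | 33.3 nt/s | ~2 kb/min, the canonical RNAPII elongation rate |
| `footprint` | 40 nt (*) | structural footprint of RNAPII on DNA |
| `lesion_density` | 1/25,000 nt (*) | mean spacing 25 kb at 20 J/m2-equivalent, consistent with elongation being restricted to the promoter-proximal 20-30 kb |
| `lesion_halflife` | 12 h (*) | effective TC-NER clearance of CPDs, the dominant UV photoproduct: bulk CPD repair half-times in human cells are of order 12-24 h, with repair substantially (but not fully) complete by 24 h; slow repair is also what keeps the K1268R activity profile stationary between 45 min and 3 h |
| `moving_removal_hazard` | 0 (*) | premature termination of *moving* polymerases is off by default: with a single recycle/degrade fate probability, any nonzero value plus degradation would erode the pool even without damage, contradicting both the pre-damage steady state and the stability of RNAPII in untreated cells; override it to study premature termination |
| `stalled_removal_hazard` | 1/1800 /s (*) | ~30 min mean residence of a halted polymerase; the WT value is re-derived by `calibrate_degradation` against the ~1.5 h pool half-life, so the default only matters as a starting point |
| `removal_recycle_prob` | 0.5 (*) | an agnostic split between dissociation-and-recycling and degradation in WT; the calibration of the stalled hazard absorbs this choice (only the product hazard x (1 - recycle) drives pool decay) |
| `completion_recycle_prob` | 1.0 | terminated polymerases return to the pool; nothing suggests completion destroys polymerase |
| `burn_in_time` | 5 transit times | comfortably beyond the ~1 transit needed to fill a gene |
| `snapshot_times` | 45 min, 3 h, 4 h | the standard observation points: elongation shutdown, initiation shutdown, mRNA horizon |
| `bin_size` | 1 kb | resolves a 100-kb gene into 100 bins |
| pausing | disabled | promoter-proximal pausing had little effect on profile shape; when enabled, a paused polymerase keeps the *moving* removal hazard, since pausing is normal transcription rather than damage-stalling |

Calibration (`calibrate_degradation`) bisects the stalled-removal hazard
in log space (bracket 1e-5 to 1e-2 /s) against the half-life fitted to the
mean surviving-pool curve sampled every 15 min over 0-4 h.  The fitted
half-life is monotone decreasing in the hazard (bisection's requirement,
checked in the tests) but each evaluation is Monte-Carlo, and at 20
replicates the estimate is heavy-tailed: a couple of sparsely-lesioned
replicates can flatten the late part of the mean curve and stretch the
fitted half-life by tens of percent.  The routine therefore uses 20
replicates per iterate only while the bracket is wide and switches to 60
once it has narrowed below a factor of 4; a weighted log-log regression
over the iterates near the target then proposes the hazard, and a final
secant polish at full replication (up to five 100-replicate evaluations,
local slope re-estimated from successive measurements and clamped to
[-0.8, -0.15] in log-log coordinates) centres the achieved half-life to
within half the requested tolerance.  The reported half-life is always
the last full-replication measurement, with fresh seeds at every stage.

## Synthetic coverage data

`simulate_coverage` emulates TT-seq-like sequencing of the simulated
density: per-bin counts are Poisson with mean
`depth x density x spike_scale`, where `spike_scale` is a per-sample
library-size factor carried as known truth (mirroring yeast spike-in
normalization at toy scale; a ratio-of-totals estimator is provided for
the case where the factor must be recovered from a spike-in track).  The
noise model is deliberately Poisson-only: the generator exists to test the
summarization math (binning, normalization, stratified metagenes), not to
model sequencing counts.  It does not emulate overdispersion, mappability,
fragment-length effects, 4SU labelling efficiency, or strand errors -
passing tests therefore say nothing about those features of real data, and
conclusions about real libraries need real libraries.

## Numerical choices

* Position comparisons use a 1e-6 nt tolerance; a polymerase arriving at
  its target is snapped to it exactly, so no drift accumulates.
* Bins are half-open `[k*bin, (k+1)*bin)`; positions are 0-based
  continuous offsets from the TSS (bedGraph convention).
* Lesion positions are strictly > 0: the TSS itself is never lesioned, so
  initiation is never directly blocked by damage (only by occupancy).
* Equal event times are resolved by the fixed priority order above;
  repairs first, so downstream reschedules see the repaired state.
* All randomness in a run flows from one `numpy` Generator seeded by the
  run seed; replicate i of an ensemble uses `seed + i`.  TSV/bedGraph
  output uses 6-significant-digit formatting so identical (config, seed)
  reruns are byte-identical.
* `fit_half_life` reports +inf when the slope is non-negative within one
  standard error: "no resolvable decay" is an answer, not an error.
* Degenerate inputs: zero lesion density, zero pool, zero initiation rate
  and empty snapshots are all valid and tested; a zero early-signal
  shutdown ratio is reported as missing (NaN) rather than inf.

## Test-suite problem sizes

The acceptance-level checks run the presets at their defaults (pool 500,
100 replicates, 100-kb gene).  The kernel-vs-brute-force equivalence uses
a deliberately tiny instance (2-kb gene, pool of 5, one lesion, 120 s
horizon, 500 runs per simulator) because a dt = 0.01 s fixed-step oracle
is O(horizon/dt) per run; the instance still exercises initiation gating,
stalling, queueing, repair resumption, both hazards and both fates.

## Known limitations

* One transcribed strand per gene; lesions only on the template strand;
  no sequence, chromatin, nucleosomes, backtracking, or CSB recruitment
  kinetics - repair is a single exponential clock.
* A single recycle probability governs all removals regardless of where
  they happen; regimes that need status-specific fates must emulate them
  with the toggles.
* All polymerases share one elongation speed; there is no speed
  heterogeneity along genes, so collision dynamics between movers never
  occur by construction.
* The queued-polymerase hazard equals the lesion-proximal hazard; if the
  elevated risk in reality applies only to the damage-adjacent complex,
  queue attrition is overestimated (flagged as an open modelling choice).
* mRNA counts are completed-transcript tallies; no degradation of the
  mRNA itself within the simulated horizon.
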
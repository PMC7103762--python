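# uvpol

Event-driven stochastic simulation of RNA polymerase II (RNAPII)
transcription under UV-type DNA damage.

## The problem

UV irradiation triggers a two-stage, genome-wide transcription shutdown:
within the first hour nascent transcription is restricted to the
promoter-proximal 20-30 kb of genes (lesions physically block elongation),
and over the following hours initiation itself ceases.  The second stage
is driven by regulation of the RNAPII *pool*: lesion-stalled polymerases
are ubiquitylated and degraded, and once the pool is sufficiently
depleted, initiation - which draws on free polymerase - collapses on
damaged and undamaged genes alike.  Cells carrying the RPB1 K1268R
substitution cannot degrade RNAPII: they keep initiating after UV, their
activity profiles freeze in the 45-min "elongation shutdown" shape, and
short genes (which usually carry no lesion) escape the shutdown entirely.

`uvpol` is a compact, fully tested simulator of this mechanism for people
who want to reason quantitatively about it: a finite pool of polymerases,
a few representative genes, lesion stalling and queueing, stochastic
repair, and removal with degrade-vs-recycle fates, plus the summary
computations used to interrogate such simulations (replicate-averaged
density maps, length-stratified metagenes, pool half-life fits, predicted
mRNA counts, synthetic spike-in-normalized coverage).

## The model

State: genes `g` with lengths `L_g` and initiation weights `w_g` (summing
to 1), a free pool `F`, and engaged polymerases at continuous positions.

* Initiation: Poisson process with rate `k_init * F`; each event picks a
  gene multinomially by `w_g` and places a polymerase at the TSS if the
  first `footprint` nucleotides are clear (otherwise the attempt is lost).
* Elongation: constant speed `v` with head-to-tail exclusion (spacing >=
  `footprint`).
* Damage at t = 0: each gene draws `Poisson(L_g * rho)` lesions, uniform
  positions; lesion lifetimes are exponential with half-life `T_rep`
  (TC-NER).  Polymerases stall at lesions; followers queue.
* Removal: exponential hazards `lambda_move` (translocating) and
  `lambda_stall` (halted at a lesion or in a queue), redrawn on status
  change; a removed polymerase recycles with probability `p_rec`, else it
  is degraded (`F + engaged + degraded = pool_size` always).
* Regimes: WT (degradation on), K1268R (`p_rec = 1`), no-dissociation
  (`lambda_stall = 0`, the pile-up scenario), undamaged (`rho = 0`).

Everything is reproducible from (config, seed); 100-replicate ensembles
average the binned occupancy into density maps.  See `docs/methods.md`
for parameter defaults, units and rationale.

## Worked example

```bash
python examples/three_gene_competition.py
```

prints (seed 7, 20 replicates):

```
mean transcripts completed within 4 h of damage (20 replicates):
        gene  untreated       WT   K1268R  WT ratio  K1268R ratio
  long_100kb      259.5     12.5     12.3      0.05          0.05
 medium_63kb      504.0     93.1    109.0      0.18          0.22
   short_5kb     1579.0   1116.8   1501.5      0.71          0.95
```

Three genes (100/63/5 kb, initiation weighted 0.1:0.2:0.7) compete for
one pool of 500 polymerases.  Four hours after damage, long and medium
genes are crushed in both regimes - they almost always carry a lesion.
The short gene is the discriminating readout: with degradation (WT) its
output falls to ~0.7 of untreated because the pool itself decays, while
with a non-degradable polymerase (K1268R) recycling keeps the free pool
intact and the short gene retains ~0.95 of its untreated output - the
escape of short genes from the shutdown.

Other example scripts: `single_gene_shutdown.py` (two-stage shutdown on a
100-kb gene), `calibrate_halflife.py` (fitting the degradation hazard to a
1.5 h pool half-life), `synthetic_coverage.py` (TT-seq-like tracks,
bedGraph round-trip, spike-in normalization, metagenes).

A thin CLI wraps the same library:

```bash
uvpol run --preset single-gene-wt --seed 1 -o out/
uvpol calibrate --preset single-gene-wt --target 1.5h --tol 0.1 --seed 1
uvpol mrna --preset three-gene-k1268r --horizon 4h --seed 1
```

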
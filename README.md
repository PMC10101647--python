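# arbordyn

Branch dynamics, spatial clustering statistics and morphometrics for
time-lapse reconstructions of neuronal arbors.

## What it is for

During activity-dependent refinement of topographic maps, developing axonal
arbors remodel on a timescale of minutes: new branches appear, explore and
are retracted, and the balance of addition and elimination depends on
whether the axon's firing is correlated with its neighbours (Hebbian
stabilization) or not (Stentian exploration). Experiments probing this use
time-lapse two-photon imaging of single axons — e.g. retinal ganglion cell
axons in the *Xenopus* tectum — reconstructed every 10 minutes across a
Darkness → Asynchronous → Synchronous (DAS) visual-stimulation protocol,
with each time point exported as an SWC file.

`arbordyn` is the analysis layer for such experiments. Given a series of
SWC reconstructions (coordinates in μm), per-axon acquisition metadata and
a branch-correspondence table, it computes:

- **Branch remodeling events.** A branch enters analysis only if it ever
  reaches 1.5 μm. An *addition* is the branch point of a branch newly
  present between *t−10 min* and *t*; an *elimination* is the terminal
  point of a branch lost between *t* and *t+10 min*. Per-interval rates
  are normalized to each axon's darkness mean, summarized in 20-min bins
  and per-epoch windows (additions: first hour of each stimulation epoch;
  losses: last hour, or last 40 min for 1.5 h epochs).
- **Spatial clustering of events.** For each epoch and event kind, the
  mean of all pairwise 3D distances between events is compared with a
  Monte-Carlo null that redistributes the observed per-interval counts on
  the arbor present at that time (additions anywhere on the 0.15 μm-resampled
  cable, eliminations on terminal points; 100 replicates). The statistic

      normalized ratio = (observed / randomized) epoch ÷ (observed / randomized) darkness

  is 1 under geometry-explained placement and falls below 1 when events
  cluster locally.
- **Morphometrics.** Strahler ordering of segments (a segment is bordered
  by two branch points or a branch and a terminal point), terminal-segment
  length distributions, skeleton length (orders > 1), terminal-point
  counts, and an arbor *span volume*: an enclosing boundary between a
  tight alpha-complex fit and the convex hull, selected by the arbor's
  convexity, with the bounded expansion index
  (V_last − V_first)/(V_first + V_last).
- **FDR correction.** The two-stage linear step-up procedure for post-hoc
  p-value families produced by downstream group statistics.

Because reviewable imaging data is scarce, the package ships a synthetic
arbor-growth generator (`arbordyn.simulate`) that emulates the whole study
design — epoch-dependent Poisson branch turnover, sub-1.5 μm transients,
optional subtree-confined elimination, rigid per-frame motion with noisy
landmarks, missing acquisitions — together with ground-truth logs, so
every stage of the analysis is testable end to end.

## Worked example

```python
import arbordyn as ad
from arbordyn.simulate import GrowthSimConfig, simulate_series

series, truth = simulate_series(GrowthSimConfig(seed=42), axon_id="demo")
aligned = series.align_to_first()                 # chain landmark fits to t0
tracks  = ad.track_branches(aligned)              # applies the 1.5 μm rule
events  = ad.detect_events(tracks, aligned.schedule, aligned.times_min)
rates   = ad.rate_series(events, aligned.schedule, aligned.times_min)
print(ad.window_means(rates, aligned.schedule).to_string(index=False))
```

prints (see `examples/01_branch_dynamics.py`):

```
     epoch        kind  window_start_min  window_end_min  mean_normalized_rate
     async    addition              60.0           120.0              1.636364
      sync    addition             180.0           240.0              0.363636
async/sync    addition               NaN             NaN              4.500000
     async elimination             120.0           180.0              1.250000
      sync elimination             240.0           300.0              0.750000
async/sync elimination               NaN             NaN              1.666667
```

A normalized rate of 1.0 is the darkness baseline: this axon adds branches
~1.6× faster than baseline during asynchronous stimulation and ~0.4× during
synchronous stimulation — the Stentian/Hebbian pattern the default
generator preset emulates. `examples/02_spatial_clustering.py` shows the
spatial statistic: an axon whose synchronous-epoch eliminations are
confined to a subtree holding ~25% of terminals yields a sync normalized
ratio of 0.67 against 1.00 in darkness, while a uniform axon stays near 1.

The same analyses run from the shell over a YAML config:

```bash
arbordyn report --seed 1 --out results_dir       # all CSV tables + manifest
arbordyn simulate --seed 1 --n-axons 5 --out sims
arbordyn spatial --config run.yaml
```

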
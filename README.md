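# miniens

Analysis toolkit for one-photon miniscope calcium imaging and associated
histology, aimed at questions about **memory allocation and ensemble
reactivation**: which neurons are recruited when two experiences are encoded,
how much two sessions' active ensembles overlap, and whether that overlap
exceeds chance. The package covers the statistics downstream of source
extraction — it consumes per-neuron fluorescence traces (e.g. a CNMF-E
`C_raw` matrix) and spatial footprints, not raw video — and ships a
synthetic-data generator with full ground truth so every stage can be
validated end to end.

## What it computes

**Calcium-event detection.** True transients show a steep rise followed by a
slow exponential decay. Each trace is convolved with Gaussian kernels of SD
50 and 100 ms, decimated 3× (one point ≈ 100 ms at 30 fps), and
first-differenced. Per neuron and per kernel, a steepness threshold is set
nonparametrically at

  T = Q3 + 1.5 · IQR   (≈ 2.698 σ above the mean for normal noise),

and a decimated point is an event (1) only if its rise exceeds the threshold
in *every* kernel pipeline; all other points are 0. The event rate is the
number of 1s per point (and per second). Quality control drops neurons with
peak-to-noise ratio < 20 or a strongly asymmetric noise distribution.

**Cross-session cell matching.** Sessions are registered by a rigid
translation estimated from the cross-correlation of summed footprint images;
cells match when their footprints' spatial correlation is ≥ 0.8 and centroid
distance ≤ 5 px, resolved one-to-one greedily by descending correlation. The
ensemble overlap index of two sessions is

  overlap index = n_matched / ((n₁ + n₂) / 2).

**Allocation statistics.** Over a shared universe of U cells, the top
fraction q of active cells per session (default q = 0.10) defines that
session's high-activity ensemble. The joint-percentile probability
P_{Aq,Bq′} = N_{Aq,Bq′}/U is normalized by its chance level q·q′
(e.g. 0.1 × 0.2 = 0.02); 1 means independence. A target session's top set is
also partitioned into prior-context-only / home-cage-only / both / unique
fractions, and the balance ratio (Top_A − Top_HC)/(Top_A + Top_HC) summarizes
which earlier ensemble dominates.

**Permutation test.** A one-sided test for above-chance overlap of top-10%
cells: identities in the target session are permuted (default 1,000
shuffles), the overlap proportion recomputed each time (cells topping all
three sessions excluded), and p = #{null ≥ real}/n_shuffles; group-level p
compares the across-subject mean with the paired shuffle means.

**Histology.** For DAPI / c-Fos / marker count tables, the chance
colocalization level is (c-Fos/DAPI) × (marker/DAPI) and enrichment is the
observed double-positive fraction over chance. Subject × region c-Fos
density tables yield pairwise Pearson correlations per group and a
gained/lost classification of significant region-pair correlations between
groups.

## Worked example

```python
import numpy as np
from miniens import (SimConfig, generate_session_pair, detect_events, event_rate,
                     FootprintMatcher, PermutationParams, permutation_test)

cfg = SimConfig(n_neurons=120, duration_s=300, firing_rate_hz=(0.05, 0.3),
                shared_fraction=0.4, shift_px=(3, -2), jitter_px=1.0, seed=7)
s1, s2, truth = generate_session_pair(cfg)

raster1 = detect_events(s1.traces)
rates1 = event_rate(raster1, "session1")
rates2 = event_rate(detect_events(s2.traces), "session2")

matcher = FootprintMatcher().fit(s1.footprints, s2.footprints)
ov = matcher.overlap_

ra = np.array([rates1.loc[i, "rate_events_per_s"] for i, _ in matcher.result_.identity_pairs()])
rb = np.array([rates2.loc[j, "rate_events_per_s"] for _, j in matcher.result_.identity_pairs()])
res = permutation_test(ra, rb, params=PermutationParams(n_shuffles=1000, q=0.10, seed=7))["A-B"]
```

prints (via the obvious `print` statements):

```
session 1: 120 cells, mean rate 0.410 events/s
estimated shift (dx, dy) = (2.90, -2.05)
matched 48 of (120, 120) cells -> overlap index 0.400
48/48 ground-truth pairs recovered
top-10% overlap: real 0.40, null mean 0.105, p = 0.082
```

The designed 40% shared pool is recovered exactly (overlap index 0.400, all
48 true pairs, no false matches) and the estimated rigid shift matches the
simulated (3, −2) px displacement. Shared cells keep their base firing rate
across sessions, so the observed top-10% overlap (0.40) sits well above the
permutation null (~0.10, the chance level for top-10% sets); with only 48
matched cells the discrete null still leaves p ≈ 0.08.

The same stages are available from the shell:

```bash
miniens simulate --n-neurons 120 --duration 300 --seed 7 --out pair/
miniens detect --session pair/session1 --out det/
miniens match pair/session1 pair/session2 --corr-min 0.8 --dist-max 5 --out m/
miniens run --config pipeline.yaml        # simulate -> detect -> match -> allocate -> permtest
```

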
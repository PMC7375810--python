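# dynamotype

Bifurcation-based simulation and classification of seizure dynamics.

A seizure's **dynamotype** is the pair of bifurcations through which the
brain enters and leaves the ictal state, read off the electrographic
recording: how the oscillation starts (saddle-node SN, saddle-node on
invariant circle SNIC, supercritical Hopf SupH, subcritical Hopf SubH), and
how it stops (saddle-homoclinic SH, SNIC, SupH, fold of limit cycles FLC).
Four admissible onsets times four admissible offsets give a taxonomy of 16
types, drawn from six bifurcations. Each bifurcation leaves an invariant
fingerprint in the trace: square-root growth of the oscillation amplitude
with the distance to the bifurcation (SupH), square-root scaling of the
frequency (SNIC), logarithmic divergence of the inter-spike interval — the
familiar terminal "slowing down" (SH), abrupt starts or stops with no
scaling law (SN, SubH, FLC), and, for SN onsets and SH offsets only, a
baseline (DC) shift.

The package has two halves that validate each other:

* **The model.** A planar fast subsystem — the unfolding of the degenerate
  Takens–Bogdanov singularity,
  `x' = -y`, `y' = x^3 - mu2*x - mu1 - y*(nu + x + x^2)` —
  whose three parameters live on a sphere of radius R = 0.4 in
  `(mu2, -mu1, nu)` space. The spherical surface is the **seizure map**:
  saddle-node and Hopf curves (closed forms) and numerically traced
  SH/SNIC/FLC curves divide it into resting, ictal, and bistable regions. A
  slow variable moves the brain's state back and forth along a great-circle
  path (seizures are hysteresis loops or slow-wave oscillations across the
  curves), an ultraslow drift migrates the path itself, and noise perturbs
  every variable.
* **The classifier.** From a marked seizure segment it measures spikes
  (fast transients < 200 ms distinguishable from background), per-spike
  peak-to-peak amplitudes, the ISI series, and DC shifts (sharp < 0.5 s
  deflections > 5x the background spread persisting >= 1 s); fits the
  candidate scaling laws to the first and last spikes with a small-sample
  information criterion; and applies the taxonomy's decision rules. Without
  a DC-coupled channel some classes are indistinguishable in principle, so
  grouped labels are emitted: SN(-DC)/SubH at onset, SH(-DC)/SNIC at offset.

## Worked example

Simulate the classic square-wave burster (SN onset, SH offset), cut the
second seizure out of the trace, and classify it:

```python
import numpy as np
from dynamotype import NoiseSpec, Recording, SlowSpec, classify_seizure, simulate
from dynamotype.experiments import default_path, extract_seizure_recordings
from dynamotype.canonical_model import simulate_ensemble

ens = simulate_ensemble(
    default_path("SN/SH"), SlowSpec(epsilon=1e-4), NoiseSpec(0.001, 0, seed=3),
    duration=20000, dt=0.02, n_sims=1, z0=0.3,
)
items = extract_seizure_recordings(ens, dt=0.02, merge_gap=150.0)
label = classify_seizure(items[1]["recs"], n_spikes=30)
print(label, "| slowing:", label.slowing,
      "| duration: %.1f s" % items[1]["duration"])
```

```
SN(+DC) / SH(+DC) | slowing: slowing | duration: 21.3 s
```

The onset is an abrupt, full-amplitude jump with a baseline shift — the
saddle-node fingerprint — and the terminal inter-spike intervals stretch
along `-ln(t_off - t)` with a shift back at offset: the saddle-homoclinic
family, split to SH(+DC) because a DC-coupled channel was available.

The same pipeline runs from the shell:

```
dynamotype map --resolution 181x361 --out run_map
dynamotype validate --n 60 --seed 1
dynamotype switch-experiment --n-sims 100 --seed 1
dynamotype sweep-noise --n-per-level 100 --seed 1
dynamotype classify my_seizure.csv --marks my_seizure.marks.json
```

`dynamotype map` writes the region grid, the bifurcation curves, a map
image, and the derived list of planar dynamotypes; `validate` prints the
confusion matrices of the gold-standard classification test; the last two
commands reproduce the ultraslow offset-switch experiment and the
status-epilepticus noise sweep.

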
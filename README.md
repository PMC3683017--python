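# visnet-hand

Simulation of how *hand-centred* visual receptive fields — neurons that
encode where a target object is **relative to the hand**, regardless of
where the hand-object pair falls on the retina — can develop by
unsupervised learning in a hierarchical competitive network, as reported
for neurons in primate posterior parietal and premotor cortex.

The package is for computational neuroscientists studying invariant
representation learning: it provides the stimulus generator, the V1-like
Gabor front end, the four-layer competitive hierarchy with trace-rule
plasticity, the information-theoretic analyses, and the end-to-end
experiment protocols.

## The model in brief

Scenes containing a fixed hand-object configuration are swept across the
retina in 5-pixel steps, emulating fixational eye movements.  Four
competitive layers (32x32 neurons each) sit on a 128x128x32 retina of
rectified Gabor-filter hypercolumns.  Per presentation each layer computes
a linear activation h_i = Σ_j w_ij x_j, soft lateral inhibition
(centre-minus-Gaussian-surround convolution), and a sigmoid
y = 1/(1 + e^{-2β(h-α)}) whose threshold α is the 95th percentile of the
layer's activations, fixing firing sparseness at ~5%.  During training the
feed-forward weights follow the **trace rule**

    ȳ(t) = (1-η) y(t) + η ȳ(t-1),      Δw_j = α_lr · ȳ(t-1) · x_j(t),

with η = 0.8 and unit-norm weight renormalization after every update.
Because frames of one sequence share the same hand-relative geometry,
cells are driven to respond to *configurations* across retinal positions.
Performance is read out with the stimulus-specific information
I(s,R) = Σ_r P(r|s) log₂(P(r|s)/P(r)) per output cell (maximum log₂ 3 ≈
1.58 bits for three configurations) and with decoding-based multiple-cell
information over the best five cells per stimulus.

## Worked example

```python
import numpy as np
from visnet_hand.experiments import (ExperimentConfig, filtered_training_set,
                                     run_replicate, count_selective_cells)
from visnet_hand.info_metrics import select_ensemble, multiple_cell_information

cfg = ExperimentConfig.baseline(seed=1)
filtered, labels = filtered_training_set(cfg)     # 3 sequences x 5 frames
rep = run_replicate(cfg, 0, filtered, labels)     # build, train 4x50 epochs

print(labels)                                     # ['Up', 'Left', 'Right']
print(rep.untrained.n_cells_at_max)               # 0
print(rep.trained.n_cells_at_max)                 # 154
print(count_selective_cells(rep.trained))         # [52 52 50]

ens = select_ensemble(rep.trained)                # 15 cells, 5 per stimulus
sizes, bits = multiple_cell_information(rep.trained_table, ens)
print(round(bits[-1], 2))                         # 1.58
```

Before training no output cell carries the maximal 1.58 bits; after
training ~150 of the 1024 output cells respond to exactly one hand-object
configuration at all five retinal positions, roughly evenly split between
the Up/Left/Right configurations, and the 15-cell ensemble decodes the
configuration perfectly (1.58 bits).

The same pipeline is exposed on the command line:

```
visnet-hand run --experiment baseline --seed 1 --out results/baseline
```

which writes the per-cell information table (CSV), the selective-cell
counts, a JSON summary, and rank-order / multiple-cell information plots.

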
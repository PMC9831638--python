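# adaptcode

Adaptive sparse population coding: belief-driven gain modulation of model
V1 neurons for efficient perceptual inference.

## The problem

Sensory cortex is under constant top-down influence: attention-like
feedback suppresses or boosts individual neurons depending on what the
organism currently needs to know. `adaptcode` implements a normative
account of this modulation. A sparse-coding population of `N` model
neurons encodes image patches `x_t` through activations `s_{n,t}`
(learned unit-norm features `φ_n`, linear decoding `x̂ = Σ_n φ_n s_n`).
Each activation then passes through a smooth shrinkage nonlinearity

    z_{n,t} = sign(s_{n,t}) · [ (1/α) log( e^{α ξ_{n,t}} + e^{α |s_{n,t}|} − 1 ) − ξ_{n,t} ],

whose per-neuron threshold `ξ_{n,t} ≥ 0` is set at every time step by a
Bayesian perceptual observer. The observer tracks a latent environmental
state `θ_t` (object present/absent, target position, dominant
orientation) from noisy measurements of the population response, and
chooses thresholds minimizing

    C(ξ) = ⟨ D_KL^sym[ p(θ | z(ξ)) ‖ p(θ | z(0)) ] + ψ Σ_n |z_n(ξ_n)| ⟩

under its predicted stimulus distribution — the inference error that
compression introduces relative to the full sparse code, plus an
"attentional resource constraint" `ψ` on neural activity. Per-belief
optima are precomputed over a discretized belief grid (resilient
backpropagation with a numerically estimated gradient, `ξ = a²`
reparametrization) and looked up online.

The package is aimed at computational neuroscientists studying efficient
coding, attention, and top-down modulation: it provides the stimulus
generators, the sparse coding model, three closed-loop inference tasks
(object detection, target localization, orientation estimation), and the
population-statistics analyses (sparsity, noise correlations, tuning
modulation, gain dynamics, uncertainty profiles).

## Worked example

```python
import numpy as np

from adaptcode.pipeline import build_model
from adaptcode.profiles import SCALED
from adaptcode.simulate import feedback_cost, run_closed_loop
from adaptcode.tasks import build_detection_task
from adaptcode.thresholds import OptimConfig, binary_belief_grid, build_threshold_table

# learn a sensory dictionary on a synthetic corpus (16x16 patches)
dictionary, corpus = build_model(SCALED, seed=0, epochs=12, corpus_size=3000)

# assemble the object-detection task and optimize thresholds per belief
task = build_detection_task(dictionary, SCALED.W, seed=1, n_train=500)
table = build_threshold_table(
    task, binary_belief_grid(SCALED.k_bins), OptimConfig(psi=4.0), seed=2
)

# closed-loop perception: standard sparse coding vs the adaptive code
full = run_closed_loop(task, T=2000, seed=3, mode="full")
adapt = run_closed_loop(task, T=2000, seed=3, mode="adaptive", table=table)

_, fb_total = feedback_cost(adapt.xi)
p_true = np.where(adapt.states == 1, adapt.belief, 1 - adapt.belief)
print(f"full-code activity      : {full.activity().mean():8.2f}")
print(f"adaptive activity       : {adapt.activity().mean():8.2f}")
print(f"feedback cost per step  : {fb_total / adapt.T:8.2f}")
print(f"posterior on true state : {p_true.mean():8.3f}")
```

Output:

```
full-code activity      :   117.80
adaptive activity       :    19.33
feedback cost per step  :     1.22
posterior on true state :    0.924
```

The adaptive code spends about six times less total activity (summed
`|z|` per step, plus the top-down feedback cost charged whenever the
threshold vector switches) than the standard sparse code on the same
stimulus sequence, while the observer's posterior still assigns 0.92
probability to the true environmental state on average. On the
orientation-estimation task the reduction exceeds a factor of ten.

The same workflow is available from the shell:

```bash
adaptcode learn-dict --n 128 --w 16 --d 128 --out dict.h5
adaptcode build-table --dict dict.h5 --task detection --psi 4 --out table.h5
adaptcode simulate --dict dict.h5 --table table.h5 --task detection \
    --t 2000 --mode adaptive --out trace.h5
adaptcode analyze --trace trace.h5 --dict dict.h5 --out stats.json
```

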
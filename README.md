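# burnspec

Burn-severity classification from hyperspectral reflectance curves with
a bidirectional selective-state-space (Mamba) network.

Clinical grading of burn depth by eye is only 65–70 % accurate, while
hyperspectral imaging records a full visible/NIR reflectance spectrum
per pixel that carries the signature of thermal tissue damage — most
prominently the loss of 600–700 nm absorption and changing NIR features.
`burnspec` is for researchers who want a reproducible, CPU-only
reference implementation of per-pixel burn classification from such
spectra: the network, its training and 10-fold cross-validation
protocol, the four-variant ablation, a baseline-classifier harness, and
a synthetic spectra generator that stands in for (non-public) burn
datasets.

## The model

A reflectance curve Y ∈ R^D (D bands, ascending wavelength) is treated
as a sequence. Each band value is embedded into a `model_dim`-wide
feature and scanned by a selective state-space model — per channel the
diagonal recurrence

    h_t = exp(Δ_t A) ⊙ h_{t−1} + Δ_t B_t u_t,   y_t = C_t · h_t + D u_t,

with input-dependent Δ_t, B_t, C_t (the Mamba selection mechanism) and
A = −exp(A_log) < 0, inside a gated block (causal depthwise conv, SiLU,
multiplicative gate). Two independent branches scan low→high and
high→low wavelength; each pools channels, applies BatchNorm + LeakyReLU,
and the outputs are fused additively:

    Y_out = Y_out-seq + Y_out-rev.

A two-layer head compresses the D-band feature to 100 units and then to
the C = 6 temperature classes (50–300 °C). Training: Adam, cross-entropy,
lr 1e−3 with decay 0.9 every 10 epochs. Evaluation: stratified 10-fold
CV reporting overall accuracy (OA), average per-class accuracy (AA) and
Cohen's κ = (Po − Pe)/(1 − Pe).

See `docs/methods.md` for the full model description, the synthetic
data generator, and every numerical choice.

## Worked example

```python
import numpy as np
from burnspec import SyntheticConfig, TrainConfig, generate, crossvalidate

ds = generate(SyntheticConfig(samples_per_class=200, noise_sd=0.0,
                              illum_scale_sd=0.0, interference_sd=0.0,
                              seed=2026))
cfg = TrainConfig(seed=2026, epochs=15, batch_size=256,
                  model={"model_dim": 8, "state_dim": 8, "expand": 1})
res = crossvalidate(ds, cfg, k=10, model="mbnet")
print(res.mean_report.summary())
```

prints

```
OA 100.00%  AA 100.00%  Kappa 1.0000
```

— on the noise-free benchmark all 1 200 synthetic spectra (6 classes ×
200) are classified perfectly under 10-fold CV: OA is the fraction of
correct predictions, AA the unweighted per-class mean (identical here
because classes are balanced), and κ = 1 means perfect chance-corrected
agreement. Add realistic noise (`SyntheticConfig(seed=0)` defaults) and
the same protocol lands in the 80–90 % range, where the ablation
(`run_ablation`) shows the bidirectional network ahead of its
single-branch and no-Mamba variants.

The same workflows are scriptable from the shell:

```bash
burnspec simulate --seed 1 --samples-per-class 200 --out data/sim.csv
burnspec crossval --data data/sim.csv --k 10 --epochs 15 --out results/cv
burnspec ablate   --data data/sim.csv --k 2  --epochs 50 --out results/ablation
```

Every run writes a `manifest.json` (config, seed, dataset hash, package
version) from which its artifacts can be regenerated.

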
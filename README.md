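# agsevnet

3D brain-tumor segmentation on multi-modal MRI with an **AGSE-VNet**: a
V-Net-shaped volumetric encoder/decoder in which every encoder stage is
recalibrated by a squeeze-and-excitation (SE) block and every decoder
stage fuses its skip connection through an attention-guided image
filter (AG). The package is aimed at medical-image-analysis researchers
who want a fully inspectable, CPU-only reference implementation of the
architecture, its weighted Dice objective and BraTS-style evaluation —
testable end to end without any external dataset thanks to a built-in
synthetic phantom generator.

Everything runs on a small numpy reverse-mode autodiff engine included
in the package (`agsevnet.autograd`), so there is no GPU or deep
learning framework dependency.

## The model

Input is a 4-channel volume (T1, T1-CE, T2, FLAIR), z-score normalized
per modality; the target is a one-hot map over (background,
necrotic/gangrene core, edema, enhancing tumor), i.e. BraTS labels
{0, 1, 2, 4}.

**SE block.** Per channel c, squeeze `z_c = mean(U_c)` over the volume,
gate `s = σ(W₂ δ(W₁ z))` with reduction factor m = 4, and rescale
`x̃_c = s_c · u_c`.

**Attention-guided filter.** The skip connection transfers edge
structure from a high-resolution guidance map `I` (projected from the
encoder feature) into the upsampled decoder feature `O`. Per window
`w_k` of radius r (default 16) the coefficients minimize

    Σ_{i∈w_k} [ T_i² (a_k I_i + b_k − O_i)² + ε a_k² ],   ε = 0.1²,

where `T ∈ (0,1)` is a learned attention map; per-voxel coefficients
`(A, B)` average `(a_k, b_k)` over all covering windows, are upsampled
trilinearly and applied as `Õ = A∘I + B`. With `T ≡ 1` this is exactly
the classical guided filter.

**Loss.** Negative class-weighted soft Dice with weights
(0.1, 1.0, 1.0, 1.0) and the squared-sum denominator, so the analytic
per-voxel gradient matches the objective exactly; a perfect prediction
scores −3.1.

**Evaluation.** Per nested region (ET ⊆ TC ⊆ WT): Dice, sensitivity,
specificity and the 95th-percentile symmetrized surface distance
(HD95), all verified against brute-force oracles in the test suite.

## Worked example

Generate ten 32³ phantoms (nested ellipsoidal tumor compartments with
BraTS-like modality contrasts), train a small network, and evaluate:

```bash
agsevnet generate --out data/ --n-cases 10 --seed 1
agsevnet train --data data/ --checkpoint ckpt.npz --seed 1 \
    --max-steps 300 --config examples/tiny.yaml
agsevnet predict --checkpoint ckpt.npz --data data/ --out preds/
agsevnet evaluate --pred preds/ --gt data/ --out metrics.csv
```

The same pipeline from Python (what the acceptance script runs, here at
reduced size):

```python
import numpy as np
from agsevnet import (PhantomConfig, generate_case, MultiModalVolume,
                      zscore_normalize, labels_to_onehot, NetworkConfig,
                      TrainConfig, train, predict_volume, evaluate_case)

cfg = PhantomConfig(volume_shape=(32, 32, 32), region_radii=(10, 6, 3),
                    center_jitter=2.0, noise_sd=5.0, seed=42, n_cases=25)
pairs, holdout = [], []
for i in range(25):
    case = generate_case(cfg, i)
    vol = zscore_normalize(MultiModalVolume(case.image.astype(float)))
    if i < 20:
        pairs.append((vol.data.astype(np.float32),
                      labels_to_onehot(case.labels)))
    else:
        holdout.append((vol, case.labels))

net = NetworkConfig(base_channels=4, patch_shape=(32, 32, 32),
                    n_encoder_stages=3, agf_radius=2, dropout_rate=0.0)
model, losses = train(pairs, TrainConfig(learning_rate=1e-3,
                                         final_learning_rate=3e-4,
                                         max_steps=500, seed=0, network=net))
for vol, labels in holdout:
    print(evaluate_case(predict_volume(model, vol), labels).dice)
```

On one CPU this trains in about three and a half minutes and prints
per-region Dice for the five held-out phantoms, e.g.

```
{'ET': 0.726, 'TC': 0.946, 'WT': 0.985}
{'ET': 0.772, 'TC': 0.907, 'WT': 0.986}
{'ET': 0.770, 'TC': 0.946, 'WT': 0.985}
{'ET': 0.748, 'TC': 0.946, 'WT': 0.986}
{'ET': 0.754, 'TC': 0.957, 'WT': 0.986}
```

— near-perfect whole-tumor overlap, with the smallest region (ET)
hardest, the pattern this architecture shows on real BraTS data as
well. Phantom scores are far above real-data scores because the
phantom geometry is deliberately simple (see `docs/methods.md`).

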
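# renuseg

Recursive self-training of a U-Net for **nuclei detection and segmentation
in H&E-stained pathology images with incomplete annotation**.

Manually outlining every nucleus in a digital-pathology tile is
impractical, so real datasets annotate only a fraction of the nuclei per
image. Training a segmentation network directly on such data presents
every unannotated nucleus as background and biases the model against the
very objects it should find. `renuseg` implements a practical remedy for
researchers working with partially annotated microscopy data:

1. **Initial stage (I-DL).** Train a U-Net only on 64×64 patches centred
   at annotated nuclei (five translated patches per nucleus) plus negative
   patches mined from acellular regions via the red-channel threshold
   `t = a·μ/σ`, minimising the combined loss
   `L = w₁·L_Dice + w₂·L_BCE` (soft Dice, `ε = 1`, `w₁ = 1`, `w₂ = 0.1`).
2. **Recursive stage (R-DL).** Apply the trained model to its own
   training images; binarise the likelihood maps (Otsu, 256 bins), clean
   them (opening, 5 px disk), and promote segmented objects with
   roundness `Rdn = 4πA/P² > 0.7` and solidity `S = A/CA > 0.9` to
   pseudo-labels. Add their five augmented patches to the positive pool
   (negatives unchanged) and retrain; stop when fewer than 20 % new
   nuclei are gained or after 3 iterations.
3. **Evaluation.** A reference nucleus counts as detected when the best
   overlapping object reaches IoU ≥ 0.5; reported measures include pooled
   detection sensitivity, matched-pair Dice/Jaccard (mean ± sd), the
   Aggregated Jaccard Index, and precision/recall/F1/mAP over the IoU
   grid 0.50…0.95.

A seeded synthetic H&E generator (elliptical nuclei, ~32 px long axis,
clustered into tissue-like nests, per-nucleus stain heterogeneity) makes
the whole pipeline testable offline, with complete ground truth from
which incomplete annotations of any fraction are derived. The U-Net and
its training loop are implemented directly on numpy (analytic backprop,
im2col + GEMM convolutions, numba-compiled kernels), so no deep-learning
framework is required.

## Worked example

```python
from renuseg.experiments import scaled_recursive_experiment

summary = scaled_recursive_experiment(seed=1559831879)
for it in summary["iterations"]:
    print(f"iteration {it['iteration']}: +{it['new_count']} pseudo-labels "
          f"(pool {it['positive_count']}) stop={it['stop']} {it['reason']}")
print(f"I-DL sensitivity {summary['idl']['sensitivity']:.3f} "
      f"({summary['idl']['n_detected']}/{summary['idl']['n_references']})")
print(f"R-DL sensitivity {summary['rdl']['sensitivity']:.3f} "
      f"({summary['rdl']['n_detected']}/{summary['rdl']['n_references']})")
```

prints

```
iteration 1: +357 pseudo-labels (pool 120) stop=False
iteration 2: +20 pseudo-labels (pool 477) stop=True gain
I-DL sensitivity 0.940 (235/250)
R-DL sensitivity 0.976 (244/250)
```

Read: 20 training tiles carried 120 annotated of ~500 true nuclei. The
first recursive iteration promoted 357 well-segmented unannotated nuclei
to pseudo-labels and retrained; the second found only 20 more (< 20 % of
477), so the loop stopped. On ten held-out tiles with complete ground
truth, recursive training lifted detection sensitivity from 0.940 to
0.976 — the mechanism recovers nuclei that incomplete annotation had
taught the initial model to suppress.

The same pipeline is scriptable from the shell:

```bash
renuseg generate --seed 7 --out run/data
renuseg prep --data run/data --out run/pools
renuseg train-initial --pools run/pools --out run/model
renuseg train-recursive --data run/data --pools run/pools \
    --model run/model/model_initial.npz --out run/recursive
renuseg evaluate --pred pred_masks/ --truth run/data/test_labels/
```

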
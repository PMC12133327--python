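# judicam

Juxtaposed class-activation-map evidence for binary fracture detection.

## The problem

A binary classifier that flags vertebral compression fractures on
radiograph crops can be right for the wrong reasons. Showing the reader a
single saliency map for the predicted class invites confirmation bias: the
map always highlights *something*, whether or not the model truly used the
lesion. This package implements a judicial evidence protocol instead: for
every image it presents **four maps side by side** — evidence *for* the
fracture class and evidence *for* the no-fracture class, each at two
feature depths (AM3, a fine-grained level, and AM4, the high-level features
feeding the classification head). The reader weighs the juxtaposed
evidence rather than a single verdict.

Three pipelines produce the four-map bundle:

| approach | positive maps | negative maps |
|---|---|---|
| single-model | one classifier, fracture neuron | same classifier, no-fracture neuron |
| dual-model | sensitivity-optimised classifier | specificity-optimised classifier |
| generative | autoencoder per (polarity, level) trained to imitate the single-model maps | likewise |

Supporting machinery: the Grad-CAM family (Grad-CAM, HiResCAM, Grad-CAM++,
XGrad-CAM, LayerCAM, plus a RandomCAM sanity reference), faithfulness
metrics for choosing among them (confidence drop/increase and a ROAD-style
remove-and-retest score with noisy discrete-harmonic imputation), STAPLE
consensus fusion of annotator masks, Fleiss'/Cohen's kappa agreement, and
IoU / IoGT overlap scoring of binarized maps against the consensus ground
truth. Everything runs on a seeded synthetic radiograph generator, so the
full study is reproducible on one CPU in minutes.

## Worked example

```python
from judicam import (
    RunConfig, run_end_to_end,
)

result = run_end_to_end(RunConfig(out_dir="demo_run"))

print(result["robustness"]["single"].rows[["Algorithm", "Drop", "ROAD"]])
print(result["ae_table"])
print(result["overlap"].rows)
```

On the default configuration (200 synthetic 64×64 images, seed 7, about
four minutes on one CPU core) this prints the faithfulness table that
motivates HiResCAM as the default algorithm:

```
   Algorithm      Drop      ROAD
     gradcam  0.013576  0.315943
    hirescam  0.013576  0.315952
  gradcam_pp  0.007261  0.044897
    xgradcam  0.013576  0.315955
    layercam  0.006278  0.051124
   randomcam  0.060531  0.004913
```

HiResCAM's ROAD (0.316) far exceeds the RandomCAM reference (0.005 ≈ 0),
passing the sanity check. Grad-CAM agrees with HiResCAM to 14 decimal
places here because at the head-feeding block the two are architecturally
identical (the class-score gradient is spatially constant per channel).

The four map autoencoders fit their single-model teacher maps closely on
the training split and generalise less tightly, as expected:

```
  Type of CAM produced  Training MSE  Validation MSE  Test MSE
0       Positive (AM4)      0.000068        0.002758  0.003082
1       Positive (AM3)      0.000646        0.007909  0.010163
2       Negative (AM4)      0.000052        0.001101  0.002977
3       Negative (AM3)      0.000853        0.006310  0.010073
```

And the juxtaposition carries signal: after μ+σ binarization, positive
maps overlap the STAPLE consensus lesion masks far better than negative
maps for every approach (mean IoGT on the positive test images):

```
approach    positive maps  negative maps
single          0.458 (AM3)     0.067 (AM3)
dual            0.363 (AM3)     0.087 (AM3)
generative      0.436 (AM3)     0.132 (AM3)
```

Pooled inter-annotator agreement across the four simulated raters:
Fleiss' κ = 0.837, Cohen's κ (specialists' vs residents' consensus) = 0.884.

## Command line

```bash
judicam demo --seed 7 --out demo_run        # full pipeline, 5 report files
judicam generate-data --n-pos 100 --n-neg 100 --out data/
judicam train --data data/ --objective sensitivity --class-weights 1,2 --out sens.pkl
judicam evaluate-cams --model sens.pkl --images data/validation/images --out road.csv
judicam explain --approach single --model sens.pkl --images data/test/images --out evidence/
judicam consensus --masks raters/ --out consensus.png --report staple.json
judicam agreement --masks raters/ --roles roles.csv --out agreement.json
judicam overlap --evidence evidence/ --gt gt/ --out overlap.csv
```

## Layout

- `src/judicam/synthetic_data.py` — seeded radiograph-like image generator, simulated raters
- `src/judicam/models.py` — block CNN classifier with AM3/AM4 feature taps
- `src/judicam/cam_algorithms.py` — Grad-CAM family and post-processing
- `src/judicam/robustness.py` — drop/increase, noisy linear imputation, ROAD, sanity check
- `src/judicam/strategies.py` — the three juxtaposed-evidence pipelines
- `src/judicam/generative.py` — map autoencoders and their training losses
- `src/judicam/agreement.py` — STAPLE, kappas, binarization, overlap study
- `src/judicam/cli_io.py`, `src/judicam/cli.py` — configuration and command line
- `docs/methods.md` — methods note (definitions, conventions, design decisions)
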
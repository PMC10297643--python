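# cpcnn — cascaded-progressive CNN for meniscus-injury detection

Tears of the knee meniscus appear on sagittal T2 MR slices as a thin
high-signal line inside the dark, triangular meniscal horns. Reading
these images is slow and reader-dependent, which motivates automatic
detection that can also *show* the reader where the suspected lesion is.

`cpcnn` implements a cascaded-progressive convolutional neural network
(C-PCNN) for this task, for researchers studying multi-resolution and
weakly-supervised lesion analysis. A case enters as a three-level
resolution pyramid (nominal 640×320 / 1280×640 / 2560×1280) processed by
three ResNet50-style tiers:

* the **primary** (low-resolution) tier classifies the image and, via
  Grad-CAM, yields a lesion localization map
  `L = ReLU(Σᵢ αᵢ fᵢ)`, `αᵢ = GAP(∂y¹/∂fᵢ)`,
  learned from image-level labels only (weak supervision);
* the **secondary** tier's features are fused additively with the
  primary's after `block_1`;
* the **tertiary** (high-resolution) tier receives the secondary fusion
  after `block_2` — an extra stride-2 convolution guarantees matching
  sizes — where a **lesion attention module** re-weights the fused
  features by a spatial-softmax feature attention map and by
  `1 + L` (location attention), before producing the final diagnosis.

Evaluation follows a stratified 5-fold cross-validation rotation with
accuracy / precision / recall / specificity / F1 from the confusion
counts and tie-aware ROC/AUC. Because the clinical images are not
public, the package ships a synthetic knee-phantom generator (dark
wedges, bright thin streak, known pixel masks) on which the entire
pipeline is trained and validated end to end. The networks run on a
compact NumPy autodiff engine included in the package; a "tiny" preset
(quarter width, single-unit blocks, 160×80 base) makes training a matter
of minutes on one CPU core.

## Worked example

Train the tiny cascade on synthetic phantoms and evaluate held-out cases
(about two minutes on one core):

```python
import numpy as np
from cpcnn import PhantomSpec, generate_dataset
from cpcnn.cascade import CascadeConfig, train, predict
from cpcnn.evaluate import (ConfusionCounts, compute_metrics, roc_auc,
                            localization_score)

train_cases = generate_dataset(PhantomSpec(base_resolution=(96, 48), seed=51), 80)
test_cases = generate_dataset(PhantomSpec(base_resolution=(96, 48), seed=52), 40)

config = CascadeConfig.tiny(base_size=(96, 48), epochs_primary=3,
                            epochs_cascade=4, seed=5)
model = train(train_cases, config)

preds = predict(model, test_cases)
labels = [c.label for c in test_cases]
counts = ConfusionCounts.from_predictions(labels, [p.label for p in preds])
report = compute_metrics(counts)
report.auc = roc_auc(labels, [p.probability for p in preds]).auc
print("confusion:", counts)
print("metrics:", report.rounded(4))

hits = [localization_score(p.localization, c.lesion_mask, dilation_radius=9)
        for p, c in zip(preds, test_cases) if c.label == 1 and p.label == 1]
print(f"Grad-CAM peak inside dilated lesion mask: {np.mean(hits):.0%} of true positives")
```

which prints:

```
confusion: ConfusionCounts(tp=27, tn=13, fp=0, fn=0)
metrics: {'acc': 1.0, 'pre': 1.0, 'recall': 1.0, 'spe': 1.0, 'f1': 1.0, 'auc': 1.0}
Grad-CAM peak inside dilated lesion mask: 59% of true positives
```

All 40 held-out phantoms are classified correctly (AUC 1.0). The
localization hit rate is bounded by the Grad-CAM map's native resolution
— only 6×3 cells at this miniature scale; at the standard tiny preset
(160×80) the 3-seed median hit rate exceeds 90%. The peak reliably lands
in the correct horn either way.

The same pipeline is scriptable from a shell:

```bash
cpcnn phantoms --n 300 --out data/ --seed 1 --base 160x80
cpcnn run --config src/cpcnn/configs/tiny.yaml --out run/
cpcnn predict --model run/model.npz --image data/case_00000_low.png --heatmap heat.png
```

## Layout

| module | contents |
|---|---|
| `cpcnn.phantoms` | synthetic knee-phantom generator with ground-truth masks |
| `cpcnn.imageio` | PNG/TIFF (optional DICOM) reading, 2:1 crop, resolution pyramid |
| `cpcnn.backbone` | ResNet50-style tiers with named feature taps |
| `cpcnn.weakloc` | Grad-CAM localization maps and heat-map overlays |
| `cpcnn.lam` | lesion attention module |
| `cpcnn.cascade` | full C-PCNN, two-stage training, prediction, checkpoints |
| `cpcnn.evaluate` | stratified k-fold protocol, confusion metrics, ROC/AUC |
| `cpcnn.cli_app` | `cpcnn` command-line interface |
| `cpcnn._tensor`, `cpcnn.nn` | NumPy reverse-mode autodiff engine and layers |

See `docs/methods.md` for the model, training protocol, numerical
choices, and the limits of what the phantom experiments demonstrate.
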
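# dualpathcnn

A toolkit for building, auditing and training the *dual-path* family of
feedforward convolutional networks, together with the two data pipelines those
networks were designed for: converting multi-parameter gas-sensor readings
into trainable images, and preparing graded retinal (diabetic-retinopathy)
photographs for classification.

It is aimed at researchers who work with small, specialized image-classification
problems — sensor telemetry rendered as images, graded medical photographs —
and who want an architecture whose every intermediate tensor shape is declared,
checked, and reproducible, with a training protocol that is exactly
deterministic given a seed.

## The model

A dual-path network is an ordered chain of modules:

* a **simple convolution** stem (3×3 stride 1, or 9×9 stride 3 for the
  "reductive" variant that subsamples high-resolution input aggressively);
* **normal dual-path modules**: parallel 1×1 and 3×3 stride-1 convolution
  branches whose outputs are concatenated along channels;
* **reduction dual-path modules**: a 3×3 stride-2 convolution branch next to a
  3×3 stride-2 max-pool branch (the pool passes all input channels through),
  halving the spatial grid while growing channels;
* a tail of global average pooling → flatten → one fully connected layer →
  softmax.

Every convolution is followed by batch normalization and a ReLU.  Spatial
sizes obey the standard convolution arithmetic

```
W_out = floor((W_in − K + 2P) / S) + 1
```

with fixed padding conventions (P=0 for 1×1, P=1 for 3×3, P=2 for the 9×9
stem), and channels concatenate: a normal module outputs the sum of its branch
filter counts; a reduction module outputs conv filters + input channels.
Four architectures are bundled (`original`, `reductive`, `deepened`,
`revised_deepened`); each ships with its declared per-module output sizes, and
`audit_spec` verifies the calculus against every declared cell.

Training is minibatch SGD with momentum 0.9, weight decay 5e-4, initial
learning rate 0.01 decayed by 0.1 on a step schedule, cross-entropy loss, and
Xavier-initialized weights — implemented in pure NumPy, fully reproducible
from a seed.

The tabular-to-image encoder renders a five-parameter sensor specimen (doping
material code, angle, force, air pressure, in-air current) as a 64×64
grayscale image with five disjoint 20×20 zones, one gray level per normalized
parameter; air-pressure ranges are expanded into one specimen per 295 Pa step.
Because a CNN sees spatial position, equal gray values in different zones
carry different information, which is what makes tabular data learnable by an
image classifier.

## Worked example

```python
import numpy as np
from dualpathcnn import archspec, network, sensor, synthetic
from dualpathcnn.analysis import count_dead_units, extract_activations

# 1. audit the bundled reductive architecture against its declared shapes
report = archspec.audit_spec(archspec.builtin_specs()["reductive"])
print(report)

# 2. synthetic sensor specimens -> five-zone images -> train the original net
cfg = synthetic.SensorGenConfig(n_specimens=80, seed=1)
specimens = sensor.normalize_parameters(synthetic.gen_sensor_specimens(cfg))
images = np.stack([sensor.encode_specimen(s) for s in specimens])
labels = np.array([s.label for s in specimens])

net = network.build_network(archspec.builtin_specs()["original"],
                            n_classes=5, width_multiplier=0.125, seed=1)
model = network.train(net, (images[:70], labels[:70]), (images[70:], labels[70:]),
                      network.TrainingConfig(epochs=15, batch_size=14, seed=1))
print("best epoch:", model.best_epoch[0], "val acc:", model.best_epoch[2])

# 3. activation-space analysis on the validation images
table = extract_activations(model, images[70:], labels[70:])
dead, alive = count_dead_units(table)
print(f"feature table {table.rows.shape}; dead units {dead}, alive {alive}")
```

The audit prints one row per module, e.g.

```
audit of reductive:
  [ 0] simple_conv      (74 x 74 x 96)  ok
  [ 1] normal_dual      (74 x 74 x 64)  ok
  [ 2] normal_dual      (74 x 74 x 80)  ok
  [ 3] reduction_dual   (37 x 37 x 160)  ok
  ...
0 mismatch(es)
```

meaning every inferred width/height/channel triple matches the declared
output size.  The training run then prints

```
best epoch: 11 val acc: 1.0
feature table (10, 42); dead units 0, alive 42
```

— the narrow (width ×0.125) original network separates the five synthetic
pollutant classes perfectly by epoch 11, and every one of its 42 pooled
feature columns activated on at least one validation image (no dead ReLU
units at this scale).

The same pipeline is available from the shell:

```sh
dualpathcnn synth sensors --out specimens.csv --seed 0
dualpathcnn encode --in specimens.csv --out imgs/
dualpathcnn train --arch original --data imgs/ --width-multiplier 0.25 --epochs 30
dualpathcnn activations --model model.npz --data imgs/
dualpathcnn embed --features activations.csv --seed 0
dualpathcnn shapes deepened
```

An estimator facade, `DualPathCNNClassifier`, exposes the trainer through the
scikit-learn `fit`/`predict`/`predict_proba`/`get_params` contract, and
`SensorImageEncoder` / `FundusPreprocessor` are sklearn-style transformers.

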
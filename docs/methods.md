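# Methods

## The architecture family and its shape calculus

A dual-path network is declared, not hard-coded: an `ArchitectureSpec` lists
an input shape and an ordered chain of modules, and every quantity the
implementation needs — spatial sizes, channel counts, the flattened feature
length — is derived by an exact integer calculus rather than discovered at
run time.  The rules are:

* convolution output size `W_out = floor((W_in − K + 2P)/S) + 1`.  Floor
  division is deliberate: it is the only convention that reproduces the
  declared width chains of the bundled tables (224 → 74 → 37 → 19 → 10 for
  the reductive variant and 224 → 112 → 56 → 28 → 14 → 7 for the deepened
  one).
* padding is fixed by kernel size: 1×1 convolutions use P=0, 3×3
  convolutions and 3×3 max pools use P=1, and the 9×9 stride-3 stem uses
  P=2 — again the only values consistent with the declared cells.  The
  source tables never state padding; these conventions are forced by
  arithmetic, not chosen freely.
* a normal dual module concatenates its 1×1 and 3×3 branch outputs along
  channels (no shortcut, no pass-through: the declared 176+160 → 336 channel
  counts leave no room for one); a reduction dual module concatenates its
  conv branch with the max-pool branch, which passes *all* input channels
  through (declared 96+336 → 432 requires it).

`audit_spec` replays this calculus over a spec and compares each module
against its declared output.  Declared outputs are optional so user-written
specs can skip auditing; audit failures are report entries rather than
exceptions, so a single wrong filter count produces a readable table, not a
stack trace.  `build_network` refuses to materialize a spec that fails its
audit.

Two declared-table ambiguities were resolved during bundling: one deepened
table cell is an obvious misprint (a 7×7 module printing 4160 channels where
its branches sum to 224+192 = 416, and the following module consumes 416),
and the revised-deepened variant's replacement tail (whose first reduction
outputs 14×14) only fits behind the deepened front's 28×28×336 feature map,
so that is the front it is bundled with.  The original variant is fixed at
64×64 input — the resolution its preprocessing actually produces and the only
one from which its final 8×8 feature maps arise.

## The network implementation

The trainer is written directly on NumPy float32 tensors in NHWC layout.
Convolutions accumulate one BLAS matmul per kernel offset (k² matmuls over
strided slices) instead of materializing a full im2col buffer; max-pooling
stores a 9-way argmax per output for its backward pass.  Gradients were
verified against central finite differences in float64 (worst relative error
~1e-7 across all parameter groups).

Numerical conventions, all fixed:

* batch normalization: epsilon 1e-5; running statistics with momentum 0.9
  (`running = 0.9·running + 0.1·batch`); evaluation mode normalizes by the
  running statistics.
* initialization: Xavier normal (sd = sqrt(2/(fan_in+fan_out))) for every
  convolution and the fully connected layer; biases, and batch-norm shifts,
  start at zero.
* optimizer: SGD with classical momentum 0.9 and weight decay 5e-4 applied
  to convolution and fully-connected weights only — never to biases or
  batch-norm parameters, the common practice where the source protocol is
  silent.
* learning rate 0.01, multiplied by 0.1 at scheduled epochs.  No schedule is
  stated for the feedforward trainings, so the default is the conventional
  two-step schedule {⌈E/2⌉, ⌈3E/4⌉} for E epochs, exposed in
  `TrainingConfig.lr_decay_epochs`.
* prediction ties break toward the lowest class index (NumPy argmax).
* a non-finite training loss aborts with a diagnostic rather than continuing.

All randomness (weight init, batch shuffling) flows from a single integer
seed; identical seeds and configs give bit-identical histories on the same
platform.

`width_multiplier` scales every filter count (minimum 1 per branch) while
leaving the module chain, strides and pooling untouched, so the architecture
can be exercised shape-faithfully at a fraction of the compute.  The
end-to-end tests train the original architecture at width ×0.25 on a
135-image training set for 30 epochs — a deliberate desk-scale choice; the
batch sizes used by the published experiments (56, 68, 7) are recorded as
presets.

## The five-zone encoder

A specimen's five parameters are max-scaled — each divided by its maximum
absolute value over all specimens — rather than min-max scaled: the encoding
contract is only that values land in [0, 1] with 1 rendering as white, and
max-scaling preserves zero.  Each parameter fills one 20×20 zone of a 64×64
canvas with `round(value·255)` (half-up); the background stays black.  The
published description fixes the canvas and the 20×20 zone size but not the
zone coordinates, so the layout here places zones 1–4 at the four corners
with a 2-pixel margin and zone 5 (the decisive in-air current) at the center;
any fixed non-overlapping layout preserves the method, since the network
learns spatial positions.  Doping material is categorical and must be coded
as a small integer before normalization.

Air-pressure ranges expand into `floor((high−low)/increment) + 1` specimens
at `low, low+increment, …` with the other four parameters copied — the data
augmentation that turns tens of measured specimens into hundreds of training
images.  The default increment is 295 Pa.

## Image preparation

Retina-style preparation is exactly two steps: bilinear resize so the shorter
edge hits the target (64 or 224 px), then a central square crop with
floor-divided offsets.  No flipping, contrast work or other enhancement is
applied, by design.  Class percentages are reported to two decimals under
round-half-up; note that the published distribution table for the DR training
set is internally inconsistent (its class-1 cell and its two rarest-class
cells do not follow from its own counts under any nearest rounding — they
match a denominator one smaller), so the package reports the correctly
recomputed values.

Dataset splitting is a uniform random partition with `floor(ratio·n)`
training records, deterministic given its seed.

## Activation analysis

The analysis operates on the global-average-pooled feature vector per sample
(the fully connected layer's input; 336 or 416 entries for the bundled
architectures).  A *dead unit* is a feature column that is exactly zero on
every sample — exact zero is the right test, because a pooled post-ReLU
average is zero iff every contributing pre-pool activation was non-positive;
no epsilon is involved.  The 3-D embedding wraps scikit-learn's t-SNE with
`method="exact"` (robust on degenerate inputs such as duplicated rows, and
exactly reproducible from the seed) and perplexity defaulting to
min(30, n/4).

## The synthetic generators

The sensor generator draws five-parameter specimens as Gaussian clusters
around five distinct per-class mean vectors (doping codes 1–5, angles
15–75°, forces 1–5 a.u., pressures 20–100 kPa, currents 1–9 a.u.), with
noise standard deviation 0.05 of each parameter's scale, 150 specimens by
default, labels round-robin.  This emulates the premise of the original
apparatus data — five well-separated pollutant classes with minimal internal
correlation — because the measured specimens themselves are unpublished.  It
does **not** emulate measurement drift, class overlap, or correlated errors;
a passing end-to-end test therefore demonstrates that the pipeline (encoding
→ architecture → optimizer) can carry class-separable structure to high
validation accuracy, not that any particular accuracy would be achieved on
real apparatus data.

The toy retina generator produces a bright disk on a dark background with an
exact per-class count of small bright spots (0/2/5/9/14 by default),
slightly wider than tall so the resize/crop path has real work to do.  It is
a pipeline fixture, not a lesion model: it shares with real fundus data only
the property that severity is monotone in a countable image feature.

## Known limitations

* The trainer is CPU-bound NumPy; it is meant for desk-scale experiments and
  tests, not for training the full-width architectures on tens of thousands
  of 224×224 images.
* The published validation accuracies on the external DR dataset and on the
  56 measured apparatus specimens are out of reach by construction: the
  former needs the external image set and GPU-scale training, the latter was
  never published.  Nothing in this package claims to reproduce them.
* The five-zone layout is one admissible realization of a figure that gives
  no coordinates; models trained on one layout do not transfer to another.
* t-SNE output is only seed-stable; its geometry carries no quantitative
  guarantees beyond the cluster-separation property the tests check.
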
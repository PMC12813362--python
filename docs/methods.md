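# Methods

`vgn` classifies vascular tissue imaged by optical-resolution
photoacoustic microscopy (OR-PAM).  The pipeline turns raw RF B-scans into
attributed vascular graphs and classifies each graph into one of five
lesion categories — normal, benign cystic, benign solid, endometriosis,
malignant — with a hybrid message-passing network.  This note records the
model, the choices that were genuinely open, and what the synthetic
validation does and does not establish.

## From RF volumes to vascular graphs

An OR-PAM C-scan is a stack of B-scans (depth samples × A-lines), 3 mm
wide at 1000 A-lines and a 3 µm step in both lateral directions, acquired
with a 25 MHz transducer.  On each B-scan, vessels are detected on the
Hilbert envelope: a pixel is vascular when it lies within a 40 dB dynamic
range of the frame maximum (the standard display convention for these
images) *and* above three times the noise floor, followed by a 3×3 binary
opening.  The noise floor is the scaled median absolute deviation
(1.4826·MAD) of the frame, which is robust to the sparse bright echoes.
Eight-connected components are ranked by pixel count and exactly five per
B-scan become graph nodes; ties go to the smaller lateral position.  When
fewer than five vessels exist, padding nodes (zero features, flagged
invalid, placed at the B-scan center) keep the graph dimensionality
constant — sparse frames are themselves diagnostic, and the classifier
sees that sparsity through the padding.

Each real node carries seven physical features:

* **t₁, t₂** — rise times: the delay from the gate start to the first
  local |RF| extremum above 3× the noise floor, and to the envelope peak.
  The reference zero is the first sample of the vessel's depth gate; the
  gate is the component's depth extent padded by 16 samples on the
  centroid A-line.  Sub-threshold gates yield missing values (NaN), which
  standardization later maps to the training mean.
* **f_c, slope, intercept** — quantitative-ultrasound spectral
  descriptors over the transducer's −6 dB band ([15, 35] MHz): the
  power-weighted spectral centroid (centroid rather than spectral peak,
  for noise robustness), and the ordinary least-squares line through the
  Hann-windowed power spectrum in dB versus frequency, with the intercept
  evaluated at 0 Hz.  No reference-phantom calibration is applied;
  features are only ever compared within one acquisition system.
* **θ, d** — local direction and corrected diameter.  The component is
  matched by nearest centroid (10-pixel lateral radius) in the
  immediately preceding and following B-scans; θ = arctan(|Δx|/Δy) over
  the matched span, and d = w·cos θ corrects the observed lateral width
  w (bounding-box column extent × pitch).  Unmatched components default
  to θ = 0.  A `span` option widens the neighbor distance to two B-scans
  for the alternative reading of "the two B-scans preceding and
  following".

Graphs are complete with inverse-distance edge weights
w(i,j) = 1/max(‖xᵢ−xⱼ‖, pitch): nearby vessels are assumed to share
correlated vascular features, distant ones less so.  The clamp at one
pixel pitch keeps co-located nodes finite.  Depth never enters positions
or distances — OR-PAM imaging depth is shallow and specimens are
compressed against the imaging window in uncontrolled ways, so depth is
not comparable across specimens.  Merged graphs over N = 41 consecutive
B-scans concatenate the per-B-scan node sets (205 nodes, 20 910 edges)
and recompute weights with the 2-D Euclidean in-plane distance, the
minimal consistent extension of the within-B-scan rule.

## Classifier

The network is a four-layer stack alternating two message-passing
mechanisms with residual connections: GIN-style blocks,
h′ = MLP((1+ε)h + Âh), and multi-head graph attention (GAT) blocks whose
per-head logits are the usual additive attention plus the scalar edge
weight scaled by a learned coefficient.  Â is the row-normalized
(random-walk) edge-weight matrix: raw inverse-distance weights reach
3.3·10⁵ m⁻¹ and would swamp the node features, while row normalization
preserves the relative inverse-distance weighting.  Node features are
embedded to width 64, attention uses 4 heads, global mean pooling over
nodes feeds a two-layer head with a softmax over the five classes.
Hidden width, head count, residual wiring, and how edge weights enter
each mechanism (multiplicative in GIN aggregation, additive in the
attention logits) are this package's choices, exposed in `VGNConfig`.

Training minimizes class-balanced focal cross-entropy,
−w_y(1−p_y)^γ log p_y with γ = 2 and inverse-frequency class weights
normalized to mean 1, using Adam at lr 10⁻² for 200 epochs with ×0.1
multistep decay at epochs 100 and 150 (milestones scale proportionally
for shorter schedules).  Specimens are split 15:3:2 into
train/validation/test with per-class largest-remainder apportionment
(remainder ties to the smaller split; every split gets at least one
specimen when a class has three or more), all graphs of a specimen
staying in one split.  Model selection keeps the epoch with the best
validation balanced accuracy, ties broken toward the lower validation
focal loss — with only a handful of validation specimens the balanced
accuracy saturates early, and the loss tie-break prefers the
sharper-fitting later epoch.  The protocol repeats over independent
seeded splits; metrics are reported as mean ± sd with percentile 95% CIs.

Because no GPU tensor framework is assumed, the network runs on a small
reverse-mode autodiff engine over numpy (`vgn.nn`).  Graphs are batched
densely — (batch, 205, features) plus (batch, 205, 205) weights — which
suits complete fixed-size graphs far better than sparse message passing.
The attention block is a single fused primitive operating in-place on
persistent per-layer buffers; together with single-precision arithmetic
this keeps the dense attention maps cheap.  Everything is seeded and
bitwise reproducible; there is no dropout or other stochastic layer.

## Inference over C-scans

A stride-1 sliding window over a C-scan of L B-scans produces L−N+1
merged graphs, scored independently.  The specimen-level call is the
majority vote of the per-window argmax classes; ties break toward the
larger mean score over the tied classes.  For visualization, the
five-vector of scores maps onto a two-dimensional color wheel: class k
sits at angle 2πk/5, the score vector becomes the point
p = Σ s_k(cos, sin)(2πk/5), hue = angle(p), saturation = |p| (uniform
scores are achromatic), and value = max score, so low-confidence regions
render dark.  Each window colors its center B-scan column; the
construction is this package's definition, with configurable anchors.

## Synthetic phantoms

The clinical cohort is not public, so validation uses class-conditioned
phantoms.  Vessels are tubes running along the slow axis with a lateral
random-walk (tortuosity = per-step heading sd), log-normal diameters, and
Poisson counts set by a surface density.  Each intersected A-line records
a Gaussian-modulated 25 MHz echo at the vessel depth whose amplitude is
proportional to the acoustic chord through the vessel and whose duration
grows with the chord transit time; white Gaussian noise is added.  The
−6 dB pulse band matches the transducer ([15, 35] MHz).  Per-specimen
depth offsets emulate variable compression and exercise the pipeline's
depth independence.  A specimen with nonzero prescribed density always
renders at least one vessel: a zero-vessel draw would leave nothing but
padding graphs, which carry no vascular information to classify — in
practice the probe would be re-sited.

The five class templates are ordered qualitatively the way superficial
ovarian vasculature presents, with each pair of adjacent classes
separated along near-orthogonal feature axes: normal is thin (25 µm
median), sparse (8 vessels/mm²), near-straight and weakly absorbing;
benign cystic has large, smooth surface vessels (90 µm, low tortuosity);
benign solid is thin (35 µm) but denser and more tortuous; endometriosis
is medium-sized (60 µm), very tortuous and strongly absorbing; malignant
is the largest (120 µm), densest (34 /mm²), most tortuous and brightest.
Cohort specimens jitter template parameters log-normally (5–8%) so
classes are distributions, not points.  The defaults are deliberately
well separated: the phantom study is a parameter-recovery check of the
pipeline, not an estimate of clinical performance.

What the phantoms do **not** model: acoustic attenuation and diffraction,
the lateral point-spread function of the optical focus, speckle from
sub-resolution absorbers, vessel branching and crossing, depth-dependent
sensitivity, and realistic inter-class overlap.  Passing the study shows
the chain is implemented coherently — features recover known geometry and
the classifier separates separable classes at small sample sizes — and
nothing more; clinical accuracy figures cannot be inferred from it.

## Study problem sizes and numerical choices

The standard validation study uses 8 specimens per class, C-scans of 45
B-scans (5 windows of 41 each), 5 protocol repeats at 60 epochs with
milestones (30, 45), batch size 16 — sizes chosen so the whole study runs
comfortably on a single CPU while still exercising 205-node graphs and
the full repeat protocol.  Feature recovery uses 50 cylinders (20–200 µm
diameter, 0–60° tilt).

Numerical details worth knowing: probabilities are clamped at 10⁻¹² in
the focal loss; zero-variance features standardize with scale 1 (with a
warning); degenerate gates are widened to the 16-sample minimum; the
γ = 0 focal loss skips the modulation factor entirely so it reduces to
cross-entropy exactly; softmax subtracts the row maximum; the MAD noise
floor is estimated on a ~64k-sample stride of large frames (it is a
statistical estimate, and the subsample pins it far more tightly than it
matters); the dynamic-range threshold is evaluated in the linear domain
(algebraically identical to the dB comparison); network
arithmetic is float32 (reproducible, with permutation invariance holding
to ~10⁻⁶), while feature extraction stays float64.

## Known limitations

Fixed five-node-per-B-scan graphs bias topology toward major vessels; the
"observed width" is a bounding-box extent and overestimates for
irregularly shaped components; directionality uses centroid matching and
can mismatch when vessels cross; the supplementary definition of the
original rise-time and spectral processing was not available, so those
definitions (gate-start reference, centroid center frequency, Hann
window, uncalibrated spectra) are this package's own, flagged in the
relevant docstrings.
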
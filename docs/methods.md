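# Methods

## Problem setting

An archive image carries three categorical characteristics: imaging
modality (λ categories), organ (μ) and disease (ν).  Only a subset of the
λ·μ·ν triples is clinically meaningful; a `LabelSpace` therefore declares
the valid combinations explicitly.  The goal is a hash function
F : image → {−1, +1}^K whose code is the ordered concatenation of three
sub-codes b = [b₁, b₂, b₃] (lengths K₁, K₂, K₃ for modality, organ,
disease), such that Hamming distance — of the full code or of a single
sub-code — reflects the corresponding label agreement.  Each sub-code
must be longer than the information-theoretic floor for its axis:
K₁ > ⌈log₂ λ⌉, K₂ > ⌈log₂ μ⌉, K₃ > ⌈log₂ ν⌉.

## Network

The encoder is a truncated-AlexNet convolutional stack at the `paper`
scale (five convolutions with overlapping 3×3/stride-2 max-pools, ending
in Linear:1024), intended for 224-px inputs.  The second convolution's
printed stride of zero is read as stride one, the standard AlexNet value;
the printed stack has no rectification after the fifth convolution and we
keep that.  For CPU-scale experiments a `tiny` profile replaces it with
three 3×3 convolution/ReLU/2×2-pool blocks ending in Linear:128.

Three heads of identical shape — Linear:512 followed by two parallel
linear maps, one to the class logits (λ | μ | ν wide) and one to the
sub-code features z (K₁ | K₂ | K₃ wide) — sit on the encoder output.  We
apply a ReLU after the 512-wide trunk: without it the trunk is an affine
map composed with affine outputs, i.e. mathematically redundant, and the
sub-code features could not inherit characteristic-specific structure
from the classification signal.  Class count and sub-code length are
independent knobs.

The relaxed code is h = [tanh(z₁), tanh(z₂), tanh(z₃)] ∈ [−1, 1]^K
during training; stored codes are b = sign(h) with the tie sign(0) := +1
so encoding is deterministic.

No pretrained weights are used; initialization is fan-in uniform from a
seeded generator.

## Losses

* **Classification, L₁** — softmax cross-entropy of each head against its
  label, summed over the three heads and over the samples of a batch.
* **Pairwise Cauchy cross-entropy, L₂** — for a pair (i, j), the
  continuous Hamming distance d = (K/2)(1 − cos(hᵢ, hⱼ)) (equal to the
  integer mismatch count on binary codes) is mapped to a predicted
  similarity ŝ = γ/(γ + d) and scored with binary cross-entropy against
  sᵢⱼ ∈ {0, 1} (1 iff all three characteristics agree).  The heavy-tailed
  Cauchy shape keeps gradients informative at large distances.  The
  distance is floored at 1e-6 inside logarithms (the s = 0 branch is
  singular at d = 0), making the loss total.  γ defaults to K/4, which
  places ŝ = 0.5 at a quarter of the code length; the original experiments
  do not report a value.
* **Quantization, L₃** — ‖h − sign(h)‖₂ per sample, summed over the
  batch; zero exactly when the code is binary.  Weight α = 0.01.

The trainer forms **all** unordered within-batch pairs and averages L₂
over them (so the learning rate is decoupled from batch size), while L₁
and L₃ are summed per batch as the formulas state.

**Structured pairwise objective.**  The learning goal covers the full
code *and* each sub-code.  With the full-code term alone nothing decides
*where* discriminative bits live: in desk-scale runs we observed two
diseases of the same modality/organ family whose disease sub-codes
collided exactly while their full codes were separated by bits in the
modality segment — defeating sub-code (Case-II) retrieval.  The trainer
therefore also applies the Cauchy cross-entropy to each sub-code's
distance with that characteristic's own label agreement as the target
(scale K_k/4).  This is controlled by `LossConfig.structured_pairs`
(default on); the per-pair loss functions themselves are unchanged.

## Training

Adam at learning rate 1e-3 (the CPU desk-scale default; the reference
full-scale settings are batch 256 at 1e-4), batch 64, at most 30 epochs,
with a reduce-on-plateau schedule (patience 10, factor 0.1) and a
saturation stop (no improvement of the best epoch loss by 1e-4 for 25
epochs).  Runs are fully seeded — data order, initialization and batch
shuffling all derive from the configured seeds — and single-threaded
deterministic: identical configurations reproduce final losses bitwise.
A non-finite loss aborts with a diagnostic.  Ablation subsets (L₁ alone;
L₁+L₂; L₁+L₂+αL₃) are selected through `LossConfig.loss_subset`; inactive
terms are logged as zero.

## Retrieval and evaluation

Gallery codes, labels and ids form a `GalleryIndex`; distances are exact
integer mismatch counts computed from the ±1 representation (the cosine
identity is a *test*, not the implementation).  Ranking is a stable sort,
ties broken by gallery insertion order, truncated at p.  Case-I ranks by
the full code; Case-II by one characteristic's sub-code.  Double/triple
characteristic queries are evaluated under full-code ranking; Case-II is
defined per single characteristic.

Relevance of a retrieved item under a spec S ⊆ {M, O, D}: for mAP it is
binary — 1 iff *every* characteristic in S matches the query; for nDCG
the gain is V = number of matching characteristics in S, scored as
(2^V − 1)/log₂(r + 1) and normalized by the descending-gain ideal.
Conventions: AP with no relevant item in the top-p is 0 (the 0/0 case);
nDCG with zero ideal DCG is 1 (any ranking is ideal).  Both metrics are
verified against independent brute-force scorers over exhaustive
permutations and gain assignments.

## Synthetic data

The generator emulates the structure of a combined public radiology
archive: 5 modalities × 4 organs × 13 diseases with 15 valid
combinations.  Disease categories are organ-specific where the archive's
"normal" classes are (normal chest / breast / retina count separately),
which is how ν = 13 with 15 triples comes out.  Each axis controls an
independent visual factor:

* **organ** → base shape (disc, rectangle, annulus, cross), with per-image
  scale/position jitter; the mask depends only on (organ, seed), never on
  the other two labels;
* **modality** → global appearance: background level and band pattern,
  gamma contrast curve, and noise texture scale;
* **disease** → a class-constant coarse binary stamp overlaid inside the
  organ mask, anchored to an organ-interior point with ±1 px jitter and a
  disease-specific intensity offset.

Additive truncated-Gaussian noise (σ = 0.05, clipped to [0, 1]) is applied
last.  Splits (train/gallery/query = 0.75/0.15/0.10) are stratified per
combination with largest-remainder rounding; the default 133 images per
combination give 1,500 / 300 / 195 images at 32×32 px.  Identical seeds
reproduce manifests and pixels bitwise.

The generator's separability contract — a pixel-level logistic probe
reaches ≥ 95% held-out accuracy per characteristic — is enforced by a
test.  What passing tests on this data do **not** show: robustness to the
intra-class appearance diversity, acquisition artefacts, class imbalance
and label noise of real archives; the synthetic factors are cleanly
independent by construction, which real anatomy is not.

## Numerical choices

* Float64 throughout the network; gradients verified against central
  differences to ~1e-8.
* sign(0) := +1; stable sort for ranking ties; distance floor 1e-6 in the
  pairwise loss; 1e-12 guards inside square roots of norm computations.
* Problem sizes for the end-to-end study (chosen as the package's
  desk-scale defaults): 32-px images, 1,500 training images, bit structure
  (18, 18, 22) — the best-performing structure of the reference sweep,
  following its K₁ = K₂ = K₃ − 4 observation — batch 64, ≤ 30 epochs.

## Known limitations

* The `paper`-scale encoder is provided and shape-verified but the
  desk-scale study trains only the `tiny` profile; full-scale behaviour
  (224-px images, batch 256) is not exercised.
* The gallery is scanned linearly; no sub-linear multi-index structures.
* Single-label per characteristic only; no DICOM ingestion.
* Run-to-run variance across seeds at desk scale is a few percent in
  disease-specific mAP; modality and organ metrics are saturated.
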
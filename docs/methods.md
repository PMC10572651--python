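# Methods

## Scope and intent

`fedlung` is a deterministic, in-process simulator of a hierarchical
federated-learning pipeline for three-class lung-nodule classification. It
models the *computational* structure of such a federation — data sharding,
local training, client scoring, thresholded admission, two-stage
aggregation — not its systems aspects (no networking, RPC, encryption,
differential privacy, or asynchrony). All data are synthetic; nothing in
this package is suitable for clinical inference.

## Synthetic cohort

Each case is a 64×64 grayscale slice with nominal 1.25 mm slice thickness
carried as metadata. Background parenchyma is a truncated Gaussian
(mean 0.2, sd 0.05, clipped to [0, 0.40]). The RoI foreground threshold is
fixed at 0.45 — five background standard deviations above the background
mean — and the truncation guarantees that a *normal* slice (background
only) has an exactly empty RoI, so the all-zero feature vector for the
normal class is a structural property, not a probabilistic one. An
unbounded Gaussian would let roughly one normal slice per thousand sprout
a single-pixel "lesion".

Lesion classes:

| parameter | benign | malignant |
|---|---|---|
| radius r₀ (px) | U(3, 6) | U(5, 9) |
| core intensity | 0.6 | 0.8 |
| spiculation amplitude a | 0 | 0.35 |
| boundary harmonics k | — | {3, 5, 7} |
| edge blur (Gaussian sd, px) | 1 | 1 |

The malignant boundary is `r(θ) = r₀(1 + a·Σₖ sin(kθ + φₖ))` with random
phases, clipped below at 0.15·r₀ so the radius never collapses. Lesion
centers are placed uniformly with a margin of the worst-case lesion extent
plus 2 px, so the RoI never touches the border; parameter sets whose
worst-case lesion cannot fit are rejected. These defaults produce classes
that are cleanly separable in the extracted features at cohort sizes of a
few hundred — deliberately: the simulator's questions are about the
*federation* (aggregation identities, thresholding behavior, scaling), and
an easy classification task keeps those answers uncontaminated by
classifier noise. Consequences of the synthetic design that real CT data
would not share: perfect labels, a single lesion per slice, no anatomy or
imaging artifacts, and class-conditional feature distributions far better
separated than radiological reality. Passing tests therefore validate the
pipeline's mechanics and invariants, not clinical accuracy.

## Feature extraction (Pa ⊕ Pd)

The RoI is the largest 8-connected component of pixels strictly above the
threshold; an empty RoI yields the all-zero 8-vector. The feature order is
fixed: density, mass, orientation, weight | pixel_ratio, growth_pattern,
pixel_intensity, expansion_density. The `⊕` joining the physical and
digital groups is realized as plain concatenation.

Numerical choices:

- **Perimeter** for the growth-pattern (compactness) feature uses the
  Crofton formula with four directions, which is close to unbiased on
  rasterized disks (compactness ≈ 0.95–1.2 for radii 3–6 px), where a naive
  pixel-edge count overestimates by ~60%. Compactness of a non-empty RoI is
  floored at 1.0, its analytic lower bound, since rasterization at small
  radii can dip a few percent below it.
- **Orientation** is the principal-axis angle from the binary mask's
  second central moments, in (−π/2, π/2], measured against the x-axis with
  the y-axis pointing up. When the moment tensor is (near-)isotropic —
  disks, squares at any rotation — the principal axis is undefined and the
  orientation is defined to be 0. Note a square rotated by 45° stays
  isotropic; only genuinely elongated shapes have a meaningful angle.
- **Expansion density** is the mean absolute radial directional derivative
  of intensity over a ~2 px band around the RoI boundary (dilation minus
  erosion), with the radial direction taken from the RoI centroid.

## Cohort bookkeeping

Class counts use largest-remainder rounding with ties broken in label
order (normal, benign, malignant). The train/test split is stratified; the
per-class train count is `round_half_up(f·n_c)` clamped to `[1, n_c−1]` so
both sides keep every class (an unclamped round can empty the test side of
a small class). Each case's pixels derive from a dedicated random stream
keyed by (cohort seed, case index), so cohorts are reproducible bit for
bit and insensitive to generation order.

## Federation topology and sharding

Clients are assigned to routing servers round-robin (router k gets clients
{i : i mod R = k}); the default router count is ⌈√n⌉. Two sharding schemes:
IID (per-class seeded shuffle dealt round-robin) and label skew (each
class's cases divided across clients by proportions drawn from a symmetric
Dirichlet(α), smaller α ⇒ stronger skew). Both always produce a set
partition; an empty shard is repaired by taking one case from the largest
shard. IID is the default — the scaling experiment varies only the node
count, and IID is the minimal assumption for it.

## Local model and training

A multilayer perceptron on the 8-dim feature vector (one hidden layer of
16 rectifier units, softmax head, 195 parameters) — the features, not raw
pixels, are the recognition interface, and the flat parameter vector is the
unit of federation. Weights initialize from U(−1/√fan_in, 1/√fan_in),
biases zero. Training is plain mini-batch gradient descent on mean softmax
cross-entropy with optional L2 on the weights; no momentum or adaptive
state, so client updates are exactly reproducible and trivially averageable.
Default schedule: 5 local epochs per round, learning rate 0.1, batch 16,
L2 1e-4. Shards smaller than one batch train full-batch. Feature
standardization (per-feature mean/sd) is fitted once on the pooled client
training data and broadcast — a mild, documented deviation from strict
data locality that avoids per-client scale drift.

## DNT and aggregation

Each round, every client model is scored on a fixed calibration set: a
stratified 20% carve-out of the training split held at the central server
(the carve-out is excluded from all client shards and from the centralized
arm, so the two arms train on identical data). `v_pa` is the calibration
accuracy with the digital coordinates masked to zero *after*
standardization (i.e. replaced by the training mean), `v_pd` the converse,
and `v` their mean. Scores accumulate in the append-only validation matrix
R (rows = rounds, columns = clients; a non-participating client is absent,
not zero).

Admission: `off` admits all; `absolute` admits `v ≥ τ` (inclusive);
`robust` admits `v ≥ median(v) − z·MAD(v)` with the unscaled MAD, which
collapses to `v ≥ median` when MAD = 0. An empty admitted set falls back to
the single best-scoring client (earliest id on ties) and flags the round —
keep-best rather than keep-previous-global, so progress is guaranteed while
the anomaly stays visible in the round log.

Aggregation is shard-size-weighted averaging of admitted clients within
each router, then averaging of router aggregates weighted by admitted
shard-size sums; routers with no admitted clients are skipped. With full
admission this equals the flat weighted mean to floating-point accuracy
(associativity of weighted means), and the test suite asserts it at 1e-10
on random topologies. A single-input average returns an exact copy, which
makes the one-client federation bit-identical to centralized training with
the same seeds.

## Evaluation

Accuracy is trace/total of the 3×3 confusion matrix (rows = truth).
Sensitivity and specificity are computed one-vs-rest per class and
macro-averaged; a class with a zero denominator is flagged and excluded
from the macro mean. Multi-class specificity has no unique definition; the
one-vs-rest macro is this package's choice and is pinned by an exhaustive
brute-force cross-check over all 3×3 matrices with cells in {0, 1, 2}.

The shipped fixtures transcribe the published centralized and
decentralized confusion matrices verbatim. Two caveats are recorded rather
than repaired: (1) the decentralized *testing* table's printed column
total for the normal class (19) contradicts its own cells (16+12+6 = 34);
row totals and grand totals are consistent, so fixture validation checks
those and carries the misprint visibly. (2) The accuracies implied by the
printed cells (52/90 and 29/65 for the testing tables) are far from the
headline percentages reported with them (89.63% / 94.31%); the package
reports what the cells imply and does not tune anything toward the
headlines, which were produced on external CT data with an unspecified
model and are not reproducible from the published numbers.

## Experiment harnesses and problem sizes

The comparison harness trains both arms on one cohort, one split, one
initialization, and reports paired metrics on the shared test split. The
default study cohort is 300 cases in equal thirds with a 60/40
train/test split — large enough that shards stay trainable at 5 clients
and results are stable, small enough to iterate comfortably. The
node-scaling harness runs counts {5, 10, 20, 40, 80, 160} with the cohort
scaled to 12 cases per client (federating a fixed 50-case cohort across
160 clients would leave sub-case shards) and 5 rounds of 20 local epochs
per count; every run is reproducible from its seed set.

## Configuration and seeds

Five named seeds (cohort, split, partition, init, train) govern all
randomness; a single master seed derives all five via a seed sequence.
Per-round, per-client training streams are keyed by (train seed, round,
client), so adding a client never perturbs another client's trajectory.
YAML configs reject unknown keys by name, round-trip losslessly, and are
copied into every artifact directory alongside a run log carrying the
round index, admitted set, and aggregate norm.

## Known limitations

- The classifier operates on 8 engineered features, not pixels; there is
  no CNN path and no claim about image-level learning capacity.
- Synthetic separability means ceiling accuracy is the expected outcome of
  the default study; the interesting quantities are the identities, the
  admission behavior, and the scaling mechanics.
- DNT filters whole clients, the only reading with operational content
  here; per-feature or per-record thresholding is not modeled.
- The empty-admission fallback trusts the calibration set; a corrupted
  calibration set would mislead both scoring and fallback.
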
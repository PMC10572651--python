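# fedlung

A desk-scale simulator of an ensemble **federated-learning (FL) pipeline for
three-class lung-nodule classification** (normal / benign / malignant), built
for method study and teaching rather than clinical use. It reproduces, on
fully synthetic data, the structure of a hierarchical hospital federation:
CT-like slices are held by clients, each client trains a local neural network,
a routing layer aggregates client models, and a central server combines
router aggregates — with a **Distributed Network Thresholding (DNT)** step
that scores every client model on a held-out calibration set and excludes
low-scoring (e.g. corrupted or mislabeled) contributions from the round's
average.

## The model

Each synthetic slice is a 64×64 grayscale image. Its Region of Interest
(RoI) — the largest connected component above a fixed foreground threshold —
yields an 8-dimensional feature vector `Pa ⊕ Pd`:

- **Pa (physical)**: density (mean RoI intensity), mass (density × area),
  orientation (principal-axis angle), weight (area fraction × density);
- **Pd (digital)**: pixel ratio (RoI area / image area), growth pattern
  (boundary irregularity `P²/4πA`), pixel intensity (max in RoI), expansion
  density (mean |radial gradient| at the RoI boundary).

Normal slices have no RoI (all-zero features), benign slices one smooth
disk-like nodule, malignant slices a larger, brighter nodule with a
spiculated boundary `r(θ) = r₀(1 + a·Σₖ sin(kθ + φₖ))`.

Each client trains a small MLP (8 → 16 → 3, softmax) by seeded mini-batch
gradient descent. Aggregation is federated averaging with shard-size
weights, performed in two stages (clients → router, routers → central);
with all clients admitted the two-stage mean equals the flat weighted mean
exactly. DNT admits clients whose combined validation score
`v = (v_Pa + v_Pd)/2` passes an absolute threshold `v ≥ τ` or a robust band
`v ≥ median(v) − z·MAD(v)`.

The package also ships the published 3×3 confusion matrices for the
centralized and decentralized arms as fixtures, plus a metric engine
(accuracy, one-vs-rest macro sensitivity/specificity). Recomputing the
metrics from the printed cells gives 52/90 ≈ 57.8% test accuracy for the
decentralized arm and 29/65 ≈ 44.6% for the centralized arm, which does not
match the headline percentages reported alongside those tables; the
fixtures keep the printed cells verbatim and the discrepancy is documented,
not corrected (see `docs/methods.md`).

## Worked example

```python
from fedlung import generate_cohort, compare_centralized_decentralized
from fedlung.model import TrainingConfig

cohort = generate_cohort(300, seed=42)          # 100 cases per class
res = compare_centralized_decentralized(
    cohort, n_clients=5, rounds=30,
    cfg=TrainingConfig(epochs=5, learning_rate=0.1, batch_size=16, l2=1e-4),
    split_seed=1, partition_seed=2, init_seed=3,
)
print(f"centralized   accuracy: {res.centralized_report.accuracy:.4f}")
print(f"decentralized accuracy: {res.decentralized_report.accuracy:.4f}")
```

prints

```
centralized   accuracy: 1.0000
decentralized accuracy: 1.0000
```

i.e. on this synthetic cohort (whose classes are separable in the Pa/Pd
features by construction) both the pooled-data model and the 5-client
federated model classify the 120-case held-out test split perfectly, so the
federation costs no accuracy here. The same experiment is available from
the shell:

```sh
fedlung compare --out runs/compare          # the comparison above
fedlung run --out runs/fed --policy robust --z 2 --seed 1
fedlung scale --out runs/scale --counts 5,10,20,40,80,160
fedlung metrics --table T2_test             # published-fixture report
```

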
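# fedprune

A desk-scale simulator for **dual-ended personalized federated learning**
with structured filter pruning and lightweight CNN backbones, developed for
day-age classification of chickens (1–100 days) from images collected by
heterogeneous edge devices in rearing houses.  Real deployments of this kind
face three coupled problems: the data are heavily imbalanced and partly
missing by age; the devices differ wildly in compute and memory; and no
single device sees enough data to train a good model alone.  `fedprune`
implements and tests, end to end, a framework that addresses all three —
entirely in NumPy, on synthetic imagery, on one CPU.

## What it implements

**Client side (data-directed pruning).**  Each client learns per-filter
importance on its *local* shard by training multiplicative gates `g`
(initialized at 1) with loss `CE + λ‖g‖₁` and the backbone frozen; it then
prunes the global model to its resource budget, retaining per channel group
the `⌈(1−r)·F⌉` filters of highest importance, where the pruning rate `r` is
the smallest grid rate whose analytic parameter/MAC cost fits the budget.

**Server side (scaling-based aggregation + tuning).**  Submodel updates are
averaged coordinate-wise over the clients that retain each coordinate, with
weights

```
w_k = n_k · (1 + r_k)
```

(`n_k` local sample count, `r_k` pruning rate) — exactly sample-weighted
FedAvg when nobody prunes.  The server then computes pairwise client
similarity (cosine of L2-normalized importance vectors), groups clients by
single linkage at threshold τ, and re-selects each group member's retained
filters from the group's shared importance ranking, so similar clients get
nested submodels and dissimilar clients stay individualized.

**Lightweighting.**  Four small backbone families (`alexnet_s`, `vgg_s`,
`googlenet_s`, `resnet_s`) and a rewriter that (a) factorizes every Dk×Dk
conv into depthwise + pointwise — MAC ratio `1/N + 1/Dk²`, an 8–9×
reduction for 3×3 kernels — (b) turns residual blocks into inverted
residuals with linear bottlenecks, and (c) moves the feature-generation
layer after global average pooling (1×1 instead of 7×7 resolution).

**Synthetic data.**  A generator producing labelled images whose class
structure matches the emulated dataset (78 present day-age classes, counts
from ~250 to ~3176, whole missing day spans), plus rebalancing
augmentations (geometric, color, SamplePairing/SMOTE-style mixing), a
stratified 7:3 split, and ratio-based non-IID client partitioning.

See `docs/methods.md` for the model, its assumptions, and every numerical
choice.

## Worked example

Train a 5-client federation of lightened `alexnet_s` models on the synthetic
10-class benchmark (2,000 images, stratified 7:3), then inspect the run:

```sh
$ cat > run.json <<'CFG'
{"clients": 5, "seed_data": 0, "seed_model": 1, "seed_train": 2}
CFG
$ fedprune train --config run.json --out runs/k5
final accuracy 0.9850 precision 0.9852 recall 0.9850
```

Per-round test accuracy of the aggregated global model is in
`runs/k5/logs.jsonl` (one JSON object per communication round, including
each client's pruning rate and local loss and the 5×5 client-similarity
matrix), and `runs/k5/resources.json` reports the analytic cost of what was
trained and shipped:

```json
{
  "model": "alexnet_s_light",
  "params": 3947,
  "macs": 197248,
  "upload_bytes_per_round": 78940,
  "original_params": 9298,
  "original_macs": 1237632,
  "param_ratio": 0.4245,
  "mac_ratio": 0.1594
}
```

i.e. lightweighting cut multiply-accumulates per image by ~6× and more than
halved the parameters, and five clients upload ~79 kB of parameters per
round.
The per-layer breakdown comes from `fedprune cost-report --model alexnet_s
--lighten`.  A 9×-class imbalanced dataset in the emulated distribution's
shape (scaled down) is written by `fedprune generate-data`, and `fedprune
report` collates many runs into one CSV.

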
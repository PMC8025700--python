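# patternnet

Semantic segmentation of plant 3D point clouds into **ear** and **non-ear**
points, with downstream wheat-ear phenotyping (ear count, ear length,
relative ear length), built around a pattern-based deep network that
operates directly on unordered point sets.

Photogrammetric reconstructions of pot-grown wheat are irregular point
clouds: no grid, arbitrary point order, varying density, noise and
outliers.  The network here segments such clouds point-wise while staying
invariant to point order and robust to rigid transforms and resolution
changes, and the phenotyping stage turns the segmentation into the
biological quantities a breeder cares about: how many ears a plant carries
and how long they are relative to plant height (a drought-sensitive
trait).

## Method

Given a cloud `P = {p_1..p_M}` with labels `γ_i ∈ {1..N}` (here `N = 2`),
the network:

1. **Decomposes** `P` into `L` disjoint random subsets `P{l}` with
   `P{l} ∩ P{k} = ∅` and `∪ P{l} = P` — exchangeable subsamples whose
   overall structure matches the full cloud, so one shared weight set
   serves every level.
2. **Searches patterns**: inside each subset, each query point's K nearest
   neighbors (recomputed in the current feature space before every block —
   dynamic links) are expanded into a `K × 2C` edge-feature table
   `(f_q, f_i − f_q)` (width 6 on raw coordinates).
3. **Learns patterns** with four consecutive blocks of two 1×1
   convolutions + batch norm + leaky-ReLU, max-pooled over the K
   neighbors (a symmetric function — this is what buys permutation
   invariance).  Concatenating the four block outputs gives a 128-long
   feature per point.
4. **Links levels**: max-pooling per subset gives per-level descriptors
   `ψ_l` (columns of `Ψ`); pooling over all points and one dense layer
   gives the global descriptor `φ`.  Assuming `φ = Ψω`, the coefficients
   `ω = Ψ⁺φ` come from the Moore–Penrose pseudo-inverse (SVD), and the
   spread `σ(ω)` is added to the loss with weight `λ = 10 000` so every
   level learns to tell the same story.
5. **Decodes** `(per-point feature ⊕ ψ_l ⊕ φ)` through dense layers
   {256, 256, N} (dropout 2/3 on all but the last) into per-point logits.

The segmentation loss is a weighted cross-entropy
`−(1/M) Σ_i Σ_k Ω_k y_ik log p_ik + λ σ(ω)` with dynamic class weights
`Ω_k = |C_k − n_k/M|` (`C_ear = 1.0`, `C_non-ear = 0.95`) that up-weight
the minority ear class.  Training uses Adam (lr 0.001 → 0.0001,
exponential decay), batch size 10, and rotation/scale/translation
augmentation.

Ears are then extracted from the predicted labels as single-linkage
connected components at a density-adaptive radius, counted, and measured
along their first principal axis; metrics include per-class IoU, mIoU,
mean accuracy, RRMSE of counts and Pearson R².

Everything — including the forward pass, backpropagation and Adam — is
implemented in NumPy; no GPU or deep-learning framework is required at
these problem sizes.

## Worked example

There is no public labeled wheat-cloud corpus bundled here; the
`synthetic_plants` module generates labeled wheat-like plants (stem,
leaves, tillers, 0–8 ellipsoidal ears, noise and outliers) with exact
ground truth:

```python
from patternnet import (PlantParams, generate_plant, normalize, phenotype)

cloud, truth = generate_plant(PlantParams(n_points=2048, n_ears=3, seed=7))
norm, record = normalize(cloud)
rec = phenotype(norm, norm.labels, record=record)
print(f"true ears: {truth.ear_count}   predicted ears: {rec.ear_count}")
print(f"plant height: {rec.plant_height:.2f} units")
print(f"ear lengths: {[round(l, 2) for l in rec.ear_lengths]}")
print(f"relative ear length: {rec.relative_ear_length:.3f}")
```

prints

```
true ears: 3   predicted ears: 3
plant height: 13.04 units
ear lengths: [1.85, 2.28, 2.02]
relative ear length: 0.157
```

i.e. the three generated ears are recovered exactly; their lengths are the
extent of each cluster along its principal axis in the plant's original
length units, and mean ear length is ~16 % of plant height.

The same pipeline is available from the shell:

```sh
patternnet generate --n-plants 50 --seed 1 --out data/
patternnet train --train-dir data/ --val-dir data/ --epochs 30 \
    --m-points 512 --seed 1 --out model/
patternnet predict --checkpoint model/checkpoint.npz --in-dir data/ \
    --m-points 512 --out pred/
patternnet evaluate --truth-dir data/ --pred-dir pred/ --out eval/
patternnet phenotype --pred-dir pred/ --out traits/
```

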
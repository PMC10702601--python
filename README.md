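# canospec

**3-D forest-stand NIR reconstruction at point-cloud level.**

UAV LiDAR gives a forest stand's precise 3-D structure but almost no
spectral information; a UAV multispectral camera gives rich band values but
only as a flat, top-down raster. `canospec` fuses the two at the level of
individual points and then *inverts* the fused spectral signal back into
three dimensions, so that every point of the cloud — including points the
camera never saw directly — carries a predicted near-infrared (NIR) value.
It is aimed at forest remote-sensing researchers who want per-point
spectral products (e.g. for canopy vigor mapping) from standard
LiDAR + orthomosaic surveys of small plots.

## Method

The pipeline has four stages:

1. **Visibility filtering (hidden point removal).** A nadir camera only
   images the outer surface of the stand, so before fusion the cloud is
   filtered to the points visible from the simulated flight-grid
   viewpoints. Each point `p` (relative to a viewpoint `C`) is reflected
   through a sphere of radius `R`:

   `p̂ = p + 2 (R − ‖p‖) p / ‖p‖`,

   and the points whose images lie on the convex hull of `{p̂} ∪ {C}` are
   kept; `R = 10^γ · max‖p − C‖`. The visible set is the union over all
   viewpoints.

2. **Spectral fusion.** Each visible point is located in the multispectral
   image. For orthomosaics this is a direct planimetric `(X, Y) → pixel`
   lookup; for single frames the full collinearity equations are used,

   `x = −f (a₁ΔX + b₁ΔY + c₁ΔZ) / (a₃ΔX + b₃ΔY + c₃ΔZ)`,
   `y = −f (a₂ΔX + b₂ΔY + c₂ΔZ) / (a₃ΔX + b₃ΔY + c₃ΔZ)`,

   with `Δ· = P − S` and `a₁..c₃` the ω-φ-κ rotation entries. The sampled
   NIR (nearest-neighbor by default) is attached to the point, giving the
   7-attribute record `(X, Y, Z, R, G, B, NIR)`.

3. **Feature enhancement.** An isolation forest removes anomalous fused
   records — a record's anomaly score is `s = 2^(−E[h]/c(ψ))` where `h` is
   its average isolation path length and `c(ψ)` the binary-search-tree
   normalizer. The NIR axis is then quantized by 1-D K-means, with K chosen
   at the knee of the SSE(k) curve, and each point receives a pseudo-label
   `1..K` in ascending NIR order. Coordinates are z-scored, colors scaled
   to [0, 1], and the set is split 8:1:1 into train/test/validation.

4. **Segmentation and inversion.** A pointwise shared-MLP network (per-point
   MLP → symmetric max-pooled global feature → per-point classifier; order
   invariant by construction) is trained to predict the pseudo-label from
   `(x, y, z, r, g, b)` — NIR prediction cast as a part-segmentation task.
   Decoding a predicted label back to its cluster center reconstructs the
   3-D NIR field, which is evaluated against the truth with overall
   accuracy `oAcc = Σpᵢᵢ / Σpᵢⱼ`, mean intersection-over-union
   `mIoU = mean_i [ pᵢᵢ / (Σⱼpᵢⱼ + Σⱼpⱼᵢ − pᵢᵢ) ]`, and per-class NIR
   frequency-distribution curves (peak positions, matched peak gaps,
   medians).

Because real survey data is large and not generally available, the package
ships a first-class **synthetic stand simulator**: 20 m × 20 m plots with
conical tree crowns, bare land and grass patches, class point counts
proportioned like real survey plots, a canopy NIR field that decays
linearly with distance from each tree apex, and an orthoimage renderer
(per-cell max-Z winner) plus an 80 m flight grid — so every stage, and the
whole loop, is testable end to end.

## Worked example

```python
import canospec as cs

results = cs.run_all(None, seed=42, out_dir="runs/example")
print(f"points simulated : {results['n_points']}")
print(f"visible after HPR: {results['n_visible']}")
print(f"outliers removed : {results['n_outliers_removed']}")
print(f"NIR clusters (K) : {results['k_selected']['all']}")
print(f"held-out oAcc    : {results['holdout_oacc']:.3f}")
print(f"held-out mIoU    : {results['holdout_miou']:.3f}")
for cls, entry in results["reconstruction"].items():
    print(f"{cls:5s} peak gap {entry['max_peak_diff']:.3f} "
          f"(bin width {entry['bin_width']:.3f}), "
          f"median true/pred {entry['median_true']:.2f}/{entry['median_pred']:.2f}")
```

prints

```
points simulated : 26759
visible after HPR: 26361
outliers removed : 1318
NIR clusters (K) : 4
held-out oAcc    : 0.889
held-out mIoU    : 0.764
tree  peak gap 0.787 (bin width 0.037), median true/pred 10.63/10.53
land  peak gap 0.052 (bin width 0.052), median true/pred 7.96/7.96
grass peak gap 0.045 (bin width 0.045), median true/pred 12.28/11.89
```

Reading this: of the ~26.8k simulated points, HPR keeps the ~26.4k that a
nadir flight grid can see; after isolation-forest cleaning, the NIR axis
quantizes into K = 4 clusters whose centers align with the land, canopy
and (two) grass spectral modes. The segmentation model recovers the
correct pseudo-label for 88.9% of held-out points from geometry and color
alone. The reconstructed NIR frequency curves land their peaks within
about one histogram bin of the true peaks for land and grass; for the
canopy class a small fraction of mispredicted points forms a secondary
spurious peak (the 0.787 entry) — the same multi-peak overestimation
pattern seen in field comparisons — while the main canopy peak matches
exactly. Medians agree to within a fraction of one inter-cluster gap.

The same pipeline is scriptable from the shell:

```sh
canospec run-all --seed 42 --out runs/example
canospec simulate --seed 7 --out scene.las --ortho ortho.tif
canospec hpr --in scene.las --out visible.las
canospec fuse --points visible.las --ortho ortho.tif --out fused.las
canospec enhance --in fused.las --k auto --out labeled.las --codebook codebook.json
canospec train --train labeled.las --out model.npz
canospec predict --model model.npz --in scene.las --out pred.las
canospec evaluate --true scene.las --pred pred.las --codebook codebook.json --out eval.json
```

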
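# wristseg

Edge-based lesion segmentation for wrist-MRI-like grayscale images:
a from-scratch **Canny** detector, a **particle-swarm-tuned kernel SVM**
that classifies edge pixels as lesion / non-lesion, and the full
segmentation-quality metric battery (PSNR, MSE, Pratt FOM, SSIM, edge
continuity/credibility, Acc/Sen/Spe/Dice) — exercised end to end on a
synthetic wrist-phantom generator with pixel-exact ground truth.

Wrist MRI is hard to segment automatically: the radius, scaphoid and
lunate have nearly identical gray levels, cartilage is a thin crescent,
and acquisitions carry noise and smooth intensity inhomogeneity (bias
field). `wristseg` targets exactly this regime. It is aimed at medical
image-analysis researchers who want a fully testable, dependency-light
reference pipeline — not a clinically validated tool.

## Method

1. **Canny edge detection.** The image is smoothed with an isotropic 2-D
   Gaussian G(x, y) = exp(−(x²+y²)/2σ²)/(2πσ²); the gradient
   (∇ₓP, ∇ᵧP) is taken by central differences, giving magnitude
   D = √(∇ₓP² + ∇ᵧP²) and direction θ = atan2(∇ᵧP, ∇ₓP); non-maximum
   suppression keeps strict directional maxima (4-sector quantization);
   double-threshold hysteresis with low/high thresholds t_l, t_h = ratio·t_l
   keeps strong responses and any weak response 8-connected to one.
2. **PSO hyperparameter search.** A global-best particle swarm with the
   bare update V ← wV + c₁r₁(pbest−H) + c₂r₂(gbest−H), H ← H + V
   minimizes (1 − k-fold CV accuracy) over log₁₀C ∈ [−2, 4],
   log₁₀γ ∈ [−4, 2].
3. **Kernel SVM.** The soft-margin dual
   max Σκᵢ − ½ΣΣ κᵢκ_s gᵢg_s K(aᵢ, a_s), s.t. Σκᵢgᵢ = 0, 0 ≤ κᵢ ≤ C,
   is solved by an internal SMO (maximal-violating-pair) solver; the
   decision function f(a) = sgn(Σ κᵢ*gᵢ K(aᵢ, a) + b) with an RBF kernel
   labels each edge pixel from a 7-component local descriptor
   (window mean/std, gradient magnitude, cos θ, sin θ, normalized
   row/col). Positive edge pixels are closed (3×3) and hole-filled into
   the lesion mask.

## Worked example

Train on three synthetic wrist phantoms, segment a held-out fourth:

```python
from wristseg import (PipelineConfig, default_wrist_spec, generate_phantom,
                      confusion, diagnostic_scores, edge_credibility,
                      segment_image)
from wristseg.pipeline import train_on_phantoms

config = PipelineConfig(seed=0)
train = [generate_phantom(default_wrist_spec(seed=s)) for s in (0, 1, 2)]
test = generate_phantom(default_wrist_spec(seed=3))

model, info = train_on_phantoms(train, config)
print(f"tuned C={info['C']:.3g}  gamma={info['gamma']:.3g}  cv_acc={info['cv_accuracy']:.3f}")

edges, lesion_edges, mask = segment_image(test.image, model, config)
print(f"edge pixels: {int(edges.sum())}   credibility vs truth: "
      f"{edge_credibility(edges, test.truth_edges):.3f}")
acc, sen, spe, dsc = diagnostic_scores(confusion(mask, test.lesion_mask))
print(f"lesion mask: Acc={acc:.4f}  Sen={sen:.4f}  Spe={spe:.4f}  Dice={dsc:.4f}")
```

Output:

```
tuned C=34.8  gamma=0.204  cv_acc=1.000
edge pixels: 648   credibility vs truth: 1.000
lesion mask: Acc=0.9981  Sen=1.0000  Spe=0.9981  Dice=0.9560
```

The swarm settles on (C, γ) with perfect cross-validated edge-pixel
accuracy; on the held-out phantom every detected edge pixel lies within
one pixel of a true boundary (credibility 1.0), and the reconstructed
lesion mask overlaps the true lesion with Dice 0.956.

The same pipeline is available from the shell:

```bash
wristseg simulate --size 128 --seed 0 --out-dir phantom/
wristseg detect --input phantom/image.png --ratio 1.8 --out edges.png
wristseg sweep --seed 0 --out sweep.csv          # th/tl ratio grid
wristseg benchmark --n 10 --seed 0 --out-dir bench/
```

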
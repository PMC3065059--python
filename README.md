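# calculoscope

Automated recognition of prostatic calculi (corpora amylacea) in H&E
histology micrographs.

Prostatic calculi are small glycoprotein concretions that sit inside the
lumina of prostatic glands and show a characteristic concentric,
"tree-ring" lamellar texture. Finding them matters to pathologists because
they identify prostate as the tissue of origin of a specimen. This package
implements a classical image-analysis pipeline that finds gland lumina,
isolates suspicious round/oval bodies inside them, and classifies each
body as calculus or non-calculus from its texture:

1. **Lumen extraction by local entropy.** For a gray image f(i,j) > 0 the
   sliding-window entropy is computed over each w x w neighborhood as

       H = -Σᵢⱼ pᵢⱼ log₂ pᵢⱼ,   pᵢⱼ = f(i,j) / Σᵢⱼ f(i,j).

   This is the entropy of the *normalized gray values* (not of the
   histogram): a perfectly homogeneous window attains the maximum
   log₂(w²), and textured stroma falls below it. Each RGB channel is
   transformed separately and the three entropy maps are composed
   (pixel-wise mean by default).
2. **Otsu thresholding.** The entropy image is cut at the threshold T
   maximizing the between-class variance
   g = ω₀(μ₀−μ)² + ω₁(μ₁−μ)², which separates the homogeneous
   (high-entropy) lumina from the stroma.
3. **Mathematical morphology.** Opening, closing, regional hole filling
   and small-object removal clean the lumen mask; a calculus inside a
   lumen is textured, leaves a hole in the entropy mask, and is restored
   by the filling step. A second Otsu pass on the gray values inside the
   lumina then segments the darker, lamellar calculus candidates.
4. **Texture features.** Each candidate region is quantized to L gray
   levels and described by gray-level co-occurrence matrices
   p(i,j | θ, d) at distance d = 1 in the directions θ = 0°, 45°, 90°,
   135°, plus the mean of the four as a fifth direction. Fourteen
   Haralick-style statistics per matrix (energy, contrast, correlation,
   entropy, variance, sum average, sum variance, homogeneity, difference
   variance, sum entropy, difference entropy, cluster shade, cluster
   prominence, maximal probability) give a 70-dimensional descriptor.
5. **PCA–SVM classification.** Features are z-scored, the correlation
   matrix is eigendecomposed, and the smallest number of components whose
   cumulative contribution rate reaches α = 0.98 feeds an RBF-kernel SVM.
   Performance is measured by ten repeats of 5-fold cross-validation,
   reporting accuracy, sensitivity and specificity from the accumulated
   TNS/FPS/FNS/TPS confusion counts.

Because no public image set exists for this problem, the package ships a
first-class synthetic phantom generator (textured stroma, bright
elliptical lumina, concentric-ring calculi, exact ground-truth masks) and
a labeled Gaussian feature-table generator, so every stage is testable
end to end.

## Worked example

```python
import numpy as np
from calculoscope import (
    PhantomConfig, generate_phantom, extract_lumina,
    segment_suspicious_regions, region_feature_vector,
    generate_feature_dataset, repeated_kfold_cv, summarize_runs,
)

# segmentation on a seeded phantom (5 lumina, 3 of them with calculi)
truth = generate_phantom(PhantomConfig(seed=7))
lumen_mask, lumina = extract_lumina(truth.image)
regions = segment_suspicious_regions(truth.image, lumen_mask)
print(f"lumina detected: {lumina.n_regions}")
print(f"suspicious regions: {len(regions)}")
vec = region_feature_vector(regions[0])
print(f"feature vector length: {vec.size}")

# classification on a 125-sample synthetic table (28 positive, 97 negative)
X, y = generate_feature_dataset(28, 97, n_features=70, separation=6.0, seed=1)
runs = repeated_kfold_cv(X, y, k=5, repeats=10, alpha=0.98, seed=1)
s = summarize_runs(runs)
print(f"mean test accuracy: {s['mean_test_accuracy']:.2f}%")
print(f"mean sensitivity:   {s['mean_sensitivity']:.2f}%")
print(f"mean specificity:   {s['mean_specificity']:.2f}%")
```

prints

```
lumina detected: 5
suspicious regions: 3
feature vector length: 70
mean test accuracy: 97.12%
mean sensitivity:   87.14%
mean specificity:   100.00%
```

All five lumina and all three seeded calculi are recovered; the
70-feature descriptor feeds the PCA–SVM, whose repeated cross-validation
accuracy on the well-separated synthetic classes is near the Bayes limit,
with sensitivity below specificity because positives are the minority
class (28 of 125).

A `calculoscope` console script exposes the same stages from the shell:

```sh
calculoscope simulate --out sim --seed 7
calculoscope segment  --image sim/phantom.png --out seg
calculoscope features --image sim/phantom.png --out features.csv
calculoscope crossval --features labeled.csv --folds 5 --repeats 10
calculoscope run      --images sim/phantom.png --out results
```

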
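# ssdmix

Hybrid generative–discriminative classification of images represented as
**bags of compositional feature vectors**: finite mixtures of
**shifted-scaled Dirichlet (SSD)** distributions learned by EM with
**Minimum Message Length (MML)** model selection, and three mixture-derived
SVM kernels — **Fisher**, **symmetrized Kullback–Leibler (SKK)** and
**Bhattacharyya (BK)** — for screening-style problems (e.g. normal vs
abnormal radiographs or retinal images) where descriptors live on the unit
simplex.

## The model

A composition `y ∈ S_D` (strictly positive, summing to 1) follows an SSD
distribution with shape `α ∈ R₊^D`, location `β ∈ S_D` and scale `b > 0`:

```
p(y | α, β, b) = Γ(α₊)/∏ᵢΓ(αᵢ) · b^{-(D-1)} · ∏ᵢ βᵢ^{-αᵢ/b} yᵢ^{αᵢ/b - 1}
                 / ( Σᵢ (yᵢ/βᵢ)^{1/b} )^{α₊},       α₊ = Σᵢ αᵢ .
```

`b = 1` recovers the scaled Dirichlet and, with uniform `β`, the Dirichlet
itself.  Data are modeled by K-component mixtures
`p(y|Θ) = Σₖ πₖ p(y|θₖ)` fitted by EM (K-means initialization, closed-form
weight updates, bounded quasi-Newton component updates with analytic
gradients).  K is chosen by minimizing the two-part message length

```
MML(Θ) = −log p(Θ) − L(Θ;Y) + ½ log|F(Θ)| + Np/2 + (Np/2)·log(1/12),
Np = K(2D+1) − 1 .
```

Classification injects the generative model into an SVM: a shared
background mixture yields Fisher scores `∇_Θ log p(bag|Θ)` (Fisher kernel),
while per-image mixtures are compared by Monte Carlo estimates of the
symmetrized KL divergence (`exp(−B·D_sym)`) or the Bhattacharyya affinity
(`∫√(p q)`), giving precomputed Gram matrices for a one-vs-all SVM with
stratified 10-fold cross-validation.

## Worked example

```python
import numpy as np
from ssdmix import (default_two_class_ground_truth, sample_mixture_bags,
                    ShiftedScaledDirichletMixture, select_k, cross_validate)

# synthetic two-class bags: 20 images/class, 50 descriptors/image, D = 3
gt = default_two_class_ground_truth(seed=0)
bags, labels = sample_mixture_bags(gt)

# fit a 2-component SSD mixture to the class-A descriptors
pooled = np.vstack([b.vectors for b in bags if labels[b.image_id] == "classA"])
est = ShiftedScaledDirichletMixture(n_components=2, random_state=0).fit(pooled)
print(est.weights_.round(3))   # [0.501 0.499]
print(est.alphas_.round(2))    # [[4.78 1.78 1.64]
                               #  [1.92 7.9  1.97]]

# MML choice of K on a subset of the descriptors
print(select_k(pooled[:600], range(1, 5), seed=0).best_k)   # 2

# 10-fold CV with the symmetrized-KL kernel SVM
cv = cross_validate(bags, labels, kernel_type="skk", seed=0, n_samples=2000)
print(f"ACC {cv.acc:.1f}%  DR {cv.dr:.1f}%  FPR {cv.fpr:.3f}  AUC {cv.auc:.3f}")
# ACC 100.0%  DR 100.0%  FPR 0.000  AUC 1.000
```

The recovered mixing weights (≈ ½, ½) and shapes (≈ (8,2,2) and (2,8,2) up
to the weak α–b coupling of the family) match the generating class-A model;
the CV report says the SKK-kernel SVM separates the two synthetic classes
perfectly.

A command-line interface mirrors the library
(`ssdmix simulate / featurize / fit / select-k / kernel / classify`).

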
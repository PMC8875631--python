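# topovote

Ensemble fusion for image segmentation masks by **topological voting** —
winner-takes-all and sliding-window variants of the Jaccard-medoid rule —
alongside the classical arithmetical (per-pixel) vote and a two-round
hybrid that uses topological scoring to reject outlier annotators.

Given n co-registered masks S₁,…,Sₙ of one image (binary "hard" masks,
or "soft" masks with per-pixel confidences in [0, 1], as produced by n
model folds or n human annotators), the methods are:

* **Arithmetical voting** — per-pixel majority for hard masks, or the
  per-pixel mean S̃ = (1/n) Σₖ S̃ₖ thresholded at 0.5 for soft masks; a
  weighted-average variant accepts per-annotator weights.
* **Topological voting** — compute each candidate's total Jaccard
  distance to the rest, dₖ = Σᵢ d_J(Sᵢ, Sₖ) with d_J = 1 − |A∩B|/|A∪B|,
  and return the minimizer **verbatim**: S_voted = S_ℓ, ℓ = argminₖ dₖ.
  The winner is the medoid of the ensemble under the Jaccard metric, so
  the output always has the shape regularity of an actual annotation.
  Soft masks are scored by the min-over-max Jaccard
  Σ min(U,V) / Σ max(U,V) after a piecewise-linear regularization that
  truncates confidences at 0.2 and 0.8.
* **Local topological voting** — the same winner-takes-all rule applied
  independently per pixel on the clipped square (2s+1)×(2s+1)
  neighborhood of that pixel; the local winner's center value is
  emitted.  The radius s interpolates between per-pixel majority (s = 0,
  n odd) and whole-image topological voting (s ≥ image size), bit-exactly.
* **Hybrid voting** — round one scores every candidate by its total
  Jaccard score Jₖ = Σᵢ J(Sᵢ, Sₖ) and excludes outliers (either keep
  Jₖ ≥ n/H for a threshold H > 1, or keep the top n_select); round two
  fuses the survivors arithmetically.

The package also contains a seeded synthetic generator of truth masks
(smooth blobs, rectangles, thin vessel trees) and annotator ensembles
with planted outliers, and the scalar/planar simulations that explain
*why* the medoid rule works: in 1D the estimator
Yₙ = argmin_{Sᵢ} Σⱼ (Sᵢ − Sⱼ)² is exactly the sample closest to the
sample mean and converges to θ at the √n rate like the mean itself,
while for structured samples Sᵢ = [xᵢ, f(xᵢ)] the mean drifts off the
curve y = f(x) (Jensen) but the medoid never does.

## Worked example

Build a 64×64 ensemble of 10 annotators of one blob-shaped truth mask,
3 of them grossly displaced outliers, then fuse and score it:

```bash
topovote synth --kind blob --n 10 --outliers 3 --seed 7 --out-dir masks
# wrote truth + 10 masks to masks (outliers at [1, 2, 6])

M=$(for f in masks/mask_*.png; do echo --masks $f; done)
topovote vote --method arith-hard  $M --out fused_arith.png
topovote vote --method topo-hard   $M --out fused_topo.png --report report.csv
topovote vote --method local-topo  $M --radius 5 --out fused_local.png
topovote vote --method hybrid --exclude threshold --H 2.0 $M --out fused_hybrid.png

for m in arith topo local hybrid; do
  topovote evaluate --pred fused_$m.png --truth masks/truth.png
done
```

which prints:

```
arith:   jaccard=0.767372 jaccard_distance=0.232628 binary_accuracy=0.962402
topo:    jaccard=0.732628 jaccard_distance=0.267372 binary_accuracy=0.956787
local:   jaccard=0.767722 jaccard_distance=0.232278 binary_accuracy=0.962402
hybrid:  jaccard=0.823263 jaccard_distance=0.176737 binary_accuracy=0.971436
```

The hybrid vote wins because round one sees the planted outliers'
low total Jaccard scores (`report.csv` shows Jₖ ≈ 3.1–3.4 for the
outliers against ≈ 5.0–6.0 for the good annotators, below the cutoff
n/H = 5) and drops them before the majority vote.  Note how the naive
binary accuracy barely separates the methods while the Jaccard score
does — accuracy is dominated by the background.

The same from Python:

```python
from topovote import (EnsembleSpec, make_ensemble, hybrid_vote,
                      ExclusionRule, jaccard_hard)
ensemble, truth, outliers = make_ensemble(
    EnsembleSpec(truth_kind="blob", n=10, n_outliers=3, seed=7))
report = hybrid_vote(ensemble, ExclusionRule.threshold(2.0))
print(sorted(set(range(10)) - set(report.survivors)) == list(outliers))  # True
print(round(jaccard_hard(report.fused, truth), 3))
```

The estimator simulations live under `topovote simulate`:

```bash
topovote simulate --dim 1 --dist normal --seed 3 --out conv.csv
topovote simulate --dim 2 --dist uniform --params 0 1 --f square \
    --replicates 500 --seed 3 --out curve.csv
```

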
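# Methods

## Setting and metric substrate

All methods operate on n ≥ 2 co-registered masks of one h×w image.  A
hard mask is S ∈ {0,1}^{h×w}; a soft mask S̃ ∈ [0,1]^{h×w} carries
per-pixel confidences such as sigmoid outputs.  Coordinates are
row-major and 0-based.  The metric substrate is the Jaccard (IoU)
score J(A,B) = |A∩B| / |A∪B| and its min-over-max generalization
J(U,V) = Σ min(U,V) / Σ max(U,V), which coincides with the set form on
binary inputs bit-exactly.  The Jaccard distance is d_J = 1 − J.

**Empty/empty convention.** J is undefined at 0/0; we set J = 1
(distance 0).  Two empty masks coincide, and — decisive for the design
— this convention makes radius-0 local topological voting agree with
per-pixel majority voting on empty regions, so the s = 0 limit below
is exact rather than approximate.

**Thresholding** uses ≥ on the upper branch (a pixel at exactly 0.5
becomes 1).  **Regularization** of soft masks truncates confidences at
0.2/0.8 with a linear middle ramp; we evaluate the ramp as (5v − 1)/3,
algebraically equal to 10(v − 0.2)/6 but exact in float64 at the
breakpoints and at v = 0.5, so regularization commutes with
thresholding away from 0.5 bit-exactly.  Regularization is a *scoring*
aid only: winners and fused outputs are always drawn from the original
masks.

## Voting methods

*Arithmetical*: per-pixel majority (hard) or mean-then-threshold
(soft).  Majority ties at even n go to 1, mirroring the ≥ threshold
branch.  The weighted variant computes Σ wₖSₖ / Σ wₖ; when no weights
are given we default to wₖ = Jₖ (total Jaccard score), one reasonable
reading of "better-agreeing annotators weigh more" — the choice of
weight law is genuinely open and the parameter accepts any
non-negative vector.

*Topological*: dₖ = Σᵢ d_J(Sᵢ, Sₖ) (the self term included; it is
zero), winner = argminₖ dₖ, ties to the lowest index, output verbatim.
Equivalently argmaxₖ Jₖ with Jₖ = n − dₖ.

*Local topological*: per pixel, the n masks restricted to the clipped
inclusive window [i−s, i+s]×[j−s, j+s] vote topologically and the
winner's center value is emitted.  Limits: s = 0 with n odd reproduces
hard majority voting; s ≥ max(h, w) reproduces global topological
voting — both bit-exact, and both verified as such in the tests.

*Hybrid*: round one excludes candidates with Jₖ < n/H (threshold
method; survivor count varies) or outside the top n_select (rank
method; count fixed), round two votes arithmetically among survivors.
If the threshold empties the field, the single top scorer is kept — a
vote must produce an output.  Keep-all reduces to arithmetical voting
and n_select = 1 to topological voting, bit-exactly.  With a radius,
exclusion and fusion are both per-pixel on windowed scores by default;
a flag switches to choosing survivors once from whole-mask scores
(the alternative reading of combining a radius with a threshold).
Soft ensembles are scored softly (with regularization) throughout.

## Numerical design for bit-exact equivalences

The limit equivalences above are claims about *computed* floats, so
both code paths must produce identical bit patterns:

* Hard-mask window scores use int64 summed-area tables for the AND/OR
  counts — exact integers, then one float division, identical to the
  naive per-window count.  Border windows use clipped-area sums;
  zero-padding would inflate union counts at the border.
* Soft-mask window scores precompute each pair's min/max images once
  and sum contiguous window copies, reproducing the reference's
  per-window `minimum`-then-`sum` operation order exactly.
* Total distances are accumulated in ascending candidate order in both
  the global and the windowed implementations, so exact ties remain
  exact ties and the lowest-index rule fires identically everywhere.
* All argmin/argmax tie-breaks are first-occurrence (lowest index).

The per-pixel soft path costs O(n²·N·s²) with Python-loop overhead; the
hard path is O(n²·N).  The naive reference implementation is kept as a
public function (`local_vote_reference`) and the tests compare the two
on hundreds of random ensembles across radii.

## Estimator simulations

1D: samples S₁..Sₙ i.i.d. with mean θ (normal(θ, σ) with σ the
standard deviation, or uniform(a, b) with θ = (a+b)/2).  The
arithmetical estimator is the sample mean Σₙ; the topological
estimator Yₙ minimizes Σⱼ (Sᵢ − Sⱼ)² over the samples.  For n ≤ 256
the totals are summed pairwise as written — this keeps exactly tied
totals (any two-sample input) exactly tied so the lowest-index rule is
meaningful; for larger n the O(n) expansion n·Sᵢ² − 2·Sᵢ·ΣSⱼ + ΣSⱼ² is
used.  The closest-to-the-mean identity (Yₙ = argmin |Sᵢ − Σₙ|) is
implemented separately and checked against the definition on 10⁴
random draws.  Convergence runs use n ∈ {10, 10², 10³, 10⁴} with 500
replicates per n — large enough that the monotone error decay and the
√n-rescaled error plateau are stable across seeds, small enough to run
in seconds.

2D: Sᵢ = [xᵢ, f(xᵢ)] with f ∈ {x², x³, 1/(1+x)} (the last only on
x ~ U(0,1), away from the pole).  The squared Euclidean distance is
the natural extension of the scalar (x−y)².  The average estimator
[mean x, mean f(x)] sits off the curve whenever f is non-affine
(Jensen); the topological estimator is a sample, hence always on the
curve.  Defaults: n = 200, 500 replicates.

## Synthetic ensembles

The generator emulates the regime the voting methods assume: most
annotators good, a minority grossly wrong, and it refuses specs with
n_outliers ≥ n/2 where voting is theoretically hopeless.

* **Truths**: `blob` (largest connected component of thresholded
  Gaussian-smoothed noise, σ = min(h,w)/8, 30% coverage quantile) for
  compact smooth objects; `rectangle` for bounding-box annotation;
  `vessel` (random 8-connected branching walks, 1–3 px wide) for thin
  structures.
* **Good annotators**: truth → integer translation (≤ 1 px default) →
  boundary jitter (one random dilation or erosion of radius ≤ 1
  default) → pixel dropout (rate 0.05 default).  Erosion backs off
  when it would remove over half the foreground: a 1-px vessel has no
  interior, and a "good" annotator never loses the object outright.
  Zero noise reproduces the truth bit-exactly.
* **Outliers**: `shift` (translation by 25–40% of the image side in a
  random direction), `spurious` (an unrelated truth draw), `empty`.

Defaults were chosen once to represent a plausibly sloppy but competent
annotator on a 64×64 image: with them, good blob annotators score
J > 0.5 against the truth in ≥ 95% of seeds while shift outliers score
below every good annotator, which is what makes the outlier-rejection
study meaningful rather than circular.  The generator produces masks
only — no image appearance — so tests show that the voting mathematics
behaves as claimed under this contamination model; they cannot show
how a particular trained segmentor ensemble is distributed around its
truth.  Thin-structure truths also expose a real phenomenon: vessel
Jaccard scores sit far below blob scores at identical noise because a
1-px misregistration halves the overlap of a 1-px-wide structure.

Soft ensembles are produced by Gaussian-blurring hard masks (default
σ = 1 px), giving boundary confidence ramps similar to sigmoid outputs.

## Known limitations

* Masks are single-class and 2D; no resizing or registration is
  performed (ensembles must share one shape).
* The Hausdorff distance, a natural alternative to Jaccard for the
  topological rule, is not implemented.
* The per-pixel soft local voter is loop-bound and intended for small
  to medium images; the hard path scales to full-size masks.
* The weighted-vote default weight law (wₖ ∝ Jₖ) is one admissible
  choice, not a canonical one.
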
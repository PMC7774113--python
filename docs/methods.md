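# Methods

## The agreement model

The package scores the spatial agreement between a model attribution
heatmap H ∈ R^(N×N) (nonnegative after channel reduction) and an expert
lesion annotation given as four binary masks HE, MA, SE, EX (masks may
overlap). Both are reduced to an S×S grid by summing over pixel blocks
of width d = N/S; cell (i, j) covers the half-open block
[i·d, (i+1)·d) × [j·d, (j+1)·d), 0-based and row-major. When N is not a
multiple of S, the trailing N mod S rows/columns are merged into the
last cell row/column — boundary cells are slightly larger, but no
annotated pixel is ever dropped. Rectangular images use independent
cell heights and widths. With S = N discretization is the identity;
total mass is always conserved to 1e-9 relative.

The expert discretization DE weights each lesion type's pixel count by
its inverse corpus frequency, w_t = max_count / count_t, so the most
frequent type has weight exactly 1 and all weights are ≥ 1. The
published IDRiD constants (1, 1.05, 5.77, 46.97 for HE, EX, SE, MA) are
kept verbatim as a preset and are deliberately never recomputed from
the rounded 47/44/8/1 percentages (whose exact ratios are 1.068, 5.875,
47): preset and rule are distinct code paths. A lesion type with zero
corpus pixels has no defined weight; `derive_weights` raises rather
than guessing.

Internally DE is computed by building the weighted pixel image
Σ_t w_t · mask_t first and block-summing once. This is algebraically
identical to summing per-lesion block sums but shares the exact
floating-point summation path of heatmap discretization, so a heatmap
equal to the weighted mask combination discretizes bit-identically to
DE and scores exactly 1 — without this, 1e-13 rounding differences can
reorder tied cells at the top-K boundary.

The score is

ECS(DE, DH) = |top_K(DE) ∩ top_K(DH)| / min(K, nnz(DE)).

Two conventions resolve cases the formula leaves open:

* **Positive-cell eligibility.** Zero-valued cells never enter a top-K
  set; a map with fewer than K positive cells contributes fewer than K
  cells. This makes a score of 0 attainable and meaningful on sparse
  maps instead of crediting accidental overlap of empty cells.
* **Deterministic ties.** Equal values are ordered by row-major index,
  so every score is reproducible; a seeded random tie-break is
  available for sensitivity analysis. An image with nnz(DE) = 0 has no
  defined score and is excluded from averages (annotated, DR-positive
  imagery is the intended domain).

Both the implementation (`lexsort` on (−value, index)) and an
independent brute-force enumeration exist; the test suite checks them
against each other on a thousand random instances.

ECS is invariant under any strictly monotone transform of heatmap
values — it compares rankings, not magnitudes — which is why methods
with wildly different output scales (gradients vs variance ensembles)
can be compared on one footing.

### Per-lesion scores and the random baseline

Per-lesion ECS discretizes a single mask with weight 1 and scores it
against the same DH; empty masks signal a skip. The random-importance
baseline draws i.i.d. uniform(0, 1) *cell* values — randomizing at
pixel level would give every cell the sum of ~d² i.i.d. values, nearly
constant across cells, which does not emulate a random importance
ranking. When all S² cells of DE are positive and K ≤ nnz, the overlap
is hypergeometric with mean K²/S², giving E[ECS] = K/S² · … = 0.15 at
S=10, K=15; the Monte-Carlo mean at 10,000 draws reproduces this within
three standard errors.

## Attribution methods

The six methods operate on a `ScoreFunction` — any scalar score with a
gradient provider (analytic, or central finite differences at 1e-5
step, which agree to 1e-4 relative on smooth scorers). Integrated
Gradients uses the **midpoint** quadrature with 64 steps by default:
the cited construction permits any quadrature, and the midpoint rule is
exact for linear and quadratic scores and O(steps⁻²) otherwise, so the
completeness axiom Σ attributions = f(x) − f(baseline) holds to
quadrature accuracy (≤ 1e-3 relative at 256 steps on the test scorers,
where a right-endpoint sum would leave ~4e-3 error). SmoothGrad
defaults are σ = 0.15 · (max x − min x) and 25 samples — conventional
values, since the original study does not report its settings. σ = 0
short-circuits to the plain gradient bit-exactly. VarGrad uses the
population (1/n) variance computed from the same sample stream as the
other ensembles, so vargrad = smoothgrad_squared − smoothgrad² holds
exactly on a shared seed. Channel reduction for three-channel maps
defaults to abs-max (|·| per channel, then max): gradient maps are
signed and the literal per-channel max would discard strong negative
evidence; the literal "max" mode (negatives clipped after the max) is
retained behind a flag.

## The synthetic corpus

The generator emulates the *structure* of IDRiD-style annotation data,
not fundus appearance. Defaults (chosen once, from the target pixel
profile): 128×128 images; per image 3–5 HE ellipses with semi-axes 5–9
px, 4–6 EX ellipses (4–8 px), 1–3 SE ellipses (3–5 px), 3–7 MA dots of
1–4 px. Expected pixel mass is ≈ 616 : 565 : 100 : 12.5 per image
(≈ 49 : 45 : 8 : 1), and over a 50-image corpus the realized fractions
land within a few percent relative of the 47/44/8/1 HE/EX/SE/MA
profile (the contract allows ±20%). Severity grades are sampled from
(0, 1/54, 18/54, 16/54, 19/54) for grades 0–4, matching the grade
composition of the 54-image tuning split this corpus emulates. An
optional cluster disk confines lesion centers to a region, emulating
the regional concentration of DR lesions; it is what makes a single
disk-shaped scorer a meaningful stand-in for a model that attends to
the lesion area.

Heatmaps with a controlled overlap target q are constructed in cell
space: round(q·K) cells drawn from the expert top-K and K − round(q·K)
from outside it receive distinct masses in (1, 2]; background cells get
uniform(0, 0.8); values are painted cell-constant and divided by cell
area so the discretized mass is exact. The resulting ECS equals
round(q·K)/K exactly. Because the painted/background margin (0.2)
exceeds the largest possible noise differential at the 10%-of-cell-mass
noise level (0.15 one-sided), the constructed score is provably
unchanged under that noise — the noisy-recovery check passes with zero
drift, which verifies ranking robustness rather than statistical
averaging.

What passing tests on this corpus do **not** show: that real heatmaps
of trained networks reach any particular ECS on real annotations.
Fixture lesions are clean ellipses, masks never carry annotation noise,
and constructed heatmaps have no spatial autocorrelation; the tests
validate the metric, the estimators and the pipeline, not any model.

## Aggregation

Dataset means are arithmetic over images. Confidence intervals use the
nonparametric percentile bootstrap over images (10,000 resamples,
seeded); interval width shrinks as ~1/√n and empirical coverage of the
true mean at n = 200 uniform scores exceeds 90% in the checks. Severity
strata with a single image report the mean without a CI. The
sensitivity sweep recomputes every score for each (S, K) combination
and reports method rankings per setting; on fixtures built at high vs
low q the ranking is identical for K ∈ {10, 15, 20}.

## Problem sizes and numerical choices

Test and verification runs use 128-px images on a 10×10 grid, corpora
of 20–200 images per check, 10,000 baseline draws and 500–10,000
bootstrap resamples — sizes at which every property above is sharp
(exact equalities, or Monte-Carlo error well inside the asserted
band). Floating tolerances: mass conservation 1e-9 relative;
finite-difference agreement 1e-4 relative; IG completeness 1e-3
relative at 256 steps. Degenerate inputs fail loudly: empty expert
maps, zero corpus counts, non-binary masks, K < 1, infeasible overlap
or geometry requests all raise typed errors rather than returning a
number.

## Known limitations

* ECS compares cell rankings only; it says nothing about calibration of
  attribution magnitudes, and pixel-level metrics (DICE, IoU) are
  deliberately out of scope.
* The inverse-frequency weights are corpus-level constants; no attempt
  is made to learn diagnostic importance.
* Architecture-bound attribution methods (Grad-CAM, Guided
  Backpropagation, DeconvNet, LRP variants) need access to network
  internals and are outside the gradient-provider contract; the CLI
  accepts their heatmaps as files like any other.
* Reproducing published ECS values for real models on IDRiD requires
  that dataset and the trained networks; this package supplies the
  metric and its verification, not those artifacts.
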
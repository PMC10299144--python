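# Methods

## Image quantification

**Otsu threshold.** Computed directly on the 256-bin histogram: the
returned integer `t ∈ [0, 254]` maximizes the between-class variance of
the classes `{≤ t}` and `{> t}`; ties resolve to the smallest `t`, and
foreground is strictly `intensity > t`.  These three conventions
(integer grid, strict foreground, smallest tie) are stated explicitly
because Otsu implementations differ on all of them; the implementation
is cross-checked in tests against both an exhaustive scan of all 255
candidate thresholds and scikit-image's reference (which may differ by
one grey level at ties).  A constant image raises — there is no
meaningful threshold.

**Skeletonization** delegates to `skimage.morphology.skeletonize`.  The
contract, not the particular thinning algorithm, is normative: the
skeleton is a subset of the mask, one pixel wide, idempotent under
re-application, and preserves the number of 8-connected components.
Tests assert the contract on synthetic vascular networks.

**VPD** is the foreground fraction of the *full* vessel mask;
**LAC** is computed on the *skeleton* only.  The split follows the
processing order of the original analysis (binarize → VPD; skeletonize →
LAC).  VPD is stored and reported as a fraction of image area in [0, 1];
summary tables label it so, since "%" labelling of fractional values is
a recurring ambiguity in the OCTA literature.  No denoising precedes
thresholding by default.

## Lacunarity

For box size `r` the image is partitioned into non-overlapping `r × r`
boxes anchored at an origin offset `(dy, dx)`; only complete boxes
count (a flag admits partial edge boxes, off by default because their
masses are not comparable), and empty boxes are retained.  Per origin,
`Λ(r, o) = Var(m)/Mean(m)²` with population variance — the boxes of one
grid are the whole population, not a sample.  Origins run over the
lattice with stride `max(1, round(f·r))`; the default stride fraction
`f = 0.5` gives four origins per scale (the "multiple origins"
de-biasing), and `f → 0` degenerates to the full gliding-box origin
set, available for sensitivity analysis.  Origins whose boxes are all
empty are skipped and logged; an entirely empty skeleton raises.

Two deliberate conventions:

* **Normalization `Λ = Var/Mean²`**, not `1 + Var/Mean²`.  Retinal
  skeleton LAC values reported in the 0.3–0.5 range are only possible
  under the former (the latter is bounded below by 1).  Absolute LAC is
  convention-dependent across tools; only orderings and contrasts are
  asserted in the acceptance checks.
* **Aggregation** over scales is the unweighted mean of `Λ(r)` on the
  dyadic ladder 4, 8, …, side/4.  No aggregation rule is standard; a
  log–log slope aggregate is available behind `aggregate="log_slope"`.

Closed forms anchor the implementation: a filled image gives Λ = 0 at
every scale; a single foreground pixel with one origin gives exactly
`Λ = B − 1` with `B` the number of boxes; an even checkerboard gives 0.
The vectorized implementation matches an explicit-loop oracle to 1e-12.

## Synthetic angiograms

The generator emulates the *statistics* the analysis consumes, not OCT
physics: no speckle, decorrelation, projection artifacts or layer
segmentation are modelled, so passing tests demonstrate the pipeline's
behaviour on controlled networks, not clinical performance.  Vessels
grow as biased random walks: trunks enter from the border aimed at the
image center, curvature jitters (SD 0.15 rad/step), walkers bifurcate
with probability 0.08/step (≤ 6 walkers per trunk), and each trunk has
a total step budget of `max(60, side/2)` so one trunk adds only ~1–3%
coverage.  Trunks are added until the foreground fraction reaches
`target_vpd − 0.01`; since increments are small, the achieved density
stays inside the ±0.05 calibration band, and an unreachable target
raises a calibration error naming the achieved fraction.  Vessel pixels
render at intensity 190, background at 35, plus Gaussian noise
(default SD 12) — a separation Otsu recovers essentially exactly, which
is what makes the density calibration meaningful.  Cystoid edema is
rendered as zero-intensity ellipses (centers in the central 60% of the
field, radii 8–24 px by default) drawn from a dedicated RNG substream,
so increasing `cyst_count` extends the cyst sequence without touching
the vessel pattern; binarized VPD is therefore non-increasing in cyst
count, and LAC rises with dropout.  The default density target 0.36
matches the reported DME perfusion density.

## Synthetic cohorts

Baseline covariates are truncated normal with the reported moments:
BCVA 64.77 ± 12.73 letters on [0, 100], CMT 420.9 ± 103.7 µm on
[150, 900], DCP LAC 0.40 ± 0.15 on [0, 1.5] (bounds are this package's
choice; only means ± SD were reported).  VMA is Bernoulli with default
prevalence 0.2 — invented, as no VMA prevalence was reported.  The
12-month BCVA is the eye's leaf value under the published tree
structure plus `N(0, σ)` noise, truncated to [0, 100].  The printed
leaves are 65 (thick CMT, high LAC) and 73 (thick CMT, low LAC)
letters; the VMA-present and thin-CMT leaves were never printed and
default to 60 and 78 letters — invented values consistent with the
reported ordering ("VMA worse, thin CMT best") and overridable; the
packaged pseudo-cohort uses 78 for its thin-CMT rows and sets VMA
absent everywhere, since all published stratum counts (36/10/26) lie on
the VMA-absent side.

`noise_sd_for_signal_fraction` solves for σ analytically: with branch
probabilities `p_k` (from the truncated-normal CDFs) and leaf values
`v_k`, the between-branch variance is `Var_s = Σ p_k (v_k − mean)²` and
`σ = sqrt(Var_s (1 − f)/f)` yields signal fraction `f`.  With the
defaults, `f = 0.81` gives σ ≈ 3.26 letters; refitted trees on such
cohorts attain training r² near 0.81, slightly above on average because
training r² of a grid-selected tree absorbs some noise.

## Trees

Greedy CART: every predictor and every midpoint of consecutive sorted
unique values is scored by SSE reduction (flags split at 0.5); `x ≥
threshold` routes high, matching the closed lower bounds of the
published node labels, so boundary eyes (CMT exactly 373, LAC exactly
0.41) go to the high branch.  Ties break deterministically: predictor
declaration order, then the smaller threshold.  Branches stop at
`max_depth`, when a child would fall below `min_leaf_n`, or when the
best gain is below `min_sse_gain` (default 1e-9, effectively any gain).
Internal nodes store their training mean and count, preserving the
weighted-mean invariant to 1e-9.

"Automatically generated" model search is realized as a small grid
(depth 1–4 × min leaf {5, 10}) scored by **training** r², because a
training determination coefficient is what the original analysis
reports; this overfits by construction (the selection ceiling grows
with the grid) and carries no out-of-sample claim.  No pruning or
cross-validation is applied; ties prefer fewer leaves, then lower
depth.  The hand-rolled fitter matches scikit-learn's
`DecisionTreeRegressor` prediction-for-prediction on continuous data in
the cross-check test, but is kept in-package for the determinism
guarantees above.

The published tree is shipped as a fixed predictor with VMA at the
root — the first-level contrast described for the study — with
topology fixed and the unprinted leaf values unset: routing into one
raises unless an override supplies a value.  The thick-CMT node carries
the printed value 71 = (10·65 + 26·73)/36 over n = 36.

## Pipeline and reproducibility

Every stochastic stage derives its seed as
`(global_seed·1000003 + crc32(stage:replicate)) mod 2³¹`, so toggling
one stage never shifts another's stream and replicate `k` is stable
regardless of replicate count.  Artifacts carry no timestamps; a rerun
with the same config and seed is byte-identical.  Problem sizes used by
the test suite — 128–256 px images, cohorts of 300–10 000 eyes, 20–50
simulation replicates, 2000 t-test replicates — were chosen as the
smallest scales at which the asserted statistics are stable.

## Known limitations

* Absolute LAC values are convention-bound; comparisons across tools
  require matching the normalization, box ladder and origin set.
* The angiogram generator produces plausible branching statistics, not
  retinal anatomy (no foveal avascular zone, no capillary hierarchy);
  VPD/LAC ranges overlap reported values but the LAC magnitude depends
  on skeleton density.
* Training-r² model selection overfits; the recovery experiment
  quantifies routing agreement, not generalization.
* The packaged pseudo-cohort reproduces marginal counts, not joint
  patient-level structure; inferential p-values computed from it are
  illustrative, not reproductions of the original patient-level tests.
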
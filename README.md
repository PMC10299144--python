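# octadme

Fractal quantification of OCT-angiography (OCTA) images and
regression-tree prediction of 12-month visual outcome in diabetic
macular edema (DME).

## The problem

DME thickens the central retina and degrades visual acuity; intravitreal
anti-VEGF therapy improves both, but individual response varies and
clinicians want baseline biomarkers that predict the one-year outcome.
En-face OCTA slabs of the superficial and deep capillary plexuses
(SCP/DCP) show the retinal microvasculature directly, and two fractal
descriptors summarize it:

* **Vascular perfusion density (VPD)** — the fraction of image area
  occupied by binarized vessel signal,

  `VPD = |{binary vessel pixels}| / |{all pixels}|`

* **Lacunarity (LAC)** — the "gappiness" of the one-pixel-wide vessel
  skeleton, from box counting at multiple grid origins: for box size *r*
  and grid origin *o*, with box masses *m*,

  `Λ(r, o) = Var(m) / Mean(m)²`  (population variance),

  averaged over origins and then over a dyadic ladder of box sizes.
  Homogeneous patterns give Λ = 0; a wide spread of lacuna sizes gives
  large Λ.

The analysis chain is: 8-bit en-face angiogram → Otsu threshold →
binary vessel mask (VPD) → topology-preserving skeleton (LAC).  Baseline
covariates then feed greedy CART regression trees for the 12-month
best-corrected visual acuity (BCVA, ETDRS letters, 0–100), with the best
tree selected by the training determination coefficient
`r² = 1 − SSE/SST`.  The published outcome tree splits on vitreomacular
adhesion (VMA), baseline central macular thickness (CMT ≥ 373 µm) and
deep-plexus lacunarity (DCP LAC ≥ 0.41); among VMA-absent, thick-CMT
eyes, high lacunarity predicts 65 letters and low lacunarity 73 letters.

Because neither the angiograms nor the patient table of the original
cohort are publicly available, the package ships (a) a synthetic
angiogram generator (seeded random-walk branching networks with optional
cystoid signal-void ellipses, density-calibrated to a target VPD), (b) a
cohort simulator whose outcome follows the published tree structure, and
(c) a packaged 66-eye pseudo-cohort reproducing every published marginal
count exactly.

## Worked example

```python
import octadme as od

# quantify a synthetic DCP angiogram with cystoid dropout
image = od.generate_angiogram(od.VesselSimParams(target_vpd=0.36,
                                                 cyst_count=4, rng_seed=7))
t = od.otsu_threshold(image)
mask = od.binarize(image, t)
metrics = od.fractal_metrics(mask, od.skeletonize(mask))
print(t, round(metrics.vpd, 3), round(metrics.lac, 3))
# 87 0.335 0.843

# the published outcome tree
tree = od.published_tree()
od.predict(tree, {"vma": 0, "cmt_baseline": 400, "lac_dcp": 0.50})  # 65.0
od.predict(tree, {"vma": 0, "cmt_baseline": 400, "lac_dcp": 0.30})  # 73.0
```

The threshold 87 separates the bright vessel network from the dark
background; VPD 0.335 means a third of the scan area carries flow signal
(the cystoid dropouts pulled it below the 0.36 target); LAC 0.843 is the
mean Var/Mean² over box sizes 4–64 px, and rises when cysts punch holes
in the skeleton.  The tree predictions are the published 65/73-letter
leaves for a thick-CMT eye with high/low deep-plexus lacunarity.

Longer narrative scripts live in `examples/` (angiogram quantification,
pseudo-cohort summary, published-tree routing, simulate-and-refit
recovery), and a thin CLI mirrors the library:

```bash
octadme summarize --reference --out summary.json
octadme simulate-cohort --n-eyes 500 --seed 1 --out cohort.csv
octadme tree fit cohort.csv --out tree.json
octadme run --config pipeline.yaml
```

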
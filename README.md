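# octamorph

Morphometric quantification of en-face OCTA (optical coherence tomography
angiography) retinal angiograms.

Diabetic retinopathy remodels the retinal microvasculature long before it
is clinically obvious: terminal branches are pruned, perfused vessel length
shrinks, and short disconnected "fragmented" vessel snippets appear.
`octamorph` measures this from 2-D en-face angiograms of the superficial or
deep vascular plexus (SVP / DVP), one 3 × 3 mm macular scan per layer, and
reports nine indices per region (fovea and parafovea):

| symbol | definition | unit |
|---|---|---|
| VL  | total skeleton (centerline) length | mm |
| VAD | mean vessel diameter, 2 × distance-transform radius over skeleton pixels | µm |
| VD  | vessel pixel fraction of the region | – |
| BNN | branch node number (junction clusters with ≥ 3 skeleton neighbours) | count |
| BND | BNN / VL | mm⁻¹ |
| EPN | end point number (skeleton pixels with 1 neighbour) | count |
| EPD | EPN / VL | mm⁻¹ |
| FVSC | fragmented vessel segment count: isolated skeleton segments shorter than k × VAD (k = 30) | count |
| FVLR | fragmented vascular length ratio: Σ fragmented length / VL | – |

The processing chain is: **local adaptive region growing** binarization →
**FAZ extraction** (distance-map topography, h-minima–suppressed watershed
of the inverted map, morphological active-contour refinement) → fovea /
parafovea partition (1.5 mm and 2.5 mm circles centred on the FAZ
centroid) → **one-pixel thinning** with per-pixel radius from the
Euclidean distance transform → neighbour-count topology → fragmentation
metrics and the 2–100 × VAD multiplier sweep → cohort statistics
(mean ± SD, unpaired two-tailed Student *t*).

Because no clinical dataset ships with the package, a first-class
**synthetic angiogram generator** grows a ground-truthed capillary plexus
(bifurcating trees around a perifoveal ring enclosing an avascular zone)
and degrades it in controlled, disease-like ways (terminal pruning,
flow-dropout gaps, planted isolated fragments). Every junction, terminal
and fragment is known by construction, so the whole pipeline is verifiable
end to end.

## Worked example

```python
import octamorph as om

# grow a healthy plexus at desk scale (256 px over the 3 mm field),
# plant 5 isolated fragments, render it noise-free, and analyze it
net = om.grow_network(om.GrowthParams().scaled(256), seed=21)
net = om.degrade(net, om.DegradationConfig(n_fragments=5, seed=21))
ras = om.rasterize(net)
res = om.analyze_angiogram(ras.angiogram)
print(res.rows[["region", "VL_mm", "VAD_um", "BNN", "EPN", "FVSC", "FVLR"]]
      .to_string(index=False))
```

prints

```
   region     VL_mm    VAD_um  BNN  EPN  FVSC     FVLR
    fovea 15.119557 26.252951   32   34     1 0.014006
parafovea 28.342402 28.656941   60   67     2 0.016084
```

Read: inside the fovea ring this eye carries ~15.1 mm of perfused
centerline at a mean calibre of ~26 µm, with 32 junctions and 34
terminals; one planted fragment fell in the fovea and two in the
parafovea, contributing ~1.5% of the local vascular length.

From a shell the same pipeline is driven by the `octamorph` CLI:

```bash
octamorph synth --out cohort/ --seed 7 --n-eyes 20 --size-px 384
octamorph cohort cohort/manifest.csv --out results/
octamorph compare results/metrics.csv --out results/comparison.csv
octamorph sweep cohort/manifest.csv --out results/sweep.csv
```

`compare` reports mean ± SD per group and the pooled-variance two-tailed
*t* per (layer, region, metric), starred at p < 0.05 / 0.01 / 0.001.

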
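# budscan

Automated tumor-budding quantification for pan-cytokeratin IHC slides.

Tumor budding — single tumor cells or clusters of up to four cells at the
invasive front — is a prognostic biomarker in colorectal cancer. The
standardized (ITBCC 2016) protocol counts buds inside a circular *hotspot*
of radius 0.5 mm (area 0.785 mm²) and converts the count into a three-tier
grade: **Bd1** (0–4 buds), **Bd2** (5–9), **Bd3** (≥ 10). `budscan`
implements the computational core of a fully automated version of this
assessment, intended for digital-pathology researchers working with
bud-detection point sets from whole-slide images:

- **Density mapping** — for every cell of a raster covering the slide,
  the exact number of detected buds inside the hotspot-sized disk centered
  on that cell: `counts[i,j] = #{k : ‖p_k − c_ij‖ ≤ r}` with `r = 500 µm`.
- **Hotspot selection** — greedy extraction with overlap suppression:
  repeatedly take the argmax cell, zero every cell within one radius,
  until 10 hotspots are found; successive centers are ≥ r apart.
- **ITBCC scoring** of the rank-1 hotspot count, plus the **Shannon
  entropy** `H = −Σ p_j log p_j` of the density distribution over raster
  cells — a slide-level spatial heterogeneity biomarker.
- **Stain tools** — Ruifrok–Johnston H-DAB color deconvolution
  (`OD = −log10((I+1)/255)`, unmixed through the inverse stain matrix),
  DAB-positive masking and connected-component candidates.
- **Pseudo-label construction** for teacher–student detector training:
  keep teacher detections with likelihood strictly > 0.80, reject those
  off the DAB mask, merge with manual annotations (certainty 1.0 vs 0.80,
  manual precedence on collisions).
- **Evaluation metrics** — sensitivity against sparse labeled references,
  Pearson comparison of manual vs automatic hotspot counts, and
  top-3 / top-10 hotspot agreement using the circle dice
  `2|A∩B| / (|A|+|B|)` with the ≥ 0.7 match criterion.
- **Synthetic slides** — seeded generator of clustered bud patterns with
  a known densest disk, distractors, noisy teacher likelihoods, and
  rendered DAB-blob imagery, so the whole pipeline is testable end to end.

## Worked example

```sh
budscan simulate --seed 1 --out-dir demo --width-mm 4 --height-mm 4
budscan density  --detections demo/true_buds.csv --out demo/map.tif
budscan hotspots --density demo/map --out demo/hotspots.json
budscan score    --hotspots demo/hotspots.json --out demo/score.csv
budscan entropy  --density demo/map --out demo/entropy.json
```

prints

```
wrote synthetic slide (39 buds) to demo
density map (602, 539) total_buds=39
10 hotspots (rank-1 count 26)
slide: 26 buds -> Bd3
entropy 11.0835 nats (normalized 0.8734)
```

The simulated 4 × 4 mm slide carries 39 buds, most in one dominant
cluster. The rank-1 hotspot holds 26 of them — Bd3, high budding — and
sits at (2320, 2982) µm, within one grid cell of the planted ground-truth
densest disk recorded in `demo/truth.json` at (2340, 2980) µm with the
same count of 26. The normalized entropy of 0.87 reflects buds spread
widely over the tissue rather than packed into a single field.

The same operations are available as a library
(`budscan.compute_density`, `budscan.select_hotspots`,
`budscan.itbcc_tier`, …); see `docs/methods.md` for the model, parameter
defaults and numerical conventions.

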
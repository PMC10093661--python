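# Methods

## Coordinate and raster conventions

All physical coordinates are micrometers in a slide-local frame (x
rightward, y downward). Raster grids follow the pixel-center convention:
cell (i, j) of a grid with spacing s and origin (ox, oy) represents the
point (ox + (j + 0.5)s, oy + (i + 0.5)s). Interchange files always carry
micrometers, never raster indices.

Disk membership is closed: a point at exactly radius distance is inside.
All membership tests compare squared distances, avoiding square roots
and their rounding.

## Density map

The density map stores, per raster cell, the exact number of counted
detections within one hotspot radius (default r = 500 µm, the 0.785 mm²
ITBCC field) of the cell center. Semantics are exact point geometry:
detection coordinates are never binned. The implementation stamps, for
each detection, the window of cells its disk can reach and applies the
squared-distance test, costing O(n · (2r/s)²); the test suite checks
exact integer equality against a full distance-matrix count on random
instances.

The default grid spacing is s = 8 µm. Scanning at the native 0.24 µm
pixel size of a slide scanner would multiply the work by ~10³ while
moving hotspot centers by at most half a cell (4 µm ≪ r), so nothing is
gained; the spacing is configurable. The raster extent defaults to the
detection bounding box padded by one radius on every side (so a disk
centered on any detection is fully rastered), or the tissue rectangle
when one is known.

Normalization divides the count grid by the slide's total bud count,
giving each cell the fraction of the slide's bud burden inside its disk
(values in [0, 1]). A slide with zero buds sets a `zero_density` flag
instead of a normalized grid — downstream consumers must treat
"no buds" as distinct from "uniformly low".

## Hotspot selection and matching

Selection is greedy with overlap suppression: take the argmax cell of
the working grid as the next hotspot center (its value is the hotspot
count), zero all cells within one radius of it, repeat until k = 10
hotspots or the grid is exhausted (fewer are returned with a warning).
Zeroing one radius guarantees successive centers are ≥ r apart, which
bounds pairwise field overlap. Argmax ties break to the smallest
row-major index — deterministic across platforms. An alternative
"recount" mode (remove the buds in the chosen field and recompute)
exists behind a flag and is off by default.

Hotspot centers live on the density grid, so their localization
resolution equals the grid spacing. Disks may overhang the raster edge;
overhanging area simply contains no cells.

Automatic/manual hotspot matching uses the analytic circle dice
2|A∩B|/(|A|+|B|) (circular-lens intersection area; general unequal-radii
formula, exercised against a 1 µm rasterized-mask oracle to within
0.005). A manual hotspot matches at the lowest rank whose dice reaches
0.7; for equal radii that corresponds to a center distance ≤ 0.476 r.
Reports flag top-3 and top-10 matches; note that at the minimum
separation d = r the geometric dice is ≈ 0.391, i.e. suppression keeps
reported fields well below 50 % area overlap.

## Biomarkers

ITBCC tiers are a pure function of the scoring-hotspot count: 0–4 Bd1,
5–9 Bd2, ≥ 10 Bd3.

Shannon entropy is computed over raster cells of the *count* grid:
p_j = counts_j / Σ counts_j, H = −Σ p_j log p_j (natural log by default,
base configurable). The count grid is used rather than the bud-normalized
grid because only the former is a probability distribution after
rescaling. H is invariant to uniform rescaling of counts, zero for a
point mass, and log K for a uniform K-cell raster; the normalized score
divides by log K. An all-zero map raises a dedicated error — undefined,
not zero. Because H depends on the raster size through K, entropies
should only be compared across slides mapped at the same spacing; the
normalized score removes most of this sensitivity.

Dichotomization rules: MEDIAN (high iff value > median; ties low —
strict inequality, documented and configurable), ITBCC (high iff Bd3 by
default), FIXED(x). Survival modelling on the resulting groups is out of
scope; the per-slide CSV is designed to feed standard survival packages.

## Stain model

Brightfield IHC follows Beer–Lambert absorption. Optical density per
channel is OD = −log10((I + 1)/255); the +1 avoids log(0) at I = 0 and
biases OD by < 0.01 for I > 40. A pixel's OD vector is modeled as a
non-negative combination of unit stain vectors; the default basis is the
published Ruifrok–Johnston H-DAB pair (hematoxylin (0.650, 0.704, 0.286),
DAB (0.268, 0.570, 0.776)) with the normalized cross product as residual.
Concentrations are the OD vector through the inverse stain matrix,
negatives clipped to zero. Any red chromogen present is absorbed by the
residual channel and ignored.

The DAB mask thresholds the DAB concentration at 0.15 OD, applies a
1-px-disk morphological opening, labels 8-connected components, and
drops components below 30 µm². These defaults are tuned on the synthetic
renderer's roundtrip (no published values exist for them) and are
configurable per run; 30 µm² is roughly a third of one epithelial cell
cross-section, and the opening removes single-pixel noise. Component
candidates get a size-heuristic likelihood: 1.0 inside a plausible
bud-area band (30–800 µm², one to four ~10 µm cells), 0.5 outside.

The synthetic renderer inverts exactly the documented deconvolution
transform, I = 255·10^(−OD) − 1, so roundtrip error comes only from
uint8 quantization (and optional bounded noise). Quantization grows with
OD — at DAB amplitude 2 the worst per-channel OD error is ≈ 0.03 — so
coefficient-recovery checks use continuous (`quantize=False`) tiles
while blob-count recovery runs on quantized, noisy ones.

## Pseudo-label construction

Teacher detections survive only with likelihood strictly greater than
0.80 (a score of exactly 0.80 is rejected) and, when a DAB mask is
supplied, only on a mask-positive pixel (tolerance default 0 µm; a
positive tolerance uses the Euclidean distance transform of the mask).
Manual annotations bypass both filters. Merging assigns certainty 1.0 to
manual and 0.80 to pseudo records — the student's loss weight contract —
and drops any pseudo record within 15 µm of a manual record (roughly one
cell diameter), so no object is supervised twice; the manual label wins.
Records are emitted in a canonical order (manual first, then by
position), making the manifest independent of input ordering. Each
record carries a patch specification (1024 px side at 1 µm spacing by
default) as the hand-off to a training framework; patch extraction and
training itself are out of scope.

## Synthetic slides

The generator emulates the *geometry* of a budding slide, not its
histology: background buds as a homogeneous Poisson process (default
1/mm² over a 6 × 6 mm tissue), one dominant Gaussian cluster (25 buds,
sd 150 µm) standing in for the invasive-front hotspot, uniform
distractors (1/mm²), a sparse manual subset (10 TB + 8 non-TB), and a
teacher whose likelihoods are Beta(8, 2) on true buds and Beta(2, 8) on
Poisson false positives (0.5/mm²) — chosen so the 0.80 threshold
separates imperfectly and the filter is actually exercised. The planted
hotspot is computed by an exhaustive densest-disk scan over the density
grid (KD-tree ball counts — an independent route from the density
module), with the same row-major tie-break as the selector.

What passing tests show: counting, selection, scoring, filtering and the
metrics are correct on point patterns with known ground truth, and the
stain roundtrip is self-consistent. What they cannot show: detector
accuracy on real tissue, stain variation beyond the linear Beer–Lambert
model, tissue-shaped (non-rectangular, non-stationary) bud distributions,
or agreement with pathologists — those require real slides and a trained
detector, which this package deliberately treats as an upstream,
exchangeable component.

## Problem sizes and tolerances

The test suite validates density counting on 50 random instances up to
500 points on 400 × 400 grids (exact equality); hotspot recovery on 100
seeded default-config simulations (planted-hotspot dice ≥ 0.7 required
in ≥ 95); dice geometry against a 1 µm raster (|Δ| ≤ 0.005); stain
roundtrips over a 10× DAB amplitude range (counts exact, coefficients
within 0.02). The acceptance script simulates 75 buds in fifteen
clusters on a 20 × 20 mm tissue (a 2500 × 2500 density grid). The whole
suite runs in well under a minute on one core, acceptance in seconds.

## Known limitations

- Hotspots are searched over the whole raster, not restricted to the
  invasive front or a tissue mask (intratumoral picks are reported, not
  filtered).
- Entropy values depend on grid spacing through the cell count; use the
  normalized score for cross-study comparison.
- The DAB mask thresholds are synthetic-calibrated defaults, not
  validated against any scanner or staining protocol.
- The stand-in mask-component detector has no notion of the bud/cluster
  cell-count distinction; it is a plumbing detector, not a classifier.
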
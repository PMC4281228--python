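# colonymap

Multi-scale image cytometry for colony-structured cell cultures — human
pluripotent stem (hPS) cells in particular. hPS cells grow as spatially
patterned colonies, and single-cell measurements only make sense together
with each cell's *population context*: which colony it belongs to, how far
it sits from the colony edge, and how crowded its neighbourhood is.
`colonymap` provides the full analysis chain for slide-scan experiments in
which a region is imaged as a rectangular grid of overlapping fields:

- **Seamless virtual slide** — per-field segmentation label matrices are
  merged into one region-level label matrix *without stitching raw pixels*.
  When the overlap margin is at least twice the diameter of the largest
  cell, every cell is fully contained in at least one field; duplicate
  instances of a cell segmented in two adjacent fields are detected by
  pixel-space overlap and resolved by keeping the larger instance.
- **Segmentation and features** — colony footprints by Gaussian blurring +
  Otsu thresholding of the mosaic; nuclei by smooth → threshold →
  distance-transform watershed; per-object area, perimeter, eccentricity,
  per-channel integrated/mean intensity and texture.
- **Colony context** — distance from the colony edge (Euclidean distance
  transform; 0 outside any colony), cell layers in units of one cell
  diameter, colony size classes (small < 150 µm ≤ medium ≤ 300 µm < large,
  by maximum edge distance), and fixed-size density windows
  (250 µm × 192 µm) classed low/mixed/high by contained cell count.
- **Gating and statistics** — cell-cycle gates fitted from the data
  (2N/4N DNA-content modes via a two-component mixture on log integrated
  DNA stain; EdU and pH3 thresholds at the antimode of their bimodal
  distributions; precedence S > M > G1/G2), marker positive/negative
  thresholds, and subpopulation frequencies per spatial bin with
  percentile bootstrap confidence intervals (B resamples with
  replacement, central interval).
- **smFISH** — single-molecule RNA FISH spot detection in 3-D stacks
  (morphological opening to remove out-of-focus light, Laplacian of
  Gaussian to sharpen foci, a statistic combining 3-D curvature with
  intensity above background), per-cell transcript counts via nuclei
  expanded to touching territories, and **adaptive threshold
  equalization**: per-field thresholds S = [s_xy] chosen to minimise

  E(S) = Σ_xy (f_r(s_xy) − f_l(s_x+1,y))² + (f_b(s_xy) − f_t(s_x,y+1))²

  where f_t/f_b/f_l/f_r count detected spots in the physically shared
  top/bottom/left/right margins of adjacent fields (a 1-norm variant is
  available for robustness). This makes spot detection consistent across
  fields despite gain and background differences.
- **Synthetic ground truth** — a first-class generator producing colony
  scenes (smoothed-blob colonies, elliptical nuclei with phase-dependent
  DNA signal, bimodal EdU/pH3/marker intensities, optional planted spatial
  enrichment), overlapping field renderings with per-field gain/background
  and Poisson + read noise, and 3-D smFISH stacks with log-normal spot
  amplitudes — so every stage is testable without real data.

## Worked example

`examples/02_cell_cycle_by_colony_position.py` generates a scene in which
peripheral cells are biased toward G1 and the outermost colony layer
toward G2, runs segmentation → consensus → features → gating → layer
binning, and prints:

```
436 cells; fitted DNA modes 2N=7337, 4N=17662 a.u.

phase frequency by cell layer (95% bootstrap CI):
  periphery  (n=  63): G1 0.67 [0.56,0.79]  S 0.13 [0.05,0.21]  G2 0.16 [0.08,0.25]  M 0.05 [0.00,0.11]
  Layer 1    (n=  53): G1 0.19 [0.09,0.30]  S 0.30 [0.19,0.43]  G2 0.49 [0.36,0.64]  M 0.02 [0.00,0.08]
  Layer 2    (n=  87): G1 0.39 [0.29,0.49]  S 0.26 [0.17,0.36]  G2 0.23 [0.15,0.32]  M 0.11 [0.05,0.18]
  Layer 3    (n=  76): G1 0.42 [0.32,0.53]  S 0.29 [0.18,0.39]  G2 0.25 [0.16,0.36]  M 0.04 [0.00,0.09]
  interior   (n= 157): G1 0.39 [0.31,0.47]  S 0.32 [0.25,0.39]  G2 0.22 [0.16,0.29]  M 0.07 [0.03,0.11]
```

Reading the table: each row is a distance band from the colony edge
(periphery = centroid outside the colony mask, Layer k = within the k-th
cell diameter inside the edge). Point estimates are observed frequencies
(rows sum to 1); brackets are 95% percentile bootstrap CIs from 1000
resamples. The G1 excess at the periphery and the G2 excess in Layer 1 —
with CIs that do not overlap the neighbouring bands — recover exactly the
enrichment planted in the generator. `2N`/`4N` are the fitted DNA-content
modes in arbitrary integrated-intensity units; their ratio exceeds 2
slightly because brighter nuclei also segment slightly larger.

The other examples show seamless consensus segmentation of an overlapping
grid (`01`) and smFISH threshold equalization between fields of unequal
gain (`03`). A thin CLI covers the file-based workflow:

```sh
colonymap simulate --seed 1 --out scratch/run1
colonymap run --config scratch/run1/config.yaml --input scratch/run1 --out scratch/run1/out
```

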
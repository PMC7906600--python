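# thalamap

Spatial statistics for classed 3D cell distributions in serial-section
whole-brain imaging. The package implements, as a tested reusable pipeline:

- **Serial-section dedup** (`thalamap.detection`) — per-slice blob centroids
  and correction of axial oversampling: detection events are grouped by the
  transitive closure of 3D distance ≤ radius and each group is reduced to its
  axially central member (or the group mean, behind a flag).
- **Region counting** (`thalamap.core`) — box-atlas region assignment
  (half-open bounds, first-match-wins ordering), per-nucleus counts and
  across-brain proportion summaries (mean ± SEM).
- **NND statistics** (`thalamap.neighborhood`) — within- and between-class
  nearest-neighbour distances, per-set max normalization, across-brain pooled
  CDFs and the two-sample Kolmogorov–Smirnov contrast.
- **Spatial clustering** (`thalamap.clustering`) — k-means (k-means++ /
  Lloyd, best-of-n restarts) with silhouette-based selection of k and
  per-cluster class composition / capture summaries.
- **Migratory orientation** (`thalamap.orientation`) — soma→tip leading
  process vectors in spherical coordinates, 2D angular histograms, per-axis
  dominant-orientation fractions and in-plane polar histograms.
- **Group statistics** (`thalamap.stats`) — chi-squared homogeneity,
  two-sample t-test, percent-reduction summaries, iterative Grubbs outlier
  flagging and ROI-pooled double-positive fractions.
- **Synthetic data** (`thalamap.synthetic`) — seeded generators with planted
  ground truth: two-class Gaussian-mixture brains, serial optical-section
  detection events, von Mises–Fisher migration directions and 2D
  fluorescence-like blob images.

Coordinate convention: µm everywhere, +x medial→lateral, +y ventral→dorsal,
+z caudal→rostral.

## CLI

```sh
thalamap simulate --seed 1 --n-brains 3 --n-cells 1000 --out cells.csv
thalamap dedup    --events events.csv --radius 10 --mode median --out cells.csv
thalamap nnd      --cells cells.csv --classes classA,classB --grid 256 --out nnd
thalamap cluster  --cells cells.csv --kmin 2 --kmax 10 --seed 7 --out clusters.json
thalamap orient   --processes proc.csv --region LGd --out orient.json
thalamap stats chi2 --table counts.csv
thalamap run --config pipeline.yaml --out report/
```

`thalamap run` executes simulate → detect/dedup → assign → NND → cluster →
orient → stats from one YAML config and writes a deterministic report bundle
(CSV/JSON outputs, resolved config, log); re-running the emitted resolved
config reproduces the bundle byte-identically.

Example `pipeline.yaml`:

```yaml
seed: 11
atlas: default
cells:
  generate: {n_brains: 3, n_cells_per_class: 1000}
processes:
  generate: {region: LGd, kappa: 20, n_cells: 300}
cluster: {kmin: 2, kmax: 10, n_init: 10}
nnd: {grid_size: 256}
```

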
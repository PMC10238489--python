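# furrowquant

Quantification of cytokinesis in asymmetrically dividing cells from
single-plane fluorescence time-lapse movies, with a fully ground-truthed
synthetic movie generator.

Large neural stem cells such as *Drosophila* larval neuroblasts divide
asymmetrically: the cleavage furrow forms off-centre, toward the basal pole,
and produces a small daughter (the ganglion mother cell, GMC) next to a
large self-renewing cell. Live imaging of a cortical myosin marker raises a
set of recurring measurement problems — how enriched is myosin on the polar
cortex relative to the cytoplasm, how fast does the contractile ring close,
where exactly is the furrow, and how big is the daughter cell it leaves
behind? `furrowquant` packages these read-outs as a tested pipeline:

- **`synthmovie`** — a generator of synthetic dividing-cell movies
  (16-bit multi-page TIFF) with complete per-frame ground truth: cell
  outline, furrow position, ring diameter `d(t)`, polar myosin pulse
  `E(t)`, and daughter-cell area. The furrow can stay where it formed or
  drift to a set target size, emulating the presence or absence of a
  furrow-position-correction mechanism.
- **`cortexprofile`** — camera-background subtraction, subpixel cell-outline
  tracing, 2-px pole-to-pole cortical linescans, cytoplasm subtraction,
  max-normalisation with neighbour-average smoothing, and the cortical
  enrichment index `(Myo_cortex − Myo_cyto) / Myo_cyto`.
- **`furrowkinetics`** — furrow detection by maximal concave membrane
  curvature, ingression-onset timing, ring diameter via half-maximum edge
  crossings at the furrow plane, and percent constriction
  `100·(d0 − d)/(d0 − d_mb)` anchored at anaphase onset (0 %) and midbody
  size (100 %, default 4 px).
- **`morphometrics`** — daughter-cell area as ROI pixel count ×
  pixel-size², and roundness `4A/(πL²)` with `L` the maximal chord.
- **`divstats`** — two-tailed Mann–Whitney tests (exact by enumeration for
  small tie-free samples), Pearson r/R², median ± IQR, and an end-to-end
  *correction contrast* experiment: simulate cohorts with and without
  furrow-position correction and correlate the initial furrow basal offset
  with the final GMC area.
- **`isoformusage`** — splice-isoform frequency estimation from
  exon-junction read counts by non-negative least squares, and
  classification of single-base codon substitutions
  (synonymous/missense/nonsense, e.g. CAG→TAG, glutamine→stop).

## Worked example

```python
from furrowquant import SimulationParams, simulate_division, subtract_camera_background
from furrowquant.furrowkinetics import constriction_curve
from furrowquant.divstats import correlation_experiment, polar_enrichment_index

params = SimulationParams(seed=1, shot_noise=False, read_noise_sd=0.0)
movie, truth = simulate_division(params)
movie = subtract_camera_background(movie, params.camera_offset)

curve = constriction_curve(movie)
print(curve[["t_s", "ring_diameter_um", "percent"]].iloc[[3, 8, 13]])

report = correlation_experiment(n_cells=30, seed=1)
print(f"correction off: r = {report.r_off:.3f}, p = {report.p_off:.2e}")
print(f"correction on : R^2 = {report.r2_on:.3f}")
```

prints

```
      t_s  ring_diameter_um    percent
3    40.0          8.410588   9.253327
8   140.0          4.600485  53.670720
13  240.0          0.720610  93.572812
```

— the measured ring diameter tracks the linear constriction schedule from
`d0 ≈ 9.2 µm` (the cell chord at the furrow plane at anaphase onset) down
to midbody size, with time in seconds from anaphase onset — and

```
correction off: r = 0.926, p = 2.34e-13
correction on : R^2 = 0.058
```

— without furrow-position correction the initial basal offset of the
furrow predicts the final daughter-cell area almost perfectly, while with
correction the two decouple.

## Command line

```sh
furrowquant simulate --config params.yaml --out movie.tif --truth truth.json --seed 4
furrowquant quantify profile  --movie movie.tif --meta meta.yaml --out profiles.csv
furrowquant quantify kinetics --movie movie.tif --meta meta.yaml --out kinetics.csv
furrowquant stats --metrics metrics.csv --groups control,mutant --out report.json
furrowquant isoform --counts examples/junction_counts_synthetic.tsv \
    --model examples/isoform_model_synthetic.json --out freqs.json --ratio RB,RA
```

`meta.yaml` carries the imaging metadata (`pixel_size`, `frame_interval`,
`anaphase_onset_index`, `camera_offset`).

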
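# voxelus

Voxel-level analysis of functional-ultrasound (power Doppler) trial data.
Three complementary strategies over a 4-D µDoppler container
(voxels-in-plane × frames × trials × contrast conditions):

- **Region averaging** (`voxelus.regionavg`) — one mean ΔI% trace per
  atlas region and contrast, plus contrast–response curves of peak
  amplitude with 95% CIs across subjects.
- **Correlation mapping** (`voxelus.corrmap`) — per-voxel Pearson
  correlation with a boxcar stimulus regressor, binarized at a
  Fisher-transform critical value (r\* = tanh(z₁₋α/√(n−3)); 0.327 at
  α=0.01, n=50), with per-region active fractions and active-area traces
  (regions with <1% active area excluded).
- **Single-voxel clustering** (`voxelus.cluster`) — pooled per-voxel
  traces (exact duplicates removed), mean-centered PCA to a 50%
  explained-variance target, Elkan K-Means (best of 100 initializations),
  elbow-based K suggestion, amplitude-ordered cluster maps/traces,
  run-to-run stability scoring, and layer-wise cluster composition tables.

Supporting modules: `voxelus.hrmetrics` (six hemodynamic-response
descriptors — peak amplitude, Simpson AUC, time to peak, response length,
FWHM and time-point of half-maximum, with an order-2 zero-phase Butterworth
prefilter for TTP/RL), `voxelus.synth` (synthetic µDoppler generator with
planted ground truth: layered regions, contiguous response classes,
saturating contrast response, analyzable noise model), and `voxelus.core`
(containers and HDF5/JSON + TIFF/CSV I/O).

## CLI

```sh
voxelus simulate --seed 0 --out data/                 # synthetic dataset + ground truth
voxelus metrics  --in data/ --region SCs --out metrics.csv
voxelus regionavg --in data/ --regions SCs,SCi,SCd --out ra/
voxelus corr     --in data/ --threshold 0.327 --out corr/
voxelus cluster  --in data/ --region SCs --k 5 --n-init 100 --seed 0 --out clus/
voxelus run      --config run.json                    # all three strategies
```

Every stage writes a JSON manifest (version, seed, config hash); identical
config and seed reproduce identical deterministic outputs.

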
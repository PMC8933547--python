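# speckledemix

Non-invasive fluorescence imaging through scattering layers, beyond the
optical memory-effect (ME) range, from stacks of low-contrast speckle
frames acquired under varying random illumination.

Each point emitter behind a scattering layer produces a unique speckle
pattern on the camera (its *fingerprint*); every frame is a non-negative
mixture of all fingerprints with random per-frame weights. The pipeline:

1. **simulate** — physics-based synthetic data: ME-correlated speckle
   fingerprints (translation within the ME range, decorrelation beyond),
   exponential/speckle-field illumination weights, Poisson + read noise.
   Full ground truth is retained for testing.
2. **preprocess** — cropping and Fourier-domain Gaussian high-pass
   background removal.
3. **demix** — non-negative matrix factorization (multiplicative updates)
   of the pixels × frames matrix into fingerprints `W` and weights `H`,
   with automatic rank selection from the RMS-residual-vs-rank knee.
4. **fbr** — fingerprint-based reconstruction: TV-regularized pairwise
   deconvolution of every fingerprint pair (ADMM, FFT data term,
   Chambolle TV prox), per-emitter partial images, a shift graph whose
   edges are quality-filtered antisymmetry-checked pairwise
   displacements, maximum-quality spanning-tree composition of emitter
   positions, and global stitching on an expanded canvas. A normalized
   cross-correlation shift estimator is included as a baseline.
5. **pipeline** — end-to-end orchestration, YAML config, recovery
   metrics against ground truth, JSON reports.

Connected chains of emitters let the reconstruction extend to ~3× the
ME range — pairs beyond the ME range are bridged through intermediate
emitters via the shift graph.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks (a
3×-ME chain recovery, NMF/rank/deconvolution oracles, within/beyond-ME
quality separation, FBR-vs-cross-correlation under noise, and geometry
invariants); it is the slow part of the suite (~15 min on one CPU).

## CLI

```sh
speckledemix simulate    --config sim.yaml --out stack.tif --truth truth.h5
speckledemix preprocess  --in stack.tif --out prep.tif
speckledemix demix       --in prep.tif --rank auto --out factors.h5
speckledemix reconstruct --factors factors.h5 --mu 100 --out recon.tif
speckledemix run         --config pipe.yaml
```

Example `pipe.yaml`:

```yaml
mode: simulate_and_reconstruct
seed: 1
output_dir: out
simulate:
  n_emitters: 10
  layout: connected_chain
  chain_step: 6.7
  fov_radius: 42
  n_frames: 1000
  optics:
    frame_height: 96
    frame_width: 96
    grain_size: 4.0
    me_range: 20.0
    noise_photons: 2.0e4
demix:
  rank: auto
  rank_max: 16
fbr:
  quality_threshold: 3.0
```

## Library use

```python
from speckledemix.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig.from_yaml("pipe.yaml")
result = run_pipeline(config)
print(result.recovery.span_me_units, result.recovery.fraction_recovered)
```
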
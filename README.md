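# ernetics

Quantitative analysis of ER network topology, protein mobility and
targeting of membrane proteins to the inner nuclear membrane (INM) —
with a synthetic-microscopy generator providing ground truth for every
analysis stage.

## The scientific problem

Newly made INM proteins reach the nuclear envelope (NE) by lateral
diffusion through the ER membrane system, passage through nuclear pore
complexes, and retention on nuclear partners (the diffusion–retention
mechanism). Because the route runs through the peripheral ER, the
*connectivity* of the polygonal tubule network — maintained by
Atlastin-mediated homotypic fusion — controls how fast proteins exchange
over long distances and therefore how fast they accumulate at the NE.
Probing this experimentally combines four quantitative readouts, all
implemented here:

* **NE enrichment** (`ernetics.nequant`) — the fraction of reporter
  fluorescence in a thin band around the nuclear contour (230 nm
  outwards, 920 nm inwards at the contour) relative to the total in
  band + ER, optionally rescaled to percent-at-NE against a pre-release
  baseline fraction F₀ (0.16 for the RUSH cohort):
  `%NE = 100·(F − F₀)/(1 − F₀)`.
* **FRAP / FLIP photokinetics** (`ernetics.photokinetics`) — full-scale
  normalized recovery curves fitted with a shared-plateau double
  exponential `F(t) = M·(1 − a·e^(−k₁t) − (1−a)·e^(−k₂t))`; the plateau
  M is the mobile fraction, t½ solves `F = M/2`, and the apparent
  diffusion coefficient is `D = (r_n² + r_e²)/(8·t½)` for the bleach
  ROI's nominal and equal-area-circle radii. FLIP reports time-to-50%
  loss in the ring around the bleach spot ("donut") and in a distant
  region.
* **ER network topology and dynamics** (`ernetics.ernet`) — the
  peripheral ER as a planar spatial graph; polygon (closed-face) counts
  in 100 μm² windows via Euler's relation `F = E − V + C`;
  tubule-attachment events scored successful/unsuccessful against a
  junction-stability threshold; and Brownian particles diffusing along
  the tubule graph for in-silico FRAP, linking connectivity to mobility.
* **Accumulation kinetics** (`ernetics.inmkinetics`) — a three-pool
  linear compartment model (ER ⇌ NE-free ⇌ NE-bound) for NE accumulation
  after synchronous release, fitted for t½ on the span
  (plateau − baseline), with bootstrap comparison of conditions.

Everything runs on synthetic data from `ernetics.synthkit`: rendered
cells (nucleus, NE ring, tubule network) with Poisson + Gaussian noise
and Gaussian PSF blur, photobleaching movies driven by the particle
engine, attachment-event movies with a known success probability, and
accumulation time series with known rates — each paired with a
`GroundTruth` record, so parameter recovery is testable end to end.

## Worked example

```python
import numpy as np
from ernetics import synthkit, nequant, inmkinetics
from ernetics.core import CellGeometry, ImagingConfig

config = ImagingConfig(pixel_size_nm=100, psf_sigma_nm=100,
                       read_noise_sd=2.0, width_px=160, height_px=160)
geometry = CellGeometry.boxed(16, 16, nucleus_radii_um=(4.0, 3.2))
graph = synthkit.generate_er_graph(16, 16, 0.5, prune_fraction=0.0, seed=3)

# simulate a RUSH release with t1/2 = 12 min, quantify, refit
model = inmkinetics.DiffusionRetentionModel(k_in=np.log(2) / 12,
                                            baseline_fraction=0.16)
t = np.arange(0, 95, 5.0)
movie, truth = synthkit.simulate_accumulation_series(
    model, t, geometry, graph, config, seed=11, total_photons=2e6)

spec = nequant.NEBandSpec(pixel_size_nm=100)  # 230 nm out / 920 nm in
fractions = [nequant.measure_cell(movie.frame(i).channel("dapi"),
                                  movie.frame(i).channel("gfp"), spec)[0]
             .fraction for i in range(movie.n_frames)]
fit = inmkinetics.fit_accumulation(
    inmkinetics.AccumulationCurve(t, np.clip(fractions, 0, 1)),
    baseline_fraction=0.16)
print(fit.summary())
```

prints

```
NE-accumulation fit (reduced diffusion-retention model)
========================================================
parameter                 estimate     std err
span                        0.8407      0.0031
rate_per_min                0.0597      0.0009
--------------------------------------------------------
baseline_fraction           0.1600
plateau                     1.0007
t_half_min                 11.6017
rss                       0.001045
```

i.e. the pipeline recovers the generating half-time (12 min) within a
few percent from noisy rendered images: `span` is the fitted
accumulation amplitude above the 0.16 baseline, `rate_per_min` the
effective exchange rate k, and `t_half_min = ln2/k` the time to half
the accumulation span.

A command-line interface wraps the same machinery
(`ernetics simulate ...`, `ernetics quantify-ne`, `ernetics frap`,
`ernetics flip`, `ernetics network ...`, `ernetics kinetics ...`,
`ernetics run --config cfg.json`).

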
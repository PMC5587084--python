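# Methods

This note documents the models, numerical choices and study conditions
behind `ernetics`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and unit conventions

Physical coordinates are micrometres with the image origin at the
top-left and y increasing downward; a pixel `(row, col)` has its centre
at `((col+0.5)·px, (row+0.5)·px)`. Pixel-space intervals are half-open.
Times are seconds for imaging and photobleaching, minutes for the slow
NE-accumulation kinetics; field names carry their unit (`_nm`, `_um`,
`_s`, `_min`). All randomness flows through `numpy.random.default_rng`
seeded explicitly; identical seeds and parameters give bit-identical
graphs, event logs and pre-noise intensity fields.

## Synthetic microscopy (synthkit)

**Network generator.** The peripheral ER is emulated by the Voronoi
tessellation of a uniform random point set (expected density
`node_density_per_um2`, default 0.5 /μm²) clipped to the field — a
planar polygonal mesh resembling the interconnected ER of a healthy
cell. A single connectivity knob, `prune_fraction`, removes
`floor(p·E)` edges uniformly at random; the pruned graph is a subgraph
of the full one, so pruning can never create polygons. Edges shorter
than `min_edge_um` (default 0.3 μm) are *contracted* (endpoints merged
at the midpoint), not dropped: contraction keeps faces closed — a
dropped sub-resolution edge would leave a gap that no image of the
network could show, making image-based polygon counts disagree with the
generator's own bookkeeping — and it bounds the shortest edge from
below, which the diffusion engine's step-size precondition needs.
Contraction is a vertex perturbation of at most half the cutoff;
planarity is re-checked by a brute-force crossing oracle in the tests.

**Rendering.** Tubules and the NE ring are sub-resolution structures
(~100 nm wide against a ≥200 nm PSF), so they are rendered as
line/arc photon deposits: expected photons are spread uniformly per
unit length (dense sampling at 5 points per pixel, accumulated with
`np.add.at`), which conserves the photon budget to rasterization
accuracy (<0.5%). The reporter channel splits `total_photons` as
`ne_fraction_true` on the nucleus-ellipse perimeter and the remainder
along the tubules, with tubule pieces inside the nucleus clipped away
(the peripheral ER surrounds the nucleus). The nucleus channel is a
filled ellipse. Imaging applies a Gaussian PSF, then Poisson shot noise
on expected photons, then additive Gaussian read noise — the standard
confocal model. Defaults: pixel 100 nm; PSF σ = 100 nm, the
diffraction-limited Gaussian width of a 63×/1.4 NA objective at 488 nm
(FWHM ≈ 235 nm); read noise 2 photons.

**Study conditions (SNR ≈ 10).** No photon budget accompanies the
protocols this generator emulates, so the default condition is an
artifact choice made once: a 16 × 16 μm field at density 0.5 /μm²
(~330 μm of tubule) with 2·10⁶ reporter photons, giving tubule-pixel
peaks of ~50–100 photons (Poisson SNR ≈ 7–10). Passing tests at these
conditions demonstrates the machinery recovers known truth at realistic
noise; it does not certify performance on real images with debris,
uneven illumination or out-of-focus light, which the generator does not
emulate (nor does it emulate 3-D stacks, microtubule-guided tubule
pulling, or membrane mechanics).

**Photobleaching movies.** Frames are rendered from the positions of
fluorescent particles diffusing on the graph (engine below) at every
frame interval; bleach events switch fluorescent particles inside the
event ROI dark with the scheduled survival probability. One schedule
type covers FRAP (single event; default 3 pre-bleach frames, 4 s
interval) and FLIP (repeated events; default spot r = 3.16 μm every
4.5 s over a 12-min course, 2 pre-bleach frames). Bleach events are
placed immediately before the first post-bleach frame so that frame
images the depleted state rather than seconds of refill. A fixed
`immobile_fraction` of particles, chosen uniformly at initialization,
never moves — the simplest mechanism producing a recovery plateau
below 1.

**Attachment dynamics.** Tubule-growth events form a spatial Poisson
process (`growth_rate_per_um2_s` × area × duration expected events;
default movies 1 frame/s for 60 s). Each event succeeds with
probability `attach_success_p`; successful junctions persist for
`stability_s` plus an exponential tail (mean 3× the threshold),
unsuccessful ones detach uniformly before 0.8× the threshold, so labels
and lifetimes are consistent by construction.

## NE-enrichment quantification (nequant)

Nuclei are segmented from the nucleus channel by global Otsu
thresholding, hole filling and connected components, discarding
components below `min_area_um2`. The NE band is the morphological
dilation of the nucleus mask by `round(230/px)` pixels minus the
erosion by `round(920/px)` pixels (round-half-up, minimum 1 px); the
eroded interior is excluded from every sum. The statistic is
`i_ne/(i_ne + i_er)` over background-subtracted pixels (scalar
background, default the median outside all masks, clamped at zero).

The ER mask comes from thresholding the reporter channel, with two
guards that matter at high NE enrichment: the Otsu threshold is
computed over reporter pixels *outside* the band, interior and a 3-px
halo margin (otherwise the bright NE ring and its PSF halo dominate
the histogram and push the cut above the dim tubules), and the
thresholded tubule mask is dilated 2 px to include the tubules' PSF
wings, keeping ER capture efficiency comparable to the band's. The
same halo margin is excluded from the final ER mask so NE halo photons
are not booked as ER signal. A fixed threshold overrides the automatic
one. Frames with several nuclei are quantified per cell, partitioning
the ER mask by nearest nucleus.

Percent-at-NE uses the affine rescale `100·(F − F₀)/(1 − F₀)` clamped
to [0, 100], so the pre-release state maps to 0% and complete NE
localization to 100%; `F/F₀` is available as a `ratio` mode. The RUSH
baseline F₀ = 0.16 is applied as a cohort constant by default (it is a
cohort average over 59 cells in the protocol it comes from), with a
per-cell option (`baseline_fraction=None` uses each curve's first
point). The Golgi-enrichment fraction I(Golgi)/I(cell) follows the same
normalization.

## FRAP / FLIP (photokinetics)

Full-scale normalization: corrected
`C(t) = (target − background)/(reference − background)`, then
`F(t) = (C − C(t₀⁺))/(mean pre-bleach C − C(t₀⁺))` with `t₀⁺` the first
post-bleach frame, using the mean of all pre-bleach frames. The fit is
`F(t) = M·(1 − a·e^(−k₁t) − (1−a)·e^(−k₂t))` over post-bleach samples
only (≥8 required), parameterized with one shared plateau and convex
weights to avoid the degenerate two-amplitude regime; bounds
M ∈ [0, 1.05], a ∈ [0, 1], rates ∈ [10⁻⁶, 10³] /s; nine multi-starts
(three weights × three rate spreads around the empirical half-rise)
with trust-region least squares, keeping the lowest residual; k₁ ≥ k₂
enforced by relabelling. t½ is found numerically on the fitted curve by
bracketed root-finding (well-defined for any a); an all-zero curve
returns M = 0 with t½ undefined. Standard errors come from the
Gauss–Newton covariance at the optimum.

The t½→D conversion uses the simplified confocal large-ROI relation
`D = (r_n² + r_e²)/(8·t½)` with the rectangular bleach ROI mapped to
its equal-area circle (`r_e = sqrt(area/π)`, `r_n = r_e` by default;
both overridable). The exact equation of the conversion is a documented
package choice — standard for large-ROI confocal FRAP — since
different radius conventions exist in the literature.

FLIP metrics take background/neighbor-corrected curves normalized to a
pre-bleach mean of 1 (checked to 5%): loss is `1 − F(t)`, t50 the first
linear-interpolated crossing of 0.5, and the distant region is flagged
stable when its final loss stays below 0.1. Neighbor correction divides
by an unbleached neighbor-cell curve and renormalizes.

## ER-network analysis (ernet)

Graphs are planar spatial multigraphs (parallel tubule arcs between the
same junction pair legitimately bound a polygon). Polygon counts use
Euler's relation `interior faces = E − V + C`, validated against a
brute-force crossing check; the independent cross-check in the tests
enumerates faces by walking the rotation system and counting
positive-area walks. Analysis windows are 100 μm² squares by default;
edges crossing the window boundary are cut there and the cut points
become degree-1 nodes, so partially visible polygons are opened and not
counted — the package's reading of how a human scorer counts fully
visible polygons (the original scoring protocol does not state its
convention).

Skeleton-to-graph recovery thins the Otsu-binarized (or
fixed-threshold) image, classifies junction (≥3 skeleton neighbours)
and endpoint pixels as nodes, traces paths between them, removes spur
branches shorter than 3 px, contracts junction nodes closer than 4 px
(thinning fractures a blurred three-way meeting into several junction
pixels whose micro-faces would inflate the polygon count), and splices
out degree-2 nodes. Edge geometry follows the traced pixel path, so
the planar embedding survives.

Attachment scoring calls an event successful when its junction persists
at least `stability_s` (default 5 s at 1 frame/s — longer than a
transient touch, far shorter than the movie; configurable), reporting
counts, the success fraction, and rates per 100 μm² per minute.

**Diffusion engine.** Mobile particles take 1-D Gaussian steps of sd
`sqrt(2·D·dt)` along their current edge; at a node the continuing edge
is drawn uniformly among incident edges (the arrival edge included,
which reflects at degree-1 tips — the simplest unbiased rule; the
stationary distribution is uniform per unit length, verified by χ²).
The step-size precondition `sqrt(2·D·dt) ≤ L_min/2` makes multi-node
hops within one step rare; the rare overshoot past a second node is
clamped at the far end of the new edge (a bias bounded by the tail of
a half-edge-length Gaussian step). Particle number is conserved
exactly; bleaching only toggles a fluorescence flag.

**Connectivity→mobility scan.** For each prune level the scan runs the
full FRAP protocol (bleach, render, extract, normalize, fit) on the
pruned network and reports seed-averaged fitted mobile fraction and
t½. The mobile fraction is deliberately the fraction exchanging on the
protocol's finite timescale, as in the bench assay, so slower recovery
on a sparser network lowers it even before components disconnect. Scan
conditions: D = 0.3 μm²/s (a realistic apparent D for an ER membrane
protein), 240 s protocol, 5000 particles, 3 seeds per level. FLIP
simulations use D = 3 μm²/s, appropriate for a soluble luminal
reporter.

## Accumulation kinetics (inmkinetics)

The three-pool linear system (ER, NE-free, NE-bound) is the package's
minimal embodiment of diffusion–retention; its rates are effective:
`k_in` lumps long-range ER diffusion and NPC passage (the step network
connectivity controls), `k_on`/`k_off` the interaction with nuclear
partners. It is solved exactly by matrix exponential — no ODE-solver
tolerance enters. The reported NE fraction is
`baseline + (1 − baseline)·(NEf + NEb)/total`, so the pre-release frame
sits at the baseline.

Fitting uses the reduced two-pool exchange (retention folded into an
effective plateau): `F(t) = F₀ + S·(1 − e^(−kt))` with span
S = plateau − F₀ and overall rate k, from which effective
`k_in = k·S/(1 − F₀)` and `k_out = k − k_in` follow. t½ = ln2/k is
the time to half the accumulation *span* — the natural half-time for a
readout that starts at a nonzero baseline. A curve whose observed span
is below 3× its noise estimate (median absolute first difference /√2)
raises `NoAccumulation`. Condition comparison fits each condition's
mean curve (cells must share the time grid) and bootstraps cells with
replacement for a percentile 95% CI on the t½ ratio; whether to fit
mean curves or average per-cell fits was an open choice — mean-curve
fitting is the default for robustness at 5-min sampling, per-cell
fitting remains available via `fit_accumulation` on individual curves.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the package's
defaults: 160–200 px frames, 3000–8000 particles per photobleaching
simulation, 20 seeds per recovery study, 150–300 bootstrap resamples,
and 12 cells per condition in the release-experiment comparison. The
recovered quantities (NE-fraction error ≤0.05, t½ within 10–15%,
Spearman ρ ≤ −0.9 for the connectivity–mobility scan) are statements
about these conditions; larger fields and particle counts tighten the
Monte-Carlo scatter roughly as 1/√n.

## Known limitations

* The generator's cells are single, convex, and uniformly illuminated;
  segmentation robustness to clumped nuclei or illumination gradients
  is untested.
* The diffusion engine is 1-D-on-a-graph; it does not model tubule
  volume, sheet regions, or the 3-D geometry that makes experimental
  "apparent D" a composite quantity — which is why in-silico FRAP is
  used for orderings and fractions, not absolute D calibration.
* The double-exponential FRAP model is phenomenological; no
  reaction–diffusion FRAP fitting or spatial profile analysis is
  included.
* Window-clipped polygon counting and the 5-s junction-stability
  threshold encode explicit conventions where the original manual
  scoring protocols stated none.
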
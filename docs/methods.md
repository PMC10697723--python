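# Methods

This note documents the models behind each analysis stage, the synthetic-data
generators that stand in for raw microscopy and metabolomics, the defaults
that matter, and the known limitations. Units are µm, s, ns, mM, mL, h and
fmol/cell/h (exchange rates) or mmol/gDW/h (model units) throughout.

## 1. Vessel diffusive permeability

**Measurement model.** For a cylindrical channel of radius `r` in a gel, the
wall flux per unit area follows Fick's first law,
`J = P_D (c_vessel − c_ECM)`. While the matrix concentration near the wall is
negligible compared to the vessel, the tracer gained by the matrix per unit
time equals `P_D c_vessel` per unit wall area, which gives the estimator

```
P_D = (r / 2) · (dI_ECM/dt) / I_vessel(0)
```

with `I_ECM` the integrated matrix fluorescence normalized by the channel
cross-section `πr²` (so intensity units cancel) and `I_vessel(0)` the mean
background-subtracted vessel intensity over the first 3 frames.

**Forward model (generator).** 1D radial finite-volume diffusion on
`r ∈ [R, R + 600 µm]` with a membrane boundary `J = P(c_vessel − c_wall)`, a
reflecting outer face, and a well-mixed vessel whose effective volume is 25×
the channel volume (the channel communicates with media reservoirs, so its
concentration decays slowly). Time stepping is Crank–Nicolson on the
symmetric conductance Laplacian, which conserves total tracer to machine
precision; the default grid (1.5 µm cells, ≤ 50 ms substeps) changes the
matrix trace by < 1% under refinement. Defaults: `r = 150 µm` (a 300 µm
needle-molded channel), frames every 2 s for 5 min, matrix diffusivity
`D = 400 µm²/s` — FITC's free-solution diffusivity at 37 °C
(Stokes–Einstein scaling of the ~425–490 µm²/s room-temperature value) with
mild hindrance in dilute collagen.

**Fit-window selection.** The matrix trace of this physics behaves like
`a·t − b·t^{3/2}`: smoothly concave curves of this family keep an OLS `r²`
near 0.99 over arbitrarily long windows, so a "longest window with
r² ≥ 0.95" rule would silently average away the early-time slope and bias
`P_D` low for every permeability. The default window instead expands a
prefix (minimum 5 frames) until the quadratic term of a local polynomial fit
becomes statistically significant (|t| > 2): noise-free concave traces stop
at the 5-frame minimum (the least-biased slope available at the 2 s
cadence), exactly linear traces use the whole movie, and noisy traces grow
until curvature is resolvable above the noise — a bias–variance trade made
by the data. An explicit window remains fully supported.

**Validity regime and a real limitation.** The estimator assumes the wall,
not the matrix, limits transport. The wall concentration rises on the
timescale set by `h = P/D`: the boundary flux decays as
`exp(h²Dt)·erfc(h√(Dt))`. At `P = 1 µm/s` this costs ≈ 10% over the first
fit window (the recovery error measured by the acceptance script); at
`P = 0.1 µm/s` it is negligible. At `P = 10 µm/s` the factor is already ≈ 0.5
by the first 2 s frame — transport is diffusion-limited, the
`c_vessel ≫ c_ECM` assumption fails within one frame interval, and the slope
estimator saturates near the matrix conductance, underestimating `P` by
≳ 50%. No frame-rate-2 s analysis of this geometry can recover such
permeabilities (it would need `D ≈ 3×10⁴ µm²/s`); the acceptance suite keeps
this regime visible as a failing recovery rather than masking it.
Practically, measured `P_D` values for leaky/empty channels are lower bounds.

## 2. Invasion morphometry

Segmentation is Gaussian blur (σ = 2 px) → Otsu threshold → connected
components → minimum-area filter (25 µm²); all steps deterministic. Shape
descriptors use the field's standard conventions: circularity `4πA/P²`
capped at 1.0 (digital perimeters can exceed it slightly; the raw value is
kept), aspect ratio from the second-central-moment equivalent ellipse.
Coordinates are pixel centers, 0-based, with x increasing toward the
endothelial channel; invasion distance is the signed nucleus displacement
`x − x_edge` (both signed and positive-only means are reported, since the
handling of cells behind the edge is a genuine convention choice).
Per-replicate normalization to a control mean is supported for pooling.

Adhesion counting: white top-hat (radius 4 px) → per-cell Otsu on within-cell
intensities → connected puncta above a minimum area. Counting is restricted
to a border-eroded cell core because the top-hat leaves a rim artifact along
cell boundaries. The collagen contraction ratio applies a Hessian ridge
("tubeness", Sato) filter at scale 2 px to the reflectance image, builds the
peripheral region as a 10 µm dilation ring around cells, and compares mean
reflectance on fiber pixels between ring and bulk; if fibers cover < 1% of a
region the full region is used (this makes the homogeneous-field ratio
exactly 1). The ratio is exactly invariant to global intensity scaling.
Motility metrics consume externally produced tracks (20-min cadence by
default) and report total-path-over-total-time speeds in µm/min plus
origin-centered paths for rose plots.

**Generators.** Invasion fields place non-overlapping ellipses with normal
x-positions (SD 100 µm) around the channel edge plus an optional bias; the
ground-truth aspect ratio grows as `1 + (x − x_edge)/100 µm` with 15%
lognormal scatter, emulating elongation at the invasion front. Disk fields,
puncta images (diffuse cytoplasm + bright puncta at SNR 10) and fibrillar
reflectance fields (random 3-px-wide line segments, ring contrast applied
multiplicatively) provide ground truth for the remaining operations. What
these generators do *not* emulate: PSF blur, photobleaching, drift, 3D fiber
architecture, touching cells — so passing tests demonstrate correctness of
the measurement chain, not robustness to every real-microscopy artifact.

## 3. NADH FLIM

Decays are fit past the histogram peak to
`A[a₁e^(−t/τ₁) + (1−a₁)e^(−t/τ₂)] + bg` by trust-region least squares with
Poisson weights (`var = max(counts, 1)`), lifetimes parameterized on a log
scale, and two initializations (τ = (0.3, 2.0) and (0.5, 3.0) ns; the best
reduced χ² wins) because bi-exponential fits are initialization-sensitive.
Components are reported in canonical order τ₁ < τ₂; if the converged ratio
τ₂/τ₁ < 1.5 the components are not identifiable and the fit is re-done
mono-exponentially with a₁ = 1. The summary statistic is the
amplitude-weighted mean lifetime `τ_m = a₁τ₁ + a₂τ₂`. Histograms under 100
photons are fit but flagged low-confidence. Per-cell summaries
photon-weight the pixel lifetimes and sum intensities exactly; cells are
tagged invaded/non-invaded by centroid position relative to the channel edge.

The generator integrates the model over 256 bins spanning ≥ 5τ₂ and Poisson
samples with an expected total of `photon_budget` counts. The default is a
delta IRF (fit start at the peak); a Gaussian IRF convolution is available
behind a flag but is not part of the default conditions, so the recovery
results say nothing about IRF-deconvolution accuracy. Raw summed counts
stand in for "NADH intensity"; no background or excitation-power
normalization is modeled.

## 4. Exchange fluxomics

Blank correction subtracts cell-free medium drift while preserving the t = 0
anchor: `corrected(t) = sample(t) − (blank(t) − blank(0))`. The endpoint
exchange rate uses the exact growth integral

```
v = ΔC · V / ∫₀ᵀ N(t) dt,   ∫₀ᵀ N dt = N₀ (e^{µT} − 1)/µ  (→ N₀T as µ → 0)
```

with µ inferred from the endpoint cell counts when not supplied;
uncertainty is first-order propagated from the endpoint concentration SDs.
Exponential interpolation (rather than an endpoint average) matters because
tumor lines grow appreciably over 48 h. Sign convention everywhere:
positive = secretion. log₂ fold changes are `log₂(C(T)/C(0))` and are
reported as unavailable (not 0) when the baseline is unquantified.
Conversion to model units uses a configurable 300 pg dry mass per cell
(`3×10⁻¹⁰ gDW/cell`), a typical mammalian-cell dry mass; the round trip is
exact.

The generator produces 0/24/48 h series with multiplicative measurement
noise, matched cell counts, paired blanks (optional abiotic drift applied to
sample and blank alike), and clipping at 0 mM with a flag. Bounds built from
endpoint rates are the default; per-interval rates are possible by slicing
the series.

## 5. Constraint-based modeling

**Network.** The packaged network is an original reduced reconstruction
(58 reactions, 40 metabolites) covering the pathway roles a core tumor
energy model needs: split upper/lower glycolysis, lactate dehydrogenase,
pyruvate dehydrogenase, a lumped TCA cycle with pyruvate carboxylase
anaplerosis and a lumped malic-enzyme cataplerosis (`oaa → pyr + CO₂`, which
also enables net glutaminolysis to lactate), oxidative phosphorylation
(P/O 2.5) with O₂ exchange, an ATP demand reaction, glutaminase/glutamine
synthetase/glutamate dehydrogenase and the transaminases, serine/glycine/
proline/asparagine synthesis, lumped catabolic sinks for the
measurement-constrained essential amino acids, UDP-glucuronate and
UDP-N-acetylglucosamine synthesis feeding hyaluronic-acid synthase, a
biomass reaction consuming glucose-6-P, ATP and all 20 amino acids, and one
exchange reaction per medium metabolite. ATP/ADP and NAD⁺/NADH are conserved
pairs in every reaction; FADH₂ is folded into NADH, GTP into ATP, and the
serine→glycine one-carbon unit is routed to CO₂ (documented lumpings — the
network is stoichiometrically consistent but not atom-balanced). JSON is the
canonical format; SBML import/export goes through cobrapy.

**Constraints.** Each measured, non-omitted metabolite pins its exchange to
`[v − k·SD, v + k·SD]` (k = 1), intersected with the default bounds. Eight
amino acids (glycine, leucine, lysine, phenylalanine, threonine, tryptophan,
tyrosine, valine) are left at default bounds by default so the LP stays
well-behaved; the remaining 12, including glutamine and glutamate, are
constrained. Growth is lower-bounded by the measured growth rate (growth is
a requirement, not the objective), and O₂ exchange is bounded by the
respirometry-derived rate.

**Solving.** `scipy.optimize.linprog` (HiGHS) maximizes HA synthesis subject
to `S·v = 0` and bounds (feasibility/optimality tolerances 1e-9). Because LP
optima are degenerate, a parsimonious second stage minimizes Σ|v| at the
fixed optimal objective so per-reaction fluxes are comparable across
conditions. Correctness is checked against an exhaustive vertex-enumeration
oracle on small random polytopes and against cobrapy on the packaged
network.

**Ensemble.** What an "n-simulation" ensemble varies had to be decided: the
only stochastic element available is measurement uncertainty, so each run
redraws every measured rate from a truncated normal (truncated to the
default bounds), rebuilds the interval constraints around the draw, and
re-solves; infeasible draws are counted and a warning fires if they exceed
half the runs. The sampler is seeded and bit-reproducible, and pluggable if
a different uncertainty model is wanted. Default n = 1000; the demo
pipeline and tests use 100–200 to keep runtimes in seconds.

**Demo conditions.** Two measured-style rate tables emulate tumor cells in
endothelial-conditioned vs control medium: the conditioned table has higher
glucose uptake and lactate secretion, less glutamate and asparagine
secretion, more proline secretion, higher O₂ consumption and slightly faster
growth. The resulting contrast (higher HA synthesis, ATP demand, upper
glycolysis, pyruvate→lactate and glutamate→α-KG flux) is a structural
consequence of the network given those inputs, not a fitted outcome.
Absolute fluxes are in nominal model units and are not comparable to any
specific genome-scale reconstruction.

## 6. Pipeline and reproducibility

All randomness flows through one seeded `numpy.random.Generator` per
generator call; no global RNG state is used or mutated. Pipeline stages
communicate only through declared files in the run directory; the manifest
records the config snapshot, seed, package version and SHA-256 of every
output. Re-running the same config and seed reproduces every stochastic
output byte-for-byte (the manifest timestamp is the only permitted
difference), and the Markdown report generator is idempotent. Problem sizes
in the shipped tests and acceptance script (60–300 s movies, 20–100 cells,
4–20 pixels of FLIM, ensembles of 25–200) were chosen so the whole suite
runs in a few minutes on one CPU while keeping every statistical check at
its stated power.

## Known limitations

- The permeability estimator is a lower bound in the diffusion-limited
  regime (§1); per-position permeability maps and convective transport are
  out of scope.
- Morphometry is 2D (projections); no volumetric descriptors or track
  linking.
- FLIM omits IRF deconvolution by default and vendor file formats entirely;
  phasor analysis is out of scope.
- Fluxomics assumes exponential growth between counted timepoints and
  endpoint-based rates.
- The metabolic network is a reduced stand-in with lumped cofactor
  bookkeeping; no flux variability analysis, dynamic FBA, or thermodynamic
  constraints.
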
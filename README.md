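# vesselflux

Quantitative analysis of microfluidic tumor–microvessel co-cultures, built as
a reusable Python library. Tumor cells cultured beside an endothelialized
channel in a collagen gel invade more, elongate, and rewire their energy
metabolism; characterizing that requires five very different measurements,
and `vesselflux` implements the full analysis chain for all of them, together
with synthetic-data generators that produce every input with known ground
truth:

1. **Vessel permeability** — the diffusive permeability of the endothelial
   barrier from a fluorescein time-lapse, via Fick's first law for a
   cylindrical channel: `P_D = (r/2) · (dI_ECM/dt) / I_vessel(0)`, where
   `I_ECM` is the matrix fluorescence (integrated density normalized by the
   channel cross-section) and `I_vessel(0)` the initial channel intensity.
2. **Invasion morphometry** — segmentation (Gaussian blur → Otsu → connected
   components), per-cell circularity `4πA/P²` and equivalent-ellipse aspect
   ratio, signed invasion distances from the channel edge, pFAK puncta
   counts, peri-cellular collagen contraction ratios (Hessian *tubeness*
   filtering), and 2D motility metrics.
3. **NADH FLIM** — weighted nonlinear least-squares fits of two-component
   photon decays `A[a₁e^(−t/τ₁) + (1−a₁)e^(−t/τ₂)] + bg` with Poisson
   weights; the amplitude-weighted mean lifetime `τ_m = a₁τ₁ + a₂τ₂`
   separates free (glycolytic) from protein-bound (oxidative) NADH.
4. **Exchange fluxomics** — per-cell secretion/uptake rates from 0/24/48 h
   medium concentrations under exponential growth,
   `v = ΔC·V / ∫₀ᵀ N(t)dt` (fmol/cell/h), with blank correction, error
   propagation and log₂ fold-change summaries.
5. **Constraint-based modeling (FBA)** — a packaged ~50-reaction core tumor
   network (glycolysis, TCA, oxidative phosphorylation, glutaminolysis,
   hyaluronic-acid synthesis, biomass, exchanges for all 20 amino acids).
   Measured rates become exchange-flux bounds `[v − SD, v + SD]`; the LP
   maximizes HA synthesis subject to `S·v = 0`, with a parsimonious second
   stage, and a truncated-normal constraint-resampling ensemble (n = 1000 by
   default) propagates measurement uncertainty into flux space.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/01_vessel_permeability.py
```

```
frames: 151 (every 2 s)
ground-truth permeability: 1.00 um/s
estimated P_D:             0.887 um/s
fit window: 0-12 s, slope = 11.935 +/- 0.211 a.u./s
```

A 5-minute movie of a channel with true wall permeability 1 µm/s (2% imaging
noise) is simulated and re-analyzed; the estimator recovers the truth to
about 10%, limited by tracer build-up at the matrix side of the wall during
the fit window. And the condition comparison:

```bash
python examples/05_fba_conditions.py
```

```
          mean_huvec_cm  mean_ctrl_cm  difference           direction
HEX1             0.5671        0.3994      0.1677  higher_in_huvec_cm
LDH              0.7654        0.5267      0.2387  higher_in_huvec_cm
GDH              0.0725        0.0173      0.0552  higher_in_huvec_cm
ATPM             1.2086        0.4284      0.7802  higher_in_huvec_cm
HAS              0.0770        0.0451      0.0320  higher_in_huvec_cm
```

Endothelial-conditioned-medium-style constraints (more glucose uptake and
lactate secretion, less glutamate secretion, higher O₂ consumption) push the
ensemble toward higher hyaluronic-acid synthesis (HAS), ATP turnover (ATPM),
upper glycolysis and glutamate→α-ketoglutarate flux — an energy-rich,
invasion-permissive phenotype.

The same stages are scriptable from a thin CLI (`vesselflux simulate|
permeability|morphometry|flim|fluxes|fba|run|report`); `vesselflux run --out
dir` executes the whole chain and `vesselflux report --dir dir` renders a
Markdown summary. Every run directory carries a manifest (seed, config,
SHA-256 of outputs) and re-running a manifest's config reproduces all
stochastic outputs bit-for-bit.

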
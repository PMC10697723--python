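"""Estimate vessel diffusive permeability from a synthetic tracer movie.

Simulates FITC-like dye leaking from a 300 µm channel (membrane permeability
1 µm/s, frames every 2 s for 5 min), then recovers the permeability from the
early-time slope of the matrix signal and the initial vessel intensity:
P_D = (r/2) * (dI_ECM/dt) / I_vessel(0).
"""
from vesselflux import SimulationConfig, estimate_permeability, simulate_vessel_diffusion

cfg = SimulationConfig(seed=1, true_permeability=1.0, noise_levels={"diffusion": 0.02})
series = simulate_vessel_diffusion(cfg)
result = estimate_permeability(series)

print(f"frames: {series.n_frames} (every {cfg.frame_interval:.0f} s)")
print(f"ground-truth permeability: {cfg.true_permeability:.2f} um/s")
print(f"estimated P_D:             {result.p_d:.3f} um/s")
print(f"fit window: {result.fit_window[0]:.0f}-{result.fit_window[1]:.0f} s, "
      f"slope = {result.slope:.3f} +/- {result.slope_stderr:.3f} a.u./s")
print()
print("The estimate sits within ~10% of truth: the early-time matrix slope is")
print("proportional to the wall flux while the vessel still dominates the")
print("concentration difference across the endothelium.")
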
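"""Fit two-component NADH decays and recover the mean lifetime.

Free NADH decays fast (~0.4 ns), protein-bound NADH slowly (~2.5 ns); the
amplitude-weighted mean lifetime tm = a1*tau1 + a2*tau2 summarizes the
glycolytic/oxidative balance. Here 10^5-photon histograms are generated and
refit per pixel.
"""
import numpy as np

from vesselflux import SimulationConfig, fit_biexponential
from vesselflux.synthetic import simulate_flim_decays

cfg = SimulationConfig(seed=3, flim_a1=0.8, flim_tau1=0.4, flim_tau2=2.5,
                       photon_budget=1e5)
hists, truth = simulate_flim_decays(cfg, n_pixels=8)
fits = [fit_biexponential(h) for h in hists]

taus = np.array([f.mean_tau for f in fits if f.converged])
print(f"pixels fit: {len(fits)}  (converged: {sum(f.converged for f in fits)})")
print(f"truth:  a1=0.80  tau1=0.40 ns  tau2=2.50 ns  tm={truth['mean_tau_ns']:.3f} ns")
f = fits[0]
print(f"pixel 0: a1={f.a1:.2f}  tau1={f.tau1:.2f} ns  tau2={f.tau2:.2f} ns  "
      f"tm={f.mean_tau:.3f} ns  chi2_r={f.chi2_reduced:.2f}")
print(f"median fitted tm over pixels: {np.median(taus):.3f} ns "
      f"({100 * abs(np.median(taus) - truth['mean_tau_ns']) / truth['mean_tau_ns']:.1f}% "
      "from truth)")
print()
print("The mean lifetime is recovered to a few percent even though the")
print("individual amplitudes/lifetimes trade off against each other.")
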
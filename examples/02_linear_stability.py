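"""Linear stability: predicting the dot spacing before simulating.

The dot subsystem's reaction Jacobian at its homogeneous steady state,
combined with the two diffusivities, gives the dispersion relation
sigma(k).  Its maximizer predicts the pattern wavelength; a full
simulation on a plain square domain should reproduce it.
"""

from dotstripe import (
    DotParams,
    FourSpeciesModel,
    GridSpec,
    SolverConfig,
    dot_linear_stability,
    estimate_wavelength,
    simulate,
)

p = DotParams()
k_max, lam_pred, sigma_max = dot_linear_stability(p)
print(f"fastest-growing wavenumber k_max = {k_max:.4f}")
print(f"predicted wavelength 2*pi/k_max  = {lam_pred:.2f}")
print(f"peak growth rate sigma_max       = {sigma_max:.4f}  (> 0: Turing unstable)")

grid = GridSpec(192, 192, 1.0)
cfg = SolverConfig(dt=0.05, T=150.0, seed=1, noise_amp=0.02, snapshot_every=3000)
traj = simulate(FourSpeciesModel(dot=p), grid, cfg)
lam_meas = estimate_wavelength(traj.final_fields["A"], traj.final_masks)

print(f"measured wavelength (192x192 run) = {lam_meas:.2f}")
print(f"relative error                    = {100 * abs(lam_meas / lam_pred - 1):.1f}%")
print()
print("The agreement shows the nonlinear pattern inherits its spacing from the")
print("linear instability; scaling both diffusivities by 4 doubles the spacing.")
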
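"""Grade image quality by correlation spectroscopy.

Computes the (R, B, N) triplet along the optical axis for the sectioned
image and for the closed-pinhole frame: R is the autocorrelation FWHM in
nm (resolution), B the contrast-weighted brightness, N the relative
noise variance at zero lag.
"""

from splitpin import (
    PhasorCalibration,
    SimulationConfig,
    decompose,
    quics_report,
    simulate_stack,
)

stack, closed = simulate_stack(SimulationConfig(S=100.0, seed=7))
split = decompose(stack, PhasorCalibration.simulation_default(), "sum").split_image

for name, img in [("sectioned (sum)", split), ("closed 0.2 A.U.", closed)]:
    rep = quics_report(img, axis="z")
    print(f"{name:16s} R_z = {rep.R:6.1f} nm   B = {rep.B:7.1f}   "
          f"N = {rep.N:6.3f}")
# The sectioned image resolves a thinner axial slice (smaller R_z) than
# the closed pinhole while keeping a lower noise level N.
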
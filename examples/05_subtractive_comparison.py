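"""Compare phasor sectioning against classical weighted subtraction.

For a two-frame series the standard alternative is
I_PH2 - gamma (I_PH1 - I_PH2); this script grades both on the synthetic
membrane phantom (two bright sheets plus out-of-focus haze).
"""

from splitpin import (
    PhasorCalibration,
    decompose,
    profile_phasor,
    quics_report,
    simulate_membrane_stack,
    subtractive_baseline,
)

stack, w_in, w_out = simulate_membrane_stack(seed=0)
calib = PhasorCalibration(profile_phasor(w_in), profile_phasor(w_out))

images = {
    "0.5 A.U. frame": stack.frame(1),
    "subtractive (g=0.15)": subtractive_baseline(stack, gamma=0.15),
    "phasor sectioned": decompose(stack, calib, "sum").split_image,
}
for name, img in images.items():
    rep = quics_report(img, axis="z")
    print(f"{name:22s} R_z = {rep.R:6.1f} nm   B = {rep.B:7.1f}")
# Both processed images sharpen the axial response relative to the raw
# small-pinhole frame, but only the phasor route also lifts contrast (B);
# plain subtraction removes haze and signal alike.
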
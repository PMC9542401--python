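"""Propose calibration points from the phasor cloud itself.

When pure in-focus / out-of-focus reference profiles are unavailable,
the extremes of the intensity-weighted phasor distribution along its
principal axis give an advisory starting calibration.
"""

from splitpin import (
    SimulationConfig,
    auto_calibrate,
    phasor_transform,
    simulate_stack,
    smooth_phasor,
)

stack, _ = simulate_stack(SimulationConfig(S=500.0, seed=4))
field = smooth_phasor(phasor_transform(stack), 3)
calib = auto_calibrate(field, intensity_threshold=50.0)
print(f"proposed P_IN  = ({calib.p_in[0]:.3f}, {calib.p_in[1]:.3f})")
print(f"proposed P_OUT = ({calib.p_out[0]:.3f}, {calib.p_out[1]:.3f})")
print("reference       = (0.250, 0.190) / (0.350, 0.190)")
# The proposal is advisory: inspect it against the phasor plot before use;
# manual calibration from known pure profiles remains the documented path.
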
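"""Decompose a pinhole series into its in-focus component.

Computes the per-pixel phasor along the pinhole dimension, projects it
onto the IN-OUT calibration segment, and synthesises the sectioned image
as f_IN times the sum of the confocal frames.
"""

import numpy as np

from splitpin import (
    PhasorCalibration,
    SimulationConfig,
    decompose,
    phasor_transform,
    simulate_stack,
)

stack, _ = simulate_stack(SimulationConfig(S=100.0, seed=7))

field = phasor_transform(stack)
bright = field.total > 50
print(f"phasor cloud of {bright.sum()} bright pixels: "
      f"g in [{field.g[bright].min():.2f}, {field.g[bright].max():.2f}], "
      f"s in [{field.s_coord[bright].min():.2f}, {field.s_coord[bright].max():.2f}]")

calib = PhasorCalibration.simulation_default()  # P_IN/(P_OUT) for this series
result = decompose(stack, calib, conf_selection="sum")
print(f"f_IN range: [{result.f_in.min():.3f}, {result.f_in.max():.3f}] "
      f"(logistic-filtered, k_L={calib.k_L})")
print(f"sectioned image: peak {result.split_image.pixels.max():.0f} counts "
      f"vs confocal sum peak {stack.frames.sum(axis=0).max():.0f}")
# f_IN near 0.88 marks in-focus pixels, near 0.12 out-of-focus ones; the
# product keeps in-focus intensity and suppresses the axial haze.
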
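"""Simulate one bipolar cell's response to a moving bar.

Builds a center-surround receptive field, sweeps a bright bar across the
1-mm arena at 0.5 mm/s, and prints when the cell starts releasing
glutamate relative to the bar's arrival at its position.  A wide RF center
responds while the bar is still far away (a negative motion lag); the
full-field flash, which engages the whole RF at once, shows only the
transport delay.
"""

import numpy as np

from starburst import (RFParams, apply_sensor_filter, flash_lag,
                       make_bar_stimulus, make_flash_stimulus,
                       motion_onset_lag, simulate_bc_response)

for width in (50.0, 200.0):
    params = RFParams(center_width=width, center_rise=40.0,
                      center_decay=600.0, delay=30.0)
    bar = make_bar_stimulus(speed=0.5, direction=1)
    raw = simulate_bc_response(params, bar, rf_x=500.0)
    trace = apply_sensor_filter(raw)
    m_lag = motion_onset_lag(trace.rf_full, bar, rf_x=500.0)

    flash = make_flash_stimulus(duration=2.0)
    f_trace = apply_sensor_filter(simulate_bc_response(params, flash, rf_x=500.0))
    f_lag = flash_lag(f_trace.rf_full)

    print(f"center FWHM {width:5.0f} um:  motion onset lag {m_lag:+7.0f} ms, "
          f"flash lag {f_lag:5.0f} ms, peak release {raw.rf_full.max():.3f}")

print("\nThe motion lag falls (and goes negative) as the center widens,")
print("while the flash lag only reflects the fixed transport delay.")
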
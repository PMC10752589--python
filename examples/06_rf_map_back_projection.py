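"""Spatial RF mapping from flashed oriented bars.

Simulates the oriented-bar protocol (five orientations 36 degrees apart,
32 positions spanning ~300 um) for a 100-um receptive field, reconstructs
the two-dimensional sensitivity map by filtered back-projection, and fits
a 2-D Gaussian (FWHM = 2 sqrt(2 ln 2) sigma_x along the motion axis).
"""

from starburst import RFParams, fit_gaussian_rf, reconstruct_rf_map
from starburst.imaging import rf_map_peak
from starburst.synthetic import gen_oriented_bar_responses

true_fwhm = 100.0
responses, orientations, positions = gen_oriented_bar_responses(
    RFParams(center_width=true_fwhm), center=(20.0, -10.0), noise_sd=0.002,
    seed=0)

rf_map = reconstruct_rf_map(responses, orientations, positions)
sx, sy, fwhm = fit_gaussian_rf(rf_map)
px, py = rf_map_peak(rf_map)

print(f"true RF: FWHM {true_fwhm:.0f} um at (20, -10) um")
print(f"reconstructed peak at ({px:+.0f}, {py:+.0f}) um")
print(f"fitted sigma_x {sx:.1f} um -> FWHM {fwhm:.0f} um")
print("\nFive projection angles leave streak artifacts, but the dominant "
      "peak position and Gaussian width are recovered within ~10%.")
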
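"""From immunoblot densitometry to in-cell molarity and affinity.

Rebuilds the quantification chain: calibrate band intensity against a
dilution series of purified protein, correct a lysate band by cell count
and transfection efficiency to fg/cell, convert to molar with the protein
mass and the ~80 fL cell volume, and turn the onset enzyme level into the
in-cell dissociation constant lam/gamma of the tripartite complex.
"""

import numpy as np

from rab5feedback import (
    AbundanceMeasurement,
    estimate_affinity_ratio,
    estimate_beta,
    fg_per_cell_to_molar,
    fit_standard_curve,
    intensity_to_fg_per_cell,
    round_sig,
)
from rab5feedback.quantify import DEFAULT_STANDARD_AMOUNTS_NG

# a clean calibration: intensity = 1.7 * ng + 5 background
amounts = np.array(DEFAULT_STANDARD_AMOUNTS_NG)
curve = fit_standard_curve(amounts, 1.7 * amounts + 5.0)
print(f"standard curve: slope {curve.slope:.3f} a.u./ng, R^2 = {curve.r_squared:.4f}")

# a band reading 209 a.u. from 2e6 cells at 20% transfection efficiency
meas = AbundanceMeasurement(band_intensity=209.0, lysate_cell_count=2e6, transfection_efficiency=0.2)
fg = intensity_to_fg_per_cell(curve, meas)
print(f"lysate band -> {fg:.1f} fg/cell in the transfected cells")

# the GAP/GEF rate balance from in vitro kinetics
beta = estimate_beta(2e-3, 100)  # intrinsic hydrolysis x 100-fold GAP boost
beta_over_alpha = beta / 2e4
print(f"beta = {beta} /s, beta/alpha = {beta_over_alpha} M")

# the two printed conversions: 32 fg/cell (40 kDa, 80 fL) and 12 fg/cell Rab5
print("32 fg/cell of the 40 kDa construct =", fg_per_cell_to_molar(32, 40, 80), "M")
print("12 fg/cell of 24 kDa Rab5          =", round_sig(fg_per_cell_to_molar(12, 24, 80), 1), "M")

# NF73: onset observed at 12 fg/cell with z_tot = 2.5e-5 M
x_onset = fg_per_cell_to_molar(12, 40, 80)
ratio = estimate_affinity_ratio(x_onset, 2.5e-5, beta_over_alpha)
print(f"NF73 affinity lam/gamma = {ratio:.3g} M  (~1e-5 M at one significant figure)")

# BHK: no onset up to the 32 fg/cell plateau with z_tot = 6e-6 M
bound = estimate_affinity_ratio(fg_per_cell_to_molar(32, 40, 80), 6e-6, beta_over_alpha)
print(f"BHK bound: lam/gamma >= {bound:.3g} M, i.e. lam/(gamma*z_tot) >= {bound / 6e-6:.1f}")
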
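"""Independent scalar reference for the muscle heat-rate model.

Hand-coded straight from the published coefficient tables of the 2003
muscle-energetics formulation with the 2010 modifications, kept deliberately
un-vectorized and separate from the package implementation; frozen as the
cross-check oracle.

Model definition (per kg of muscle, multiplied by muscle mass at the end):

  A       = u                 if u > a, else (u + a)/2
  F_iso   = exp(-(l - 1)^2 / 0.45)          (Gaussian force-length factor)
  h_AM0   = 128 f_FT + 25                   [W/kg at full activation]
  h_A     = 0.4 h_AM0 * A^0.6 * S
  h_M     = 0.6 h_AM0 * A^0.6 * S           (* F_iso when l > 1)
  V_maxST = V_maxFT / 2.5
  shortening (v < 0):
      h_SL = (-v) * (100/V_maxST (1-f_FT) + 153/V_maxFT f_FT) * A^2 * S
  lengthening (v > 0):
      h_SL = v * (4 * 100/V_maxST) * A * S
  (h_SL * F_iso when l > 1)
  W_dot   = -F_active * v * l_opt           [W, fiber only]

with f_FT the fast-twitch fraction, S the aerobic scale, v the normalized
fiber velocity in optimal lengths per second (negative = shortening).
"""

import math


def oracle_heat_rates(
    a,
    u,
    fiber_length,
    fiber_velocity,
    active_force,
    muscle_mass,
    fast_twitch_fraction,
    max_shortening_velocity=12.0,
    optimal_fiber_length=0.1,
    aerobic_scale=1.5,
    clamp_total_nonnegative=False,
    basal_rate_per_kg=0.0,
):
    """Return (w_dot, hA_dot, hM_dot, hSL_dot, total), all in W."""
    f = fast_twitch_fraction
    S = aerobic_scale
    if u > a:
        A = u
    else:
        A = (u + a) / 2.0
    f_iso = math.exp(-((fiber_length - 1.0) ** 2) / 0.45)

    h_am0 = 128.0 * f + 25.0
    h_a = 0.4 * h_am0 * (A ** 0.6) * S
    h_m = 0.6 * h_am0 * (A ** 0.6) * S
    if fiber_length > 1.0:
        h_m = h_m * f_iso

    v_max_ft = max_shortening_velocity
    v_max_st = v_max_ft / 2.5
    alpha_st = 100.0 / v_max_st
    alpha_ft = 153.0 / v_max_ft
    v = fiber_velocity
    if v <= 0.0:  # shortening
        h_sl = (-v) * (alpha_st * (1.0 - f) + alpha_ft * f) * (A ** 2.0) * S
    else:  # lengthening
        h_sl = v * (4.0 * alpha_st) * A * S
    if fiber_length > 1.0:
        h_sl = h_sl * f_iso

    h_m = h_m + basal_rate_per_kg

    w_dot = -active_force * v * optimal_fiber_length
    hA = muscle_mass * h_a
    hM = muscle_mass * h_m
    hSL = muscle_mass * h_sl
    total = w_dot + hA + hM + hSL
    if clamp_total_nonnegative and total < 0.0:
        total = 0.0
    return w_dot, hA, hM, hSL, total
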
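"""Independent reference computations used to cross-check the package.

These are deliberately written as separate, step-by-step implementations
(FAO-56 equation list for reference evapotranspiration; a minute-resolution
scan of solar elevation for day length; a plain weighted sum for IDW) so the
tests compare two independent code paths.
"""

import math

import numpy as np


def fao56_et0_oracle(t_mean, t_min, t_max, rh, u2, sunshine, lat_deg, doy, elev):
    """Daily FAO-56 Penman-Monteith ET0, equation by equation.

    Eq. numbers refer to the FAO Irrigation & Drainage Paper 56 list.
    """
    # Eq. 8: atmospheric pressure; Eq. 7 in some printings
    P = 101.3 * ((293.0 - 0.0065 * elev) / 293.0) ** 5.26
    # psychrometric constant
    gamma = 0.000665 * P
    # Eq. 11: saturation vapour pressure at a temperature
    e0 = lambda T: 0.6108 * math.exp(17.27 * T / (T + 237.3))  # noqa: E731
    # Eq. 12: mean saturation vapour pressure
    es = (e0(t_max) + e0(t_min)) / 2.0
    # Eq. 13: slope of the saturation vapour pressure curve
    Delta = 4098.0 * e0(t_mean) / (t_mean + 237.3) ** 2
    # Eq. 19 variant: actual vapour pressure from mean RH (fraction)
    ea = rh * es
    # Eqs. 21-25: extraterrestrial radiation and daylight hours
    J = doy
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * J / 365.0)
    dec = 0.409 * math.sin(2.0 * math.pi * J / 365.0 - 1.39)
    phi = math.radians(lat_deg)
    ws = math.acos(-math.tan(phi) * math.tan(dec))
    Ra = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws)
    )
    N = 24.0 / math.pi * ws
    # Eq. 35: Angstrom solar radiation
    Rs = (0.25 + 0.50 * min(sunshine, N) / N) * Ra
    # Eq. 37: clear-sky radiation
    Rso = (0.75 + 2e-5 * elev) * Ra
    # Eq. 38: net shortwave
    Rns = (1.0 - 0.23) * Rs
    # Eq. 39: net longwave
    Rnl = (
        4.903e-9
        * ((t_max + 273.16) ** 4 + (t_min + 273.16) ** 4) / 2.0
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * min(Rs / Rso, 1.0) - 0.35)
    )
    Rn = Rns - Rnl
    G = 0.0
    # Eq. 6: the Penman-Monteith combination equation
    et0 = (0.408 * Delta * (Rn - G) + gamma * 900.0 / (t_mean + 273.0) * u2 * (es - ea)) / (
        Delta + gamma * (1.0 + 0.34 * u2)
    )
    return max(et0, 0.0)


def day_length_scan_oracle(lat_deg, doy, step_minutes=0.25):
    """Day length by brute-force scan: minutes with solar elevation > 0."""
    phi = math.radians(lat_deg)
    dec = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    minutes = np.arange(0.0, 24 * 60.0, step_minutes)
    hour_angle = (minutes / (24 * 60.0) - 0.5) * 2.0 * math.pi
    sin_elev = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * np.cos(hour_angle)
    return float(np.sum(sin_elev > 0) * step_minutes / 60.0)


def idw_bruteforce_oracle(sample_xy_km, sample_values, probe_xy_km, power):
    """Plain inverse-distance weighted sum over all samples at one probe."""
    total_w = 0.0
    total = 0.0
    for (x, y), v in zip(sample_xy_km, sample_values):
        d = math.hypot(probe_xy_km[0] - x, probe_xy_km[1] - y)
        if d == 0.0:
            return v
        w = d ** (-power)
        total_w += w
        total += w * v
    return total / total_w
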
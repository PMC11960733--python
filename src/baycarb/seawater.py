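"""Physical seawater properties: density, oxygen solubility, DO unit conversion.

Density follows the EOS-80 international equation of state (UNESCO, 1983;
Millero & Poisson, 1981) evaluated at zero gauge pressure, which is the
appropriate form for a surface-deployed monitoring network reporting
practical salinity.  Oxygen saturation follows the combined-fit solubility
polynomial of Garcia & Gordon (1992), Benson & Krause coefficients, in
umol/kg.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "density",
    "o2_solubility",
    "do_mgL_to_umolkg",
    "do_umolkg_to_mgL",
]

#: Molar mass of O2, g/mol.
M_O2 = 31.998


def density(temperature, salinity):
    """Seawater density at atmospheric pressure, kg/m^3 (EOS-80).

    Parameters
    ----------
    temperature : array_like
        In-situ temperature, deg C (IPTS-68 and ITS-90 differ by far less
        than the sensor accuracy at stake here; no conversion is applied).
    salinity : array_like
        Practical salinity, PSU.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)

    # Pure-water reference density (Bigg 1967, as fitted in UNESCO 1983)
    rho_w = (999.842594
             + 6.793952e-2 * t
             - 9.095290e-3 * t**2
             + 1.001685e-4 * t**3
             - 1.120083e-6 * t**4
             + 6.536332e-9 * t**5)

    a = (8.24493e-1
         - 4.0899e-3 * t
         + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3
         + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4

    rho = rho_w + a * s + b * s**1.5 + c * s**2
    return rho if rho.shape else float(rho)


# Garcia & Gordon (1992) combined fit, Benson & Krause data, umol/kg.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_solubility(temperature, salinity):
    """Oxygen saturation concentration, umol/kg (Garcia & Gordon 1992).

    The saturation concentration at one atmosphere total pressure of
    water-vapor-saturated air.  Decreasing in both temperature and salinity.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))  # scaled temperature

    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (a0 + a1 * ts + a2 * ts**2 + a3 * ts**3 + a4 * ts**4 + a5 * ts**5
            + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
            + _GG_C0 * s**2)
    out = np.exp(ln_c)
    return out if out.shape else float(out)


def do_mgL_to_umolkg(do_mgL, temperature, salinity):
    """Convert dissolved oxygen from mg/L to umol/kg at in-situ T, S.

    result = do_mgL * (1000 / M_O2) / rho, with rho in kg/L at surface
    pressure, so that the quantity tracks oxygen content per unit mass of
    the water parcel rather than per unit volume.
    """
    rho_kgL = np.asarray(density(temperature, salinity)) / 1000.0
    out = np.asarray(do_mgL, dtype=float) * (1000.0 / M_O2) / rho_kgL
    return out if out.shape else float(out)


def do_umolkg_to_mgL(do_umolkg, temperature, salinity):
    """Inverse of :func:`do_mgL_to_umolkg`."""
    rho_kgL = np.asarray(density(temperature, salinity)) / 1000.0
    out = np.asarray(do_umolkg, dtype=float) * rho_kgL / (1000.0 / M_O2)
    return out if out.shape else float(out)
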
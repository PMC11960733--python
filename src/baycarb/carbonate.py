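"""Carbonate-system speciation and marine CO2-chemistry utilities.

The inorganic carbon system in seawater is described by four principal,
mutually constrained quantities: total alkalinity (TA), dissolved inorganic
carbon (DIC), pH, and CO2 partial pressure (pCO2).  Given temperature,
salinity and any two of the four, equilibrium thermodynamics fixes the other
two.  This module implements that speciation from first principles at
surface pressure:

* alkalinity balance  TA = [HCO3-] + 2[CO3 2-] + [B(OH)4-] + [OH-]
  - [H+]free - [HF]   (nutrient bases set to zero: the monitoring network
  does not measure them and they are minor in these waters);
* equilibrium constants on the total hydrogen-ion scale: carbonic acid from
  Lueker et al. (2000), borate from Dickson (1990b), bisulfate from Dickson
  (1990a), water from Millero (1995), fluoride from Perez & Fraga (1987),
  CO2 solubility from Weiss (1974), total borate from Uppstrom (1974);
* a vectorized bracketed bisection on pH over [3, 12] for the implicit
  pairs; algebraic closed forms for the explicit ones.

Also provided: the TA-salinity and DIC-salinity endmember regressions for
Narragansett Bay, the constant NBS/total pH-scale offset used with
glass-electrode network sensors, pCO2 and pH temperature sensitivities, and
Monte-Carlo propagation of sensor uncertainty into calculated DIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConstantsSet",
    "CarbonateState",
    "EndmemberModel",
    "ENDMEMBER_MODELS",
    "NBS_TOTAL_OFFSET",
    "ta_from_salinity",
    "dic_from_salinity",
    "ph_scale_offset",
    "solve_carbonate",
    "solve_ph_from_ta_dic",
    "dic_from_ta_ph",
    "pco2_from_dic_ph",
    "pco2_temperature_sensitivity",
    "ph_temperature_sensitivity",
    "propagate_dic_error",
]

#: Constant offset between NBS and total hydrogen-ion pH scales adopted for
#: glass-electrode estuarine sensors: pH_NBS = pH_total + 0.13.
NBS_TOTAL_OFFSET = 0.13


@dataclass(frozen=True)
class ConstantsSet:
    """Named choice of equilibrium-constant formulations.

    The default mirrors the common default of the standard CO2-system
    calculators (Lueker carbonic acid, Dickson bisulfate, Uppstrom borate);
    the name travels with every output so the choice is always on record.
    """

    name: str = "lueker2000-dickson-uppstrom"
    k1k2: str = "lueker2000"
    kso4: str = "dickson1990"
    borate: str = "uppstrom1974"

    def evaluate(self, temperature, salinity):
        """Return a dict of constants (total scale, mol/kg-sw) at T, S."""
        t = np.asarray(temperature, dtype=float)
        s = np.asarray(salinity, dtype=float)
        tk = t + 273.15
        lntk = np.log(tk)

        if self.k1k2 != "lueker2000":
            raise ValueError(f"unknown K1/K2 formulation: {self.k1k2!r}")
        # Lueker, Dickson & Keeling (2000), total scale
        pk1 = 3633.86 / tk - 61.2172 + 9.67770 * lntk - 0.011555 * s + 0.0001152 * s**2
        pk2 = 471.78 / tk + 25.9290 - 3.16967 * lntk - 0.01781 * s + 0.0001122 * s**2
        k1 = 10.0 ** (-pk1)
        k2 = 10.0 ** (-pk2)

        # Water dissociation, Millero (1995), total scale
        lnkw = (148.9802 - 13847.26 / tk - 23.6521 * lntk
                + (118.67 / tk - 5.977 + 1.0495 * lntk) * np.sqrt(s)
                - 0.01615 * s)
        kw = np.exp(lnkw)

        # Borate, Dickson (1990b), total scale
        sq = np.sqrt(s)
        lnkb = ((-8966.90 - 2890.53 * sq - 77.942 * s
                 + 1.728 * s * sq - 0.0996 * s**2) / tk
                + 148.0248 + 137.1942 * sq + 1.62142 * s
                - (24.4344 + 25.085 * sq + 0.2474 * s) * lntk
                + 0.053105 * sq * tk)
        kb = np.exp(lnkb)

        # Bisulfate, Dickson (1990a), free scale, mol/kg-H2O
        ion = 19.924 * s / (1000.0 - 1.005 * s)
        lnks = (-4276.1 / tk + 141.328 - 23.093 * lntk
                + (-13856.0 / tk + 324.57 - 47.986 * lntk) * np.sqrt(ion)
                + (35474.0 / tk - 771.54 + 114.723 * lntk) * ion
                - 2698.0 / tk * ion**1.5 + 1776.0 / tk * ion**2
                + np.log(1.0 - 0.001005 * s))
        ks = np.exp(lnks)

        # Hydrogen fluoride, Perez & Fraga (1987), total scale
        lnkf = 874.0 / tk - 9.68 + 0.111 * np.sqrt(s)
        kf = np.exp(lnkf)

        # CO2 solubility, Weiss (1974), mol/kg-sw/atm
        tk100 = tk / 100.0
        lnk0 = (-60.2409 + 93.4517 / tk100 + 23.3585 * np.log(tk100)
                + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2))
        k0 = np.exp(lnk0)

        # Total concentrations from salinity
        bt = 0.0004157 * s / 35.0     # Uppstrom (1974)
        st = 0.02824 * s / 35.0       # Morris & Riley (1966)
        ft = 0.00007 * s / 35.0       # Riley (1965)

        return {"k1": k1, "k2": k2, "kw": kw, "kb": kb, "ks": ks, "kf": kf,
                "k0": k0, "bt": bt, "st": st, "ft": ft,
                "free_to_total": 1.0 + st / ks}


DEFAULT_CONSTANTS = ConstantsSet()


@dataclass(frozen=True)
class CarbonateState:
    """A thermodynamically consistent carbonate-system state at surface pressure.

    pH is on the total hydrogen-ion scale; use :func:`ph_scale_offset` (or the
    ``pH_nbs`` property) for the NBS sensor convention.  TA and DIC in
    umol/kg, pCO2 in uatm.
    """

    temperature: float
    salinity: float
    TA: float
    DIC: float
    pH: float
    pCO2: float
    constants: str = DEFAULT_CONSTANTS.name

    @property
    def pH_nbs(self) -> float:
        return self.pH + NBS_TOTAL_OFFSET


@dataclass(frozen=True)
class EndmemberModel:
    """Linear TA-S and DIC-S relations defining a conservative mixing space."""

    ta_slope: float
    ta_intercept: float
    dic_slope: float
    dic_intercept: float
    label: str = ""

    def ta(self, salinity):
        return self.ta_slope * np.asarray(salinity, dtype=float) + self.ta_intercept

    def dic(self, salinity):
        return self.dic_slope * np.asarray(salinity, dtype=float) + self.dic_intercept

    def with_freshwater_dic(self, dic_intercept: float) -> "EndmemberModel":
        return replace(self, dic_intercept=dic_intercept,
                       label=self.label + f"+fwDIC={dic_intercept:g}")


#: Registered Narragansett Bay endmember regressions.  "bottle" is the
#: discrete-sample reference line as printed alongside the TA regression;
#: "bottle_mixing" is the same relation as printed with the mixing analysis
#: (coefficients differ in the last digit between the two printings; both are
#: kept and the mixing variant is the default for mixing curves).  "sensor"
#: is the line refit from sensor pH with salinity-estimated TA.
ENDMEMBER_MODELS = {
    "bottle": EndmemberModel(51.99, 477.62, 50.60, 397.5, "bottle"),
    "bottle_mixing": EndmemberModel(51.99, 477.62, 50.59, 397.65, "bottle_mixing"),
    "sensor": EndmemberModel(51.99, 477.62, 52.05, 382.64, "sensor"),
}

DEFAULT_ENDMEMBERS = ENDMEMBER_MODELS["bottle_mixing"]


def ta_from_salinity(salinity, model: EndmemberModel = DEFAULT_ENDMEMBERS):
    """Total alkalinity (umol/kg) from salinity via the endmember regression."""
    return model.ta(salinity)


def dic_from_salinity(salinity, model: EndmemberModel = DEFAULT_ENDMEMBERS):
    """Conservative-mixing DIC (umol/kg) from salinity via the regression."""
    return model.dic(salinity)


def ph_scale_offset(pH, from_scale: str, to_scale: str):
    """Convert pH between the NBS and total scales by the constant offset.

    A constant additive offset (NBS = total + 0.13) is the convention for the
    network's glass-electrode sensors; an activity-coefficient computation is
    not attainable from the data these sensors report.
    """
    scales = {"nbs", "total"}
    f, t = from_scale.lower(), to_scale.lower()
    if f not in scales or t not in scales:
        raise ValueError(f"unknown pH scale in {from_scale!r} -> {to_scale!r}")
    if f == t:
        return pH
    return pH + NBS_TOTAL_OFFSET if t == "nbs" else pH - NBS_TOTAL_OFFSET


# ---------------------------------------------------------------------------
# speciation core (vectorized; concentrations in mol/kg inside)

def _alkalinity_residual(h, dic, ta, k):
    """TA residual (mol/kg) at total-scale [H+] h, given DIC; zero at solution."""
    denom = h * h + k["k1"] * h + k["k1"] * k["k2"]
    hco3 = dic * k["k1"] * h / denom
    co3 = dic * k["k1"] * k["k2"] / denom
    balk = k["bt"] * k["kb"] / (k["kb"] + h)
    oh = k["kw"] / h
    hfree = h / k["free_to_total"]
    hf = k["ft"] * hfree / (k["kf"] + hfree)
    return hco3 + 2.0 * co3 + balk + oh - hfree - hf - ta


def _carbonate_alkalinity(h, ta, k):
    """CAlk = TA minus non-carbonate contributions, at total-scale [H+]."""
    balk = k["bt"] * k["kb"] / (k["kb"] + h)
    oh = k["kw"] / h
    hfree = h / k["free_to_total"]
    hf = k["ft"] * hfree / (k["kf"] + hfree)
    return ta - balk - oh + hfree + hf


def _dic_from_ta_h(h, ta, k):
    calk = _carbonate_alkalinity(h, ta, k)
    return calk * (h * h + k["k1"] * h + k["k1"] * k["k2"]) / (
        k["k1"] * h + 2.0 * k["k1"] * k["k2"])


def _co2star_from_dic_h(h, dic, k):
    return dic * h * h / (h * h + k["k1"] * h + k["k1"] * k["k2"])


def _fugacity_factor(temperature):
    """fCO2/pCO2 ratio from the Weiss (1974) virial expression at 1 atm."""
    tk = np.asarray(temperature, dtype=float) + 273.15
    # cm3/mol virial coefficients
    b = -1636.75 + 12.0408 * tk - 3.27957e-2 * tk**2 + 3.16528e-5 * tk**3
    delta = 57.7 - 0.118 * tk
    r = 83.1451  # cm3 bar / (mol K)
    p_bar = 1.01325
    return np.exp(p_bar * (b + 2.0 * delta) / (r * tk))


_PH_LO, _PH_HI = 3.0, 12.0


def solve_ph_from_ta_dic(ta_umol, dic_umol, temperature, salinity,
                         constants: ConstantsSet = DEFAULT_CONSTANTS,
                         tol: float = 1e-12):
    """Total-scale pH from (TA, DIC, T, S) by vectorized bracketed bisection.

    The alkalinity residual is monotone decreasing in pH over [3, 12] for any
    physical TA:DIC ratio, so plain bisection is unconditionally convergent;
    it is iterated to ``tol`` in pH (default well below every downstream
    tolerance), leaving the charge-balance residual at roundoff level.

    Raises ``ValueError`` if the root is not bracketed (non-physical input).
    """
    ta = np.asarray(ta_umol, dtype=float) * 1e-6
    dic = np.asarray(dic_umol, dtype=float) * 1e-6
    k = constants.evaluate(temperature, salinity)

    shape = np.broadcast_shapes(ta.shape, dic.shape,
                                np.shape(k["k1"]) or (), np.shape(k["kw"]) or ())
    lo = np.full(shape, _PH_LO)
    hi = np.full(shape, _PH_HI)
    ta, dic = np.broadcast_to(ta, shape).copy(), np.broadcast_to(dic, shape).copy()

    def f(ph):
        return _alkalinity_residual(10.0 ** (-ph), dic, ta, k)

    flo, fhi = f(lo), f(hi)
    # residual decreases with [H+]... i.e. increases with pH
    bad = ~((flo <= 0) & (fhi >= 0)) & ~((flo >= 0) & (fhi <= 0))
    if np.any(bad):
        raise ValueError(
            f"carbonate solver: root not bracketed in pH [3, 12] for "
            f"{int(np.sum(bad))} input(s); non-physical TA/DIC combination")
    # orient so that f(lo) <= 0 <= f(hi)
    flip = flo > 0
    if np.any(flip):
        lo2 = np.where(flip, hi, lo)
        hi2 = np.where(flip, lo, hi)
        lo, hi = lo2, hi2
    n_iter = int(np.ceil(np.log2((_PH_HI - _PH_LO) / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_hi = fm > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    ph = 0.5 * (lo + hi)
    return ph if ph.shape else float(ph)


def dic_from_ta_ph(ta_umol, ph_total, temperature, salinity,
                   constants: ConstantsSet = DEFAULT_CONSTANTS):
    """DIC (umol/kg) from TA and total-scale pH — the closed-form direction."""
    ta = np.asarray(ta_umol, dtype=float) * 1e-6
    h = 10.0 ** (-np.asarray(ph_total, dtype=float))
    k = constants.evaluate(temperature, salinity)
    out = _dic_from_ta_h(h, ta, k) * 1e6
    return out if np.ndim(out) else float(out)


def pco2_from_dic_ph(dic_umol, ph_total, temperature, salinity,
                     constants: ConstantsSet = DEFAULT_CONSTANTS):
    """pCO2 (uatm) from DIC and total-scale pH."""
    dic = np.asarray(dic_umol, dtype=float) * 1e-6
    h = 10.0 ** (-np.asarray(ph_total, dtype=float))
    k = constants.evaluate(temperature, salinity)
    co2star = _co2star_from_dic_h(h, dic, k)
    fco2 = co2star / k["k0"] * 1e6
    out = fco2 / _fugacity_factor(temperature)
    return out if np.ndim(out) else float(out)


def solve_carbonate(known_pair: dict, temperature: float, salinity: float,
                    constants: ConstantsSet = DEFAULT_CONSTANTS) -> CarbonateState:
    """Full carbonate state from any two of {TA, DIC, pH, pCO2} plus T, S.

    Parameters
    ----------
    known_pair : dict
        Exactly two of the keys ``"TA"`` (umol/kg), ``"DIC"`` (umol/kg),
        ``"pH"`` (total scale) and ``"pCO2"`` (uatm).
    temperature, salinity : float
        In-situ conditions; pressure is fixed at the surface.

    Returns
    -------
    CarbonateState
        With pH on the total scale and the constants-set name recorded.
    """
    keys = set(known_pair)
    valid = {"TA", "DIC", "pH", "pCO2"}
    if len(known_pair) != 2 or not keys <= valid:
        raise ValueError(f"known_pair must be two of {sorted(valid)}, got {sorted(keys)}")
    k = constants.evaluate(temperature, salinity)

    if keys == {"TA", "pH"}:
        ta, ph = known_pair["TA"], known_pair["pH"]
        dic = dic_from_ta_ph(ta, ph, temperature, salinity, constants)
    elif keys == {"TA", "DIC"}:
        ta, dic = known_pair["TA"], known_pair["DIC"]
        ph = solve_ph_from_ta_dic(ta, dic, temperature, salinity, constants)
    elif keys == {"DIC", "pH"}:
        dic, ph = known_pair["DIC"], known_pair["pH"]
        h = 10.0 ** (-ph)
        calk = dic * 1e-6 * (k["k1"] * h + 2 * k["k1"] * k["k2"]) / (
            h * h + k["k1"] * h + k["k1"] * k["k2"])
        balk = k["bt"] * k["kb"] / (k["kb"] + h)
        oh = k["kw"] / h
        hfree = h / k["free_to_total"]
        hf = k["ft"] * hfree / (k["kf"] + hfree)
        ta = (calk + balk + oh - hfree - hf) * 1e6
    elif keys == {"pH", "pCO2"}:
        ph, pco2 = known_pair["pH"], known_pair["pCO2"]
        h = 10.0 ** (-ph)
        co2star = pco2 * 1e-6 * _fugacity_factor(temperature) * k["k0"]
        dic = co2star * (h * h + k["k1"] * h + k["k1"] * k["k2"]) / (h * h) * 1e6
        return solve_carbonate({"DIC": dic, "pH": ph}, temperature, salinity, constants)
    elif keys == {"TA", "pCO2"}:
        ta, pco2 = known_pair["TA"], known_pair["pCO2"]
        co2star = pco2 * 1e-6 * _fugacity_factor(temperature) * k["k0"]

        def resid(ph):
            h = 10.0 ** (-ph)
            calk = _carbonate_alkalinity(h, ta * 1e-6, k)
            # CAlk implied by CO2* at this pH:
            calk_co2 = co2star * (k["k1"] / h + 2 * k["k1"] * k["k2"] / (h * h))
            return calk_co2 - calk

        from scipy.optimize import brentq
        ph = brentq(resid, _PH_LO, _PH_HI, xtol=1e-12)
        h = 10.0 ** (-ph)
        dic = co2star * (h * h + k["k1"] * h + k["k1"] * k["k2"]) / (h * h) * 1e6
    elif keys == {"DIC", "pCO2"}:
        dic, pco2 = known_pair["DIC"], known_pair["pCO2"]
        co2star = pco2 * 1e-6 * _fugacity_factor(temperature) * k["k0"]
        frac = co2star / (dic * 1e-6)  # = h^2 / (h^2 + k1 h + k1 k2)
        if not 0 < frac < 1:
            raise ValueError("non-physical DIC/pCO2 combination")
        # quadratic in h: (1-frac) h^2 - frac k1 h - frac k1 k2 = 0
        a, b, c = (1 - frac), -frac * k["k1"], -frac * k["k1"] * k["k2"]
        h = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        ph = -np.log10(h)
        return solve_carbonate({"DIC": dic, "pH": float(ph)}, temperature, salinity, constants)
    else:  # pragma: no cover
        raise AssertionError

    ph = float(ph)
    dic = float(dic)
    ta = float(ta)
    pco2 = float(pco2_from_dic_ph(dic, ph, temperature, salinity, constants))
    return CarbonateState(temperature=float(temperature), salinity=float(salinity),
                          TA=ta, DIC=dic, pH=ph, pCO2=pco2, constants=constants.name)


# ---------------------------------------------------------------------------
# sensitivities and error propagation

def pco2_temperature_sensitivity(state: CarbonateState, dT: float = 1.0,
                                 constants: ConstantsSet | None = None) -> float:
    """Fractional pCO2 change for a ``dT`` warming at fixed TA and DIC.

    Returns (pCO2(T+dT) - pCO2(T)) / pCO2(T); about +0.04/degC for typical
    coastal seawater (the Takahashi-type isochemical temperature effect).
    """
    cs = constants or ConstantsSet(name=state.constants)
    warm = solve_carbonate({"TA": state.TA, "DIC": state.DIC},
                           state.temperature + dT, state.salinity, cs)
    return (warm.pCO2 - state.pCO2) / state.pCO2


def ph_temperature_sensitivity(state: CarbonateState, dT: float = 1.0,
                               constants: ConstantsSet | None = None) -> float:
    """pH change per ``dT`` warming at fixed TA and DIC (negative)."""
    cs = constants or ConstantsSet(name=state.constants)
    warm = solve_carbonate({"TA": state.TA, "DIC": state.DIC},
                           state.temperature + dT, state.salinity, cs)
    return (warm.pH - state.pH) / dT


def propagate_dic_error(ta_sigma: float, ph_sigma: float,
                        conditions: Sequence[tuple[float, float, float]],
                        n_draws: int = 5000, seed: int | None = None,
                        constants: ConstantsSet = DEFAULT_CONSTANTS,
                        max_failure_fraction: float = 0.01):
    """Monte-Carlo standard error of DIC calculated from (TA, pH) pairs.

    For each condition ``(temperature, salinity, pH_total)`` the nominal TA
    comes from the salinity regression; ``n_draws`` joint draws with
    independent zero-mean normal errors on TA and pH are speciated to DIC and
    the per-condition standard deviation taken.  Returns ``(mean_sigma_dic,
    per_condition_sigmas)`` in umol/kg.  Deterministic given ``seed``.
    """
    if ta_sigma < 0 or ph_sigma < 0:
        raise ValueError("sigmas must be non-negative")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sigmas = []
    n_fail = 0
    n_total = 0
    for (t, s, ph) in conditions:
        ta0 = float(ta_from_salinity(s))
        ta = ta0 + rng.normal(0.0, ta_sigma, n_draws) if ta_sigma else np.full(n_draws, ta0)
        phd = ph + rng.normal(0.0, ph_sigma, n_draws) if ph_sigma else np.full(n_draws, ph)
        dic = dic_from_ta_ph(ta, phd, t, s, constants)
        ok = np.isfinite(dic) & (dic > 0)
        n_fail += int(np.sum(~ok))
        n_total += n_draws
        sigmas.append(float(np.std(np.asarray(dic)[ok], ddof=1)) if n_draws > 1 else 0.0)
    if n_total and n_fail / n_total > max_failure_fraction:
        raise RuntimeError(
            f"propagate_dic_error: {n_fail}/{n_total} draws failed speciation")
    return float(np.mean(sigmas)), np.asarray(sigmas)
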
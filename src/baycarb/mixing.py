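"""Two-endmember mixing curves and driver-attribution budgets.

Because total alkalinity and (absent biology and gas exchange) DIC mix
conservatively, their linear salinity regressions define the carbonate
chemistry of any mixture of the freshwater and saline endmembers.  Solving
the carbonate system along a salinity grid at a fixed reference temperature
yields the "pH mixing curve": the pH expected from water-mass mixing alone.
Deviations of observed pH from the curve isolate non-conservative
processes (production, respiration, air-sea exchange).

The attribution budgets decompose observed DO and pH trends into named
driver terms (solubility response to warming/salinity for DO; mixing,
respiration, warming and atmospheric CO2 uptake for pH), with the
unexplained remainder reported as a residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbonate import (
    ConstantsSet, DEFAULT_CONSTANTS, EndmemberModel, DEFAULT_ENDMEMBERS,
    NBS_TOTAL_OFFSET, dic_from_ta_ph, solve_ph_from_ta_dic, ph_scale_offset,
)

__all__ = [
    "MixingCurve",
    "AttributionBudget",
    "PAPER_COEFFICIENTS",
    "build_mixing_curve",
    "perturb_endmember",
    "mixing_deviation",
    "adjust_ph_to_temperature",
    "do_solubility_budget",
    "ph_budget",
]

#: Frozen bay-wide anomaly-regression coefficients for reproducing the
#: published budget arithmetic without refitting: slopes of DO anomalies on
#: temperature and salinity anomalies (umol/kg per degC, per PSU), of pH
#: anomalies on salinity and DO anomalies, and the open-ocean atmospheric
#: acidification rate (pH/yr).
PAPER_COEFFICIENTS = {
    "do_per_degC": -3.7,
    "do_per_psu": -0.98,
    "ph_per_psu": 0.0163,
    "ph_per_do": 0.00156,
    "oa_rate": -0.0015,       # midpoint of the -0.001 to -0.002 literature range
}


@dataclass(frozen=True)
class MixingCurve:
    """pH along a salinity grid for conservative two-endmember mixing."""

    reference_temperature: float
    salinity: np.ndarray
    ph_total: np.ndarray
    ta: np.ndarray
    dic: np.ndarray
    endmembers: EndmemberModel
    constants: str = DEFAULT_CONSTANTS.name

    @property
    def ph_nbs(self) -> np.ndarray:
        return self.ph_total + NBS_TOTAL_OFFSET

    def interp_ph(self, salinity, scale: str = "total"):
        """Curve pH at arbitrary salinity by linear interpolation on the grid.

        Salinities outside the grid return NaN (excluded, not extrapolated).
        """
        s = np.asarray(salinity, dtype=float)
        ph = np.interp(s, self.salinity, self.ph_total,
                       left=np.nan, right=np.nan)
        if scale == "nbs":
            ph = ph + NBS_TOTAL_OFFSET
        elif scale != "total":
            raise ValueError(f"unknown scale {scale!r}")
        return ph if np.ndim(salinity) else float(ph)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "salinity": self.salinity, "TA": self.ta, "DIC": self.dic,
            "pH_total": self.ph_total, "pH_nbs": self.ph_nbs})


@dataclass(frozen=True)
class AttributionBudget:
    """Named driver terms (units/yr) decomposing an observed trend."""

    target: str
    units: str
    observed_trend: float
    terms: dict[str, float]
    inputs: dict = field(default_factory=dict)
    window_years: float | None = None

    @property
    def explained(self) -> float:
        return float(sum(self.terms.values()))

    @property
    def residual(self) -> float:
        return self.observed_trend - self.explained

    def cumulative(self, years: float | None = None) -> dict[str, float]:
        """Terms integrated over a window (default: the budget's own)."""
        span = years if years is not None else self.window_years
        if span is None:
            raise ValueError("no window_years set for cumulative form")
        out = {name: rate * span for name, rate in self.terms.items()}
        out["observed"] = self.observed_trend * span
        out["residual"] = self.residual * span
        return out

    def to_dict(self) -> dict:
        return {"target": self.target, "units": self.units,
                "observed_trend": self.observed_trend, "terms": dict(self.terms),
                "explained": self.explained, "residual": self.residual,
                "inputs": dict(self.inputs), "window_years": self.window_years}


def build_mixing_curve(endmembers: EndmemberModel = DEFAULT_ENDMEMBERS,
                       reference_temperature: float = 17.0,
                       grid=None,
                       constants: ConstantsSet = DEFAULT_CONSTANTS) -> MixingCurve:
    """pH mixing curve: speciate (TA(S), DIC(S)) along a salinity grid.

    The default grid spans the freshwater endmember to S=33 at 0.1 PSU —
    fine enough that linear interpolation resolves the curve's low-salinity
    curvature to well below 1e-4 pH; the default reference temperature is
    the bay annual mean of 17 degC.
    """
    s = np.arange(0.0, 33.0 + 1e-9, 0.1) if grid is None else np.asarray(grid, float)
    if s.ndim != 1 or s.size < 2 or np.any(np.diff(s) <= 0):
        raise ValueError("grid must be strictly increasing, length >= 2")
    if s[0] < 0 or s[-1] > 35:
        raise ValueError("grid must lie within [0, 35]")
    ta = endmembers.ta(s)
    dic = endmembers.dic(s)
    if np.any(ta <= 0) or np.any(dic <= 0):
        raise ValueError("endmember model predicts non-positive TA or DIC on grid")
    ph = solve_ph_from_ta_dic(ta, dic, reference_temperature, s, constants)
    return MixingCurve(reference_temperature=float(reference_temperature),
                       salinity=s, ph_total=np.asarray(ph), ta=ta, dic=dic,
                       endmembers=endmembers, constants=constants.name)


def perturb_endmember(endmembers: EndmemberModel = DEFAULT_ENDMEMBERS,
                      fraction: float | None = None,
                      delta_umolkg: float | None = None,
                      reference_temperature: float = 17.0,
                      grid=None,
                      constants: ConstantsSet = DEFAULT_CONSTANTS,
                      ) -> tuple[MixingCurve, MixingCurve]:
    """Base and freshwater-DIC-perturbed mixing curves, as a pair.

    The perturbation shifts the DIC intercept (freshwater endmember) either
    by a fraction of itself or by an absolute amount in umol/kg; exactly one
    must be given, and fractional perturbations beyond +/-50% are refused.
    """
    if (fraction is None) == (delta_umolkg is None):
        raise ValueError("give exactly one of fraction / delta_umolkg")
    if fraction is not None:
        if abs(fraction) > 0.5:
            raise ValueError("fractional perturbation limited to +/-50%")
        delta = fraction * endmembers.dic_intercept
    else:
        delta = float(delta_umolkg)
        if abs(delta) > 0.5 * endmembers.dic_intercept:
            raise ValueError("perturbation limited to +/-50% of the intercept")
    base = build_mixing_curve(endmembers, reference_temperature, grid, constants)
    shifted = endmembers.with_freshwater_dic(endmembers.dic_intercept + delta)
    pert = build_mixing_curve(shifted, reference_temperature, grid, constants)
    return base, pert


def adjust_ph_to_temperature(ph_nbs, salinity, temperature, t_ref: float = 17.0,
                             endmembers: EndmemberModel = DEFAULT_ENDMEMBERS,
                             constants: ConstantsSet = DEFAULT_CONSTANTS):
    """Re-express observed pH at a reference temperature, NBS scale.

    Speciates each observation at in-situ temperature using salinity-derived
    TA and the measured pH (converted to the total scale), then re-solves at
    ``t_ref`` holding TA and DIC fixed — the isochemical temperature
    adjustment.
    """
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    ph_tot = np.asarray(ph_scale_offset(np.asarray(ph_nbs, float), "nbs", "total"))
    ta = endmembers.ta(s)
    dic = dic_from_ta_ph(ta, ph_tot, t, s, constants)
    ph_ref = solve_ph_from_ta_dic(ta, dic, t_ref, s, constants)
    out = np.asarray(ph_ref) + NBS_TOTAL_OFFSET
    return out if out.shape else float(out)


def mixing_deviation(observations: pd.DataFrame, curve: MixingCurve,
                     endmembers: EndmemberModel | None = None,
                     constants: ConstantsSet = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Observed-minus-curve pH after temperature adjustment to the curve's T.

    ``observations`` needs columns salinity, temperature, pH_nbs.  Returns
    the input plus ``ph_at_tref`` (NBS) and ``delta_ph``; rows whose salinity
    falls outside the curve grid get NaN and are counted in
    ``frame.attrs["n_outside_grid"]``.
    """
    frame = observations.copy()
    em = endmembers or curve.endmembers
    frame["ph_at_tref"] = adjust_ph_to_temperature(
        frame["pH_nbs"].to_numpy(float), frame["salinity"].to_numpy(float),
        frame["temperature"].to_numpy(float), curve.reference_temperature,
        em, constants)
    curve_ph = curve.interp_ph(frame["salinity"].to_numpy(float), scale="nbs")
    frame["delta_ph"] = frame["ph_at_tref"] - curve_ph
    frame.attrs["n_outside_grid"] = int(np.sum(~np.isfinite(curve_ph)))
    return frame


def do_solubility_budget(trend_T: float, trend_S: float, observed_trend: float,
                         slope_T: float = PAPER_COEFFICIENTS["do_per_degC"],
                         slope_S: float = PAPER_COEFFICIENTS["do_per_psu"],
                         target: str = "bottom DO",
                         window_years: float = 15.0) -> AttributionBudget:
    """Decompose a DO trend into solubility terms and a biological residual.

    temperature term = slope_T * trend_T; salinity term = slope_S * trend_S;
    the biological term is whatever remains of the observed trend.
    """
    terms = {"temperature": slope_T * trend_T, "salinity": slope_S * trend_S}
    return AttributionBudget(
        target=target, units="umol/kg/yr", observed_trend=observed_trend,
        terms=terms,
        inputs={"trend_T": trend_T, "trend_S": trend_S,
                "slope_T": slope_T, "slope_S": slope_S},
        window_years=window_years)


def ph_budget(observed_trend: float, salinity_trend: float, warming_rate: float,
              do_biological_rate: float,
              ph_per_psu: float = PAPER_COEFFICIENTS["ph_per_psu"],
              ph_per_do: float = PAPER_COEFFICIENTS["ph_per_do"],
              ph_per_degC: float = -0.015,
              oa_rate: float = PAPER_COEFFICIENTS["oa_rate"],
              target: str = "bottom pH",
              window_years: float = 15.0) -> AttributionBudget:
    """Four-process decomposition of a pH trend.

    Terms (all pH/yr): water-mass mixing (salinity trend x pH-salinity
    slope), respiration change (biological DO rate x pH-DO slope), warming
    (rate x isochemical pH-temperature sensitivity, from the carbonate
    solver), and atmospheric CO2 uptake (an exogenous open-ocean literature
    rate — not computed from CO2 records).
    """
    terms = {
        "mixing": ph_per_psu * salinity_trend,
        "respiration": ph_per_do * do_biological_rate,
        "warming": ph_per_degC * warming_rate,
        "atmospheric_co2": oa_rate,
    }
    return AttributionBudget(
        target=target, units="pH/yr", observed_trend=observed_trend,
        terms=terms,
        inputs={"salinity_trend": salinity_trend, "warming_rate": warming_rate,
                "do_biological_rate": do_biological_rate,
                "ph_per_psu": ph_per_psu, "ph_per_do": ph_per_do,
                "ph_per_degC": ph_per_degC, "oa_rate": oa_rate},
        window_years=window_years)
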
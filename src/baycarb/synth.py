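"""Synthetic monitoring-network generator with a full truth ledger.

Generates multi-station, two-layer water-quality time series that mimic a
temperate urbanized estuary's fixed-site sensor network: seasonal harmonics
plus linear trends plus autocorrelated noise for temperature, salinity and
surface chlorophyll; dissolved oxygen built from the physical solubility of
the generated T and S plus a biological deviation (chlorophyll-coupled in
the surface, respiration-like in the bottom); and pH derived through the
carbonate solver from salinity-conservative TA and DIC perturbed by the
biological oxygen signal and a biogeochemical DIC noise process — so the
generated (T, S, TA, DIC, pH) tuples satisfy carbonate-system closure
exactly by construction (at daily cadence; sub-daily expansion adds reading
noise to the reported sensor values only).

Noise has two scales: a daily AR(1) "weather" component — white at monthly
lags, matching the near-uncorrelated monthly anomalies real networks show —
split into a bay-wide shared forcing felt by every station and an
independent per-station part, plus white per-reading measurement noise.

The trends actually injected are calibrated internally: the requested total
DO and pH trends are decomposed through locally averaged partial
derivatives (solubility with respect to T and S; pH with respect to S, T
and DIC), and every calibrated coefficient is written to the
:class:`TruthLedger` along with injected outlier timestamps.  Identical
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from . import carbonate as cb
from . import seawater as sw
from .qaqc import iqr_fences

__all__ = [
    "HarmonicSpec",
    "DOSpec",
    "DICNoiseSpec",
    "StationSpec",
    "SyntheticConfig",
    "TruthLedger",
    "nb_like",
    "generate_network",
    "inject_outliers",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class HarmonicSpec:
    """Mean + two seasonal harmonics + linear trend + two-scale noise.

    ``phase1``/``phase2`` are the day-of-year of each harmonic's maximum.
    ``ar1`` is the daily autocorrelation of the red-noise component;
    ``ar1_sd`` its per-station daily innovation sd and ``shared_sd`` the
    innovation sd of the bay-wide shared forcing (same units as the
    parameter); ``daily_sd`` is white per-reading sensor noise.
    ``excursion_amp`` adds a slow sinusoid with exactly two full periods
    over the record (decade-scale freshening/drought cycles that leave the
    linear trend unbiased).
    """

    mean: float
    amp1: float = 0.0
    phase1: float = 215.0
    amp2: float = 0.0
    phase2: float = 120.0
    trend: float = 0.0
    ar1: float = 0.75
    ar1_sd: float = 0.2
    shared_sd: float = 0.2
    daily_sd: float = 0.3
    excursion_amp: float = 0.0
    clip: tuple[float, float] | None = None


@dataclass(frozen=True)
class DOSpec:
    """Dissolved-oxygen construction: solubility + biological deviation.

    ``trend`` is the *total* DO trend to realize (umol/kg/yr); the internal
    linear biological rate is calibrated against the solubility response to
    the configured T and S trends.  ``chl_coupling`` couples the surface
    biological term to chlorophyll anomalies (umol/kg per ug/L);
    ``temp_bio_coupling`` is a biological response to temperature anomalies
    on top of the solubility response.  Noise fields as in
    :class:`HarmonicSpec`.
    """

    trend: float = 0.0
    offset: float = 0.0
    chl_coupling: float = 0.0
    temp_bio_coupling: float = 0.0
    ar1: float = 0.75
    ar1_sd: float = 7.0
    shared_sd: float = 8.0
    daily_sd: float = 3.0


@dataclass(frozen=True)
class DICNoiseSpec:
    """AR(1) DIC variability not tied to oxygen (umol/kg).

    Stands for biogeochemical DIC sources the oxygen signal does not carry:
    air-sea CO2 exchange, lateral transport, calcification.  Gives the
    generated pH a realistic anomaly spread while keeping carbonate closure
    exact.
    """

    ar1: float = 0.75
    ar1_sd: float = 6.0
    shared_sd: float = 8.0


@dataclass(frozen=True)
class StationSpec:
    station_id: str
    year_round: bool = False
    salinity_offset: float = 0.0
    temperature_offset: float = 0.0
    bottom_depth: float = 8.0


@dataclass
class SyntheticConfig:
    """Everything that determines a synthetic network realization."""

    stations: list[StationSpec]
    start_year: int = 2005
    end_year: int = 2019
    cadence: int = 1                      # readings per day
    climate: dict = field(default_factory=dict)   # layer -> {param -> HarmonicSpec}
    do: dict = field(default_factory=dict)        # layer -> DOSpec
    dic_noise: dict = field(default_factory=dict)  # layer -> DICNoiseSpec
    ph_trend: dict = field(default_factory=dict)  # layer -> total pH(NBS) trend /yr
    ph_per_do: float = 0.00156            # target pH change per umol/kg biological DO
    outlier_rate: float = 0.0             # per parameter-day
    outlier_magnitude: float = 1.0        # IQRs beyond the fence
    sampling_months: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    endmembers: cb.EndmemberModel = cb.DEFAULT_ENDMEMBERS
    constants: cb.ConstantsSet = cb.DEFAULT_CONSTANTS
    seed: int = 0


@dataclass
class TruthLedger:
    """The exact ground truth behind one generated realization."""

    seed: int
    trends: dict = field(default_factory=dict)       # station -> layer -> param -> /yr
    couplings: dict = field(default_factory=dict)    # layer -> effective couplings
    calibration: dict = field(default_factory=dict)  # layer -> partial derivatives used
    outliers: list = field(default_factory=list)     # dicts: station, layer, date, parameter
    climatology: dict = field(default_factory=dict)  # layer -> param -> HarmonicSpec dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)


def nb_like(seed: int = 0, cadence: int = 1, outlier_rate: float = 0.01,
            n_years: int = 15) -> SyntheticConfig:
    """The default bay-like network profile.

    Ten stations (two sampled year-round, the rest May-October, one
    river-influenced low-salinity station "PD"), fifteen years at the given
    cadence, and the observed bay rates as injected truths: surface DO
    -0.69 and bottom DO +0.43 umol/kg/yr, bottom pH +0.0021/yr, surface
    chlorophyll -0.26 ug/L/yr, surface warming 0.02 and bottom warming
    0.041 degC/yr, slight salinification 0.0363 PSU/yr, and a +/-2 PSU
    decade-scale salinity excursion.
    """
    stations = [
        StationSpec("GD", year_round=True, salinity_offset=-1.0),
        StationSpec("TW", year_round=True, salinity_offset=0.5),
        StationSpec("BR", salinity_offset=-2.0),
        StationSpec("NP", salinity_offset=0.8),
        StationSpec("CP", salinity_offset=-0.5),
        StationSpec("MV", salinity_offset=0.2),
        StationSpec("QP", salinity_offset=-1.5),
        StationSpec("PP", salinity_offset=1.0),
        StationSpec("SR", salinity_offset=0.0),
        StationSpec("PD", salinity_offset=-12.0),
    ]
    climate = {
        "surface": {
            "temperature": HarmonicSpec(12.0, amp1=10.0, phase1=220, amp2=1.0,
                                        trend=0.020, ar1_sd=0.45, shared_sd=0.50,
                                        daily_sd=0.3, clip=(-2.5, 35)),
            "salinity": HarmonicSpec(29.5, amp1=1.2, phase1=280, amp2=0.4,
                                     trend=0.0363, ar1_sd=0.30, shared_sd=0.40,
                                     daily_sd=0.3, excursion_amp=2.0,
                                     clip=(0.5, 39)),
            "chl": HarmonicSpec(7.0, amp1=2.0, phase1=200, amp2=0.8, phase2=60,
                                trend=-0.26, ar1=0.5, ar1_sd=0.9, shared_sd=0.9,
                                daily_sd=0.6, clip=(-1.0, 60)),
        },
        "bottom": {
            "temperature": HarmonicSpec(11.5, amp1=9.0, phase1=230, amp2=0.8,
                                        trend=0.041, ar1_sd=0.40, shared_sd=0.45,
                                        daily_sd=0.3, clip=(-2.5, 35)),
            "salinity": HarmonicSpec(30.5, amp1=0.8, phase1=280, amp2=0.3,
                                     trend=0.020, ar1_sd=0.25, shared_sd=0.35,
                                     daily_sd=0.25, excursion_amp=1.5,
                                     clip=(0.5, 39)),
        },
    }
    do = {
        "surface": DOSpec(trend=-0.69, offset=8.0, chl_coupling=2.0,
                          temp_bio_coupling=0.95, ar1_sd=7.0, shared_sd=8.0),
        "bottom": DOSpec(trend=0.43, offset=-28.0, chl_coupling=0.0,
                         temp_bio_coupling=0.95, ar1_sd=7.0, shared_sd=8.0),
    }
    dic_noise = {"surface": DICNoiseSpec(), "bottom": DICNoiseSpec()}
    ph_trend = {"surface": 0.0005, "bottom": 0.0021}
    return SyntheticConfig(
        stations=stations, start_year=2005, end_year=2005 + n_years - 1,
        cadence=cadence, climate=climate, do=do, dic_noise=dic_noise,
        ph_trend=ph_trend, outlier_rate=outlier_rate, seed=seed)


# ---------------------------------------------------------------------------

def _harmonic(doy: np.ndarray, spec: HarmonicSpec) -> np.ndarray:
    w = 2.0 * np.pi / DAYS_PER_YEAR
    return (spec.amp1 * np.cos(w * (doy - spec.phase1))
            + spec.amp2 * np.cos(2.0 * w * (doy - spec.phase2)))


def _ar1(n_days: int, rho: float, innov_sd: float,
         rng: np.random.Generator) -> np.ndarray:
    """Daily AR(1) red noise with a stationary start."""
    if innov_sd == 0.0:
        return np.zeros(n_days)
    innov = rng.normal(0.0, innov_sd, n_days)
    x = np.empty(n_days)
    x[0] = innov[0] / np.sqrt(max(1.0 - rho * rho, 1e-12))
    for i in range(1, n_days):
        x[i] = rho * x[i - 1] + innov[i]
    return x


def _series(doy, t_years, t_total_years, spec: HarmonicSpec,
            rng: np.random.Generator, shared: np.ndarray,
            offset: float = 0.0) -> np.ndarray:
    n = len(doy)
    x = (spec.mean + offset + _harmonic(doy, spec) + spec.trend * t_years
         + shared + _ar1(n, spec.ar1, spec.ar1_sd, rng)
         + rng.normal(0.0, spec.daily_sd, n))
    if spec.excursion_amp:
        # two full periods over the record: zero projection onto the trend
        x = x + spec.excursion_amp * np.cos(
            2.0 * np.pi * 2.0 * (t_years - t_years[0]) / t_total_years)
    if spec.clip is not None:
        x = np.clip(x, *spec.clip)
    return x


def _mean_partial(fun, x0: np.ndarray, dx: float) -> float:
    """Mean centered finite-difference derivative of fun over sample points x0."""
    return float(np.mean((fun(x0 + dx) - fun(x0 - dx)) / (2.0 * dx)))


def inject_outliers(values: np.ndarray, rate: float, magnitude: float,
                    rng: np.random.Generator | int,
                    valid_range: tuple[float, float] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Replace a random fraction of days with values beyond the IQR fences.

    Each selected day is set to ``magnitude`` IQRs beyond the upper or lower
    Tukey fence of the clean series (side chosen at random among those that
    stay inside ``valid_range``).  Returns the modified copy and the indices
    of injected days.  Deterministic given the generator state or seed.
    """
    if not 0.0 <= rate <= 0.1:
        raise ValueError("outlier rate limited to [0, 0.1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = np.array(values, dtype=float, copy=True)
    finite = np.flatnonzero(np.isfinite(out))
    if rate == 0.0 or finite.size < 4:
        return out, np.empty(0, dtype=int)
    fences = iqr_fences(out[finite])
    if fences.iqr == 0:
        return out, np.empty(0, dtype=int)
    n = int(round(rate * finite.size))
    idx = rng.choice(finite, size=n, replace=False) if n else np.empty(0, dtype=int)
    hi_val = fences.upper + magnitude * fences.iqr
    lo_val = fences.lower - magnitude * fences.iqr
    lo_ok, hi_ok = True, True
    if valid_range is not None:
        lo_ok = lo_val >= valid_range[0]
        hi_ok = hi_val <= valid_range[1]
    if not (lo_ok or hi_ok):
        return out, np.empty(0, dtype=int)
    for i in idx:
        side_hi = rng.random() < 0.5
        if (side_hi and hi_ok) or not lo_ok:
            out[i] = hi_val
        else:
            out[i] = lo_val
    return out, np.sort(idx)


_OUTLIER_RANGES = {
    "temperature": (-2.9, 39.9), "salinity": (0.01, 39.9),
    "do_umolkg": (0.1, 900.0), "ph_nbs": (5.05, 9.95),
}


def generate_network(config: SyntheticConfig) -> tuple[pd.DataFrame, TruthLedger]:
    """Generate the full network and its truth ledger.

    Returns a record frame in the sensor-CSV layout (columns station,
    timestamp, layer, temperature, salinity, do_mgL, pH, chl, depth) and the
    :class:`TruthLedger`.  DO is emitted in mg/L (converted at in-situ T and
    S, as a sensor reports it); pH on the NBS scale.
    """
    master = np.random.SeedSequence(config.seed)
    shared_seed, *station_seeds = master.spawn(len(config.stations) + 1)

    dates = pd.date_range(f"{config.start_year}-01-01",
                          f"{config.end_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    t_years = (dates - dates[0]).days.to_numpy(float) / DAYS_PER_YEAR
    t_years = t_years - t_years.mean()
    t_total = (dates[-1] - dates[0]).days / DAYS_PER_YEAR

    ledger = TruthLedger(seed=config.seed)
    ledger.climatology = {
        layer: {p: asdict(spec) for p, spec in params.items()}
        for layer, params in config.climate.items()}

    calib = _calibrate(config)
    ledger.calibration = {layer: dict(v) for layer, v in calib.items()}
    ledger.couplings = {
        layer: {
            "do_per_chl": config.do[layer].chl_coupling,
            "do_per_degC_total": calib[layer]["dsol_dT"] + config.do[layer].temp_bio_coupling,
            "ph_per_do": config.ph_per_do,
            "dic_per_do": calib[layer]["dic_per_do"],
        } for layer in config.do}

    # bay-wide shared forcing, one series per layer/parameter
    shared_rng = np.random.default_rng(shared_seed)
    n_days = len(dates)
    shared: dict[str, dict[str, np.ndarray]] = {}
    for layer in ("surface", "bottom"):
        climate = config.climate[layer]
        dospec = config.do[layer]
        dicspec = config.dic_noise.get(layer, DICNoiseSpec(ar1_sd=0.0, shared_sd=0.0))
        shared[layer] = {
            param: _ar1(n_days, spec.ar1, spec.shared_sd, shared_rng)
            for param, spec in climate.items()}
        shared[layer]["do"] = _ar1(n_days, dospec.ar1, dospec.shared_sd, shared_rng)
        shared[layer]["dic"] = _ar1(n_days, dicspec.ar1, dicspec.shared_sd, shared_rng)

    frames = []
    for spec, seed in zip(config.stations, station_seeds):
        rng = np.random.default_rng(seed)
        for layer in ("surface", "bottom"):
            frames.append(_station_layer(
                spec, layer, config, calib, dates, doy, t_years, t_total,
                rng, shared[layer], ledger))
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["station", "layer", "timestamp"],
                                  kind="stable").reset_index(drop=True)
    return records, ledger


def _calibrate(config: SyntheticConfig) -> dict:
    """Per-layer partial derivatives and calibrated linear rates."""
    out = {}
    for layer, dospec in config.do.items():
        tspec = config.climate[layer]["temperature"]
        sspec = config.climate[layer]["salinity"]
        # sample the seasonal envelope of T and S for averaged partials
        doy_grid = np.linspace(0.0, DAYS_PER_YEAR, 24, endpoint=False)
        t_grid = tspec.mean + _harmonic(doy_grid, tspec)
        s_grid = sspec.mean + _harmonic(doy_grid, sspec)
        dsol_dT = _mean_partial(lambda t: sw.o2_solubility(t, s_grid), t_grid, 0.5)
        dsol_dS = _mean_partial(lambda s: sw.o2_solubility(t_grid, s), s_grid, 0.25)

        em, cs = config.endmembers, config.constants

        def ph_of(s, t, ddic=0.0):
            return cb.solve_ph_from_ta_dic(em.ta(s), em.dic(s) + ddic, t, s, cs)

        dph_dS = _mean_partial(lambda s: ph_of(s, t_grid), s_grid, 0.25)
        dph_dT = _mean_partial(lambda t: ph_of(s_grid, t), t_grid, 0.5)
        dph_dDIC = float(np.mean(
            (ph_of(s_grid, t_grid, 5.0) - ph_of(s_grid, t_grid, -5.0)) / 10.0))

        dic_per_do = config.ph_per_do / (-dph_dDIC)  # positive: DO up, DIC down

        chl_trend = (config.climate[layer]["chl"].trend
                     if "chl" in config.climate[layer] else 0.0)
        # biological DO rate needed so the total equals the requested trend
        bio_rate = (dospec.trend
                    - (dsol_dT + dospec.temp_bio_coupling) * tspec.trend
                    - dsol_dS * sspec.trend
                    - dospec.chl_coupling * chl_trend)
        do_dev_rate = (dospec.trend - dsol_dT * tspec.trend - dsol_dS * sspec.trend)
        # DIC rate delivering the requested total pH trend
        ph_target = config.ph_trend.get(layer, 0.0)
        dic_rate = ((ph_target - dph_dS * sspec.trend - dph_dT * tspec.trend)
                    / dph_dDIC + dic_per_do * do_dev_rate)
        out[layer] = {
            "dsol_dT": dsol_dT, "dsol_dS": dsol_dS,
            "dph_dS_conservative": dph_dS, "dph_dT": dph_dT,
            "dph_dDIC": dph_dDIC, "dic_per_do": dic_per_do,
            "do_bio_rate": bio_rate, "do_dev_rate": do_dev_rate,
            "dic_rate": dic_rate,
        }
    return out


def _station_layer(spec: StationSpec, layer: str, config: SyntheticConfig,
                   calib: dict, dates, doy, t_years, t_total,
                   rng: np.random.Generator, shared: dict,
                   ledger: TruthLedger) -> pd.DataFrame:
    climate = config.climate[layer]
    dospec = config.do[layer]
    dicspec = config.dic_noise.get(layer, DICNoiseSpec(ar1_sd=0.0, shared_sd=0.0))
    cal = calib[layer]
    n = len(doy)

    temperature = _series(doy, t_years, t_total, climate["temperature"], rng,
                          shared["temperature"], spec.temperature_offset)
    salinity = _series(doy, t_years, t_total, climate["salinity"], rng,
                       shared["salinity"], spec.salinity_offset)
    chl = None
    chl_dev = 0.0
    if layer == "surface" and "chl" in climate:
        cspec = climate["chl"]
        chl = _series(doy, t_years, t_total, cspec, rng, shared["chl"])
        chl_dev = chl - (cspec.mean + _harmonic(doy, cspec))

    # biological DO deviation (everything except solubility)
    t_dev = temperature - (climate["temperature"].mean + spec.temperature_offset
                           + _harmonic(doy, climate["temperature"]))
    noise = (shared["do"] + _ar1(n, dospec.ar1, dospec.ar1_sd, rng)
             + rng.normal(0.0, dospec.daily_sd, n))
    do_dev = (dospec.offset
              + dospec.chl_coupling * chl_dev
              + dospec.temp_bio_coupling * t_dev
              + cal["do_bio_rate"] * t_years
              + noise)
    do_umolkg = np.maximum(sw.o2_solubility(temperature, salinity) + do_dev, 1.0)

    # carbonate chemistry: conservative DIC + biological/biogeochemical parts
    dic_noise = shared["dic"] + _ar1(n, dicspec.ar1, dicspec.ar1_sd, rng)
    dic = (config.endmembers.dic(salinity)
           - cal["dic_per_do"] * (do_dev - dospec.offset)
           + cal["dic_rate"] * t_years
           + dic_noise)
    ta = config.endmembers.ta(salinity)
    ph_nbs = (cb.solve_ph_from_ta_dic(ta, dic, temperature, salinity,
                                      config.constants)
              + cb.NBS_TOTAL_OFFSET)

    # truth trends for this station/layer
    ledger.trends.setdefault(spec.station_id, {})[layer] = {
        "temperature": climate["temperature"].trend,
        "salinity": climate["salinity"].trend,
        "do_umolkg": dospec.trend,
        "ph_nbs": config.ph_trend.get(layer, 0.0),
        **({"chl": climate["chl"].trend} if chl is not None else {}),
    }

    # sensor-artifact outliers on the reported values only
    arrays = {"temperature": temperature, "salinity": salinity,
              "do_umolkg": do_umolkg, "ph_nbs": ph_nbs}
    if config.outlier_rate > 0:
        for param in ("temperature", "salinity", "do_umolkg", "ph_nbs"):
            arrays[param], idx = inject_outliers(
                arrays[param], config.outlier_rate, config.outlier_magnitude,
                rng, _OUTLIER_RANGES[param])
            for i in idx:
                ledger.outliers.append({
                    "station": spec.station_id, "layer": layer,
                    "date": dates[i].date().isoformat(), "parameter": param})

    # seasonal sampling window
    if spec.year_round:
        mask = np.ones(len(dates), dtype=bool)
    else:
        mask = dates.month.isin(config.sampling_months)

    frame = pd.DataFrame({
        "date": dates[mask],
        "temperature": arrays["temperature"][mask],
        "salinity": arrays["salinity"][mask],
        "do_umolkg": arrays["do_umolkg"][mask],
        "ph_nbs": arrays["ph_nbs"][mask],
        "chl": chl[mask] if chl is not None else np.nan,
    })
    frame["do_mgL"] = sw.do_umolkg_to_mgL(
        frame["do_umolkg"].to_numpy(), frame["temperature"].to_numpy(),
        frame["salinity"].to_numpy())

    frame = _expand_cadence(frame, config.cadence, rng, climate, dospec)
    frame["station"] = spec.station_id
    frame["layer"] = layer
    frame["depth"] = 1.0 if layer == "surface" else spec.bottom_depth
    cols = ["station", "timestamp", "layer", "temperature", "salinity",
            "do_mgL", "pH", "chl", "depth"]
    return frame.rename(columns={"ph_nbs": "pH"})[cols]


def _expand_cadence(frame: pd.DataFrame, cadence: int, rng, climate, dospec
                    ) -> pd.DataFrame:
    """Expand daily truth to sub-daily readings at even intervals.

    Sub-daily structure is white reading noise around the daily value: the
    analysis consumes daily means, so tidal-frequency realism is out of
    scope.  Reported pH keeps the daily speciated value.
    """
    if cadence < 1:
        raise ValueError("cadence must be >= 1")
    if cadence == 1:
        out = frame.copy()
        out["timestamp"] = pd.to_datetime(out["date"]) + pd.Timedelta(hours=12)
        return out.drop(columns=["date", "do_umolkg"])
    reps = frame.loc[frame.index.repeat(cadence)].reset_index(drop=True)
    offsets = np.tile(np.arange(cadence) * (24.0 / cadence), len(frame))
    reps["timestamp"] = pd.to_datetime(reps["date"]) + pd.to_timedelta(offsets, unit="h")
    n = len(reps)
    reps["temperature"] += rng.normal(0, climate["temperature"].daily_sd / 2, n)
    reps["salinity"] = np.maximum(
        reps["salinity"] + rng.normal(0, climate["salinity"].daily_sd / 2, n), 0.05)
    reps["do_mgL"] = np.maximum(
        reps["do_mgL"] + rng.normal(0, dospec.daily_sd / 30, n), 0.05)
    if "chl" in climate:
        reps["chl"] = np.maximum(
            reps["chl"] + rng.normal(0, climate["chl"].daily_sd / 2, n), 0.01)
    return reps.drop(columns=["date", "do_umolkg"])
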